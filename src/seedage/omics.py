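"""Metabolite feature-table hygiene and correlation screens.

Untargeted LC-MS (lipids) and GC-MS (volatiles) profiling of stored seeds
yields a samples × compounds matrix of relative intensities.  This module
implements the standard downstream steps: reproducibility filtering,
internal-standard normalisation, Pearson correlation of each compound with
seed viability (mean germination %) and with storage duration, threshold
selection of top compounds, fold-change versus the initial control,
inclusion–exclusion set comparisons across storage conditions, Kovats
retention indices for GC features, and PCA score exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "FeatureTable",
    "filter_features",
    "normalize_internal_standard",
    "correlate",
    "select_top",
    "percent_of_initial",
    "venn_sets",
    "retention_index",
    "pca_scores",
]

#: Default reproducibility filter: detected in >= 3 samples above 15,000
#: counts (three times a typical peak-picking detection threshold).
DEFAULT_MIN_SAMPLES = 3
DEFAULT_MIN_ABUNDANCE = 15_000.0


@dataclass
class FeatureTable:
    """Samples × compounds relative-intensity matrix with sidecar metadata.

    Attributes
    ----------
    intensities
        DataFrame, rows = samples, columns = compound ids, non-negative.
        Missing values are allowed (treated as not-detected for filtering
        and excluded pairwise for correlation).
    sample_meta
        DataFrame indexed like ``intensities`` rows, with at least
        ``treatment`` and ``storage_days`` columns; ``germination_pct``
        (mean germination of the matching lot/treatment/time) is required
        for viability correlations.
    compound_meta
        DataFrame indexed by compound id; typical columns: ``rt_min``,
        ``mz``, ``adduct``.
    is_channel
        Compound id of the internal-standard channel, if present.
    """

    intensities: pd.DataFrame
    sample_meta: pd.DataFrame = None
    compound_meta: pd.DataFrame = None
    is_channel: str | None = None

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.intensities.index)
        if self.compound_meta is None:
            self.compound_meta = pd.DataFrame(index=self.intensities.columns)
        if (self.intensities.to_numpy(float) < 0).any():
            raise ValueError("intensities must be non-negative")
        if not self.sample_meta.index.equals(self.intensities.index):
            raise ValueError("sample_meta index must match intensity rows")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.intensities.shape[1]

    def _subset(self, compounds: Sequence) -> "FeatureTable":
        return FeatureTable(
            intensities=self.intensities[list(compounds)],
            sample_meta=self.sample_meta,
            compound_meta=self.compound_meta.loc[
                self.compound_meta.index.intersection(compounds)
            ].reindex(compounds),
            is_channel=self.is_channel if self.is_channel in compounds else None,
        )


def filter_features(
    table: FeatureTable,
    min_samples: int = DEFAULT_MIN_SAMPLES,
    min_abundance: float = DEFAULT_MIN_ABUNDANCE,
) -> FeatureTable:
    """Keep compounds detected in at least ``min_samples`` samples strictly
    above ``min_abundance``.

    Missing intensities count as not detected.  Column order is preserved;
    the operation is idempotent.  The internal-standard channel, when set,
    is always retained (it is required downstream).
    """
    x = table.intensities.fillna(0.0)
    detected = (x > min_abundance).sum(axis=0)
    keep = detected[detected >= min_samples].index.tolist()
    if table.is_channel is not None and table.is_channel not in keep:
        keep.append(table.is_channel)
    kept = [c for c in table.intensities.columns if c in set(keep)]
    return table._subset(kept)


def normalize_internal_standard(
    table: FeatureTable, is_channel: str | None = None
) -> FeatureTable:
    """Correct per-sample intensity variation against the internal standard.

    Each sample's intensities are divided by its internal-standard (IS)
    intensity and rescaled by the panel-mean IS intensity, so the IS channel
    becomes constant and the overall intensity scale is preserved.  Results
    are thereby invariant to any per-sample multiplicative factor (dilution,
    injection volume).
    """
    is_channel = is_channel or table.is_channel
    if is_channel is None or is_channel not in table.intensities.columns:
        raise ValueError("internal-standard channel not found in table")
    is_vals = table.intensities[is_channel]
    bad = is_vals[~(is_vals > 0)].index.tolist()
    if bad:
        raise ValueError(f"non-positive internal-standard intensity in samples: {bad}")
    factor = is_vals.mean() / is_vals
    out = table.intensities.mul(factor, axis=0)
    return FeatureTable(
        intensities=out,
        sample_meta=table.sample_meta,
        compound_meta=table.compound_meta,
        is_channel=is_channel,
    )


def correlate(table: FeatureTable, trait: str) -> pd.DataFrame:
    """Pearson correlation of every compound with a per-sample trait.

    ``trait`` names a column of ``sample_meta`` — typically
    ``"germination_pct"`` (viability) or ``"storage_days"``.  Samples with a
    missing trait or missing intensity are excluded pairwise.  Returns a
    DataFrame indexed by compound with columns ``r``, ``p_value`` and ``n``;
    compounds with zero variance over the used samples get NaN.
    """
    if trait not in table.sample_meta.columns:
        raise ValueError(f"trait {trait!r} not in sample metadata")
    tvals = table.sample_meta[trait].astype(float)
    if tvals.dropna().size < 3:
        raise ValueError("need at least 3 samples with the trait defined")
    if tvals.dropna().nunique() == 1:
        raise ValueError(f"trait {trait!r} is constant; correlation undefined")
    rows = []
    for comp in table.intensities.columns:
        pair = pd.concat([table.intensities[comp], tvals], axis=1).dropna()
        n = len(pair)
        x = pair.iloc[:, 0].to_numpy(float)
        y = pair.iloc[:, 1].to_numpy(float)
        if n < 3 or _near_constant(x) or _near_constant(y):
            r, p = math.nan, math.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append({"compound": comp, "r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows).set_index("compound")


def _near_constant(x: np.ndarray) -> bool:
    """Variation below float precision — correlation is undefined."""
    scale = np.max(np.abs(x)) or 1.0
    return bool(np.ptp(x) <= 1e-10 * scale)


@dataclass(frozen=True)
class SelectionRule:
    """A threshold rule on a correlation column, e.g. ``r < -0.98``."""

    column: str
    op: str  # "<" or ">"
    threshold: float

    def apply(self, results: pd.DataFrame) -> set:
        if self.op not in ("<", ">"):
            raise ValueError(f"unknown comparison {self.op!r}")
        vals = results[self.column]
        mask = vals < self.threshold if self.op == "<" else vals > self.threshold
        return set(results.index[mask.fillna(False)])


def select_top(
    results: pd.DataFrame, rule: SelectionRule | Mapping | tuple
) -> set:
    """Select compounds whose correlation passes a strict threshold rule.

    Rules are data, not code: ``SelectionRule("r", "<", -0.98)``, a mapping
    with the same keys, or a ``(column, op, threshold)`` tuple.  Inequalities
    are strict on both sides of zero (``r < -0.98`` excludes exactly −0.98).
    """
    if results.empty:
        raise ValueError("empty correlation results")
    if isinstance(rule, Mapping):
        rule = SelectionRule(rule["column"], rule["op"], rule["threshold"])
    elif isinstance(rule, tuple):
        rule = SelectionRule(*rule)
    if not isinstance(rule, SelectionRule):
        raise ValueError(f"unknown rule specification: {rule!r}")
    if rule.column not in results.columns:
        raise ValueError(f"unknown rule column {rule.column!r}")
    return rule.apply(results)


def percent_of_initial(
    table: FeatureTable,
    group_col: str = "storage_days",
    initial_group=0,
) -> pd.DataFrame:
    """Mean intensity per timepoint as a percentage of the initial control.

    ``100 × mean(timepoint) / mean(initial)`` per compound — values below
    100 indicate compounds declining during storage (e.g. antioxidants).
    Compounds with zero mean in the initial group get NaN.
    """
    if group_col not in table.sample_meta.columns:
        raise ValueError(f"{group_col!r} not in sample metadata")
    groups = table.sample_meta[group_col]
    if not (groups == initial_group).any():
        raise ValueError(f"no samples in initial group {initial_group!r}")
    means = table.intensities.groupby(groups).mean()
    initial = means.loc[initial_group].replace(0.0, np.nan)
    out = 100.0 * means.div(initial, axis=1)
    out.index.name = group_col
    return out


def venn_sets(sets: Mapping[str, set]) -> pd.DataFrame:
    """Exact inclusion–exclusion partition of 2–4 labelled sets.

    Returns one row per non-empty membership pattern with boolean columns
    per set name, the exclusive ``count`` of elements showing exactly that
    pattern, and the pattern's member list.  Counts sum to the size of the
    union, and any set's total is recovered by summing its rows.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    if len(names) > 4:
        raise ValueError("at most 4 sets supported")
    universe = set().union(*sets.values())
    rows = []
    for element in universe:
        pattern = tuple(element in sets[n] for n in names)
        rows.append((pattern, element))
    agg: dict[tuple, list] = {}
    for pattern, element in rows:
        agg.setdefault(pattern, []).append(element)
    out = []
    for pattern, members in sorted(agg.items(), reverse=True):
        row = {n: inc for n, inc in zip(names, pattern)}
        row["count"] = len(members)
        row["members"] = sorted(map(str, members))
        out.append(row)
    return pd.DataFrame(out)


def retention_index(
    rt_min: float, alkane_ladder: Sequence[tuple[int, float]]
) -> float:
    """Kovats retention index by linear interpolation on an n-alkane ladder.

    ``alkane_ladder`` is a sequence of ``(carbon_number, rt_min)`` pairs
    (typically C8–C22) with strictly increasing retention times.  For a
    retention time between the alkanes with n and n+1 carbons:

        RI = 100 · (n + (rt − rt_n) / (rt_{n+1} − rt_n))

    Retention times outside the ladder span raise — no silent extrapolation.
    """
    ladder = sorted(alkane_ladder, key=lambda x: x[0])
    carbons = np.array([c for c, _ in ladder], dtype=float)
    rts = np.array([r for _, r in ladder], dtype=float)
    if len(ladder) < 2:
        raise ValueError("alkane ladder needs at least two rungs")
    if np.any(np.diff(carbons) <= 0) or np.any(np.diff(rts) <= 0):
        raise ValueError("alkane ladder must be strictly increasing in rt")
    if not rts[0] <= rt_min <= rts[-1]:
        raise ValueError(
            f"retention time {rt_min} outside alkane ladder span "
            f"[{rts[0]}, {rts[-1]}]"
        )
    i = int(np.searchsorted(rts, rt_min, side="right")) - 1
    i = min(max(i, 0), len(ladder) - 2)
    frac = (rt_min - rts[i]) / (rts[i + 1] - rts[i])
    return 100.0 * (carbons[i] + frac * (carbons[i + 1] - carbons[i]))


def pca_scores(
    table: FeatureTable, n_components: int = 2, log_scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and explained-variance fractions from a PCA.

    The intensity matrix is mean-centred per compound (and optionally
    log10-transformed first, with missing/zero values floored at 1).
    Rank-deficient inputs return however many components exist.
    """
    if table.n_samples < 2 or table.n_compounds < 2:
        raise ValueError("PCA needs at least 2 samples and 2 compounds")
    x = table.intensities.fillna(0.0).to_numpy(float)
    if log_scale:
        x = np.log10(np.maximum(x, 1.0))
    k = min(n_components, table.n_samples - 1, table.n_compounds)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(x)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=table.intensities.index, columns=cols),
        pca.explained_variance_ratio_,
    )
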