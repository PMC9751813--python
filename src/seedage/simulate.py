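"""Synthetic germination panels and metabolite feature tables.

The generators reproduce the statistical structure the analysis stages
assume, so the whole pipeline is testable without any measured data:

* germination counts are binomial draws whose success probability follows
  the viability probit line, optionally multiplied by a dormancy-release
  probit (after-ripening);
* within-test germination times follow the Hill curve, with t50 inflated
  as lots age (aged seeds germinate slower);
* metabolite intensities are log-normal, with designated aging-responsive
  channels whose log-intensity rises in proportion to viability loss,
  antioxidant channels that decline, and a multiplicative internal-standard
  channel emulating per-sample instrument variation.

Every generator is deterministic given its recorded seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from seedage import datasets
from seedage.annotation import adduct_mz, tag_formula
from seedage.omics import FeatureTable

__all__ = [
    "AccessionTruth",
    "PanelSpec",
    "OmicsSpec",
    "default_panel_spec",
    "simulate_survival_panel",
    "simulate_germination_timecourses",
    "simulate_feature_table",
]

#: Plausible truth ranges for a rice diversity panel (NED; NED/day).
KI_RANGE = (0.5, 4.0)
SIGMA_INV_RANGE = (0.03, 0.13)


@dataclass(frozen=True)
class AccessionTruth:
    """True longevity parameters of one simulated seed lot."""

    Ki: float
    sigma_inv: float
    Knd: float | None = None  # initial non-dormant proportion, NED
    sigma_nd: float | None = None  # days per probit of dormancy release

    def __post_init__(self) -> None:
        if not KI_RANGE[0] <= self.Ki <= KI_RANGE[1]:
            raise ValueError(f"Ki outside plausible range {KI_RANGE}")
        if not SIGMA_INV_RANGE[0] <= self.sigma_inv <= SIGMA_INV_RANGE[1]:
            raise ValueError(f"sigma_inv outside plausible range {SIGMA_INV_RANGE}")
        if (self.Knd is None) != (self.sigma_nd is None):
            raise ValueError("Knd and sigma_nd must be given together")
        if self.sigma_nd is not None and self.sigma_nd <= 0:
            raise ValueError("sigma_nd must be positive")


@dataclass(frozen=True)
class PanelSpec:
    """Design of a simulated storage experiment.

    ``treatments`` maps a storage-condition label to its aging-rate
    multiplier: the viability line sees the effective dose
    ``p × multiplier``.  The study design this emulates is 20 accessions ×
    4 storage conditions × storage days {0, 14, 21, 28, 42, 56} × 2
    replicates of 45 seeds.
    """

    accessions: dict[str, AccessionTruth]
    treatments: dict[str, float] = field(
        default_factory=lambda: {
            "ambient": 0.10,
            "EPPN": 0.15,
            "EPPO": 1.0,
            "CD": 0.8,
        }
    )
    storage_days: tuple = (0, 14, 21, 28, 42, 56)
    replicates: int = 2
    seeds_per_test: int = 45
    t50_h: float = 64.0  # unaged time to half-maximal germination
    hill_h: float = 4.0
    aging_t50_factor: float = 3.0  # fractional t50 inflation at full dose
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError("at least one accession required")
        if self.replicates < 1 or self.seeds_per_test < 1:
            raise ValueError("replicates and seeds_per_test must be >= 1")
        if any(m < 0 for m in self.treatments.values()):
            raise ValueError("rate multipliers must be non-negative")


#: Accessions of the default panel known to show dormancy/after-ripening.
_DORMANT_DEFAULT = {"IRGC 117266", "IRGC 117267", "IRGC 117283"}


def default_panel_spec(seed: int = 0, **overrides) -> PanelSpec:
    """The study-shaped default panel.

    Truth values are the published EPPO longevity parameters of the
    20-accession rice panel (see :func:`seedage.datasets.rice_longevity_panel`),
    clipped into the plausible simulation range; the three lots that showed
    after-ripening in storage carry a dormancy component
    (Knd = 0.5 NED, σ_nd = 10 d/probit).
    """
    panel = datasets.rice_longevity_panel("EPPO")
    accs = {}
    for _, row in panel.iterrows():
        kwargs = {}
        if row["accession"] in _DORMANT_DEFAULT:
            kwargs = {"Knd": 0.5, "sigma_nd": 10.0}
        accs[row["accession"]] = AccessionTruth(
            Ki=float(np.clip(row["Ki"], *KI_RANGE)),
            sigma_inv=float(np.clip(row["sigma_inv"], *SIGMA_INV_RANGE)),
            **kwargs,
        )
    return PanelSpec(accessions=accs, seed=seed, **overrides)


def _germination_prob(truth: AccessionTruth, dose_days: float, age_days: float) -> float:
    """P(germinate) = P(non-dormant after ``age_days``) × P(viable at ``dose_days``)."""
    viable = ndtr(truth.Ki - dose_days * truth.sigma_inv)
    if truth.Knd is None:
        return float(viable)
    nondormant = ndtr(truth.Knd + age_days / truth.sigma_nd)
    return float(nondormant * viable)


def simulate_survival_panel(spec: PanelSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw binomial germination counts for every panel cell.

    Returns ``(observations, truth)``:

    * ``observations`` — long format with columns ``accession, treatment,
      replicate, storage_days, germinated, total``;
    * ``truth`` — one row per accession with the generating parameters and
      the true P50 (for recovery tests).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for acc in sorted(spec.accessions):
        truth = spec.accessions[acc]
        for trt in spec.treatments:
            mult = spec.treatments[trt]
            for day in spec.storage_days:
                prob = _germination_prob(truth, day * mult, day)
                for rep in range(1, spec.replicates + 1):
                    g = int(rng.binomial(spec.seeds_per_test, prob))
                    rows.append(
                        (acc, trt, f"R{rep}", float(day), g, spec.seeds_per_test)
                    )
    obs = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "treatment",
            "replicate",
            "storage_days",
            "germinated",
            "total",
        ],
    )
    truth_rows = []
    for acc in sorted(spec.accessions):
        t = spec.accessions[acc]
        truth_rows.append(
            {
                "accession": acc,
                "Ki": t.Ki,
                "sigma_inv": t.sigma_inv,
                "Knd": t.Knd if t.Knd is not None else math.nan,
                "sigma_nd": t.sigma_nd if t.sigma_nd is not None else math.nan,
                "p50": t.Ki / t.sigma_inv,
            }
        )
    return obs, pd.DataFrame(truth_rows)


def simulate_germination_timecourses(
    observations: pd.DataFrame, spec: PanelSpec
) -> pd.DataFrame:
    """Expand final germination counts into daily cumulative time courses.

    Each germinating seed draws its germination time from the Hill-implied
    distribution, truncated at the 336 h test end; the lot-level t50 is
    inflated with aging dose by ``1 + aging_t50_factor × dose/56`` to
    emulate the slower germination of aged seeds.  Counts are reported on a
    daily (24 h) grid up to 336 h.
    """
    rng = np.random.default_rng(spec.seed + 1)
    grid = np.arange(24.0, 336.0 + 1e-9, 24.0)
    rows = []
    for _, r in observations.iterrows():
        mult = spec.treatments[r["treatment"]]
        dose = r["storage_days"] * mult
        t50 = spec.t50_h * (1.0 + spec.aging_t50_factor * dose / 56.0)
        h = spec.hill_h
        g = int(r["germinated"])
        if g > 0:
            f336 = 336.0**h / (t50**h + 336.0**h)
            u = rng.uniform(0.0, f336, size=g)
            times = t50 * (u / (1.0 - u)) ** (1.0 / h)
            cum = np.searchsorted(np.sort(times), grid, side="right")
        else:
            cum = np.zeros_like(grid, dtype=int)
        for t, c in zip(grid, cum):
            rows.append(
                (
                    r["accession"],
                    r["treatment"],
                    r["replicate"],
                    r["storage_days"],
                    float(t),
                    int(c),
                    int(r["total"]),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "treatment",
            "replicate",
            "storage_days",
            "time_h",
            "cum_germinated",
            "total",
        ],
    )


@dataclass(frozen=True)
class OmicsSpec:
    """Design of a simulated metabolite feature table.

    Responsive channels gain ``slope × (100 − viability)/100`` log10 units
    of intensity as viability falls (oxidized-lipid behaviour); antioxidant
    channels decline.  ``noise_cv`` is the log-normal intensity CV; the
    internal-standard channel applies a per-sample multiplicative factor
    with CV ``is_cv`` to every compound, emulating injection variation.
    """

    n_compounds: int = 200
    n_responsive: int = 10
    n_antioxidant: int = 5
    slope_range: tuple = (0.8, 1.6)  # log10 units over full viability loss
    antioxidant_slope_range: tuple = (-0.6, -0.3)
    baseline_log10_range: tuple = (3.7, 5.7)
    noise_cv: float = 0.20
    is_cv: float = 0.15
    is_nominal: float = 1.0e5
    is_channel: str = "IS_PC_10:0_10:0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responsive + self.n_antioxidant > self.n_compounds:
            raise ValueError("more designated channels than compounds")
        if self.noise_cv <= 0 or self.is_cv <= 0 or self.is_nominal <= 0:
            raise ValueError("noise parameters must be positive")


def _lognormal_sd(cv: float) -> float:
    """Natural-log sigma of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log(1.0 + cv**2))


def simulate_feature_table(
    spec: OmicsSpec, sample_meta: pd.DataFrame
) -> tuple[FeatureTable, pd.DataFrame]:
    """Simulate a samples × compounds intensity table for given samples.

    ``sample_meta`` must be indexed by sample id and provide ``treatment``,
    ``storage_days`` and ``germination_pct`` (the panel-mean germination of
    the matching lot/treatment/time).  Returns the feature table (with m/z
    and retention-time metadata; responsive channels carry oxidized-TAG
    masses so the annotation stage has real work to do) and a truth record
    listing each channel's role and slope.
    """
    required = {"treatment", "storage_days", "germination_pct"}
    missing = required - set(sample_meta.columns)
    if missing:
        raise ValueError(f"sample_meta missing columns: {sorted(missing)}")
    rng = np.random.default_rng(spec.seed)
    n_s = len(sample_meta)
    names = [f"C{i + 1:04d}" for i in range(spec.n_compounds)]
    roles = np.array(["inert"] * spec.n_compounds, dtype=object)
    roles[: spec.n_responsive] = "responsive"
    roles[spec.n_responsive : spec.n_responsive + spec.n_antioxidant] = "antioxidant"

    slopes = np.zeros(spec.n_compounds)
    slopes[roles == "responsive"] = rng.uniform(
        *spec.slope_range, size=spec.n_responsive
    )
    slopes[roles == "antioxidant"] = rng.uniform(
        *spec.antioxidant_slope_range, size=spec.n_antioxidant
    )
    baselines = rng.uniform(*spec.baseline_log10_range, size=spec.n_compounds)

    loss = (100.0 - sample_meta["germination_pct"].to_numpy(float)) / 100.0
    log10_mu = baselines[None, :] + slopes[None, :] * loss[:, None]
    sd_ln = _lognormal_sd(spec.noise_cv)
    noise = rng.normal(0.0, sd_ln / math.log(10.0), size=(n_s, spec.n_compounds))
    intens = 10.0 ** (log10_mu + noise)

    # per-sample instrument factor, recorded by the internal standard
    is_factor = rng.lognormal(mean=0.0, sigma=_lognormal_sd(spec.is_cv), size=n_s)
    intens = intens * is_factor[:, None]
    is_col = spec.is_nominal * is_factor

    intensities = pd.DataFrame(intens, index=sample_meta.index, columns=names)
    intensities[spec.is_channel] = is_col

    # compound metadata: oxidized TAGs for responsive channels
    tag_c = rng.choice(np.arange(48, 57, 2), size=spec.n_compounds)
    tag_d = rng.integers(1, 7, size=spec.n_compounds)
    meta_rows = []
    for j, name in enumerate(names):
        if roles[j] == "responsive":
            n_o = int(rng.integers(1, 3))
        elif roles[j] == "antioxidant":
            n_o = 0
        else:
            meta_rows.append(
                {
                    "compound": name,
                    "rt_min": float(rng.uniform(1.0, 20.0)),
                    "mz": float(rng.uniform(300.0, 1000.0)),
                    "adduct": "",
                    "formula": "",
                }
            )
            continue
        f = tag_formula(int(tag_c[j]), int(tag_d[j]), n_o)
        mz = adduct_mz(f, "ammoniated")
        mz *= 1.0 + rng.uniform(-1.5e-6, 1.5e-6)  # instrument mass error
        meta_rows.append(
            {
                "compound": name,
                "rt_min": float(rng.uniform(12.0, 20.0)),
                "mz": mz,
                "adduct": "ammoniated",
                "formula": f,
            }
        )
    meta_rows.append(
        {
            "compound": spec.is_channel,
            "rt_min": 8.0,
            "mz": adduct_mz("C28H56NO8P", "protonated"),
            "adduct": "protonated",
            "formula": "C28H56NO8P",
        }
    )
    compound_meta = pd.DataFrame(meta_rows).set_index("compound")

    table = FeatureTable(
        intensities=intensities,
        sample_meta=sample_meta.copy(),
        compound_meta=compound_meta,
        is_channel=spec.is_channel,
    )
    truth = pd.DataFrame(
        {"compound": names, "role": roles, "slope": slopes}
    ).set_index("compound")
    return table, truth
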