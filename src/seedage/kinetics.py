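"""Within-test germination kinetics and the ΔEPPO pressure correction.

A germination test follows the cumulative fraction of germinated seeds over
up to 336 h.  The cumulative curve is summarised by fitting a Hill function

    G(t) = Gmax · t^h / (t50^h + t^h)

where ``Gmax`` is the plateau germination percentage, ``t50`` the time at
which the fitted curve reaches half of ``Gmax``, and ``h`` a dimensionless
steepness exponent.

Because storing seeds under 20 MPa of nitrogen (EPPN) alone already affects
some lots, germination traits measured after high-pressure-oxygen (EPPO)
aging are corrected replicate-wise by the difference between the ambient
control and the pressure control of the same lot; the corrected series is
labelled ΔEPPO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "GerminationCurveFit",
    "hill_curve",
    "fit_germination_curve",
    "delta_eppo_correct",
]

#: Germination tests are scored for at most 14 days.
MAX_TEST_HOURS = 336.0
HILL_EXPONENT_BOUNDS = (1.0, 20.0)


def hill_curve(t: np.ndarray, gmax: float, t50: float, h: float) -> np.ndarray:
    """Cumulative Hill germination curve, in the same units as ``gmax``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = gmax * t[pos] ** h / (t50**h + t[pos] ** h)
    return out


@dataclass
class GerminationCurveFit:
    """Hill-curve summary of one germination test."""

    gmax: float  # fitted plateau, percent of seeds sown
    t50: float  # hours to half the fitted plateau (NaN if no germination)
    h: float  # Hill exponent
    gmax_raw: float  # observed percentage at the final (<= 336 h) scoring
    rss: float  # residual sum of squares on the percentage scale
    left_censored: bool = False  # all germination before the first scoring

    @property
    def t50_defined(self) -> bool:
        return math.isfinite(self.t50)


def _validate_counts(times, cumulative, total):
    t = np.asarray(times, dtype=float)
    c = np.asarray(cumulative, dtype=float)
    if t.ndim != 1 or t.size < 4:
        raise ValueError("need at least 4 observation times")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[-1] > MAX_TEST_HOURS:
        raise ValueError(f"final observation exceeds {MAX_TEST_HOURS:.0f} h")
    if np.any(np.diff(c) < 0):
        raise ValueError("cumulative germination must be non-decreasing")
    if np.any(c < 0) or np.any(c > total):
        raise ValueError("cumulative counts must lie in [0, total]")
    return t, c


def fit_germination_curve(
    times_h, cumulative_germinated, total: int
) -> GerminationCurveFit:
    """Fit the Hill curve to one cumulative germination time course.

    ``cumulative_germinated`` are counts out of ``total`` seeds sown;
    fitting is least squares on the percentage scale.  Start values take
    ``Gmax`` from the last point, ``t50`` from the first crossing of the
    half-maximum and ``h = 4``; the exponent is bounded to [1, 20].

    A test with zero germination returns ``Gmax = 0`` with an undefined
    (NaN) ``t50``.  If every germinating seed had already germinated at the
    first scoring, ``t50`` is only known to be at most the first time and
    the fit is flagged ``left_censored``.
    """
    t, c = _validate_counts(times_h, cumulative_germinated, total)
    pct = 100.0 * c / total
    gmax_raw = float(pct[-1])

    if c[-1] == 0:
        return GerminationCurveFit(
            gmax=0.0, t50=math.nan, h=math.nan, gmax_raw=0.0, rss=0.0
        )

    left_censored = c[0] == c[-1]

    g0 = max(gmax_raw, 1e-6)
    half = g0 / 2.0
    above = np.nonzero(pct >= half)[0]
    t50_0 = float(t[above[0]]) if above.size else float(t[-1])
    t50_0 = max(t50_0, 1e-3)

    lo = [0.0, 1e-3, HILL_EXPONENT_BOUNDS[0]]
    hi = [100.0, 10.0 * MAX_TEST_HOURS, HILL_EXPONENT_BOUNDS[1]]
    x0 = np.clip([g0, t50_0, 4.0], lo, hi)

    res = optimize.least_squares(
        lambda th: hill_curve(t, *th) - pct, x0, bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    gmax, t50, h = res.x
    rss = float(np.sum(res.fun**2))
    if left_censored:
        t50 = min(t50, float(t[0]))
    return GerminationCurveFit(
        gmax=float(gmax),
        t50=float(t50),
        h=float(h),
        gmax_raw=gmax_raw,
        rss=rss,
        left_censored=bool(left_censored),
    )


def delta_eppo_correct(
    trait_eppo: pd.DataFrame,
    trait_ambient_ctrl: pd.DataFrame,
    trait_eppn_ctrl: pd.DataFrame,
    value_col: str = "value",
    percent: bool = True,
) -> pd.DataFrame:
    """Replicate-wise pressure correction of EPPO germination traits (ΔEPPO).

    ``corrected = eppo + (ambient_ctrl − eppn_ctrl)`` per (accession,
    replicate), with the controls taken at the fixed control storage time
    (21 days).  Percentage traits are clipped to [0, 100] after the
    correction; the clip is applied per replicate, never after averaging.

    Parameters
    ----------
    trait_eppo
        Columns ``accession, replicate, storage_days, <value_col>`` — the
        EPPO series to correct.
    trait_ambient_ctrl, trait_eppn_ctrl
        Columns ``accession, replicate, <value_col>`` — one control value
        per lot and replicate.
    percent
        Clip the corrected values to [0, 100] (set False for t50 in hours).

    A missing control for any (accession, replicate) present in the EPPO
    series propagates as NaN in the output — it is never imputed.
    """
    keys = ["accession", "replicate"]
    for df, name in (
        (trait_eppo, "trait_eppo"),
        (trait_ambient_ctrl, "trait_ambient_ctrl"),
        (trait_eppn_ctrl, "trait_eppn_ctrl"),
    ):
        missing = [c for c in keys + [value_col] if c not in df.columns]
        if missing:
            raise ValueError(f"{name} missing columns: {missing}")

    amb = trait_ambient_ctrl.set_index(keys)[value_col]
    epn = trait_eppn_ctrl.set_index(keys)[value_col]
    if amb.index.has_duplicates or epn.index.has_duplicates:
        raise ValueError("controls must be unique per (accession, replicate)")
    offset = (amb - epn).rename("offset")

    out = trait_eppo.copy()
    out = out.join(offset, on=keys)
    out[value_col] = out[value_col] + out["offset"]
    if percent:
        out[value_col] = out[value_col].clip(lower=0.0, upper=100.0)
    out = out.drop(columns="offset")
    out["treatment"] = "dEPPO"
    return out
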