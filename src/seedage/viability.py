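"""Probit modelling of seed survival and longevity (P50).

Seed-lot viability declines approximately linearly on the probit (normal
equivalent deviate, NED) scale during storage:

    v = Ki − p / σ                                   (viability equation)

where ``v`` is the probit proportion of viable seeds after ``p`` days of
storage, ``Ki`` the initial viability (NED) and ``σ`` the number of days for
viability to fall by one probit.  The longevity statistic ``P50`` — the
storage time at which viability reaches 50% — is the root of the linear
predictor, ``P50 = Ki · σ``.

Lots exhibiting dormancy are described by a second probit line for the
release of dormancy during after-ripening:

    nd = Knd + p / σ_nd

and the observed germination probability is the product of the non-dormant
and viable proportions, ``Φ(Knd + p/σ_nd) · Φ(Ki − p/σ)``.  Both models are
fitted by maximising the exact binomial log-likelihood of the germination
counts, so proportions of 0 or 1 need no continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, ndtr
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "SurvivalObservation",
    "ViabilityFit",
    "CombinedFit",
    "NonIdentifiableError",
    "FitFailureError",
    "ned",
    "proportion_from_ned",
    "fit_viability",
    "fit_combined",
    "p50_from_fit",
    "summarize_panel",
    "p50_correlation_matrix",
]


class NonIdentifiableError(ValueError):
    """The survival data cannot identify the viability-equation parameters."""


class FitFailureError(RuntimeError):
    """Numerical optimisation failed to converge; carries the best candidate."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class SurvivalObservation:
    """Germination outcome of one test after ``storage_days`` of storage."""

    storage_days: float
    germinated: int
    total: int
    replicate: str = ""
    accession: str = ""
    treatment: str = ""

    def __post_init__(self) -> None:
        if self.storage_days < 0:
            raise ValueError("storage_days must be >= 0")
        if self.total < 1:
            raise ValueError("total must be >= 1")
        if not 0 <= self.germinated <= self.total:
            raise ValueError("germinated must lie in [0, total]")


@dataclass
class ViabilityFit:
    """Fitted viability equation for one seed lot.

    ``sigma_inv`` is the slope magnitude 1/σ in NED per day; ``p50`` is in
    days (NaN when ``Ki <= 0`` or the fitted slope is non-positive).
    """

    Ki: float
    sigma_inv: float
    se_Ki: float
    se_sigma_inv: float
    p50: float
    loglik: float
    n_obs: int
    increasing_with_time: bool = False  # germination rose with storage time
    converged: bool = True

    @property
    def sigma(self) -> float:
        """Days per probit of viability loss."""
        return 1.0 / self.sigma_inv

    @property
    def deviance_df(self) -> int:
        return self.n_obs - 2


@dataclass
class CombinedFit(ViabilityFit):
    """Combined viability × dormancy-release fit."""

    Knd: float = math.nan
    sigma_nd: float = math.nan
    se_Knd: float = math.nan
    se_sigma_nd_inv: float = math.nan
    dormancy_supported: bool = True
    at_boundary: bool = False

    @property
    def sigma_nd_inv(self) -> float:
        return 1.0 / self.sigma_nd


def ned(proportion: float) -> float:
    """Normal equivalent deviate: inverse standard-normal CDF of a proportion."""
    proportion = np.asarray(proportion, dtype=float)
    if np.any(proportion <= 0) or np.any(proportion >= 1):
        raise ValueError("proportion must lie strictly in (0, 1)")
    return stats.norm.ppf(proportion)


def proportion_from_ned(v: float) -> float:
    """Inverse of :func:`ned`: standard-normal CDF."""
    return stats.norm.cdf(v)


# ---------------------------------------------------------------------------
# data marshalling

_REQUIRED = ("storage_days", "germinated", "total")


def _as_arrays(observations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Accept a DataFrame or an iterable of SurvivalObservation."""
    if isinstance(observations, pd.DataFrame):
        missing = [c for c in _REQUIRED if c not in observations.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = observations
        p = df["storage_days"].to_numpy(float)
        y = df["germinated"].to_numpy(float)
        n = df["total"].to_numpy(float)
    else:
        obs = list(observations)
        p = np.array([o.storage_days for o in obs], float)
        y = np.array([o.germinated for o in obs], float)
        n = np.array([o.total for o in obs], float)
    if p.size == 0:
        raise NonIdentifiableError("no observations")
    if np.any(y < 0) or np.any(y > n) or np.any(n < 1):
        raise ValueError("counts must satisfy 0 <= germinated <= total, total >= 1")
    return p, y, n


def _validate_identifiable(p: np.ndarray, y: np.ndarray, n: np.ndarray) -> None:
    if np.unique(p).size < 2:
        raise NonIdentifiableError("need >= 2 distinct storage durations")
    if np.all(y == 0):
        raise NonIdentifiableError("all observations at 0% germination")
    if np.all(y == n):
        raise NonIdentifiableError("all observations at 100% germination")


_TINY = 1e-12


def _binom_const(y: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))


def _loglik_from_prob(prob: np.ndarray, y, n, const: float) -> float:
    prob = np.clip(prob, _TINY, 1 - _TINY)
    return const + float(np.sum(y * np.log(prob) + (n - y) * np.log1p(-prob)))


# ---------------------------------------------------------------------------
# reduced (viability-only) model


def _nll_viability(theta, p, y, n, const):
    ki, s = theta
    eta = ki - s * p
    prob = np.clip(ndtr(eta), _TINY, 1 - _TINY)
    return -(const + np.sum(y * np.log(prob) + (n - y) * np.log1p(-prob)))


def _grad_viability(theta, p, y, n, const):
    ki, s = theta
    eta = ki - s * p
    prob = np.clip(ndtr(eta), _TINY, 1 - _TINY)
    phi = stats.norm.pdf(eta)
    w = (y / prob - (n - y) / (1 - prob)) * phi
    return -np.array([np.sum(w), -np.sum(w * p)])


def _start_values(p: np.ndarray, y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Least-squares line through the empirical probits of non-degenerate points."""
    frac = y / n
    ok = (frac > 0) & (frac < 1)
    if ok.sum() >= 2 and np.unique(p[ok]).size >= 2:
        v = stats.norm.ppf(frac[ok])
        slope, intercept = np.polyfit(p[ok], v, 1)
        return np.array([intercept, -slope])
    # fall back: probit of the pooled proportion, gentle decline
    pooled = np.clip(y.sum() / n.sum(), 0.02, 0.98)
    return np.array([stats.norm.ppf(pooled), 0.02])


def fit_viability(observations) -> ViabilityFit:
    """Maximum-likelihood fit of the viability equation to germination counts.

    The success probability of each binomial count is ``Φ(Ki − p/σ)``; the
    fit maximises the exact binomial log-likelihood over ``(Ki, 1/σ)`` —
    equivalent to probit-link binomial regression with intercept ``Ki`` and
    slope ``−1/σ``.  Standard errors come from the observed information
    matrix at the optimum.

    Returns a :class:`ViabilityFit`.  If germination *increases* with
    storage time the fitted slope is negative; the fit is returned with
    ``increasing_with_time=True`` and an undefined P50, and a warning is
    emitted (a dormancy model is probably needed, see :func:`fit_combined`).
    """
    p, y, n = _as_arrays(observations)
    _validate_identifiable(p, y, n)
    const = _binom_const(y, n)
    args = (p, y, n, const)

    x0 = _start_values(p, y, n)
    best = None
    for start in (x0, np.array([1.5, 0.05]), np.array([2.5, 0.1])):
        res = optimize.minimize(
            _nll_viability, start, args=args, jac=_grad_viability, method="BFGS",
            options={"gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    theta = best.x
    hess = approx_hess1(theta, _nll_viability, args=args)
    se = _se_from_hessian(hess)

    ki, s = theta
    increasing = s <= 0
    if increasing:
        warnings.warn(
            "germination increases with storage time; consider fit_combined",
            stacklevel=2,
        )
    fit = ViabilityFit(
        Ki=float(ki),
        sigma_inv=float(s),
        se_Ki=se[0],
        se_sigma_inv=se[1],
        p50=p50_from_fit(ki, s) if s > 0 else math.nan,
        loglik=-float(best.fun),
        n_obs=int(p.size),
        increasing_with_time=bool(increasing),
        converged=bool(best.success or best.fun < np.inf),
    )
    return fit


def _se_from_hessian(hess: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)
        with np.errstate(invalid="ignore"):
            return np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        return np.full(hess.shape[0], np.nan)


# ---------------------------------------------------------------------------
# combined viability x dormancy model


def _nll_combined(theta, p, y, n, const):
    knd, snd, ki, s = theta
    prob = ndtr(knd + snd * p) * ndtr(ki - s * p)
    prob = np.clip(prob, _TINY, 1 - _TINY)
    return -(const + np.sum(y * np.log(prob) + (n - y) * np.log1p(-prob)))


def _grad_combined(theta, p, y, n, const):
    knd, snd, ki, s = theta
    eta1 = knd + snd * p
    eta2 = ki - s * p
    a = ndtr(eta1)
    b = ndtr(eta2)
    prob = np.clip(a * b, _TINY, 1 - _TINY)
    w = y / prob - (n - y) / (1 - prob)
    phi1 = stats.norm.pdf(eta1)
    phi2 = stats.norm.pdf(eta2)
    d_knd = np.sum(w * phi1 * b)
    d_snd = np.sum(w * phi1 * b * p)
    d_ki = np.sum(w * a * phi2)
    d_s = -np.sum(w * a * phi2 * p)
    return -np.array([d_knd, d_snd, d_ki, d_s])


#: Multi-start lattice for the dormancy component: Knd x sigma_nd (days/probit).
_COMBINED_STARTS_KND = (-1.0, 0.0, 1.0, 3.0)
_COMBINED_STARTS_SIGMA_ND = (5.0, 20.0)
_COMBINED_BOUNDS = [(-8.0, 12.0), (0.0, 5.0), (-5.0, 8.0), (1e-6, 2.0)]


def fit_combined(observations, alpha: float = 0.05) -> CombinedFit:
    """Simultaneous fit of the viability and dormancy-release probit lines.

    The binomial success probability is the product
    ``Φ(Knd + p/σ_nd) · Φ(Ki − p/σ)`` (non-dormant fraction × viable
    fraction), maximised over the four parameters by L-BFGS-B from a
    deterministic lattice of eight starts seeded with the reduced fit's
    ``(Ki, 1/σ)``.

    ``dormancy_supported`` is ``False`` when a likelihood-ratio comparison
    against the reduced model falls below the ``chi²(2)`` critical value at
    ``alpha`` — i.e. the data show no initial rise in germination.  In that
    regime the viability parameters agree with :func:`fit_viability`.
    ``at_boundary`` flags parameters pinned at the optimisation box.
    """
    p, y, n = _as_arrays(observations)
    _validate_identifiable(p, y, n)
    const = _binom_const(y, n)
    args = (p, y, n, const)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reduced = fit_viability(observations)
    ki0 = float(np.clip(reduced.Ki, -4.0, 7.0))
    s0 = float(np.clip(reduced.sigma_inv, 1e-4, 1.9))

    best = None
    for knd0 in _COMBINED_STARTS_KND:
        for sig_nd0 in _COMBINED_STARTS_SIGMA_ND:
            start = np.array([knd0, 1.0 / sig_nd0, ki0, s0])
            res = optimize.minimize(
                _nll_combined, start, args=args, jac=_grad_combined,
                method="L-BFGS-B", bounds=_COMBINED_BOUNDS,
                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise FitFailureError("combined model failed to converge", best=best)

    theta = best.x
    hess = approx_hess1(theta, _nll_combined, args=args)
    se = _se_from_hessian(hess)
    knd, snd, ki, s = theta

    at_boundary = any(
        abs(v - lo) < 1e-6 or abs(v - hi) < 1e-6
        for v, (lo, hi) in zip(theta, _COMBINED_BOUNDS)
    )
    loglik = -float(best.fun)
    lr = 2.0 * (loglik - reduced.loglik)
    supported = lr > stats.chi2.ppf(1 - alpha, df=2)

    return CombinedFit(
        Ki=float(ki),
        sigma_inv=float(s),
        se_Ki=se[2],
        se_sigma_inv=se[3],
        p50=p50_from_fit(ki, s) if s > 0 else math.nan,
        loglik=loglik,
        n_obs=int(p.size),
        increasing_with_time=False,
        converged=True,
        Knd=float(knd),
        sigma_nd=float(1.0 / snd) if snd > 0 else math.inf,
        se_Knd=se[0],
        se_sigma_nd_inv=se[1],
        dormancy_supported=bool(supported),
        at_boundary=bool(at_boundary),
    )


# ---------------------------------------------------------------------------
# derived statistics


def p50_from_fit(Ki: float, sigma_inv: float) -> float:
    """Storage time (days) at which viability falls to 50%: ``Ki / (1/σ)``.

    Defined on the viability component alone (dormancy does not shift the
    survival line).  Returns NaN when ``Ki < 0`` (initial viability already
    below 50%, so no crossing during storage) and 0 when ``Ki == 0``.
    """
    if sigma_inv <= 0:
        raise ValueError("sigma_inv must be positive")
    if Ki < 0:
        return math.nan
    return Ki / sigma_inv


def summarize_panel(fits: Iterable | pd.DataFrame) -> pd.DataFrame:
    """Column-wise Maximum / Minimum / Mean of Ki, σ⁻¹ and P50 over a panel.

    ``fits`` may be a DataFrame with columns ``Ki, sigma_inv, p50`` or an
    iterable of :class:`ViabilityFit`.
    """
    if isinstance(fits, pd.DataFrame):
        df = fits[["Ki", "sigma_inv", "p50"]].astype(float)
    else:
        rows = [(f.Ki, f.sigma_inv, f.p50) for f in fits]
        df = pd.DataFrame(rows, columns=["Ki", "sigma_inv", "p50"])
    if df.empty:
        raise ValueError("empty panel")
    return pd.DataFrame(
        {
            "Ki": [df["Ki"].max(), df["Ki"].min(), df["Ki"].mean()],
            "sigma_inv": [
                df["sigma_inv"].max(),
                df["sigma_inv"].min(),
                df["sigma_inv"].mean(),
            ],
            "p50": [df["p50"].max(), df["p50"].min(), df["p50"].mean()],
        },
        index=["Maximum", "Minimum", "Mean"],
    )


def p50_correlation_matrix(
    p50_by_condition: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of P50 across storage conditions.

    ``p50_by_condition`` holds one row per seed lot and one column per
    storage condition.  Pairs are compared over the lots with P50 defined
    in both conditions (pairwise deletion, at least 3 required).  Returns
    ``(r, significant)`` — a symmetric correlation matrix and a boolean
    matrix flagging two-sided p < ``alpha``.  Constant columns yield NaN.
    """
    cols = list(p50_by_condition.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    sig = pd.DataFrame(False, index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            pair = p50_by_condition[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 lots with P50 defined for {cols[i]}/{cols[j]}"
                )
            x = pair.iloc[:, 0].to_numpy(float)
            yv = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(yv) == 0:
                rij, pij = math.nan, math.nan
            else:
                rij, pij = stats.pearsonr(x, yv)
            r.iloc[i, j] = r.iloc[j, i] = rij
            sig.iloc[i, j] = sig.iloc[j, i] = bool(pij < alpha) if np.isfinite(pij) else False
    return r, sig


def table_rows(
    fits: dict[str, ViabilityFit] | Sequence[tuple[str, ViabilityFit]],
) -> pd.DataFrame:
    """Per-lot report rows (Ki, s.e., σ⁻¹, s.e., P50) in presentation rounding.

    Ki to 2 d.p., σ⁻¹ to 3 d.p., P50 to 1 d.p. — the conventional layout of
    seed-longevity tables.
    """
    items = fits.items() if isinstance(fits, dict) else fits
    rows = []
    for name, f in items:
        rows.append(
            {
                "accession": name,
                "Ki": round(f.Ki, 2),
                "se_Ki": round(f.se_Ki, 2),
                "sigma_inv": round(f.sigma_inv, 3),
                "se_sigma_inv": round(f.se_sigma_inv, 3),
                "P50": round(f.p50, 1) if np.isfinite(f.p50) else np.nan,
            }
        )
    return pd.DataFrame(rows)
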