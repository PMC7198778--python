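"""Temperature sensitivity (Q10) of cumulative N2O emission.

The van't Hoff exponential model R = alpha * exp(beta * t) is fitted to
cumulative emission at the incubation temperatures (15/25/35 degC), and
Q10 = exp(10 * beta).  The fit is ordinary least squares of ln(R) on t
(log-linear by construction, exact on true exponentials); a nonlinear
raw-scale fit is available for comparison.  Q10 is invariant to rescaling the
emissions, and a two-point fit reduces to the closed form
Q10 = (R2/R1)^(10/(t2-t1)).

Between-treatment Q10 differences are tested by bootstrapping per-replicate
fits, consistent with the partitioning module's resampling machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["Q10Fit", "Q10Comparison", "fit_vant_hoff", "fit_replicate_q10", "compare_q10"]


class TempSensError(ValueError):
    """Invalid temperature-sensitivity input."""


@dataclass
class Q10Fit:
    """Fitted van't Hoff parameters and Q10."""

    alpha: float               # pre-exponential, emission units
    beta: float                # per degC
    q10: float                 # exp(10 * beta)
    r_squared: float           # on the log scale
    n: int
    method: str = "log-ols"
    replicate_betas: np.ndarray | None = field(default=None, repr=False)


@dataclass
class Q10Comparison:
    q10_a: float
    q10_b: float
    difference: float          # q10_b - q10_a
    ci_lo: float
    ci_hi: float
    p: float
    B: int
    seed: int


def fit_vant_hoff(
    points: list[tuple[float, float]],
    method: str = "log-ols",
) -> Q10Fit:
    """Fit R = alpha * exp(beta * t) to (temperature degC, emission) points.

    Emissions must be strictly positive (the log transform is undefined
    otherwise; no silent offset is applied).  A 2-point fit is exact and
    warned about.
    """
    if len(points) < 2:
        raise TempSensError("need at least 2 temperature points")
    t = np.asarray([p[0] for p in points], dtype=float)
    r = np.asarray([p[1] for p in points], dtype=float)
    if np.any(r <= 0):
        raise TempSensError(
            "non-positive emission: log fit undefined; consider an explicit "
            "baseline offset before fitting (never applied silently)"
        )
    if len(points) == 2:
        warnings.warn("two-point fit is exact but has no residual df", stacklevel=2)

    if method == "log-ols":
        res = stats.linregress(t, np.log(r))
        beta, ln_alpha = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2) if len(points) > 2 else 1.0
        alpha = float(np.exp(ln_alpha))
    elif method == "nls":
        res0 = stats.linregress(t, np.log(r))
        (alpha, beta), _ = optimize.curve_fit(
            lambda tt, a, b: a * np.exp(b * tt), t, r,
            p0=(np.exp(res0.intercept), res0.slope), maxfev=10000,
        )
        alpha, beta = float(alpha), float(beta)
        pred = np.log(alpha) + beta * t
        ss_res = float(np.sum((np.log(r) - pred) ** 2))
        ss_tot = float(np.sum((np.log(r) - np.log(r).mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        raise TempSensError(f"unknown method {method!r}")
    return Q10Fit(alpha=alpha, beta=beta, q10=float(np.exp(10 * beta)),
                  r_squared=r2, n=len(points), method=method)


def fit_replicate_q10(
    series: dict[int, list[tuple[float, float]]] | list[list[tuple[float, float]]],
    pooled: bool = False,
) -> Q10Fit:
    """Fit Q10 from per-replicate (temperature, cumulative emission) series.

    ``pooled=False`` (default) fits one van't Hoff curve per replicate and
    reports the mean beta with per-replicate betas attached; ``pooled=True``
    fits a single curve through all points.
    """
    if isinstance(series, dict):
        series = [series[k] for k in sorted(series)]
    if not series:
        raise TempSensError("no replicate series supplied")
    if pooled:
        allpts = [p for s in series for p in s]
        fit = fit_vant_hoff(allpts)
        fit.method = "log-ols-pooled"
        return fit
    fits = [fit_vant_hoff(s) for s in series]
    betas = np.array([f.beta for f in fits])
    beta = float(betas.mean())
    return Q10Fit(
        alpha=float(np.exp(np.mean([np.log(f.alpha) for f in fits]))),
        beta=beta, q10=float(np.exp(10 * beta)),
        r_squared=float(np.mean([f.r_squared for f in fits])),
        n=sum(f.n for f in fits), method="log-ols-replicate-mean",
        replicate_betas=betas,
    )


def compare_q10(
    group_a: list[list[tuple[float, float]]],
    group_b: list[list[tuple[float, float]]],
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> Q10Comparison:
    """Bootstrap test of a Q10 difference between two replicate groups.

    Per-replicate betas are fitted, replicates are resampled with replacement
    within each group, and the percentile CI / two-sided bootstrap p of the
    Q10 difference (B - A) is returned.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise TempSensError("need >= 2 replicate series per group")
    beta_a = np.array([fit_vant_hoff(s).beta for s in group_a])
    beta_b = np.array([fit_vant_hoff(s).beta for s in group_b])
    q10_a = float(np.exp(10 * beta_a.mean()))
    q10_b = float(np.exp(10 * beta_b.mean()))

    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(beta_a), size=(B, len(beta_a)))
    ib = rng.integers(0, len(beta_b), size=(B, len(beta_b)))
    diffs = np.exp(10 * beta_b[ib].mean(axis=1)) - np.exp(10 * beta_a[ia].mean(axis=1))
    p = min(1.0, 2.0 * min(np.mean(diffs >= 0), np.mean(diffs <= 0)))
    return Q10Comparison(
        q10_a=q10_a, q10_b=q10_b, difference=q10_b - q10_a,
        ci_lo=float(np.percentile(diffs, 100 * alpha / 2)),
        ci_hi=float(np.percentile(diffs, 100 * (1 - alpha / 2))),
        p=float(p), B=B, seed=seed,
    )
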