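"""Viability normalisation, 4PL EC50 fitting, outlier screening, Dunnett test.

The dose-response model is the four-parameter logistic
``response = bottom + (top - bottom) / (1 + (dose/ec50)^hill)``, decreasing
in dose for hill > 0 (viability declining with concentration). The EC50
confidence interval is asymptotic on log(EC50) and exponentiated, giving
the familiar asymmetric interval. Doses are normalised internally by their
geometric mean so EC50 and its interval rescale exactly with dose units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "normalize_viability",
    "fit_4pl",
    "four_pl",
    "detect_response_outliers",
    "anova_dunnett",
    "DoseResponseFit",
    "DunnettResult",
]


def four_pl(dose, ec50, hill, top, bottom):
    """Four-parameter logistic response, decreasing in dose for hill > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def normalize_viability(plate: pd.DataFrame) -> pd.DataFrame:
    """Blank-correct and control-normalise a plate to percent viability.

    percent = 100 * (signal - mean blank) / (mean control - mean blank).
    The returned frame keeps treated wells only, with a ``viability`` column.
    """
    for col in ("dose", "signal", "well_type"):
        if col not in plate.columns:
            raise ValueError(f"plate is missing column {col!r}")
    blanks = plate.loc[plate["well_type"] == "blank", "signal"]
    controls = plate.loc[plate["well_type"] == "control", "signal"]
    if blanks.empty or controls.empty:
        raise ValueError("plate must contain at least one blank and one control well")
    blank_mean = float(blanks.mean())
    control_mean = float(controls.mean())
    if control_mean <= blank_mean:
        raise ValueError(
            f"mean control signal ({control_mean:g}) must exceed mean blank "
            f"({blank_mean:g})"
        )
    out = plate.copy()
    out["viability"] = 100.0 * (out["signal"] - blank_mean) / (control_mean - blank_mean)
    return out[out["well_type"] == "treated"].reset_index(drop=True)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters with EC50 and its 95% confidence interval."""

    ec50: float
    hill: float
    top: float
    bottom: float
    ci95_ec50: tuple
    se_log_ec50: float
    rss: float
    n_points: int
    outlier_flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))
    converged: bool = True
    message: str = ""

    def predict(self, dose) -> np.ndarray:
        return four_pl(dose, self.ec50, self.hill, self.top, self.bottom)


def _fit_4pl_core(log_dose: np.ndarray, response: np.ndarray, p0: np.ndarray):
    """Least squares in (log_ec50, hill, top, bottom) on log-dose data."""

    def residuals(params):
        log_ec50, hill, top, bottom = params
        pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (log_dose - log_ec50)))
        return pred - response

    return optimize.least_squares(residuals, p0, method="lm", max_nfev=10000)


def fit_4pl(doses, responses) -> DoseResponseFit:
    """Fit a sigmoid dose-response curve and report EC50 with a 95% CI.

    Initialisation comes from the response quartiles (bottom/top from the
    data extremes, EC50 from the dose nearest the half-response); a small
    multistart over Hill slopes backs the first attempt up. The CI is
    asymptotic on log(EC50) from the fit covariance.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have equal length")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (controls anchor normalisation, not the curve)")
    if np.unique(doses).size < 4:
        raise ValueError("need at least 4 distinct doses spanning the transition")
    if np.allclose(responses, responses[0]):
        raise ValueError("constant responses: EC50 unidentifiable")

    # exact unit equivariance: work on doses scaled by their geometric mean
    scale = float(np.exp(np.mean(np.log(doses))))
    log_dose = np.log(doses / scale)

    top0, bottom0 = float(np.max(responses)), float(np.min(responses))
    half = 0.5 * (top0 + bottom0)
    ec50_0 = log_dose[int(np.argmin(np.abs(responses - half)))]
    best = None
    for hill0 in (1.0, 0.5, 2.0, 4.0):
        for lec0 in (ec50_0, np.median(log_dose)):
            try:
                res = _fit_4pl_core(
                    log_dose, responses, np.array([lec0, hill0, top0, bottom0])
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-12:
                best = res
        if best is not None and best.cost < 1e-12:
            break
    if best is None or not best.success:
        raise RuntimeError(
            "4PL fit failed to converge after multistart; check that the doses "
            "span the response transition"
        )

    log_ec50, hill, top, bottom = best.x
    if top < bottom:  # symmetric reparameterisation; normalise orientation
        top, bottom, hill = bottom, top, -hill
    n, k = doses.size, 4
    rss = float(2.0 * best.cost)
    dof = max(n - k, 1)
    sigma2 = rss / dof
    jtj = best.jac.T @ best.jac
    try:
        cov = sigma2 * np.linalg.inv(jtj)
        se_log_ec50 = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se_log_ec50 = np.nan
    tcrit = stats.t.ppf(0.975, dof)
    if np.isfinite(se_log_ec50):
        lo = float(np.exp(log_ec50 - tcrit * se_log_ec50) * scale)
        hi = float(np.exp(log_ec50 + tcrit * se_log_ec50) * scale)
    else:
        lo = hi = np.nan
    return DoseResponseFit(
        ec50=float(np.exp(log_ec50) * scale),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        ci95_ec50=(lo, hi),
        se_log_ec50=se_log_ec50,
        rss=rss,
        n_points=int(n),
        converged=True,
        message=best.message,
    )


def detect_response_outliers(doses, responses, q: float = 0.01):
    """ROUT-style outlier flags: robust 4PL fit, then FDR-screened residuals.

    A soft-L1 robust fit provides residuals whose scale is estimated by the
    MAD; per-point two-sided t-probabilities are screened with a
    Benjamini-Hochberg pass at rate ``q``. Returns (flags, refit) where the
    refit excludes flagged points, or None when refitting was declined
    (more than 30% flagged) or underpowered (< 6 points).
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    n = doses.size
    if n < 6:
        warnings.warn("fewer than 6 points: outlier detection is underpowered", stacklevel=2)
        return np.zeros(n, dtype=bool), None

    scale = float(np.exp(np.mean(np.log(doses))))
    log_dose = np.log(doses / scale)
    top0, bottom0 = float(np.max(responses)), float(np.min(responses))
    half = 0.5 * (top0 + bottom0)
    p0 = np.array([log_dose[int(np.argmin(np.abs(responses - half)))], 1.0, top0, bottom0])

    def residuals(params):
        log_ec50, hill, top, bottom = params
        pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (log_dose - log_ec50)))
        return pred - responses

    robust = optimize.least_squares(residuals, p0, loss="soft_l1", f_scale=np.std(responses) / 5)
    resid = residuals(robust.x)
    mad_scale = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if mad_scale == 0:
        return np.zeros(n, dtype=bool), fit_4pl(doses, responses)
    tstat = resid / mad_scale
    dof = max(n - 4, 1)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    adjusted = stats.false_discovery_control(pvals, method="bh")
    flags = adjusted < q
    if flags.mean() > 0.30:
        warnings.warn(
            f"{int(flags.sum())}/{n} points flagged (>30%); refit declined",
            stacklevel=2,
        )
        return flags, None
    keep = ~flags
    refit = fit_4pl(doses[keep], responses[keep])
    refit.outlier_flags = flags
    return flags, refit


# ---------------------------------------------------------------------------
# One-way ANOVA + Dunnett many-to-one
# ---------------------------------------------------------------------------

_DUNNETT_CACHE: dict = {}


def _dunnett_null_draws(ns: tuple, dof: int, n_draws: int, seed: int) -> np.ndarray:
    """Sorted null draws of max_i |T_i| for Dunnett's statistic by Monte Carlo."""
    key = (ns, dof, n_draws, seed)
    if key not in _DUNNETT_CACHE:
        rng = np.random.default_rng(seed)
        n0, rest = ns[0], ns[1:]
        means = rng.normal(0.0, 1.0, size=(n_draws, len(ns))) / np.sqrt(np.asarray(ns))
        s = np.sqrt(rng.chisquare(dof, size=n_draws) / dof)
        denom = np.sqrt(1.0 / np.asarray(rest) + 1.0 / n0)
        tstats = (means[:, 1:] - means[:, [0]]) / (s[:, None] * denom)
        _DUNNETT_CACHE[key] = np.sort(np.max(np.abs(tstats), axis=1))
    return _DUNNETT_CACHE[key]


@dataclass
class DunnettResult:
    """Per-group comparison against the shared control."""

    table: pd.DataFrame  # group, diff, t, p_adjusted, significant
    f_statistic: float
    f_pvalue: float
    critical_value: float


def anova_dunnett(
    groups: dict, control: str, alpha: float = 0.05, n_draws: int = 100_000, seed: int = 0
) -> DunnettResult:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons.

    ``groups`` maps group name -> replicate responses; ``control`` names the
    reference group. Critical values and adjusted p-values come from
    seeded Monte-Carlo draws of the max-|T| null (cached per group
    configuration), with the family-wise rate controlled at ``alpha``.
    """
    if control not in groups:
        raise KeyError(f"control group {control!r} not among groups")
    names = [control] + [g for g in groups if g != control]
    if len(names) < 3:
        raise ValueError("need the control plus at least 2 comparison groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 replicates")
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")

    f_stat, f_p = stats.f_oneway(*arrays)
    ns = tuple(a.size for a in arrays)
    total_n = sum(ns)
    dof = total_n - len(ns)
    pooled_var = sum((a.size - 1) * a.var(ddof=1) for a in arrays) / dof
    control_mean = arrays[0].mean()

    draws = _dunnett_null_draws(ns, dof, n_draws, seed)
    critical = float(draws[int(np.ceil((1.0 - alpha) * n_draws)) - 1])

    rows = []
    for name, arr in zip(names[1:], arrays[1:]):
        diff = arr.mean() - control_mean
        se = np.sqrt(pooled_var * (1.0 / arr.size + 1.0 / arrays[0].size))
        t = diff / se
        p_adj = float(1.0 - np.searchsorted(draws, abs(t), side="right") / n_draws)
        rows.append(
            {
                "group": name,
                "diff": float(diff),
                "t": float(t),
                "p_adjusted": p_adj,
                "significant": bool(abs(t) > critical),
            }
        )
    return DunnettResult(
        table=pd.DataFrame(rows),
        f_statistic=float(f_stat),
        f_pvalue=float(f_p),
        critical_value=critical,
    )
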