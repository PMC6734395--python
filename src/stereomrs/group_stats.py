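"""Subject-level inference: paired tests, dependent correlations, the
condition × order split-plot ANOVA, and psychometric (cumulative Gaussian)
fitting for the Vernier task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PairedT",
    "paired_t",
    "pearson_r",
    "steiger_z",
    "compare_dependent_correlations",
    "permutation_compare_correlations",
    "mixed_anova_2x2",
    "PsychometricFit",
    "fit_cumulative_gaussian",
]


class PairedT(NamedTuple):
    t: float
    df: int
    p: float


def paired_t(x, y) -> PairedT:
    """Classic paired t-test (df = n − 1) on complete pairs.

    Zero-variance differences are undefined: returns t = NaN unless the
    differences are identically zero, in which case t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedT(0.0, n - 1, 1.0)
        return PairedT(np.nan, n - 1, np.nan)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedT(float(t), n - 1, float(p))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p on complete pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    res = stats.pearsonr(x[keep], y[keep])
    return float(res.statistic), float(res.pvalue)


def steiger_z(r_xy: float, r_xz: float, r_yz: float, n: int) -> tuple[float, float]:
    """Steiger's (1980) z for two dependent correlations sharing variable x.

    Tests H0: rho_xy = rho_xz on the same n subjects, accounting for the
    correlation r_yz between the non-shared variables via the correlation
    between the two Fisher-transformed estimates.  Antisymmetric in its
    first two arguments.
    """
    if n < 4:
        raise ValueError("need n >= 4 subjects")
    for r in (r_xy, r_xz, r_yz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    z1 = np.arctanh(r_xy)
    z2 = np.arctanh(r_xz)
    rbar2 = ((r_xy + r_xz) / 2.0) ** 2
    # correlation between the two z estimates (Dunn & Clark, pooled r)
    s = (r_yz * (1 - 2 * rbar2) - 0.5 * rbar2 * (1 - 2 * rbar2 - r_yz**2)) / (
        (1 - rbar2) ** 2
    )
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * s))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_dependent_correlations(x, y, z) -> dict:
    """Compare corr(x, y) against corr(x, z) measured on the same subjects.

    Returns the three Pearson correlations (with p values) and Steiger's z
    for the difference between the two correlations that share ``x``.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 complete subjects")
    r_xy, p_xy = pearson_r(x, y)
    r_xz, p_xz = pearson_r(x, z)
    r_yz, p_yz = pearson_r(y, z)
    zstat, pz = steiger_z(r_xy, r_xz, r_yz, n)
    return {
        "n": n,
        "r_xy": r_xy, "p_xy": p_xy,
        "r_xz": r_xz, "p_xz": p_xz,
        "r_yz": r_yz, "p_yz": p_yz,
        "z": zstat, "p_z": pz,
    }


def permutation_compare_correlations(
    x, y, z, n_perm: int = 2000, seed: int | np.random.Generator = 0
) -> float:
    """Permutation p value for H0: corr(x, y) == corr(x, z).

    Under the null the (standardised) y and z values are exchangeable
    within subject; each permutation swaps y_i and z_i for a random subset
    of subjects and recomputes the correlation difference.  Serves as the
    assumption-light check on the analytic z test.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    keep = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[keep], y[keep], z[keep]
    ys = (y - y.mean()) / y.std(ddof=1)
    zs = (z - z.mean()) / z.std(ddof=1)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )

    def rdiff(a, b):
        return np.corrcoef(x, a)[0, 1] - np.corrcoef(x, b)[0, 1]

    obs = abs(rdiff(ys, zs))
    count = 0
    for _ in range(n_perm):
        swap = rng.random(x.size) < 0.5
        yp = np.where(swap, zs, ys)
        zp = np.where(swap, ys, zs)
        if abs(rdiff(yp, zp)) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def mixed_anova_2x2(
    values: np.ndarray,
    order: np.ndarray,
    convention: str = "textbook",
) -> dict:
    """Split-plot ANOVA: 2 within-subject conditions × 2 between groups.

    ``values`` is subjects × 2 (the two within-condition measurements);
    ``order`` labels each subject's group.  Sums of squares follow the
    standard decomposition: between-subject variance splits into the group
    effect and subjects-within-groups error; within-subject variance
    splits into condition, condition × group, and the within error.

    ``convention="textbook"`` (default) tests the within effects against
    the within error with df (1, N − 2).  ``convention="pooled"`` ignores
    the grouping for the condition test — F is the square of the paired t,
    df (1, N − 1) — matching the reporting convention in which a 20-subject
    design yields F(1,19).
    """
    values = np.asarray(values, dtype=float)
    order = np.asarray(order)
    if values.ndim != 2 or values.shape[1] != 2:
        raise ValueError("values must be subjects x 2")
    groups = np.unique(order)
    if groups.size != 2:
        raise ValueError("order must have exactly 2 levels")
    for g in groups:
        if (order == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    if convention not in ("textbook", "pooled"):
        raise ValueError("convention must be 'textbook' or 'pooled'")

    n_subj = values.shape[0]
    grand = values.mean()
    subj_means = values.mean(axis=1)

    ss_total = ((values - grand) ** 2).sum()
    ss_between_subj = 2 * ((subj_means - grand) ** 2).sum()
    ss_order = 0.0
    for g in groups:
        m = subj_means[order == g]
        ss_order += 2 * m.size * (m.mean() - grand) ** 2
    ss_subj_err = ss_between_subj - ss_order
    df_subj_err = n_subj - 2

    cond_means = values.mean(axis=0)
    ss_cond = n_subj * ((cond_means - grand) ** 2).sum()
    ss_inter = 0.0
    for gi, g in enumerate(groups):
        sel = order == g
        cell = values[sel].mean(axis=0)
        gmean = values[sel].mean()
        ss_inter += sel.sum() * ((cell - gmean - cond_means + grand) ** 2).sum()
    ss_within = ss_total - ss_between_subj
    ss_within_err = ss_within - ss_cond - ss_inter
    df_within_err = n_subj - 2

    def f_and_p(ss_eff, ss_err, df_err):
        if ss_err <= 0:
            return (0.0, 1.0) if ss_eff <= 1e-12 else (np.inf, 0.0)
        f = (ss_eff / 1.0) / (ss_err / df_err)
        return float(f), float(stats.f.sf(f, 1, df_err))

    f_order, p_order = f_and_p(ss_order, ss_subj_err, df_subj_err)
    if convention == "textbook":
        f_cond, p_cond = f_and_p(ss_cond, ss_within_err, df_within_err)
        df_cond = df_within_err
    else:
        res = paired_t(values[:, 0], values[:, 1])
        f_cond = res.t**2 if np.isfinite(res.t) else 0.0
        p_cond = stats.f.sf(f_cond, 1, res.df)
        df_cond = res.df
    f_inter, p_inter = f_and_p(ss_inter, ss_within_err, df_within_err)

    return {
        "condition": {"F": f_cond, "df": (1, df_cond), "p": p_cond},
        "order": {"F": f_order, "df": (1, df_subj_err), "p": p_order},
        "interaction": {"F": f_inter, "df": (1, df_within_err), "p": p_inter},
        "ss": {
            "total": float(ss_total),
            "between_subjects": float(ss_between_subj),
            "order": float(ss_order),
            "subjects_within_groups": float(ss_subj_err),
            "condition": float(ss_cond),
            "interaction": float(ss_inter),
            "within_error": float(ss_within_err),
        },
    }


@dataclass
class PsychometricFit:
    bias: float  # mu, arcmin
    sigma: float  # arcmin
    lapse: float
    loglik: float
    converged: bool
    message: str = ""


def fit_cumulative_gaussian(
    trials: pd.DataFrame,
    offset_col: str = "offset_arcmin",
    response_col: str = "response_right",
    free_lapse: bool = False,
    max_lapse: float = 0.1,
) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian psychometric fit.

    Fits P(respond "right" | x) = lapse/2 + (1 − lapse)·Φ((x − mu)/sigma)
    to Bernoulli responses; ``bias`` is mu (the 50% point), the vergence
    measure of interest.  Lapse is fixed at 0 unless ``free_lapse`` (then
    bounded at ``max_lapse``).  Complete separation (responses perfectly
    split by offset) drives sigma to its lower bound and is flagged.
    """
    x = trials[offset_col].to_numpy(dtype=float)
    r = trials[response_col].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need responses at >= 2 distinct offsets")
    span = float(np.ptp(x))
    sigma_lo, sigma_hi = span * 1e-3, span * 1e3

    # probit-regression initialisation from per-offset proportions
    xs, inv = np.unique(x, return_inverse=True)
    prop = np.bincount(inv, weights=r) / np.bincount(inv)
    q = stats.norm.ppf(np.clip(prop, 0.01, 0.99))
    slope, icept = np.polyfit(xs, q, 1) if xs.size > 1 else (1.0, 0.0)
    sigma0 = float(np.clip(1.0 / max(slope, 1e-6), sigma_lo, sigma_hi))
    mu0 = float(np.clip(-icept * sigma0, xs[0] - span, xs[-1] + span))

    def nll(params):
        mu, log_sigma = params[0], params[1]
        lapse = params[2] if free_lapse else 0.0
        p = lapse / 2 + (1 - lapse) * stats.norm.cdf((x - mu) / np.exp(log_sigma))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -np.sum(r * np.log(p) + (1 - r) * np.log(1 - p))

    p0 = [mu0, np.log(sigma0)] + ([0.02] if free_lapse else [])
    bounds = [(xs[0] - span, xs[-1] + span), (np.log(sigma_lo), np.log(sigma_hi))]
    if free_lapse:
        bounds.append((0.0, max_lapse))
    res = optimize.minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    lapse = float(res.x[2]) if free_lapse else 0.0
    at_bound = sigma <= sigma_lo * 1.01
    separated = bool(
        np.all(r[x < np.median(x)] == 0) and np.all(r[x > np.median(x)] == 1)
    )
    converged = bool(res.success) and not at_bound and not separated
    msg = "" if converged else (
        "complete separation (sigma unidentified)" if separated else str(res.message)
    )
    return PsychometricFit(mu, sigma, lapse, -float(res.fun), converged, msg)
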