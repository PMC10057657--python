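"""Moderated differential-expression statistics for the three-group design.

The design is a one-way layout over the groups N (adjacent normal), T
(tumor) and F1 (first-passage xenograft). Per-feature residual
variances are shrunk toward an empirical-Bayes prior (d0, s0^2)
estimated by moment matching on the log-variances, exactly the
hierarchical model behind limma's moderated t and F statistics: the
posterior variance

    s~^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces the per-feature variance, and test statistics gain d0 extra
degrees of freedom. Fold changes are reported on the signed linear
scale (-2 means 2-fold down).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .io import ExpressionMatrix

log = logging.getLogger(__name__)

#: variance floor for features with zero within-group variance
VAR_FLOOR = 1e-10

#: d0 search bracket; values beyond are treated as infinite
D0_MAX = 1e8


@dataclass(frozen=True)
class EbayesPrior:
    """Empirical-Bayes variance prior: d0 degrees of freedom, s0^2 scale."""

    d0: float  # may be math.inf
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")


@dataclass(frozen=True)
class FilterSpec:
    """The DE filter cascade: |FC| >= fc_min (inclusive), p < p_max,
    overall F-test FDR < f_fdr_max, and a species prefix on the
    transcript id (the miRNA array carries human, mouse and rat
    transcripts; only ``hsa`` features are kept)."""

    fc_min: float = 1.5
    p_max: float = 0.05
    f_fdr_max: float = 0.005
    species_prefix: str = "hsa"

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        for name in ("p_max", "f_fdr_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def tukey_biweight(values, c: float = 5.0, eps: float = 1e-4) -> float:
    """One-step Tukey biweight robust average of log2 intensities.

    Distances from the median are scaled by ``c * MAD + eps``; points at
    scaled distance >= 1 get weight zero, the rest weight (1-u^2)^2. If
    every weight vanishes the median is returned.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("tukey_biweight: empty input")
    if not np.all(np.isfinite(x)):
        raise ValueError("tukey_biweight: non-finite input")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    u = (x - med) / (c * mad + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    total = w.sum()
    if total == 0.0:
        return med
    return float((w * x).sum() / total)


def signed_fc(log2_diff: float):
    """Signed linear fold change of a log2 difference.

    2^d for d >= 0, else -2^(-d); the image is (-inf, -1] u [1, inf),
    so a log2 difference of -1 maps to -2 (2-fold down).
    """
    d = np.asarray(log2_diff, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("signed_fc: non-finite input")
    out = np.where(d >= 0, 2.0**d, -(2.0 ** (-d)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GroupFit:
    """One-way fit: per-group means, pooled residual variance and df."""

    means: pd.DataFrame  # features x groups
    s_sq: pd.Series  # pooled within-group variance, floored at VAR_FLOOR
    d_g: int  # residual degrees of freedom, n_total - n_groups
    n_per_group: dict[str, int]
    zero_variance: pd.Series  # bool flag: raw pooled variance was 0


def fit_groups(matrix: ExpressionMatrix) -> GroupFit:
    """Fit the one-way group layout feature by feature.

    Every present group needs >= 2 samples so the pooled within-group
    variance is defined. Features whose raw pooled variance is exactly
    zero are floored at ``VAR_FLOOR`` and flagged.
    """
    groups = matrix.groups_present
    if len(groups) < 2:
        raise ValueError("fit_groups: need >= 2 groups")
    n_per = {}
    for g in groups:
        n = len(matrix.samples_in(g))
        if n < 2:
            raise ValueError(
                f"fit_groups: group {g!r} has {n} sample(s); variance undefined"
            )
        n_per[g] = n
    n_total = sum(n_per.values())
    d_g = n_total - len(groups)

    means = pd.DataFrame(index=matrix.values.index, dtype=float)
    rss = np.zeros(len(matrix.values), dtype=float)
    for g in groups:
        sub = matrix.values[matrix.samples_in(g)].to_numpy()
        m = sub.mean(axis=1)
        means[g] = m
        rss += ((sub - m[:, None]) ** 2).sum(axis=1)
    s_sq_raw = rss / d_g
    zero = s_sq_raw <= 0.0
    if zero.any():
        log.warning("fit_groups: %d feature(s) with zero variance floored", zero.sum())
    s_sq = np.where(zero, VAR_FLOOR, s_sq_raw)
    return GroupFit(
        means=means,
        s_sq=pd.Series(s_sq, index=matrix.values.index),
        d_g=d_g,
        n_per_group=n_per,
        zero_variance=pd.Series(zero, index=matrix.values.index),
    )


def _trigamma_inv(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by monotone bisection."""
    lo, hi = 1e-8, D0_MAX
    if y >= special.polygamma(1, lo):
        return lo
    if y <= special.polygamma(1, hi):
        return math.inf
    for _ in range(200):
        mid = math.sqrt(lo * hi)  # bisect in log space
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
        if hi / lo - 1.0 < 1e-10:
            break
    return math.sqrt(lo * hi)


def estimate_ebayes_prior(s_sq, d_g: int) -> EbayesPrior:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Works on e_g = log s_g^2 - psi(d_g/2) + log(d_g/2): under the
    scaled-inverse-chi-square prior, var(e_g) exceeds trigamma(d_g/2) by
    trigamma(d0/2), and mean(e_g) = log s0^2 - psi(d0/2) + log(d0/2).
    When the excess variance is <= 0, d0 is declared infinite and
    s0^2 = exp(mean(e_g)). Zero or negative variances are excluded
    (with a warning); at least two positive variances are required.
    """
    s = np.asarray(s_sq, dtype=float)
    pos = s > VAR_FLOOR
    if (~pos).any():
        log.warning(
            "estimate_ebayes_prior: excluding %d zero-variance feature(s)",
            (~pos).sum(),
        )
    s = s[pos]
    if s.size < 2:
        raise ValueError("estimate_ebayes_prior: need >= 2 positive variances")
    half = d_g / 2.0
    e = np.log(s) - special.digamma(half) + math.log(half)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, half))
    if evar <= 0:
        return EbayesPrior(d0=math.inf, s0_sq=math.exp(emean))
    half0 = _trigamma_inv(evar)
    if not math.isfinite(half0) or 2 * half0 > D0_MAX:
        return EbayesPrior(d0=math.inf, s0_sq=math.exp(emean))
    d0 = 2.0 * half0
    s0_sq = math.exp(emean + special.digamma(half0) - math.log(half0))
    return EbayesPrior(d0=d0, s0_sq=s0_sq)


def posterior_var(s_sq, d_g: int, prior: EbayesPrior):
    """Shrunken variance s~^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g)."""
    s_sq = np.asarray(s_sq, dtype=float)
    if math.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + d_g * s_sq) / (prior.d0 + d_g)


def moderated_t(diff, v_c: float, s_sq, d_g: int, prior: EbayesPrior):
    """Moderated t statistic and two-sided p for one contrast.

    ``diff`` is the contrast estimate (log2 scale), ``v_c`` its unscaled
    variance (e.g. 1/n_a + 1/n_b for a two-group difference). The null
    reference is Student t with d0 + d_g df (normal when d0 is
    infinite).
    """
    if v_c <= 0:
        raise ValueError("moderated_t: contrast variance v_c must be > 0")
    diff = np.asarray(diff, dtype=float)
    s_tilde_sq = posterior_var(s_sq, d_g, prior)
    if np.any(s_tilde_sq <= 0):
        raise ValueError("moderated_t: zero posterior variance")
    t = diff / np.sqrt(s_tilde_sq * v_c)
    if math.isinf(prior.d0):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df=prior.d0 + d_g)
    return t, p


def moderated_f(fit: GroupFit, prior: EbayesPrior):
    """Moderated one-way F across the groups: between-group mean square
    over the shrunken variance, with (n_groups - 1, d0 + d_g) df."""
    groups = list(fit.means.columns)
    k = len(groups)
    if k < 2:
        raise ValueError("moderated_f: need >= 2 groups")
    n = np.array([fit.n_per_group[g] for g in groups], dtype=float)
    m = fit.means.to_numpy()
    grand = (m * n).sum(axis=1) / n.sum()
    msb = ((n * (m - grand[:, None]) ** 2).sum(axis=1)) / (k - 1)
    s_tilde_sq = posterior_var(fit.s_sq, fit.d_g, prior)
    if np.any(s_tilde_sq <= 0):
        raise ValueError("moderated_f: zero posterior variance")
    F = msb / s_tilde_sq
    if math.isinf(prior.d0):
        p = sps.chi2.sf(F * (k - 1), df=k - 1)
    else:
        p = sps.f.sf(F, dfn=k - 1, dfd=prior.d0 + fit.d_g)
    return F, p


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    adj_(i) = min_{j >= i} p_(j) * n / j, capped at 1, mapped back to
    the input order. Inputs must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("benjamini_hochberg: p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n, dtype=float)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


#: contrast definitions: name -> (numerator group, denominator group)
CONTRASTS = {"TvN": ("T", "N"), "F1vT": ("F1", "T")}


def run_de(
    matrix: ExpressionMatrix,
    spec: FilterSpec | None = None,
) -> dict[str, pd.DataFrame]:
    """Full moderated DE analysis of the three-group matrix.

    Fits the one-way layout, estimates the variance prior, computes the
    moderated t for each contrast (TvN = T - N, F1vT = F1 - T) and the
    overall moderated F across groups, BH-adjusts p-values per contrast
    and the F p-values across features, and marks the filter cascade.

    Returns one DataFrame per contrast with columns feature_id,
    log2_diff, fold_change, t_mod, p_value, fdr, f_fdr, passes_filter.
    """
    spec = spec or FilterSpec()
    fit = fit_groups(matrix)
    try:
        prior = estimate_ebayes_prior(fit.s_sq.to_numpy(), fit.d_g)
    except ValueError:
        # fully degenerate input (e.g. a noiseless simulation): no
        # shrinkage is possible, fall back to the floored variances
        log.warning("run_de: no positive variances; using unmoderated floor")
        prior = EbayesPrior(d0=0.0, s0_sq=VAR_FLOOR)
    F, f_p = moderated_f(fit, prior)
    f_fdr = benjamini_hochberg(f_p)

    out: dict[str, pd.DataFrame] = {}
    for name, (num, den) in CONTRASTS.items():
        if num not in fit.means.columns or den not in fit.means.columns:
            continue
        diff = (fit.means[num] - fit.means[den]).to_numpy()
        v_c = 1.0 / fit.n_per_group[num] + 1.0 / fit.n_per_group[den]
        t, p = moderated_t(diff, v_c, fit.s_sq.to_numpy(), fit.d_g, prior)
        df = pd.DataFrame(
            {
                "feature_id": matrix.feature_ids,
                "log2_diff": diff,
                "fold_change": signed_fc(diff),
                "t_mod": t,
                "p_value": p,
                "fdr": benjamini_hochberg(p),
                "f_fdr": f_fdr,
            }
        )
        df["passes_filter"] = _cascade_mask(df, spec)
        out[name] = df
    return out


def _cascade_mask(df: pd.DataFrame, spec: FilterSpec) -> pd.Series:
    return (
        (df["fold_change"].abs() >= spec.fc_min)
        & (df["p_value"] < spec.p_max)
        & (df["f_fdr"] < spec.f_fdr_max)
        & df["feature_id"].str.startswith(spec.species_prefix)
    )


def de_filter(results: pd.DataFrame, spec: FilterSpec | None = None) -> pd.DataFrame:
    """Apply the filter cascade and sort by fold change descending.

    Keeps |FC| >= fc_min (inclusive), p < p_max (strict), overall
    F-test FDR < f_fdr_max (strict) and feature ids starting with the
    species prefix (case-sensitive).
    """
    spec = spec or FilterSpec()
    kept = results[_cascade_mask(results, spec)].copy()
    kept.sort_values(
        ["fold_change", "feature_id"], ascending=[False, True], inplace=True
    )
    return kept.reset_index(drop=True)
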