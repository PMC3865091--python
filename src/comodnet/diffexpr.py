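"""Group-means linear model with empirical-Bayes variance moderation.

Per feature, a group-means model is fitted on log2 expression and the
per-feature residual variances are shrunk toward a common prior by moment
matching on the log scale: if s^2_g ~ s0^2 * F(d, d0) under the hierarchical
model, then log s^2_g has mean log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) +
log(d0/2) and variance psi'(d/2) + psi'(d0/2), where psi and psi' are the
digamma and trigamma functions. The prior degrees of freedom d0 come from
inverting the trigamma equation by Newton iteration; when the empirical
variance of log s^2 does not exceed its sampling expectation, d0 = infinity
(complete shrinkage). Contrast tests use the moderated t statistic

    t = log2fc / (s_tilde * sqrt(1/n1 + 1/n2)),
    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d),

with d0 + d degrees of freedom. With d0 = 0 this reduces exactly to the
classical pooled t statistic; with d0 = infinity every feature is tested
against the common prior variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .design import StudyDesign
from .errors import InputError, ModelError, ParameterError
from .matrix import ExpressionMatrix

#: the three pairwise comparisons, as (name, group_a, group_b); log2fc = a - b
COMPARISONS = {
    "CIEvsAir": ("CIE2BC", "Air2BC"),
    "CIEvsNaive": ("CIE2BC", "Naive"),
    "AirvsNaive": ("Air2BC", "Naive"),
}

_P_FLOOR = np.finfo(float).tiny


@dataclass(frozen=True)
class GroupMeansFit:
    """Per-feature group means with pooled within-group residual variance."""

    means: pd.DataFrame  # features x groups
    s2: pd.Series  # pooled residual variance per feature
    df_residual: int  # N - number of groups
    n_per_group: pd.Series  # samples per group


@dataclass(frozen=True)
class ModerationParams:
    """Hierarchical-prior parameters of the moderated-t model."""

    d0: float  # prior degrees of freedom, may be math.inf
    s0_sq: float  # prior variance
    d_residual: int

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ParameterError("d0 must be >= 0")
        if self.s0_sq <= 0:
            raise ParameterError("s0_sq must be > 0")


def fit_group_means(m: ExpressionMatrix, design: StudyDesign) -> GroupMeansFit:
    """Fit the group-means model on log2 data.

    The pooled residual variance per feature is SSE / (N - k) over the k
    groups present in the design; every group needs at least 2 samples.
    """
    if m.scale != "log2":
        raise ModelError("linear modeling expects log2-scale data")
    groups = design.groups.reindex(m.sample_ids)
    if groups.isna().any():
        raise ModelError("samples in matrix missing from design")
    counts = groups.value_counts()
    if (counts < 2).any():
        raise ModelError("every group needs at least 2 samples")
    X = m.values
    group_names = [g for g in ("Naive", "Air2BC", "CIE2BC") if g in set(groups)]
    means = {}
    sse = np.zeros(len(X))
    for g in group_names:
        cols = groups.index[groups == g]
        sub = X[cols].to_numpy(dtype=float)
        mu = sub.mean(axis=1)
        means[g] = mu
        sse += ((sub - mu[:, None]) ** 2).sum(axis=1)
    df = m.n_samples - len(group_names)
    means_df = pd.DataFrame(means, index=X.index)
    s2 = pd.Series(sse / df, index=X.index, name="s2")
    return GroupMeansFit(
        means=means_df,
        s2=s2,
        df_residual=df,
        n_per_group=counts.reindex(group_names),
    )


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the monotone decreasing convex shape of trigamma; iterates on x via
    the update of the moment-matching literature, returning inf when y is
    not positive (no finite solution).
    """
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_moderation(s2: pd.Series | np.ndarray, d_residual: int) -> ModerationParams:
    """Estimate prior df and prior variance by log-scale moment matching."""
    s2 = np.asarray(s2, dtype=float)
    if len(s2) < 10:
        raise ModelError("need at least 10 features to estimate the prior")
    if (s2 < 0).any():
        raise InputError("negative variances")
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise InputError("all variances are zero")
    if np.allclose(positive, positive[0]):
        return ModerationParams(d0=math.inf, s0_sq=float(positive[0]), d_residual=d_residual)
    z = np.log(positive)
    d = d_residual
    e_bias = special.digamma(d / 2.0) - math.log(d / 2.0)
    var_z = float(z.var(ddof=1))
    excess = var_z - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        d0 = math.inf
        log_s0 = float(z.mean()) - e_bias
    else:
        half_d0 = _trigamma_inverse(excess)
        d0 = 2.0 * half_d0
        log_s0 = (
            float(z.mean())
            - e_bias
            + special.digamma(half_d0)
            - math.log(half_d0)
        )
    return ModerationParams(d0=d0, s0_sq=float(np.exp(log_s0)), d_residual=d_residual)


def moderated_contrast(
    fit: GroupMeansFit, params: ModerationParams, contrast: str
) -> pd.DataFrame:
    """Moderated t-test for one pairwise group comparison.

    Returns a table with feature_id, comparison, log2fc, fold_change
    (2^log2fc), t_mod, p (two-sided, clamped away from zero) and the
    BH-adjusted q.
    """
    if contrast not in COMPARISONS:
        raise ParameterError(f"unknown contrast {contrast!r}; one of {list(COMPARISONS)}")
    ga, gb = COMPARISONS[contrast]
    for g in (ga, gb):
        if g not in fit.means.columns:
            raise ModelError(f"group {g!r} absent from fit")
    d0, d = params.d0, params.d_residual
    s2 = fit.s2.to_numpy()
    if math.isinf(d0):
        s_tilde_sq = np.full_like(s2, params.s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * params.s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    log2fc = (fit.means[ga] - fit.means[gb]).to_numpy()
    n1 = int(fit.n_per_group[ga])
    n2 = int(fit.n_per_group[gb])
    denom = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, log2fc / np.where(denom > 0, denom, 1.0), np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, _P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "feature_id": fit.means.index,
            "comparison": contrast,
            "log2fc": log2fc,
            "fold_change": np.power(2.0, log2fc),
            "t_mod": t,
            "p": p,
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment (order-preserving).

    q_i = min over j with p_j >= p_i of min(1, m * p_j / rank_j).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise InputError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def moderated_de_tables(
    m: ExpressionMatrix, design: StudyDesign, contrasts: tuple[str, ...] = tuple(COMPARISONS)
) -> dict[str, pd.DataFrame]:
    """Fit, moderate and test all requested pairwise comparisons."""
    fit = fit_group_means(m, design)
    params = estimate_moderation(fit.s2, fit.df_residual)
    return {c: moderated_contrast(fit, params, c) for c in contrasts}


def directional_summary(
    tables: dict[str, pd.DataFrame],
    fc_lo: float = 0.05,
    p_thresh: float = 0.05,
    n_total: int | None = None,
) -> pd.DataFrame:
    """Directional summary per comparison: DE counts and up/down percentages.

    A feature counts as up-regulated when fold_change > 1 + fc_lo with
    p < p_thresh, and down-regulated when fold_change < 1 / (1 + fc_lo)
    (the reciprocal convention, symmetric on the log scale) with p < p_thresh.
    Percentages are taken against ``n_total`` detected features (defaults to
    the table length). Prevalent direction is "up"/"down" by strict count
    majority, "balanced" on ties.
    """
    rows = []
    for name, tab in tables.items():
        total = n_total if n_total is not None else len(tab)
        sig = tab["p"] < p_thresh
        up = int((sig & (tab["fold_change"] > 1.0 + fc_lo)).sum())
        down = int((sig & (tab["fold_change"] < 1.0 / (1.0 + fc_lo))).sum())
        n_de = up + down
        if up > down:
            direction = "up"
        elif down > up:
            direction = "down"
        else:
            direction = "balanced"
        rows.append(
            {
                "comparison": name,
                "n_de": n_de,
                "pct_de": 100.0 * n_de / total if total else 0.0,
                "pct_up": 100.0 * up / total if total else 0.0,
                "pct_down": 100.0 * down / total if total else 0.0,
                "prevalent_direction": direction,
            }
        )
    return pd.DataFrame(rows)
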