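"""Stage-wise differential expression.

Cohort-level fold change is the log2 ratio of group means computed on the
linear scale::

    log2FC(gene) = log2( mean(E_tumor) / mean(E_normal) )

Significance comes from an empirical-Bayes moderated two-sample t-test:
gene-wise sample variances are shrunk toward a common prior variance whose
location and degrees of freedom are estimated by the method of moments from
the observed distribution of log variances (Smyth-style squeezing), and the
t statistic is referred to a t distribution on residual + prior degrees of
freedom.  Benjamini-Hochberg step-up adjustment controls the FDR, and genes
are classified up/down/neither against configurable fold-change and FDR
gates (boundary values count as significant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: default pseudocount added before every log2 transform of raw expression
DEFAULT_PSEUDOCOUNT = 1.0
#: default significance gate on BH-adjusted p-values (inclusive)
DEFAULT_FDR_THRESHOLD = 0.01
#: default gate on |log2 fold change|: twofold on the linear scale
DEFAULT_LOG2FC_THRESHOLD = 1.0
#: alternative fourfold profile for sensitivity analyses
STRICT_LOG2FC_THRESHOLD = 2.0
#: a stage with fewer tumors than this is dropped from stage-wise DE
DEFAULT_MIN_STAGE_SAMPLES = 5


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------

def log2_fold_change(
    expr: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-gene log2 ratio of mean tumor to mean normal expression.

    Means are taken on the linear scale; the ratio is log2-transformed.
    ``pseudocount`` (default 0) is added to both means before the ratio to
    guard against zero normal means.
    """
    if len(tumor_ids) == 0 or len(normal_ids) == 0:
        raise ValueError("log2_fold_change requires non-empty tumor and normal groups")
    t_mean = expr[tumor_ids].mean(axis=1) + pseudocount
    n_mean = expr[normal_ids].mean(axis=1) + pseudocount
    zero = n_mean == 0
    if zero.any():
        bad = expr.index[zero][:5].tolist()
        raise ValueError(
            f"zero normal mean with zero pseudocount for genes {bad}; "
            "supply a positive pseudocount"
        )
    return pd.Series(np.log2(t_mean / n_mean), index=expr.index, name="log2_fc")


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t
# ---------------------------------------------------------------------------

def trigamma_inverse(y: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Uses the asymptotic starting point x = 0.5 + 1/y and the update
    x <- x + trigamma(x) * (1 - trigamma(x)/y) / polygamma(2, x), which is
    monotone convergent for this convex problem.
    """
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = np.where(y > 1e7, 1.0 / np.sqrt(y), 0.5 + 1.0 / y)
    x = np.where(y < 1e-6, 1.0 / y, x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(-dif / x) < 1e-10:
            break
    return x if x.size > 1 else float(x[0])


def estimate_variance_prior(
    sample_vars: np.ndarray, resid_df: float
) -> tuple[float, float]:
    """Moment-match an inverse-chi-square prior to gene-wise variances.

    Models s_g^2 ~ s0^2 * F(resid_df, d0) and recovers (d0, s0^2) from the
    mean and variance of log s_g^2 via digamma/trigamma identities.  Genes
    with non-positive sample variance are excluded from the fit.  Returns
    ``(prior_df, prior_var)``; ``prior_df`` is ``inf`` when the observed
    spread of log variances is no larger than expected under a single
    common variance.
    """
    s2 = np.asarray(sample_vars, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size == 0:
        return np.inf, 0.0
    z = np.log(s2)
    e = z - special.digamma(resid_df / 2.0) + np.log(resid_df / 2.0)
    e_mean = float(np.mean(e))
    if s2.size < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, resid_df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_sq


@dataclass
class ModeratedTResult:
    """Per-gene moderated-t output plus the fitted variance prior."""

    t_stat: pd.Series
    p_value: pd.Series
    posterior_df: float
    prior_df: float
    prior_var: float
    untestable: pd.Index = field(default_factory=lambda: pd.Index([]))


def moderated_t(
    expr: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    prior_df: float | None = None,
    log_transform: bool = True,
) -> ModeratedTResult:
    """Empirical-Bayes moderated two-sample t-test per gene.

    Works on log2(x + pseudocount).  Gene-wise pooled variances are squeezed
    toward the moment-estimated prior: the posterior variance is the
    df-weighted combination ``(d0*s0^2 + df*s^2) / (d0 + df)`` and the t
    statistic uses ``df + d0`` degrees of freedom.  Forcing ``prior_df=0``
    recovers the ordinary pooled two-sample t-test exactly.

    Genes whose posterior variance is zero (no within-group variability
    anywhere and a zero prior) are flagged untestable: t=NaN, p=NaN.
    """
    n1, n2 = len(tumor_ids), len(normal_ids)
    if n1 < 2 or n2 < 2:
        raise ValueError("moderated_t requires at least 2 samples per group")
    x = expr[tumor_ids].to_numpy(dtype=float)
    y = expr[normal_ids].to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)

    resid_df = n1 + n2 - 2
    mean_diff = x.mean(axis=1) - y.mean(axis=1)
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / resid_df

    if prior_df is None:
        d0, s0_sq = estimate_variance_prior(s2, resid_df)
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_variance_prior(s2, resid_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = 1e9  # effectively normal reference
    elif d0 == 0:
        s2_post = s2
        total_df = resid_df
    else:
        s2_post = (d0 * s0_sq + resid_df * s2) / (d0 + resid_df)
        total_df = resid_df + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    untestable = se == 0
    t = np.where(untestable, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    # exact-tie genes: zero difference is t=0, p=1 regardless of variance
    p = np.where(np.isnan(t), np.nan, p)
    if untestable.any():
        logger.warning("%d genes untestable (zero posterior variance)", untestable.sum())
    idx = expr.index
    return ModeratedTResult(
        t_stat=pd.Series(t, index=idx, name="t"),
        p_value=pd.Series(p, index=idx, name="p"),
        posterior_df=float(total_df),
        prior_df=float(d0),
        prior_var=float(s0_sq),
        untestable=idx[untestable],
    )


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> pd.Series | np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN inputs propagate as NaN (they do not enter the ranking); a warning
    records how many were skipped.  Output is clipped at 1 and order-
    preserving in the usual step-up sense.
    """
    is_series = isinstance(p_values, pd.Series)
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    n_nan = int((~ok).sum())
    if n_nan:
        warnings.warn(f"bh_adjust: {n_nan} NaN p-values propagated", stacklevel=2)
        logger.warning("bh_adjust skipped %d NaN p-values", n_nan)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if is_series:
        return pd.Series(out, index=p_values.index, name="fdr")
    return out


def classify_de(
    log2_fc,
    fdr,
    up_thresh: float = DEFAULT_LOG2FC_THRESHOLD,
    down_thresh: float = -DEFAULT_LOG2FC_THRESHOLD,
    fdr_thresh: float = DEFAULT_FDR_THRESHOLD,
) -> pd.Series:
    """Three-way up/down/neither call; thresholds are inclusive (≤ / ≥)."""
    fc = np.asarray(log2_fc, dtype=float)
    q = np.asarray(fdr, dtype=float)
    sig = q <= fdr_thresh
    direction = np.where(
        sig & (fc >= up_thresh), "up", np.where(sig & (fc <= down_thresh), "down", "neither")
    )
    idx = log2_fc.index if isinstance(log2_fc, pd.Series) else None
    return pd.Series(direction, index=idx, name="direction")


# ---------------------------------------------------------------------------
# stage-wise driver
# ---------------------------------------------------------------------------

@dataclass
class StageDEResult:
    """Per-stage DE tables plus per-direction gene sets and Venn counts."""

    tables: dict[str, pd.DataFrame]
    up_sets: dict[str, set[str]]
    down_sets: dict[str, set[str]]
    intersections: dict[str, dict[str, int]]
    dropped_stages: list[str]

    def all_stage_up(self) -> set[str]:
        """Genes called up in every analyzed stage."""
        if not self.up_sets:
            return set()
        return set.intersection(*self.up_sets.values())

    def any_stage_up(self) -> set[str]:
        """Genes called up in at least one analyzed stage."""
        if not self.up_sets:
            return set()
        return set.union(*self.up_sets.values())

    def all_stage_down(self) -> set[str]:
        if not self.down_sets:
            return set()
        return set.intersection(*self.down_sets.values())

    def any_stage_down(self) -> set[str]:
        if not self.down_sets:
            return set()
        return set.union(*self.down_sets.values())


def _venn_counts(sets: dict[str, set[str]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    names = sorted(sets)
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[s] for s in combo))
            counts["&".join(combo)] = len(inter)
    return counts


def stage_de(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    up_thresh: float = DEFAULT_LOG2FC_THRESHOLD,
    down_thresh: float = -DEFAULT_LOG2FC_THRESHOLD,
    fdr_thresh: float = DEFAULT_FDR_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_stage_samples: int = DEFAULT_MIN_STAGE_SAMPLES,
) -> StageDEResult:
    """Differential expression of each tumor stage against all normals.

    ``samples`` needs columns ``sample``, ``group`` (tumor/normal) and
    ``stage``.  Stages with fewer than ``min_stage_samples`` tumors are
    dropped with a warning (mirrors excluding an under-sampled late stage).
    BH adjustment is performed within each stage.
    """
    normal_ids = samples.loc[samples["group"] == "normal", "sample"].tolist()
    tumors = samples[samples["group"] == "tumor"]
    if not normal_ids:
        raise ValueError("no normal samples in annotation")

    tables: dict[str, pd.DataFrame] = {}
    up_sets: dict[str, set[str]] = {}
    down_sets: dict[str, set[str]] = {}
    dropped: list[str] = []
    for stage, grp in tumors.groupby("stage", sort=True):
        ids = grp["sample"].tolist()
        if len(ids) < min_stage_samples:
            logger.warning(
                "stage %s dropped: %d tumors < minimum %d", stage, len(ids), min_stage_samples
            )
            dropped.append(str(stage))
            continue
        fc = log2_fold_change(expr, ids, normal_ids, pseudocount=pseudocount)
        mt = moderated_t(expr, ids, normal_ids, pseudocount=pseudocount)
        fdr = bh_adjust(mt.p_value)
        direction = classify_de(fc, fdr, up_thresh, down_thresh, fdr_thresh)
        tab = pd.DataFrame(
            {
                "gene": expr.index,
                "stage": str(stage),
                "log2_fc": fc.to_numpy(),
                "t": mt.t_stat.to_numpy(),
                "p": mt.p_value.to_numpy(),
                "fdr": fdr.to_numpy(),
                "direction": direction.to_numpy(),
            }
        ).set_index("gene", drop=False)
        tables[str(stage)] = tab
        up_sets[str(stage)] = set(tab.index[tab["direction"] == "up"])
        down_sets[str(stage)] = set(tab.index[tab["direction"] == "down"])

    intersections = {"up": _venn_counts(up_sets), "down": _venn_counts(down_sets)}
    return StageDEResult(tables, up_sets, down_sets, intersections, dropped)
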