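"""Tumor-suppressor anti-correlation and the multivariate expression score.

The prognostic analysis fits a multivariate Cox proportional-hazards model
to a gene panel, forms a per-patient score as the coefficient-weighted sum
of the (log2, standardized) expression values, splits patients at the
median score, and compares the two groups with Kaplan-Meier curves and the
log-rank test.  A companion routine correlates EEA-gene expression with a
tumor-suppressor panel (pairwise Pearson r with two-sided t-transform
p-values) to test for coordinated anti-correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 1.0
#: refuse a joint fit when genes exceed this fraction of patients
DEFAULT_MAX_GENE_FRACTION = 0.5
DEFAULT_RIDGE = 0.1


# ---------------------------------------------------------------------------
# suppressor correlation
# ---------------------------------------------------------------------------

def suppressor_correlation(
    expr_eea: pd.DataFrame,
    expr_suppressors: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation between two gene panels across patients.

    Expression is log2(x + pseudocount).  Returns (r, p, significant) frames
    indexed by EEA genes with suppressor genes as columns.  Two-sided
    p-values use the exact t transform t = r sqrt((n-2)/(1-r^2)) on n-2 df.
    Zero-variance genes yield NaN rows/columns.
    """
    shared = [s for s in expr_eea.columns if s in expr_suppressors.columns]
    n = len(shared)
    if n < 3:
        raise ValueError("need at least 3 shared patients for correlation p-values")
    X = np.log2(expr_eea[shared].to_numpy(dtype=float) + pseudocount)
    Y = np.log2(expr_suppressors[shared].to_numpy(dtype=float) + pseudocount)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.linalg.norm(Xc, axis=1)
    sy = np.linalg.norm(Yc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Yc.T) / np.outer(sx, sy)
    r = np.clip(r, -1.0, 1.0)
    r[sx == 0, :] = np.nan
    r[:, sy == 0] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 0.0, p)
    p = np.where(np.isnan(r), np.nan, p)
    idx, cols = expr_eea.index, expr_suppressors.index
    r_df = pd.DataFrame(r, index=idx, columns=cols)
    p_df = pd.DataFrame(p, index=idx, columns=cols)
    sig = p_df < alpha
    return r_df, p_df, sig


# ---------------------------------------------------------------------------
# Cox model and expression score
# ---------------------------------------------------------------------------

def _prepare_cox_matrix(
    expr_subset: pd.DataFrame, pseudocount: float
) -> pd.DataFrame:
    """Patients x genes design matrix: log2(x + pc), standardized per gene."""
    X = np.log2(expr_subset.to_numpy(dtype=float) + pseudocount).T
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    return pd.DataFrame(Z, index=expr_subset.columns, columns=expr_subset.index)


@dataclass
class CoxResult:
    """Fitted per-gene log-hazard coefficients with diagnostics."""

    coefficients: pd.Series
    standard_errors: pd.Series
    p_values: pd.Series
    mode: str                       # "multivariate" | "univariate"
    penalizer: float = 0.0
    converged: bool = True
    notes: list[str] = field(default_factory=list)


def fit_cox(
    expr_subset: pd.DataFrame,
    survival: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    max_gene_fraction: float = DEFAULT_MAX_GENE_FRACTION,
    penalizer: float = 0.0,
    standardize: bool = True,
) -> CoxResult:
    """Multivariate Cox partial-likelihood fit of gene expression on survival.

    ``expr_subset`` is genes x patients; ``survival`` needs columns
    ``sample``, ``time``, ``event``.  Expression enters as standardized
    log2(x + pseudocount).  When the panel exceeds ``max_gene_fraction`` of
    the patient count, the joint fit is ill-posed and the routine falls back
    to per-gene univariate coefficients with a warning.  Separation or
    non-convergence triggers one ridge-stabilized retry (recorded).
    """
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    patients = [p for p in expr_subset.columns if p in surv.index]
    if len(patients) < 3:
        raise ValueError("too few patients with survival records")
    surv = surv.loc[patients, ["time", "event"]].astype(float)
    if (surv["time"] < 0).any():
        raise ValueError("negative survival times")
    if surv["event"].sum() == 0:
        raise ValueError("no events observed: Cox model undefined")

    if standardize:
        Z = _prepare_cox_matrix(expr_subset[patients], pseudocount)
    else:
        Z = expr_subset[patients].T.astype(float)
    df = pd.concat([Z, surv], axis=1)
    genes = list(expr_subset.index)
    notes: list[str] = []

    if len(genes) > max_gene_fraction * len(patients):
        logger.warning(
            "%d genes > %.0f%% of %d patients: falling back to univariate coefficients",
            len(genes), 100 * max_gene_fraction, len(patients),
        )
        notes.append("univariate fallback: panel too large for a joint fit")
        coefs, ses, ps = {}, {}, {}
        for g in genes:
            cph = CoxPHFitter()
            cph.fit(df[[g, "time", "event"]], duration_col="time", event_col="event")
            coefs[g] = float(cph.params_[g])
            ses[g] = float(cph.standard_errors_[g])
            ps[g] = float(cph.summary.loc[g, "p"])
        return CoxResult(
            coefficients=pd.Series(coefs, name="coef"),
            standard_errors=pd.Series(ses),
            p_values=pd.Series(ps),
            mode="univariate",
            notes=notes,
        )

    used_pen = penalizer
    try:
        cph = CoxPHFitter(penalizer=used_pen)
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence / separation
        used_pen = max(penalizer, DEFAULT_RIDGE)
        notes.append(f"ridge stabilization (penalizer={used_pen}) after: {exc}")
        logger.warning("Cox fit unstable (%s); retrying with ridge %.3g", exc, used_pen)
        cph = CoxPHFitter(penalizer=used_pen)
        cph.fit(df, duration_col="time", event_col="event")
    return CoxResult(
        coefficients=cph.params_.reindex(genes).rename("coef"),
        standard_errors=cph.standard_errors_.reindex(genes),
        p_values=cph.summary["p"].reindex(genes),
        mode="multivariate",
        penalizer=used_pen,
        notes=notes,
    )


def univariate_cox_pvalues(
    expr_subset: pd.DataFrame,
    survival: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene univariate Cox p-values (panel-selection helper)."""
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    patients = [p for p in expr_subset.columns if p in surv.index]
    surv = surv.loc[patients, ["time", "event"]].astype(float)
    Z = _prepare_cox_matrix(expr_subset[patients], pseudocount)
    ps = {}
    for g in expr_subset.index:
        d = pd.concat([Z[[g]], surv], axis=1)
        try:
            cph = CoxPHFitter()
            cph.fit(d, duration_col="time", event_col="event")
            ps[g] = float(cph.summary.loc[g, "p"])
        except Exception:
            ps[g] = np.nan
    return pd.Series(ps, name="univariate_p")


def multivariate_score(
    expr_subset: pd.DataFrame,
    coefficients: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    standardize: bool = False,
) -> pd.Series:
    """Per-patient score: sum of expression values times Cox coefficients.

    By default the raw expression values are combined; with
    ``standardize=True`` the same standardized log2 matrix used by
    :func:`fit_cox` is combined instead (the pipeline's choice, so the
    score is on the scale the coefficients were estimated on).
    """
    missing = [g for g in coefficients.index if g not in expr_subset.index]
    if missing:
        raise ValueError(f"expression matrix lacks score genes: {missing[:5]}")
    sub = expr_subset.loc[coefficients.index]
    if standardize:
        M = _prepare_cox_matrix(sub, pseudocount)  # patients x genes
        scores = M.to_numpy() @ coefficients.to_numpy()
    else:
        scores = sub.to_numpy().T @ coefficients.to_numpy()
    return pd.Series(scores, index=sub.columns, name="score")


# ---------------------------------------------------------------------------
# Kaplan-Meier by median score
# ---------------------------------------------------------------------------

@dataclass
class ScoreResult:
    """Median-split survival comparison of the multivariate score."""

    scores: pd.Series
    groups: pd.Series                     # "high" | "low" per patient
    km_curves: dict[str, pd.DataFrame]    # per group: time, survival, at_risk
    logrank_statistic: float
    logrank_p: float
    median_score: float


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit Kaplan-Meier estimate with at-risk counts."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    surv = kmf.survival_function_
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.iloc[:, 0].to_numpy(dtype=float),
        }
    )
    at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
    out["at_risk"] = at_risk.to_numpy()
    return out


def km_by_median(
    scores: pd.Series,
    survival: pd.DataFrame,
) -> ScoreResult:
    """Split patients at the median score and compare survival.

    Ties at the median go to the low group.  Requires at least two patients
    per group.  Returns per-group KM curves and the two-group log-rank test.
    """
    surv = survival.set_index("sample") if "sample" in survival.columns else survival
    patients = [p for p in scores.index if p in surv.index]
    s = scores.loc[patients]
    surv = surv.loc[patients, ["time", "event"]].astype(float)
    med = float(s.median())
    groups = pd.Series(np.where(s <= med, "low", "high"), index=s.index, name="group")
    n_low = int((groups == "low").sum())
    n_high = int((groups == "high").sum())
    if n_low < 2 or n_high < 2:
        raise ValueError(
            f"degenerate median split (low={n_low}, high={n_high}); "
            "scores may be constant"
        )
    low_idx = groups.index[groups == "low"]
    high_idx = groups.index[groups == "high"]
    curves = {
        "low": km_estimate(surv.loc[low_idx, "time"].to_numpy(),
                           surv.loc[low_idx, "event"].to_numpy()),
        "high": km_estimate(surv.loc[high_idx, "time"].to_numpy(),
                            surv.loc[high_idx, "event"].to_numpy()),
    }
    res = logrank_test(
        surv.loc[low_idx, "time"],
        surv.loc[high_idx, "time"],
        event_observed_A=surv.loc[low_idx, "event"],
        event_observed_B=surv.loc[high_idx, "event"],
    )
    return ScoreResult(
        scores=s,
        groups=groups,
        km_curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
        median_score=med,
    )
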