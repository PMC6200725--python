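"""Copy-number / expression concordance filtering and EEA derivation.

Upregulated genes whose overexpression can be explained by DNA amplification
are removed before any evolutionary interpretation.  Three screens apply:

* recurrent amplification — a gene amplified (call ≥ threshold) in ≥ 40% of
  patients is "cancer-relevant amplified"; a cytoband where ≥ 40% of its
  genes are recurrently amplified is an amplified region;
* CNA-associated expression — for each gene, patients split into amplified
  (S1) and non-amplified (S2); the difference of log2 group means together
  with a moderated t-test flags genes with ≥ 1 positive log2 fold difference
  at FDR < 0.01;
* expression/copy-number correlation — Pearson r between log2 expression and
  the integer call across patients; r > 0.3 flags a CNA-driven gene.

Genes surviving all screens, minus externally supplied mutated and
ambiguous-locus lists, form the exclusively expression-altered (EEA) set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, moderated_t

logger = logging.getLogger(__name__)

DEFAULT_AMP_CALL_THRESHOLD = 1  # call >= 1 counts as amplified; 2 = high-level only
DEFAULT_MIN_AMP_FRACTION = 0.40
DEFAULT_MIN_REGION_FRACTION = 0.40
DEFAULT_ASSOC_FOLD = 1.0
DEFAULT_ASSOC_FDR = 0.01
DEFAULT_CORR_CUTOFF = 0.3
# genes amplified in ≥ this fraction of patients cannot be cleared of CNA
# drive (no usable non-amplified group) and are excluded conservatively
FULLY_AMPLIFIED_FRACTION = 0.90

#: fixed precedence when a gene carries several removal reasons
REASON_PRECEDENCE = ("region", "association", "correlation", "mutated", "ambiguous")


@dataclass
class CnaProfile:
    """Gene x sample integer copy-number calls plus binary amplification."""

    calls: pd.DataFrame
    call_threshold: int = DEFAULT_AMP_CALL_THRESHOLD
    call_range: tuple[int, int] = (-2, 2)

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("CNA calls must be integers")
            self.calls = self.calls.astype(int)
            vals = self.calls.to_numpy()
        lo, hi = self.call_range
        if vals.min() < lo or vals.max() > hi:
            raise ValueError(f"CNA calls outside configured range [{lo}, {hi}]")

    @property
    def amplified(self) -> pd.DataFrame:
        """Binary gene x sample amplification status at the call threshold."""
        return (self.calls >= self.call_threshold).astype(np.int8)

    def amplified_fraction(self) -> pd.Series:
        return self.amplified.mean(axis=1)


def recurrently_amplified_genes(
    cna: CnaProfile,
    min_frac: float = DEFAULT_MIN_AMP_FRACTION,
    strict: bool = False,
) -> set[str]:
    """Genes amplified in at least ``min_frac`` of patients (inclusive)."""
    frac = cna.amplified_fraction()
    hit = frac > min_frac if strict else frac >= min_frac
    return set(frac.index[hit])


def amplified_regions(
    genes: pd.DataFrame,
    amplified_set: set[str],
    min_frac: float = DEFAULT_MIN_REGION_FRACTION,
    strict: bool = False,
) -> pd.DataFrame:
    """Cytobands where ≥ ``min_frac`` of their genes are recurrently amplified.

    ``genes`` requires columns ``gene`` and ``cytoband``; genes without a
    cytoband are ignored here (they surface via the ambiguous-locus list).
    Returns a frame (cytoband, n_genes, n_amplified, fraction, called).
    """
    ann = genes.dropna(subset=["cytoband"])
    rows = []
    for band, grp in ann.groupby("cytoband", sort=True):
        n = len(grp)
        if n == 0:
            logger.warning("cytoband %s has no annotated genes; skipped", band)
            continue
        n_amp = int(grp["gene"].isin(amplified_set).sum())
        frac = n_amp / n
        called = frac > min_frac if strict else frac >= min_frac
        rows.append((band, n, n_amp, frac, bool(called)))
    return pd.DataFrame(
        rows, columns=["cytoband", "n_genes", "n_amplified", "fraction", "called"]
    ).set_index("cytoband", drop=False)


def cna_expression_association(
    expr: pd.DataFrame,
    cna: CnaProfile,
    genes: list[str] | None = None,
    fold_cutoff: float = DEFAULT_ASSOC_FOLD,
    fdr_cutoff: float = DEFAULT_ASSOC_FDR,
    min_group: int = 2,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Test expression against per-gene amplification status.

    For each gene, patients shared between the expression and CNA matrices
    split into amplified (S1) and non-amplified (S2).  The CNA-associated
    fold change is log2(mean expr in S1) − log2(mean expr in S2); the p-value
    comes from the shared moderated-t machinery on log2 expression, with BH
    adjustment across all tested genes.  A gene is flagged when the fold
    change is ≥ ``fold_cutoff`` and FDR < ``fdr_cutoff``.  Genes with a
    group smaller than ``min_group`` are marked indeterminate.
    """
    shared = [s for s in expr.columns if s in cna.calls.columns]
    if len(shared) < 2 * min_group:
        raise ValueError("too few samples shared between expression and CNA matrices")
    if genes is None:
        genes = [g for g in expr.index if g in cna.calls.index]
    amp = cna.amplified

    records = []
    log_expr = np.log2(expr[shared] + pseudocount)
    for g in genes:
        status = amp.loc[g, shared].to_numpy()
        s1 = [s for s, a in zip(shared, status) if a]
        s2 = [s for s, a in zip(shared, status) if not a]
        if len(s1) < min_group or len(s2) < min_group:
            records.append((g, np.nan, np.nan, np.nan, True))
            continue
        row = expr.loc[[g], shared]
        m1 = float(row[s1].mean(axis=1).iloc[0]) + pseudocount
        m2 = float(row[s2].mean(axis=1).iloc[0]) + pseudocount
        fold = float(np.log2(m1) - np.log2(m2))
        x1 = log_expr.loc[g, s1].to_numpy()
        x2 = log_expr.loc[g, s2].to_numpy()
        t, p = _two_sample_t(x1, x2)
        records.append((g, fold, t, p, False))
    out = pd.DataFrame(
        records, columns=["gene", "fold_change", "t", "p", "indeterminate"]
    ).set_index("gene", drop=False)
    out["fdr"] = _bh_tested(out)
    out["flagged"] = (
        (out["fold_change"] >= fold_cutoff) & (out["fdr"] < fdr_cutoff)
    ).fillna(False)
    # shrink variances jointly across genes when enough genes are tested
    tested = out.index[~out["indeterminate"]]
    if len(tested) >= 10:
        out = _moderated_association(expr[shared], amp[shared], out, tested,
                                     fold_cutoff, fdr_cutoff, pseudocount)
    return out


def _two_sample_t(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(x1, x2)
    return float(t), float(p)


def _bh_tested(out: pd.DataFrame) -> pd.Series:
    """BH over testable genes only; indeterminate genes stay NaN by design."""
    fdr = pd.Series(np.nan, index=out.index, name="fdr")
    tested = out.index[~out["indeterminate"]]
    if len(tested):
        fdr.loc[tested] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return fdr


def _moderated_association(expr, amp, out, tested, fold_cutoff, fdr_cutoff, pseudocount):
    """Re-test with empirical-Bayes variance shrinkage across genes.

    Group splits differ per gene, so genes are batched by their amplified
    patient set where possible; the common case (a planted carrier pattern
    shared by no one) falls back to a per-gene pooled t with a prior fitted
    on all gene-wise pooled variances.
    """
    n = expr.shape[1]
    log_expr = np.log2(expr.loc[tested] + pseudocount)
    status = amp.loc[tested].to_numpy().astype(bool)
    vals = log_expr.to_numpy()
    m1 = np.array([vals[i, status[i]].mean() for i in range(len(tested))])
    m2 = np.array([vals[i, ~status[i]].mean() for i in range(len(tested))])
    v1 = np.array([vals[i, status[i]].var(ddof=1) for i in range(len(tested))])
    v2 = np.array([vals[i, ~status[i]].var(ddof=1) for i in range(len(tested))])
    n1 = status.sum(axis=1)
    n2 = n - n1
    resid_df = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / resid_df
    from .diffexpr import estimate_variance_prior

    d0, s0_sq = estimate_variance_prior(s2, float(np.median(resid_df)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        total_df = np.full_like(s2, 1e9)
    else:
        s2_post = (d0 * s0_sq + resid_df * s2) / (d0 + resid_df)
        total_df = resid_df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=total_df)
    out.loc[tested, "t"] = t
    out.loc[tested, "p"] = p
    out["fdr"] = _bh_tested(out)
    out["flagged"] = (
        (out["fold_change"] >= fold_cutoff) & (out["fdr"] < fdr_cutoff)
    ).fillna(False)
    return out


def cna_expression_correlation(
    expr: pd.DataFrame,
    cna: CnaProfile,
    genes: list[str] | None = None,
    cutoff: float = DEFAULT_CORR_CUTOFF,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene Pearson r between log2 expression and the integer CNA call.

    Flags CNA-driven genes at r > ``cutoff`` (strict, as conventional).
    Zero-variance pairings leave r undefined (NaN, not flagged).
    """
    shared = [s for s in expr.columns if s in cna.calls.columns]
    if genes is None:
        genes = [g for g in expr.index if g in cna.calls.index]
    x = np.log2(expr.loc[genes, shared].to_numpy(dtype=float) + pseudocount)
    c = cna.calls.loc[genes, shared].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    cc = c - c.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum(axis=1))
    sc = np.sqrt((cc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * cc).sum(axis=1) / (sx * sc)
    undef = (sx == 0) | (sc == 0)
    r[undef] = np.nan
    if undef.any():
        logger.warning("%d genes have zero-variance expression or calls; r undefined",
                       int(undef.sum()))
    out = pd.DataFrame({"gene": genes, "pearson_r": r}, index=pd.Index(genes, name=None))
    out["flagged"] = out["pearson_r"] > cutoff
    out["flagged"] = out["flagged"].fillna(False)
    return out


@dataclass
class EeaDerivation:
    """Provenance of the EEA filter: what went in, what was removed and why."""

    input_genes: set[str]
    removed_in_amplified_region: set[str]
    removed_cna_associated: set[str]
    removed_correlated: set[str]
    removed_mutated: set[str]
    removed_ambiguous: set[str]
    eea_genes: set[str]
    primary_reason: dict[str, str] = field(default_factory=dict)

    def removal_table(self) -> pd.DataFrame:
        rows = [(g, self.primary_reason.get(g, "kept")) for g in sorted(self.input_genes)]
        return pd.DataFrame(rows, columns=["gene", "reason"])


def derive_eea(
    frequent_up: set[str],
    association: pd.DataFrame | None = None,
    correlation: pd.DataFrame | None = None,
    region_calls: pd.DataFrame | None = None,
    gene_annotations: pd.DataFrame | None = None,
    mutated_list: set[str] | None = None,
    ambiguous_list: set[str] | None = None,
    amplified_fraction: pd.Series | None = None,
) -> EeaDerivation:
    """Remove CNA-, mutation- and locus-compromised genes from the frequent set.

    A frequent upregulated gene is removed when it (a) lies in a called
    amplified region, (b) is flagged by the association or correlation
    screen (indeterminate genes are removed only when amplified in ≥ 90% of
    patients — they cannot be cleared), (c) appears in the mutated-gene
    list, or (d) has no / ambiguous locus annotation.  The survivors are the
    EEA genes.  Per-gene primary reasons follow the fixed precedence
    region > association > correlation > mutated > ambiguous.
    """
    frequent_up = set(frequent_up)
    mutated_list = set(mutated_list or ())
    ambiguous_list = set(ambiguous_list or ())

    unknown = (mutated_list | ambiguous_list) - frequent_up
    if unknown:
        logger.warning("%d exclusion-list genes not in the frequent set; ignored",
                       len(unknown))

    in_region: set[str] = set()
    if region_calls is not None and gene_annotations is not None:
        called_bands = set(region_calls.loc[region_calls["called"], "cytoband"])
        ann = gene_annotations.set_index("gene")["cytoband"]
        in_region = {
            g for g in frequent_up if g in ann.index and ann[g] in called_bands
        }

    assoc_flagged: set[str] = set()
    if association is not None:
        assoc_flagged = set(association.index[association["flagged"]]) & frequent_up
        if amplified_fraction is not None:
            indet = set(association.index[association["indeterminate"]]) & frequent_up
            fully = {
                g for g in indet
                if g in amplified_fraction.index
                and amplified_fraction[g] >= FULLY_AMPLIFIED_FRACTION
            }
            assoc_flagged |= fully

    corr_flagged: set[str] = set()
    if correlation is not None:
        corr_flagged = set(correlation.index[correlation["flagged"]]) & frequent_up

    mutated = mutated_list & frequent_up
    ambiguous = ambiguous_list & frequent_up
    if gene_annotations is not None:
        ann = gene_annotations.set_index("gene")
        missing_locus = {
            g for g in frequent_up
            if g not in ann.index or pd.isna(ann.loc[g, "cytoband"])
        }
        ambiguous |= missing_locus

    reason_sets = {
        "region": in_region,
        "association": assoc_flagged,
        "correlation": corr_flagged,
        "mutated": mutated,
        "ambiguous": ambiguous,
    }
    removed = set().union(*reason_sets.values())
    primary: dict[str, str] = {}
    for g in removed:
        for reason in REASON_PRECEDENCE:
            if g in reason_sets[reason]:
                primary[g] = reason
                break
    eea = frequent_up - removed
    logger.info(
        "EEA derivation: %d in, removed region=%d assoc=%d corr=%d mut=%d ambig=%d -> %d EEA",
        len(frequent_up), len(in_region), len(assoc_flagged), len(corr_flagged),
        len(mutated), len(ambiguous), len(eea),
    )
    return EeaDerivation(
        input_genes=frequent_up,
        removed_in_amplified_region=in_region,
        removed_cna_associated=assoc_flagged,
        removed_correlated=corr_flagged,
        removed_mutated=mutated,
        removed_ambiguous=ambiguous,
        eea_genes=eea,
        primary_reason=primary,
    )
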