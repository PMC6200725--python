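"""End-to-end pipeline driver: DE -> recurrence -> CNA filter -> lineage -> outcome.

The driver mirrors the analysis funnel: stage-wise differential expression
against normals, per-patient recurrence of the upregulated candidates, the
CNA/mutation/locus exclusion filter yielding the EEA genes, patient
clustering and neighbor-joining lineage over the EEA upregulation profiles,
subset assignment calling the early-burst set, and finally the multivariate
expression score with Kaplan-Meier evaluation.  A run manifest records the
config snapshot, per-stage gene counts (the funnel), wall-clock per stage
and the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cna as cna_mod
from . import diffexpr, evolution, io, outcome, recurrence

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every pipeline threshold, plus optional input paths for file runs."""

    # input paths (optional when running on in-memory tables)
    expression: str | None = None
    samples: str | None = None
    genes: str | None = None
    cna: str | None = None
    mutated_list: str | None = None
    ambiguous_list: str | None = None
    suppressor_list: str | None = None
    outdir: str | None = None
    # thresholds (documented defaults)
    fdr_threshold: float = diffexpr.DEFAULT_FDR_THRESHOLD
    log2fc_threshold: float = diffexpr.DEFAULT_LOG2FC_THRESHOLD
    min_frequency: float = recurrence.DEFAULT_MIN_FREQUENCY
    amp_call_threshold: int = cna_mod.DEFAULT_AMP_CALL_THRESHOLD
    min_amp_fraction: float = cna_mod.DEFAULT_MIN_AMP_FRACTION
    min_region_fraction: float = cna_mod.DEFAULT_MIN_REGION_FRACTION
    assoc_fold_cutoff: float = cna_mod.DEFAULT_ASSOC_FOLD
    assoc_fdr_cutoff: float = cna_mod.DEFAULT_ASSOC_FDR
    corr_cutoff: float = cna_mod.DEFAULT_CORR_CUTOFF
    k_clusters: int = evolution.DEFAULT_K
    linkage: str = evolution.DEFAULT_LINKAGE
    pseudocount: float = diffexpr.DEFAULT_PSEUDOCOUNT
    min_stage_samples: int = diffexpr.DEFAULT_MIN_STAGE_SAMPLES
    univariate_p_cutoff: float = 0.05
    run_outcome: bool = True
    seed: int = 0

    _RANGES = {
        "fdr_threshold": (0.0, 1.0),
        "min_frequency": (0.0, 1.0),
        "min_amp_fraction": (0.0, 1.0),
        "min_region_fraction": (0.0, 1.0),
        "assoc_fdr_cutoff": (0.0, 1.0),
        "corr_cutoff": (-1.0, 1.0),
        "univariate_p_cutoff": (0.0, 1.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"RunConfig.{name}={v} outside [{lo}, {hi}]")
        if self.log2fc_threshold <= 0:
            raise ValueError("RunConfig.log2fc_threshold must be positive")
        if self.k_clusters < 2:
            raise ValueError("RunConfig.k_clusters must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        if "n_tumor_per_stage" in data:  # defensive; not a RunConfig field
            raise ValueError("cohort generation keys belong to CohortConfig")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    """All stage outputs of one run."""

    manifest: RunManifest
    stage_de: diffexpr.StageDEResult
    frequency: pd.DataFrame
    frequent_up: set[str]
    eea: cna_mod.EeaDerivation
    profile: recurrence.UpregulationProfile | None
    clusters: evolution.ClusterSet | None
    lineage: evolution.LineageTree | None
    earliest: str | None
    assignments: evolution.SubsetAssignment | None
    early_burst: dict[str, set[str]] | None
    score_result: outcome.ScoreResult | None
    cox: outcome.CoxResult | None
    suppressor_r: pd.DataFrame | None = None


def run_pipeline(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    cna_profile: cna_mod.CnaProfile,
    config: RunConfig | None = None,
    mutated: set[str] | None = None,
    ambiguous: set[str] | None = None,
    suppressors: set[str] | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory tables.

    Deterministic given (inputs, config): no stage draws random numbers.
    Any stage failure aborts with the stage name prefixed to the error.
    """
    cfg = config or RunConfig()
    cfg.validate()
    manifest = RunManifest(config=cfg.snapshot(), seed=cfg.seed)
    stage = "setup"

    def tick(name: str, t0: float) -> None:
        manifest.timings[name] = round(_time.perf_counter() - t0, 4)

    try:
        tumor_ids = samples.loc[samples["group"] == "tumor", "sample"].tolist()
        normal_ids = samples.loc[samples["group"] == "normal", "sample"].tolist()

        # 1. stage-wise differential expression
        stage = "diffexpr"
        t0 = _time.perf_counter()
        de = diffexpr.stage_de(
            expr, samples,
            up_thresh=cfg.log2fc_threshold,
            down_thresh=-cfg.log2fc_threshold,
            fdr_thresh=cfg.fdr_threshold,
            pseudocount=cfg.pseudocount,
            min_stage_samples=cfg.min_stage_samples,
        )
        candidates = sorted(de.any_stage_up())
        manifest.counts["de_up_any_stage"] = len(candidates)
        manifest.counts["de_up_all_stages"] = len(de.all_stage_up())
        manifest.counts["de_down_any_stage"] = len(de.any_stage_down())
        tick(stage, t0)

        # 2. per-patient recurrence over all tumors
        stage = "recurrence"
        t0 = _time.perf_counter()
        pfc = recurrence.per_patient_fc(expr, tumor_ids, normal_ids,
                                        pseudocount=cfg.pseudocount)
        freq = recurrence.upregulation_frequency(pfc, up_thresh=cfg.log2fc_threshold)
        frequent_up = recurrence.frequent_genes(
            freq.loc[candidates], min_freq=cfg.min_frequency, direction="up"
        ) if candidates else set()
        manifest.counts["frequent_up"] = len(frequent_up)
        tick(stage, t0)

        # 3. CNA / mutation / locus exclusion -> EEA
        stage = "cna_filter"
        t0 = _time.perf_counter()
        amplified = cna_mod.recurrently_amplified_genes(
            cna_profile, min_frac=cfg.min_amp_fraction
        )
        regions = cna_mod.amplified_regions(
            genes, amplified, min_frac=cfg.min_region_fraction
        )
        test_genes = sorted(frequent_up & set(cna_profile.calls.index))
        assoc = cna_mod.cna_expression_association(
            expr, cna_profile, genes=test_genes,
            fold_cutoff=cfg.assoc_fold_cutoff, fdr_cutoff=cfg.assoc_fdr_cutoff,
            pseudocount=cfg.pseudocount,
        ) if test_genes else None
        corr = cna_mod.cna_expression_correlation(
            expr, cna_profile, genes=test_genes, cutoff=cfg.corr_cutoff,
            pseudocount=cfg.pseudocount,
        ) if test_genes else None
        eea = cna_mod.derive_eea(
            frequent_up,
            association=assoc,
            correlation=corr,
            region_calls=regions,
            gene_annotations=genes,
            mutated_list=mutated,
            ambiguous_list=ambiguous,
            amplified_fraction=cna_profile.amplified_fraction(),
        )
        manifest.counts["amplified_regions"] = int(regions["called"].sum())
        manifest.counts["removed_region"] = len(eea.removed_in_amplified_region)
        manifest.counts["removed_association"] = len(eea.removed_cna_associated)
        manifest.counts["removed_correlation"] = len(eea.removed_correlated)
        manifest.counts["removed_mutated"] = len(eea.removed_mutated)
        manifest.counts["removed_ambiguous"] = len(eea.removed_ambiguous)
        manifest.counts["eea"] = len(eea.eea_genes)
        tick(stage, t0)

        # 4. clustering, lineage, subset assignment, early burst
        stage = "evolution"
        t0 = _time.perf_counter()
        profile = clusters = lineage = assignments = None
        earliest = None
        early = None
        eea_sorted = sorted(eea.eea_genes)
        if len(eea_sorted) >= 2 and len(tumor_ids) >= cfg.k_clusters:
            profile = recurrence.binarize_upregulation(
                pfc.loc[eea_sorted], up_thresh=cfg.log2fc_threshold
            )
            clusters = evolution.hierarchical_clusters(
                profile, k=cfg.k_clusters, linkage_method=cfg.linkage
            )
            lineage = evolution.build_lineage(clusters.mean_profiles)
            earliest = evolution.earliest_cluster(lineage)
            gene_profiles = evolution.gene_cluster_profiles(profile, clusters)
            assignments = evolution.subset_assignment(gene_profiles)
            early = evolution.early_burst_genes(assignments, earliest, eea.eea_genes)
            manifest.counts["early_burst_inclusive"] = len(early["inclusive"])
            manifest.counts["early_burst_strict"] = len(early["strict"])
        else:
            manifest.warnings.append("evolution stage skipped: too few EEA genes or tumors")
        tick(stage, t0)

        # 5. outcome: suppressor correlation + multivariate score
        stage = "outcome"
        t0 = _time.perf_counter()
        score_result = cox = None
        supp_r = None
        has_survival = (
            "time" in samples.columns
            and samples.loc[samples["group"] == "tumor", "time"].notna().any()
        )
        if cfg.run_outcome and early is not None and has_survival:
            panel = sorted(early["inclusive"])
            surv = samples.loc[
                (samples["group"] == "tumor") & samples["time"].notna(),
                ["sample", "time", "event"],
            ]
            if panel and len(surv) >= 10 and surv["event"].sum() > 0:
                uni_p = outcome.univariate_cox_pvalues(
                    expr.loc[panel, surv["sample"]], surv, pseudocount=cfg.pseudocount
                )
                selected = sorted(uni_p.index[uni_p <= cfg.univariate_p_cutoff])
                manifest.counts["prognostic_panel"] = len(selected)
                if selected:
                    cox = outcome.fit_cox(
                        expr.loc[selected, surv["sample"]], surv,
                        pseudocount=cfg.pseudocount,
                    )
                    scores = outcome.multivariate_score(
                        expr.loc[selected, surv["sample"]], cox.coefficients,
                        pseudocount=cfg.pseudocount, standardize=True,
                    )
                    score_result = outcome.km_by_median(scores, surv)
            if suppressors:
                supp = sorted(set(suppressors) & set(expr.index))
                if supp and panel:
                    supp_r, _, _ = outcome.suppressor_correlation(
                        expr.loc[panel, tumor_ids], expr.loc[supp, tumor_ids],
                        pseudocount=cfg.pseudocount,
                    )
        tick(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    return PipelineResult(
        manifest=manifest,
        stage_de=de,
        frequency=freq,
        frequent_up=frequent_up,
        eea=eea,
        profile=profile,
        clusters=clusters,
        lineage=lineage,
        earliest=earliest,
        assignments=assignments,
        early_burst=early,
        score_result=score_result,
        cox=cox,
        suppressor_r=supp_r,
    )


def run_pipeline_files(config: RunConfig) -> PipelineResult:
    """Read inputs from ``config`` paths, run, and write all stage outputs."""
    cfg = config
    for req in ("expression", "samples", "genes", "cna", "outdir"):
        if getattr(cfg, req) is None:
            raise ValueError(f"RunConfig.{req} is required for a file-based run")
    expr = io.read_expression(cfg.expression)
    samples = io.read_samples(cfg.samples, expression=expr)
    genes = io.read_genes(cfg.genes)
    cna_profile = io.read_cna(cfg.cna, call_threshold=cfg.amp_call_threshold)
    mutated = io.read_gene_list(cfg.mutated_list) if cfg.mutated_list else set()
    ambiguous = io.read_gene_list(cfg.ambiguous_list) if cfg.ambiguous_list else set()
    suppressors = io.read_gene_list(cfg.suppressor_list) if cfg.suppressor_list else set()

    result = run_pipeline(expr, samples, genes, cna_profile, cfg,
                          mutated=mutated, ambiguous=ambiguous, suppressors=suppressors)
    for name in ("expression", "samples", "genes", "cna"):
        result.manifest.input_checksums[name] = io.sha256_of(getattr(cfg, name))

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for st, tab in result.stage_de.tables.items():
        tab.to_csv(out / f"de_stage_{st}.tsv", sep="\t", index=False)
    (out / "de_intersections.json").write_text(
        json.dumps(result.stage_de.intersections, indent=2)
    )
    result.frequency.to_csv(out / "frequency.tsv", sep="\t", index_label="gene")
    result.eea.removal_table().to_csv(out / "eea_provenance.tsv", sep="\t", index=False)
    io.write_gene_list(result.eea.eea_genes, out / "eea_genes.txt")
    if result.profile is not None:
        result.profile.matrix.to_csv(out / "upregulation_profile.tsv", sep="\t",
                                     index_label="gene")
        result.clusters.labels.to_frame().to_csv(out / "clusters.tsv", sep="\t",
                                                 index_label="sample")
        result.clusters.mean_profiles.to_csv(out / "cluster_mean_profiles.tsv",
                                             sep="\t", index_label="gene")
        (out / "lineage.nwk").write_text(result.lineage.newick() + "\n")
        result.assignments.table.to_csv(out / "subset_assignments.tsv", sep="\t",
                                        index=False)
        io.write_gene_list(result.early_burst["inclusive"], out / "early_burst_genes.txt")
    if result.score_result is not None:
        result.score_result.scores.to_frame().to_csv(out / "scores.tsv", sep="\t",
                                                     index_label="sample")
        for g, curve in result.score_result.km_curves.items():
            curve.to_csv(out / f"km_{g}.tsv", sep="\t", index=False)
        (out / "logrank.json").write_text(json.dumps({
            "statistic": result.score_result.logrank_statistic,
            "p": result.score_result.logrank_p,
            "median_score": result.score_result.median_score,
        }, indent=2))
    (out / "manifest.json").write_text(result.manifest.to_json())
    return result
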