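"""Seeded synthetic staged-tumor cohorts with ground-truth planted signals.

The generator emulates the statistical structure the pipeline assumes:
log-normal expression (normal on the log2 scale, exponentiated), tumors in
three stages plus a pool of normals, four planted patient clusters, and
four classes of planted genes —

* ``early_burst``   upregulated in tumors of every cluster (the shared block
  that should survive all filters and land in the earliest cluster's call);
* ``late``          upregulated only in a subset of the later clusters,
  drawn from the nonzero subset vectors that exclude cluster 1, so the
  planted lineage has a well-defined earliest subpopulation;
* ``down``          downregulated across tumors;
* ``cna_driven``    upregulated exactly in carriers of a planted +2
  amplification call, grouped into dedicated cytobands so both the region
  screen and the per-gene concordance screens can find them;
* ``null``          everything else.

Survival times follow an exponential baseline with a log-linear effect of a
small hazard-gene panel and independent uniform censoring.  Everything is
reproducible from (config, seed); truth tables record each gene's planted
role and each tumor's planted cluster.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cna import CnaProfile
from .evolution import enumerate_subsets


class ConfigError(ValueError):
    """Invalid cohort configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.field = fieldname
        super().__init__(f"invalid CohortConfig.{fieldname}: {message}")


@dataclass
class SurvivalConfig:
    """Exponential-baseline survival with gene-linked log hazards."""

    baseline_hazard: float = 0.1
    hazard_coef: float = 0.7       # per-gene log-hazard on standardized log2 expr
    n_hazard_genes: int = 5        # drawn from the early-burst block
    censoring_rate: float = 0.3    # target fraction censored (uniform horizon)


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults mirror a small staged study."""

    n_normal: int = 50
    n_tumor_per_stage: tuple[int, int, int] = (50, 50, 50)
    n_genes: int = 2000
    n_early_burst: int = 83
    n_late: int = 120
    n_down: int = 100
    n_cna_driven: int = 40
    effect_log2: float = 2.0
    penetrance: float = 0.9
    noise_sd: float = 0.5
    n_clusters: int = 4
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0
    baseline_log2_range: tuple[float, float] = (4.0, 9.0)
    cna_background_rate: float = 0.05  # per-entry rate of ±1 noise calls
    genes_per_band: int = 25

    def validate(self) -> None:
        for name in ("n_normal", "n_genes", "n_early_burst", "n_late",
                     "n_down", "n_cna_driven", "n_clusters"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be non-negative")
        if any(n < 0 for n in self.n_tumor_per_stage):
            raise ConfigError("n_tumor_per_stage", "stage counts must be non-negative")
        planted = self.n_early_burst + self.n_late + self.n_down + self.n_cna_driven
        if planted > self.n_genes:
            raise ConfigError("n_genes", f"planted gene sets ({planted}) exceed n_genes")
        if not 0 <= self.penetrance <= 1:
            raise ConfigError("penetrance", "must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd", "must be positive")
        if self.n_late > 0 and self.n_clusters < 2:
            raise ConfigError("n_clusters", "late genes need at least 2 clusters")
        if not 0 <= self.survival.censoring_rate < 1:
            raise ConfigError("survival", "censoring_rate must lie in [0, 1)")
        if self.survival.baseline_hazard <= 0:
            raise ConfigError("survival", "baseline_hazard must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort: data tables plus the planted ground truth."""

    expression: pd.DataFrame     # genes x samples, linear scale, > 0
    cna: CnaProfile
    samples: pd.DataFrame        # sample, group, stage, cluster?, time, event
    genes: pd.DataFrame          # gene, chrom, start, end, cytoband
    gene_truth: pd.DataFrame     # gene, role, subset
    patient_truth: pd.DataFrame  # sample, cluster
    carriers: pd.DataFrame       # genes x tumors bool: planted shift present
    config: CohortConfig


def _censoring_horizon(lam: float, target: float) -> float:
    """Uniform-censoring horizon u with P(C < T) = target for T ~ Exp(lam)."""
    if target <= 0:
        return np.inf

    def frac_censored(u: float) -> float:
        return (1.0 - np.exp(-lam * u)) / (lam * u) - target

    lo, hi = 1e-9, 1e3 / lam
    return brentq(frac_censored, lo, hi)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; bit-identical for a fixed (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- samples -----------------------------------------------------------
    stages = ["I", "II", "III"]
    tumor_ids, stage_of = [], {}
    for st, n in zip(stages, cfg.n_tumor_per_stage):
        for i in range(n):
            sid = f"T{st}{i + 1:03d}"
            tumor_ids.append(sid)
            stage_of[sid] = st
    normal_ids = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    n_tumor = len(tumor_ids)
    samples_all = tumor_ids + normal_ids

    # planted clusters partition the tumors (balanced, shuffled)
    if cfg.n_clusters > 0 and n_tumor > 0:
        base = np.repeat(np.arange(cfg.n_clusters), -(-n_tumor // cfg.n_clusters))
        cluster_idx = base[:n_tumor]
        rng.shuffle(cluster_idx)
    else:
        cluster_idx = np.zeros(n_tumor, dtype=int)
    cluster_label = np.array([f"K{c + 1}" for c in cluster_idx])

    # --- gene roles ---------------------------------------------------------
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    roles = np.array(["null"] * cfg.n_genes, dtype=object)
    cursor = 0
    slices = {}
    for role, n in (("early_burst", cfg.n_early_burst), ("late", cfg.n_late),
                    ("down", cfg.n_down), ("cna_driven", cfg.n_cna_driven)):
        slices[role] = slice(cursor, cursor + n)
        roles[slices[role]] = role
        cursor += n

    # late genes get subset vectors over clusters 2..k (cluster 1 stays early)
    subset_of = np.array([""] * cfg.n_genes, dtype=object)
    if cfg.n_early_burst:
        subset_of[slices["early_burst"]] = "1" * cfg.n_clusters
    if cfg.n_late:
        later = [v for v in enumerate_subsets(cfg.n_clusters) if v[0] == 0]
        picks = rng.integers(0, len(later), size=cfg.n_late)
        subset_of[slices["late"]] = ["".join(map(str, later[p])) for p in picks]

    # --- expression on the log2 scale ---------------------------------------
    lo, hi = cfg.baseline_log2_range
    mu = rng.uniform(lo, hi, size=cfg.n_genes)
    log2x = mu[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples_all)))

    carrier = np.zeros((cfg.n_genes, n_tumor), dtype=bool)
    for gi in range(*slices["early_burst"].indices(cfg.n_genes)):
        carrier[gi] = rng.random(n_tumor) < cfg.penetrance
        log2x[gi, :n_tumor][carrier[gi]] += cfg.effect_log2
    for gi in range(*slices["late"].indices(cfg.n_genes)):
        in_subset = np.array([subset_of[gi][c] == "1" for c in cluster_idx])
        carrier[gi] = in_subset & (rng.random(n_tumor) < cfg.penetrance)
        log2x[gi, :n_tumor][carrier[gi]] += cfg.effect_log2
    for gi in range(*slices["down"].indices(cfg.n_genes)):
        carrier[gi] = rng.random(n_tumor) < cfg.penetrance
        log2x[gi, :n_tumor][carrier[gi]] -= cfg.effect_log2
    for gi in range(*slices["cna_driven"].indices(cfg.n_genes)):
        carrier[gi] = rng.random(n_tumor) < cfg.penetrance
        log2x[gi, :n_tumor][carrier[gi]] += cfg.effect_log2

    expression = pd.DataFrame(
        np.exp2(log2x), index=pd.Index(gene_ids, name="gene"), columns=samples_all
    )

    # --- CNA calls -----------------------------------------------------------
    calls = np.zeros((cfg.n_genes, n_tumor), dtype=int)
    noise = rng.random((cfg.n_genes, n_tumor))
    calls[noise < cfg.cna_background_rate / 2] = -1
    calls[(noise >= cfg.cna_background_rate / 2) & (noise < cfg.cna_background_rate)] = 1
    for gi in range(*slices["cna_driven"].indices(cfg.n_genes)):
        calls[gi][carrier[gi]] = 2
        calls[gi][~carrier[gi]] = 0  # planted genes: clean background
    cna = CnaProfile(
        calls=pd.DataFrame(calls, index=pd.Index(gene_ids, name="gene"), columns=tumor_ids)
    )

    # --- gene annotation: CNA-driven genes share dedicated cytobands --------
    chrom, band, start = [], [], []
    pos, band_i, chrom_i, in_band = 0, 1, 1, 0
    cna_band_i = 1
    for gi in range(cfg.n_genes):
        if roles[gi] == "cna_driven":
            local = gi - slices["cna_driven"].start
            chrom.append("8")
            band.append(f"8q{24 + local // cfg.genes_per_band}.1")
        else:
            if in_band >= cfg.genes_per_band:
                in_band = 0
                band_i += 1
                if band_i > 8:
                    band_i = 1
                    chrom_i += 1
            chrom.append(str(chrom_i))
            band.append(f"{chrom_i}q{band_i}1.{1 + (band_i % 3)}")
            in_band += 1
        start.append(pos * 10_000 + 1)
        pos += 1
    genes_df = pd.DataFrame(
        {
            "gene": gene_ids,
            "chrom": chrom,
            "start": start,
            "end": [s + 5_000 for s in start],
            "cytoband": band,
        }
    )

    # --- survival -------------------------------------------------------------
    sv = cfg.survival
    n_hz = min(sv.n_hazard_genes, cfg.n_early_burst)
    if n_hz > 0 and n_tumor > 0:
        hz = log2x[slices["early_burst"].start:slices["early_burst"].start + n_hz, :n_tumor]
        z = (hz - hz.mean(axis=1, keepdims=True)) / np.where(
            hz.std(axis=1, ddof=1, keepdims=True) == 0, 1.0, hz.std(axis=1, ddof=1, keepdims=True)
        )
        lp = sv.hazard_coef * z.mean(axis=0)
    else:
        lp = np.zeros(n_tumor)
    rate = sv.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate) if n_tumor else np.array([])
    if sv.censoring_rate > 0 and n_tumor:
        horizon = _censoring_horizon(sv.baseline_hazard, sv.censoring_rate)
        c_time = rng.uniform(0.0, horizon, size=n_tumor)
        time = np.minimum(t_event, c_time)
        event = (t_event <= c_time).astype(int)
    else:
        time, event = t_event, np.ones(n_tumor, dtype=int)

    samples_df = pd.DataFrame(
        {
            "sample": samples_all,
            "group": ["tumor"] * n_tumor + ["normal"] * cfg.n_normal,
            "stage": [stage_of[s] for s in tumor_ids] + [""] * cfg.n_normal,
            "er": "negative",
            "pr": "negative",
            "her2": "negative",
            "time": list(np.round(time, 6)) + [np.nan] * cfg.n_normal,
            "event": list(event) + [np.nan] * cfg.n_normal,
        }
    )

    gene_truth = pd.DataFrame({"gene": gene_ids, "role": roles, "subset": subset_of})
    patient_truth = pd.DataFrame({"sample": tumor_ids, "cluster": cluster_label})

    return SyntheticCohort(
        expression=expression,
        cna=cna,
        samples=samples_df,
        genes=genes_df,
        gene_truth=gene_truth,
        patient_truth=patient_truth,
        carriers=pd.DataFrame(carrier, index=pd.Index(gene_ids, name="gene"),
                              columns=tumor_ids),
        config=dataclasses.replace(cfg),
    )


def truth_report(cohort: SyntheticCohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(gene -> planted role, tumor -> planted cluster), one row each."""
    return cohort.gene_truth.copy(), cohort.patient_truth.copy()
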