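"""TSV readers/writers and cross-reference validation for pipeline inputs.

Formats (all tab-separated, UTF-8, header row):

* expression — first column ``gene``, remaining columns sample ids, linear
  non-negative values;
* samples — columns ``sample``, ``group`` (tumor|normal), ``stage`` and
  optional ``time``/``event`` survival columns;
* genes — columns ``gene``, ``chrom``, ``start``, ``end``, ``cytoband``
  (1-based inclusive coordinates);
* cna — same layout as expression with thresholded integer calls;
* gene lists — one gene per line, ``#`` comments and blank lines ignored.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import pandas as pd

from .cna import CnaProfile
from .synthetic import SyntheticCohort

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = {"sample", "group", "stage"}
GENE_COLUMNS = {"gene", "chrom", "start", "end", "cytoband"}


class FormatError(ValueError):
    """A malformed input file; message carries the path and offending ids."""


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.duplicated().any():
        dups = index[index.duplicated()].unique()[:5].tolist()
        raise FormatError(f"{path}: duplicated {what} ids {dups}")


def read_expression(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse expression TSV: {exc}") from exc
    df.index.name = "gene"
    _check_unique(df.index, "gene", path)
    _check_unique(df.columns, "sample", path)
    bad = df.columns[~df.apply(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise FormatError(f"{path}: non-numeric expression columns {bad[:5].tolist()}")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative expression values")
    return df


def read_samples(path: str | Path, expression: pd.DataFrame | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "stage": str})
    missing = SAMPLE_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing sample columns {sorted(missing)}")
    _check_unique(pd.Index(df["sample"]), "sample", path)
    bad_group = set(df["group"].unique()) - {"tumor", "normal"}
    if bad_group:
        raise FormatError(f"{path}: unknown group labels {sorted(bad_group)}")
    if expression is not None:
        unannotated = [s for s in expression.columns if s not in set(df["sample"])]
        if unannotated:
            raise FormatError(
                f"{path}: samples present in expression but missing annotations: "
                f"{unannotated[:10]}"
            )
    df["stage"] = df["stage"].fillna("")
    return df


def read_genes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "cytoband": str})
    missing = GENE_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gene annotation columns {sorted(missing)}")
    _check_unique(pd.Index(df["gene"]), "gene", path)
    return df


def read_cna(path: str | Path, call_threshold: int = 1) -> CnaProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    _check_unique(df.index, "gene", path)
    try:
        return CnaProfile(calls=df, call_threshold=call_threshold)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_gene_list(path: str | Path) -> set[str]:
    path = Path(path)
    genes: set[str] = set()
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.add(line)
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_cna(cna: CnaProfile, path: str | Path) -> None:
    cna.calls.to_csv(path, sep="\t", index_label="gene")


def write_gene_list(genes: set[str] | list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic cohort in the same formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "genes": outdir / "genes.tsv",
        "cna": outdir / "cna.tsv",
        "gene_truth": outdir / "truth_genes.tsv",
        "patient_truth": outdir / "truth_patients.tsv",
    }
    write_expression(cohort.expression, paths["expression"])
    write_samples(cohort.samples, paths["samples"])
    write_genes(cohort.genes, paths["genes"])
    write_cna(cohort.cna, paths["cna"])
    cohort.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    cohort.patient_truth.to_csv(paths["patient_truth"], sep="\t", index=False)
    return paths


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
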