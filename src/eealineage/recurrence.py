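"""Per-patient fold change, recurrence frequency and binary profiles.

Each tumor is compared individually against the pooled normal mean::

    log2FC(gene, patient) = log2( E_patient / mean(E_normal) )

A gene's recurrence frequency is the fraction of tumors whose per-patient
fold change clears the threshold; genes recurrent in at least ``min_freq``
of patients (default 70%) are the "frequent" set feeding the EEA filter.
Thresholding the per-patient matrix yields the binary upregulation profile
that the clustering and lineage stages consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEFAULT_LOG2FC_THRESHOLD

logger = logging.getLogger(__name__)

DEFAULT_MIN_FREQUENCY = 0.70


def per_patient_fc(
    expr: pd.DataFrame,
    tumor_ids: list[str],
    normal_ids: list[str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Gene x patient log2 fold change versus the pooled normal mean."""
    if len(normal_ids) == 0:
        raise ValueError("per_patient_fc requires a non-empty normal set")
    if len(tumor_ids) == 0:
        raise ValueError("per_patient_fc requires a non-empty tumor set")
    n_mean = expr[normal_ids].mean(axis=1).to_numpy() + pseudocount
    if (n_mean == 0).any():
        bad = expr.index[n_mean == 0][:5].tolist()
        raise ValueError(f"zero normal mean for genes {bad}; supply a positive pseudocount")
    vals = expr[tumor_ids].to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        pfc = np.log2(vals / n_mean[:, None])
    return pd.DataFrame(pfc, index=expr.index, columns=tumor_ids)


def upregulation_frequency(
    pfc: pd.DataFrame,
    up_thresh: float = DEFAULT_LOG2FC_THRESHOLD,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-gene fraction of patients beyond the fold-change cut.

    Returns a frame with columns ``up`` (fraction ≥ up_thresh) and ``down``
    (fraction ≤ -up_thresh).  ``strict=True`` switches to strict
    inequalities at the boundary.
    """
    if pfc.shape[1] == 0:
        raise ValueError("frequency undefined for an empty patient set")
    vals = pfc.to_numpy()
    if strict:
        up = (vals > up_thresh).mean(axis=1)
        down = (vals < -up_thresh).mean(axis=1)
    else:
        up = (vals >= up_thresh).mean(axis=1)
        down = (vals <= -up_thresh).mean(axis=1)
    return pd.DataFrame({"up": up, "down": down}, index=pfc.index)


def frequent_genes(
    freq: pd.Series | pd.DataFrame,
    min_freq: float = DEFAULT_MIN_FREQUENCY,
    direction: str = "up",
) -> set[str]:
    """Genes recurrent in at least ``min_freq`` of patients (inclusive)."""
    if not 0 < min_freq <= 1:
        raise ValueError("min_freq must lie in (0, 1]")
    s = freq[direction] if isinstance(freq, pd.DataFrame) else freq
    return set(s.index[s >= min_freq])


@dataclass
class UpregulationProfile:
    """Binary gene x patient upregulation matrix with its threshold."""

    matrix: pd.DataFrame  # int {0,1}, genes x patients
    threshold: float

    def __post_init__(self) -> None:
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("upregulation profile entries must be 0/1")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def patients(self) -> pd.Index:
        return self.matrix.columns

    def frequency(self) -> pd.Series:
        """Row means; equals upregulation_frequency()['up'] by construction."""
        return self.matrix.mean(axis=1)


def binarize_upregulation(
    pfc: pd.DataFrame,
    up_thresh: float = DEFAULT_LOG2FC_THRESHOLD,
    strict: bool = False,
) -> UpregulationProfile:
    """Threshold the per-patient fold-change matrix into a 0/1 profile."""
    vals = pfc.to_numpy()
    binary = (vals > up_thresh) if strict else (vals >= up_thresh)
    mat = pd.DataFrame(binary.astype(np.int8), index=pfc.index, columns=pfc.columns)
    return UpregulationProfile(matrix=mat, threshold=up_thresh)
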