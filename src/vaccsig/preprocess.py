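"""Gene filtering, fold-change tensor construction and ddCt quantification.

Filtering follows the bead-array screening convention: probes are removed
when they are never detected above background (detection p-value), never rise
above a minimal intensity, or never change expression beyond a 0.5- to 2-fold
window during treatment.  Fold changes are taken against each patient's
leukapheresis (pre-treatment) sample; patients lacking one fall back to the
per-gene mean reference of the patients that have one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    TIMEPOINTS,
    TREATMENT_TIMEPOINTS,
    ExpressionMatrix,
    FoldChangeTensor,
    SampleMeta,
)

__all__ = ["FilterConfig", "FilterResult", "filter_genes",
           "build_fold_changes", "delta_delta_ct"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the probe-screening step.

    detection_scope:
        "any"  -- keep a gene detected (p <= detection_p_max) in at least one
                  sample; drop only when every sample fails (permissive).
        "all"  -- require detection in every sample.
    The fold-change window is open: a fold change of exactly ``fc_low`` or
    ``fc_high`` rescues the gene.
    """

    intensity_cutoff: float = 20.0
    detection_p_max: float = 0.01
    fc_low: float = 0.5
    fc_high: float = 2.0
    detection_scope: str = "any"

    def __post_init__(self) -> None:
        if not (0 < self.fc_low < 1 < self.fc_high):
            raise ValueError("fold-change window must satisfy 0 < low < 1 < high")
        if self.intensity_cutoff < 0:
            raise ValueError("intensity cutoff must be >= 0")
        if self.detection_scope not in ("any", "all"):
            raise ValueError("detection_scope must be 'any' or 'all'")


@dataclass
class FilterResult:
    kept: list[str]
    dropped: list[str]
    reasons: dict[str, str]  # per dropped gene: intensity | detection_p | fc_window


def filter_genes(matrix: ExpressionMatrix, fc: FoldChangeTensor,
                 config: FilterConfig = FilterConfig()) -> FilterResult:
    """Partition genes into kept/dropped with a recorded drop reason.

    A gene is dropped iff it fails the intensity screen (below cutoff in
    every sample), the detection screen (see ``detection_scope``), or the
    fold-change screen (every available fold change strictly inside the
    (fc_low, fc_high) window).  Reasons record the first failing screen in
    that order.
    """
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    if list(matrix.gene_ids) != list(fc.gene_ids):
        raise ValueError("matrix and fold-change tensor gene ids differ")

    low_intensity = (matrix.intensities < config.intensity_cutoff).all(axis=1)

    if matrix.detection_p is None:
        undetected = np.zeros(matrix.n_genes, dtype=bool)
    else:
        fails = matrix.detection_p > config.detection_p_max
        undetected = fails.all(axis=1) if config.detection_scope == "any" \
            else fails.any(axis=1)

    vals = fc.values[:, fc.mask]  # (genes, available cells)
    inside = (vals > config.fc_low) & (vals < config.fc_high)
    flat = inside.all(axis=1) if vals.size else np.ones(fc.n_genes, dtype=bool)

    kept, dropped, reasons = [], [], {}
    for i, gene in enumerate(matrix.gene_ids):
        if low_intensity[i]:
            reasons[gene] = "intensity"
        elif undetected[i]:
            reasons[gene] = "detection_p"
        elif flat[i]:
            reasons[gene] = "fc_window"
        else:
            kept.append(gene)
            continue
        dropped.append(gene)
    return FilterResult(kept=kept, dropped=dropped, reasons=reasons)


def build_fold_changes(matrix: ExpressionMatrix,
                       meta: Sequence[SampleMeta]) -> FoldChangeTensor:
    """Construct the fold-change tensor g_{i,p}(t) from intensities.

    The per-patient reference is the leukapheresis sample; for patients
    without one, the per-gene unweighted mean of the other patients'
    reference intensities is imputed.  The availability mask is False where
    the (patient, timepoint) sample is absent.
    """
    metas = list(meta)
    known = {m.sample_id for m in metas}
    missing = [s for s in matrix.sample_ids if s not in known]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")

    patients = list(dict.fromkeys(m.patient_id for m in metas))
    sample_of = {(m.patient_id, m.timepoint): m.sample_id for m in metas
                 if m.sample_id in set(matrix.sample_ids)}
    col = {s: j for j, s in enumerate(matrix.sample_ids)}

    ref_cols = {p: col[sample_of[(p, "leukapheresis")]]
                for p in patients if (p, "leukapheresis") in sample_of}
    if not ref_cols:
        raise ValueError("no patient has a leukapheresis reference sample")

    ref_matrix = matrix.intensities[:, sorted(ref_cols.values())]
    zero_rows = np.argwhere((ref_matrix == 0).any(axis=1))
    if zero_rows.size:
        gene = matrix.gene_ids[int(zero_rows[0, 0])]
        raise ValueError(f"zero reference intensity for gene {gene!r}")
    imputed_ref = ref_matrix.mean(axis=1)  # per-gene mean over owning patients

    n_t = len(TREATMENT_TIMEPOINTS)
    values = np.full((matrix.n_genes, len(patients), n_t), np.nan)
    mask = np.zeros((len(patients), n_t), dtype=bool)
    for pi, p in enumerate(patients):
        if p in ref_cols:
            ref = matrix.intensities[:, ref_cols[p]]
        else:
            ref = imputed_ref
        for t, tp in enumerate(TREATMENT_TIMEPOINTS):
            sid = sample_of.get((p, tp))
            if sid is None:
                continue
            values[:, pi, t] = matrix.intensities[:, col[sid]] / ref
            mask[pi, t] = True
    return FoldChangeTensor(list(matrix.gene_ids), patients, values, mask)


def delta_delta_ct(ct_target_sample, ct_hk_sample,
                   ct_target_ref, ct_hk_ref):
    """Relative quantification by the ddCt (Livak) method.

    Returns ``2 ** -ddCt`` with
    ``ddCt = (ct_target_sample - ct_hk_sample) - (ct_target_ref - ct_hk_ref)``,
    where *hk* is the housekeeping (normalizer) gene.  Accepts scalars or
    broadcastable arrays of cycle-threshold values.
    """
    cts = [np.asarray(x, dtype=float)
           for x in (ct_target_sample, ct_hk_sample, ct_target_ref, ct_hk_ref)]
    for x in cts:
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite Ct value")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    result = 2.0 ** (-ddct)
    return float(result) if np.isscalar(ct_target_sample) or result.ndim == 0 \
        else result
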