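"""The nine per-gene time-course scores.

Given fold changes g_{i,p}(t) over the five treatment time points
(t = 1..5: four vaccinations plus the DTH evaluation) and a responder (R) /
non-responder (N) split of the patients, each gene receives:

* ``sim``        |mean_R g(1) - mean_N g(1)| -- group similarity at the first
                 vaccination (small = groups start alike).
* ``diff26``     Euclidean distance between the group-average time series over
                 all five points (large = trajectories diverge).
* ``tscoreR``,  ``tscoreN``   sum of sign(log g) over the group's available
                 cells at the last two time points; +k means consistently
                 up-regulated, -k consistently down, near 0 mixed.
* ``SignifR``, ``SignifN``    count of available group cells with g > 2 or
                 g < 0.5 (strict) over all time points -- significant moves.
* ``absFCR``, ``absFCN``      sum of |log g| over the group's available
                 cells; a magnitude-of-regulation score (log base matters for
                 its thresholds; natural log by default).
* ``NumSigPos``  number of responders with g > 2 at some time point.
* ``NumSigNeg``  -1 - (number of responders with g < 0.5 at some time point);
                 the sentinel -1 therefore means "no responder ever
                 significantly down-regulates".

All sums and means skip unavailable (masked) cells.  Genes whose data cannot
support a score (e.g. a group with no first-vaccination samples) receive NaN
for that score, never a silent zero.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .core import SCORE_FIELDS, FoldChangeTensor, GroupAssignment

__all__ = [
    "score_sim", "score_diff26", "score_tscore", "score_signif",
    "score_absfc", "score_numsigpos", "score_numsigneg", "score_all",
]

#: indices (0-based) of the last two time points (4th vaccination, DTH eval)
LATE_TIMEPOINTS = (3, 4)

_LOG_FNS = {"e": np.log, "2": np.log2, "10": np.log10,
            math.e: np.log, 2: np.log2, 10: np.log10}


def _log_fn(log_base):
    try:
        return _LOG_FNS[log_base]
    except (KeyError, TypeError):
        raise ValueError(f"unsupported log base {log_base!r}; use e, 2 or 10")


def _group_cells(values: np.ndarray, mask: np.ndarray,
                 idx: np.ndarray) -> np.ndarray:
    """Available values for the given patient indices, flattened (per gene)."""
    sub = values[..., idx, :]
    return sub[..., mask[idx, :]]


def _gene_slice(g_i: np.ndarray) -> np.ndarray:
    g_i = np.asarray(g_i, dtype=float)
    if g_i.ndim != 2:
        raise ValueError("per-gene slice must be (patients, timepoints)")
    return g_i


# --- single-gene scores ----------------------------------------------------
# These operate on one gene's (patients x timepoints) slice with NaN marking
# unavailable cells, plus index arrays for the two groups.  score_all below
# vectorizes the same definitions across all genes.

def score_sim(g_i: np.ndarray, r_idx: Iterable[int], n_idx: Iterable[int]) -> float:
    """Absolute difference of group means at the first vaccination."""
    g_i = _gene_slice(g_i)
    means = []
    for name, idx in (("R", list(r_idx)), ("N", list(n_idx))):
        x = g_i[idx, 0]
        x = x[~np.isnan(x)]
        if x.size == 0:
            raise ValueError(f"group {name} has no data at the first time point")
        means.append(x.mean())
    return float(abs(means[0] - means[1]))


def score_diff26(g_i: np.ndarray, r_idx: Iterable[int],
                 n_idx: Iterable[int]) -> float:
    """Euclidean distance between the group-average time series."""
    g_i = _gene_slice(g_i)
    series = []
    for name, idx in (("R", list(r_idx)), ("N", list(n_idx))):
        sub = g_i[idx, :]
        counts = (~np.isnan(sub)).sum(axis=0)
        if (counts == 0).any():
            t = int(np.argwhere(counts == 0)[0, 0]) + 1
            raise ValueError(f"group {name} has no data at time point {t}")
        series.append(np.nanmean(sub, axis=0))
    return float(np.sqrt(((series[0] - series[1]) ** 2).sum()))


def score_tscore(g_i: np.ndarray, group_idx: Iterable[int]) -> int:
    """Sum of fold-change signs over the last two time points (one group)."""
    g_i = _gene_slice(g_i)
    cells = g_i[np.asarray(list(group_idx), dtype=int)][:, LATE_TIMEPOINTS]
    cells = cells[~np.isnan(cells)]
    return int(np.sign(np.log(cells)).sum()) if cells.size else 0


def score_signif(g_i: np.ndarray, group_idx: Iterable[int]) -> int:
    """Count of significant fold changes (> 2 or < 0.5) in one group."""
    g_i = _gene_slice(g_i)
    cells = g_i[np.asarray(list(group_idx), dtype=int)]
    cells = cells[~np.isnan(cells)]
    return int(((cells > 2.0) | (cells < 0.5)).sum())


def score_absfc(g_i: np.ndarray, group_idx: Iterable[int],
                log_base="e") -> float:
    """Sum of absolute log fold changes in one group (regulation magnitude)."""
    log = _log_fn(log_base)
    g_i = _gene_slice(g_i)
    cells = g_i[np.asarray(list(group_idx), dtype=int)]
    cells = cells[~np.isnan(cells)]
    return float(np.abs(log(cells)).sum()) if cells.size else 0.0


def score_numsigpos(g_i: np.ndarray, r_idx: Iterable[int]) -> int:
    """Number of responders up-regulated > 2-fold at some time point."""
    g_i = _gene_slice(g_i)
    sub = g_i[np.asarray(list(r_idx), dtype=int)]
    with np.errstate(invalid="ignore"):
        return int((np.nan_to_num(sub, nan=1.0) > 2.0).any(axis=1).sum())


def score_numsigneg(g_i: np.ndarray, r_idx: Iterable[int]) -> int:
    """-1 - (number of responders down-regulated < 0.5-fold somewhere).

    Encoded so that -1 reads "no significant down-regulation in any responder",
    the sentinel the selection rules test for.
    """
    g_i = _gene_slice(g_i)
    sub = g_i[np.asarray(list(r_idx), dtype=int)]
    with np.errstate(invalid="ignore"):
        n_down = int((np.nan_to_num(sub, nan=1.0) < 0.5).any(axis=1).sum())
    return -1 - n_down


# --- full score table ------------------------------------------------------

def score_all(tensor: FoldChangeTensor, groups: GroupAssignment,
              log_base="e") -> pd.DataFrame:
    """Compute all nine scores for every gene (vectorized).

    Returns a DataFrame indexed by gene id with columns
    :data:`vaccsig.core.SCORE_FIELDS` plus ``availR``/``availN`` (available
    cell counts per group).  Scores whose precondition fails (a group with no
    data at a required time point) are NaN.
    """
    if tensor.n_genes == 0:
        raise ValueError("empty fold-change tensor")
    known = set(tensor.patient_ids)
    for label, grp in (("responders", groups.responders),
                       ("non-responders", groups.non_responders)):
        members = grp & known
        if not members:
            raise ValueError(f"no {label} present in the tensor")
    r_idx = tensor.patient_indices(groups.responders & known)
    n_idx = tensor.patient_indices(groups.non_responders & known)

    V, M = tensor.values, tensor.mask
    log = _log_fn(log_base)

    def group_mean_series(idx):
        sub = V[:, idx, :]
        m = M[idx, :]
        counts = m.sum(axis=0)  # available patients per timepoint
        with np.errstate(invalid="ignore"):
            sums = np.where(m, sub, 0.0).sum(axis=1)
        means = np.divide(sums, counts, out=np.full_like(sums, np.nan),
                          where=counts > 0)
        return means, counts  # (genes, timepoints), (timepoints,)

    mean_r, count_r = group_mean_series(r_idx)
    mean_n, count_n = group_mean_series(n_idx)

    n_genes = tensor.n_genes
    if count_r[0] > 0 and count_n[0] > 0:
        sim = np.abs(mean_r[:, 0] - mean_n[:, 0])
    else:
        sim = np.full(n_genes, np.nan)
    if (count_r > 0).all() and (count_n > 0).all():
        diff26 = np.sqrt(((mean_r - mean_n) ** 2).sum(axis=1))
    else:
        diff26 = np.full(n_genes, np.nan)

    def per_group(idx):
        cells = _group_cells(V, M, idx)  # (genes, n_avail)
        if cells.shape[1] == 0:
            return (np.zeros(n_genes, int), np.zeros(n_genes, int),
                    np.zeros(n_genes, float))
        signif = ((cells > 2.0) | (cells < 0.5)).sum(axis=1)
        absfc = np.abs(log(cells)).sum(axis=1)
        late = V[:, idx, :][:, :, LATE_TIMEPOINTS]
        late_m = M[idx, :][:, LATE_TIMEPOINTS]
        late_cells = late[:, late_m]
        tsc = (np.sign(np.log(late_cells)).sum(axis=1).astype(int)
               if late_cells.shape[1] else np.zeros(n_genes, int))
        return tsc, signif.astype(int), absfc

    tscore_r, signif_r, absfc_r = per_group(r_idx)
    tscore_n, signif_n, absfc_n = per_group(n_idx)

    sub_r = V[:, r_idx, :]
    m_r = M[r_idx, :]
    up = np.where(m_r, sub_r > 2.0, False).any(axis=2).sum(axis=1)
    down = np.where(m_r, sub_r < 0.5, False).any(axis=2).sum(axis=1)

    df = pd.DataFrame({
        "sim": sim,
        "diff26": diff26,
        "tscoreR": tscore_r,
        "tscoreN": tscore_n,
        "SignifR": signif_r,
        "SignifN": signif_n,
        "absFCR": absfc_r,
        "absFCN": absfc_n,
        "NumSigPos": up.astype(int),
        "NumSigNeg": (-1 - down).astype(int),
        "availR": int(M[r_idx, :].sum()),
        "availN": int(M[n_idx, :].sum()),
    }, index=pd.Index(tensor.gene_ids, name="gene"))
    df.attrs["log_base"] = str(log_base)
    return df[list(SCORE_FIELDS) + ["availR", "availN"]]
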