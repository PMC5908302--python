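"""ROC analysis with Youden-optimal cutoffs and exact Mann-Whitney tests.

The positive class is the responder group, with the fixed direction
"higher value predicts responder" (the screening selects genes overexpressed
in responders).  The AUC is computed by cross-group pair counting,
P(pos > neg) + 0.5 P(pos = neg), which equals the normalized Mann-Whitney U
statistic.  Candidate cutoffs are the midpoints between adjacent pooled
unique values plus the two infinite extremes; the reported operating point
maximizes Youden's J = sensitivity + specificity - 100 under the rule
"value >= cutoff predicts responder", with ties broken toward the smallest
cutoff.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

import numpy as np
from scipy import stats

from .core import FoldChangeTensor, GroupAssignment, RocResult

__all__ = ["mann_whitney", "roc_analysis", "roc_timecourse"]

#: largest number of relabelings enumerated for the tie-exact test
_MAX_ENUMERATION = 500_000


def mann_whitney(a, b, mode: str = "exact") -> float:
    """Two-sided Mann-Whitney p-value.

    ``mode='exact'``: the null distribution of U is evaluated exactly -- via
    the closed-form recursion for tie-free data, or by full enumeration of
    all C(n1+n2, n1) group labelings when ties are present (falling back to
    the tie-corrected normal approximation if enumeration would exceed
    5e5 labelings).  The two-sided p is 2 * min(tail), capped at 1.
    ``mode='approx'``: tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in ("exact", "approx"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "approx":
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if not has_ties:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="exact").pvalue)
    if comb(a.size + b.size, a.size) <= _MAX_ENUMERATION:
        return _exact_enumeration(a, b)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_enumeration(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided p by enumerating all group labelings (handles ties)."""
    pooled = np.concatenate([a, b])
    n = pooled.size
    n1 = a.size
    observed = _u_statistic(a, b)
    total = comb(n, n1)
    le = ge = 0
    for chosen in combinations(range(n), n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(chosen)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if u <= observed + 1e-12:
            le += 1
        if u >= observed - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def roc_analysis(values_pos, values_neg, p_mode: str | None = None) -> RocResult:
    """ROC summary for responder (positive) vs non-responder values.

    AUC by pair counting; the cutoff maximizes Youden's J over midpoints of
    adjacent pooled unique values plus the infinite extremes; sensitivity and
    specificity (percent) are achieved simultaneously at that cutoff; the
    p-value is the two-sided Mann-Whitney test (exact when both groups have
    <= 12 observations unless overridden via ``p_mode``).
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")

    auc = _u_statistic(pos, neg) / (pos.size * neg.size)

    uniq = np.unique(np.concatenate([pos, neg]))
    degenerate = uniq.size == 1
    candidates = [-inf] + list((uniq[:-1] + uniq[1:]) / 2.0) + [inf]
    best_cut, best_j, best_sens, best_spec = -inf, -np.inf, 0.0, 0.0
    for cut in candidates:
        sens = 100.0 * (pos >= cut).mean()
        spec = 100.0 * (neg < cut).mean()
        j = sens + spec - 100.0
        if j > best_j + 1e-12:
            best_cut, best_j, best_sens, best_spec = cut, j, sens, spec

    if p_mode is None:
        p_mode = "exact" if max(pos.size, neg.size) <= 12 else "approx"
    p = mann_whitney(pos, neg, mode=p_mode)
    return RocResult(auc=float(auc), cutoff=float(best_cut),
                     sensitivity=float(best_sens), specificity=float(best_spec),
                     p_value=float(p), degenerate=bool(degenerate))


def roc_timecourse(tensor: FoldChangeTensor, groups: GroupAssignment,
                   gene: str, timepoint: int) -> RocResult:
    """ROC analysis on per-patient fold changes of one gene at one time point.

    ``timepoint`` is 1-based (1..5 = first vaccination .. DTH evaluation).
    Raises when a group has no available sample at that time point, listing
    the patients whose samples are missing.
    """
    if not 1 <= timepoint <= 5:
        raise ValueError("timepoint must be in 1..5")
    gi = tensor.gene_index(gene)
    t = timepoint - 1
    values = {}
    for label, members in (("responders", groups.responders),
                           ("non_responders", groups.non_responders)):
        idx = tensor.patient_indices(members & set(tensor.patient_ids))
        avail = idx[tensor.mask[idx, t]]
        if avail.size == 0:
            missing = sorted(tensor.patient_ids[i] for i in idx)
            raise ValueError(
                f"no {label} samples at time point {timepoint} for gene "
                f"{gene!r}; missing patients: {missing}")
        values[label] = tensor.values[gi, avail, t]
    return roc_analysis(values["responders"], values["non_responders"])
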