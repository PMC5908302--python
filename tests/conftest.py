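"""Shared fixtures and independent reference (oracle) implementations.

The oracles here are deliberately naive -- straight Python loops over cells,
hand-rolled counting statistics -- so they stay independent of the vectorized
production code paths they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from vaccsig.core import FoldChangeTensor, GroupAssignment


# ---------------------------------------------------------------------------
# tensor construction helpers
# ---------------------------------------------------------------------------

def tensor_from_rows(r_rows, n_rows, gene_id="g1"):
    """Build a one-gene tensor from per-patient 5-value rows (NaN = missing)."""
    rows = [list(map(float, r)) for r in list(r_rows) + list(n_rows)]
    values = np.array(rows, dtype=float)[None, :, :]
    mask = ~np.isnan(values[0])
    r_ids = [f"R{i}" for i in range(len(r_rows))]
    n_ids = [f"N{i}" for i in range(len(n_rows))]
    tensor = FoldChangeTensor([gene_id], r_ids + n_ids, values, mask)
    return tensor, GroupAssignment(r_ids, n_ids)


def random_tensor(rng, n_genes=8, n_r=4, n_n=3, missing_frac=0.2):
    """Random positive tensor with a random availability mask (every patient
    keeps at least one cell, every timepoint keeps one patient per group)."""
    n_p = n_r + n_n
    values = np.exp(rng.normal(0, 0.7, size=(n_genes, n_p, 5)))
    while True:
        mask = rng.random((n_p, 5)) > missing_frac
        r_ok = mask[:n_r].any(axis=0).all()
        n_ok = mask[n_r:].any(axis=0).all()
        if r_ok and n_ok and mask.any(axis=1).all():
            break
    values[:, ~mask] = np.nan
    genes = [f"g{i}" for i in range(n_genes)]
    r_ids = [f"R{i}" for i in range(n_r)]
    n_ids = [f"N{i}" for i in range(n_n)]
    tensor = FoldChangeTensor(genes, r_ids + n_ids, values, mask)
    return tensor, GroupAssignment(r_ids, n_ids)


# ---------------------------------------------------------------------------
# naive scoring oracle (triple loop, no numpy vectorization)
# ---------------------------------------------------------------------------

def naive_score_all(tensor: FoldChangeTensor, groups: GroupAssignment,
                    log=math.log) -> pd.DataFrame:
    r_idx = [i for i, p in enumerate(tensor.patient_ids)
             if p in groups.responders]
    n_idx = [i for i, p in enumerate(tensor.patient_ids)
             if p in groups.non_responders]
    rows = {}
    for gi, gene in enumerate(tensor.gene_ids):
        def cells(idx, tps=range(5)):
            out = []
            for p in idx:
                for t in tps:
                    if tensor.mask[p, t]:
                        out.append(tensor.values[gi, p, t])
            return out

        def mean_at(idx, t):
            vals = [tensor.values[gi, p, t] for p in idx if tensor.mask[p, t]]
            return sum(vals) / len(vals) if vals else None

        m_r0, m_n0 = mean_at(r_idx, 0), mean_at(n_idx, 0)
        sim = abs(m_r0 - m_n0) if (m_r0 is not None and m_n0 is not None) \
            else float("nan")
        series = [(mean_at(r_idx, t), mean_at(n_idx, t)) for t in range(5)]
        if any(a is None or b is None for a, b in series):
            diff26 = float("nan")
        else:
            diff26 = math.sqrt(sum((a - b) ** 2 for a, b in series))

        def sign(x):
            return 0 if x == 0 else (1 if x > 0 else -1)

        tscore_r = sum(sign(math.log(v)) for v in cells(r_idx, (3, 4)))
        tscore_n = sum(sign(math.log(v)) for v in cells(n_idx, (3, 4)))
        signif_r = sum(1 for v in cells(r_idx) if v > 2 or v < 0.5)
        signif_n = sum(1 for v in cells(n_idx) if v > 2 or v < 0.5)
        absfc_r = sum(abs(log(v)) for v in cells(r_idx))
        absfc_n = sum(abs(log(v)) for v in cells(n_idx))
        num_pos = sum(1 for p in r_idx if any(
            tensor.mask[p, t] and tensor.values[gi, p, t] > 2 for t in range(5)))
        num_neg = -1 - sum(1 for p in r_idx if any(
            tensor.mask[p, t] and tensor.values[gi, p, t] < 0.5
            for t in range(5)))
        rows[gene] = dict(sim=sim, diff26=diff26, tscoreR=tscore_r,
                          tscoreN=tscore_n, SignifR=signif_r, SignifN=signif_n,
                          absFCR=absfc_r, absFCN=absfc_n, NumSigPos=num_pos,
                          NumSigNeg=num_neg)
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# independent log-rank statistic (for permutation oracles)
# ---------------------------------------------------------------------------

def naive_logrank_chi2(times, events, is_group_a, wilcoxon=False) -> float:
    """Two-group (weighted) log-rank chi-square by direct risk-set counting."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    a = np.asarray(is_group_a, dtype=bool)
    obs_minus_exp = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & a).sum()
        d = (events & (times == t)).sum()
        d_a = (events & (times == t) & a).sum()
        if n < 2:
            continue
        w = n if wilcoxon else 1.0
        expected = d * n_a / n
        var = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        obs_minus_exp += w * (d_a - expected)
        variance += w * w * var
    return obs_minus_exp ** 2 / variance if variance > 0 else 0.0


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def patient_records():
    from vaccsig import load_patient_table
    return load_patient_table()


@pytest.fixture(scope="session")
def classified_records(patient_records):
    from vaccsig import classify_clinical, classify_immunological
    return classify_clinical(classify_immunological(patient_records))
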