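"""Seeded simulator of cohorts, fold-change tensors and survival tables.

The generator emulates the statistical structure the screening pipeline
assumes: a small two-group cohort (7 responders, 5 non-responders by
default), five treatment time points relative to a pre-treatment reference,
multiplicative (log-normal) measurement noise on fold changes, an optional
missing-sample mask matching the study-like per-timepoint availability, and
"planted" signature genes constructed to match each of the five selection
archetypes.  Null genes carry pure noise: log g ~ Normal(0, noise_sd^2).

Planted genes of archetypes 1-3 have their first-timepoint noise centered
within each group (the group means of the available log fold changes are
exactly zero), expressing the archetype's premise that both groups start at
the same baseline; without centering the baseline-similarity score would be
dominated by sampling noise of the tiny cohort rather than by the planted
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .core import (
    TREATMENT_TIMEPOINTS,
    ExpressionMatrix,
    FoldChangeTensor,
    GroupAssignment,
    PatientRecord,
    SampleMeta,
)
from .scores import LATE_TIMEPOINTS
from .selection import SelectionResult, default_rules

__all__ = [
    "ARCHETYPES", "SimulationConfig", "SimulationTruth",
    "study_missing_pattern", "simulate_cohort", "simulate_expression",
    "simulate_survival", "evaluate_recovery",
]

#: archetype keys, matching the names of :func:`vaccsig.selection.default_rules`
ARCHETYPES = tuple(r.name for r in default_rules())


def _default_planted() -> dict[str, int]:
    return {name: 1 for name in ARCHETYPES}


@dataclass
class SimulationConfig:
    """Generator settings; identical seeds give bitwise-identical output.

    Effect sizes are natural-scale fold changes: ``up_fold`` drives the
    responder up-regulation of archetypes 2-5, ``divergence_fold`` the
    late divergence of archetype 1 (larger, so the group-mean Euclidean
    distance clears its threshold), ``down_fold`` the non-responder
    down-regulation of archetype 2, and ``flat_wobble`` (natural-log units)
    the small alternating non-responder wobble that archetype 3 uses to pin
    its sign-sum score at the -1 sentinel.
    """

    n_responders: int = 7
    n_non_responders: int = 5
    n_null_genes: int = 200
    planted: Mapping[str, int] = field(default_factory=_default_planted)
    noise_sd: float = 0.2
    up_fold: float = 4.0
    divergence_fold: float = 6.0
    down_fold: float = 0.6
    flat_wobble: float = 0.45
    missing_pattern: object = None  # None (complete), "study", or bool array
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_non_responders < 1:
            raise ValueError("both groups need at least one patient")
        if self.n_null_genes < 0:
            raise ValueError("n_null_genes must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.planted) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetype keys: {sorted(unknown)}; "
                             f"expected {list(ARCHETYPES)}")
        planted = {name: int(self.planted.get(name, 0)) for name in ARCHETYPES}
        if any(v < 0 for v in planted.values()):
            raise ValueError("planted counts must be >= 0")
        object.__setattr__(self, "planted", planted)
        if planted["up_in_6_of_7_responders"] and self.n_responders < 6:
            raise ValueError(
                "archetype 'up_in_6_of_7_responders' needs >= 6 responders")
        if planted["up_in_5_of_7_responders"] and self.n_responders < 5:
            raise ValueError(
                "archetype 'up_in_5_of_7_responders' needs >= 5 responders")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    planted: dict[str, list[str]]
    null_gene_ids: list[str]
    groups: GroupAssignment
    config: SimulationConfig


def study_missing_pattern(n_responders: int = 7,
                          n_non_responders: int = 5) -> np.ndarray:
    """Availability mask reproducing the study-like per-timepoint counts.

    Responders: 5 of 7 at each vaccination, 6 of 7 at the DTH evaluation;
    non-responders: 3, 4, 1, 2, 1 across the five time points.  Only defined
    for the default 7+5 cohort.
    """
    if (n_responders, n_non_responders) != (7, 5):
        raise ValueError("the study-like pattern is defined for a 7+5 cohort")
    mask = np.zeros((12, 5), dtype=bool)
    # responders R1..R7 (rows 0..6)
    mask[0:5, 0:4] = True              # R1-R5 at vac1-vac4
    mask[[0, 1, 2, 3, 5, 6], 4] = True  # R1-R4, R6, R7 at DTH evaluation
    # non-responders N1..N5 (rows 7..11)
    mask[[7, 8, 9], 0] = True           # vac1: n=3
    mask[[7, 8, 9, 10], 1] = True       # vac2: n=4
    mask[11, 2] = True                  # vac3: n=1
    mask[[7, 8], 3] = True              # vac4: n=2
    mask[10, 4] = True                  # DTH evaluation: n=1
    return mask


def _resolve_mask(config: SimulationConfig) -> np.ndarray:
    n_p = config.n_responders + config.n_non_responders
    if config.missing_pattern is None:
        return np.ones((n_p, 5), dtype=bool)
    if isinstance(config.missing_pattern, str):
        if config.missing_pattern != "study":
            raise ValueError(
                f"unknown missing pattern {config.missing_pattern!r}")
        return study_missing_pattern(config.n_responders,
                                     config.n_non_responders)
    mask = np.asarray(config.missing_pattern, dtype=bool)
    if mask.shape != (n_p, 5):
        raise ValueError(f"missing pattern shape {mask.shape} != {(n_p, 5)}")
    return mask


def simulate_cohort(config: SimulationConfig
                    ) -> tuple[FoldChangeTensor, GroupAssignment, SimulationTruth]:
    """Generate a fold-change tensor with planted archetype genes."""
    rng = np.random.default_rng(config.seed)
    n_r, n_n = config.n_responders, config.n_non_responders
    r_ids = [f"R{i + 1:02d}" for i in range(n_r)]
    n_ids = [f"N{i + 1:02d}" for i in range(n_n)]
    patients = r_ids + n_ids
    r_rows = np.arange(n_r)
    n_rows = np.arange(n_r, n_r + n_n)
    mask = _resolve_mask(config)

    gene_ids: list[str] = []
    planted: dict[str, list[str]] = {}
    for k, name in enumerate(ARCHETYPES, start=1):
        ids = [f"sig{k}_{j + 1:02d}" for j in range(config.planted[name])]
        planted[name] = ids
        gene_ids.extend(ids)
    null_ids = [f"null_{j + 1:04d}" for j in range(config.n_null_genes)]
    gene_ids.extend(null_ids)
    if not gene_ids:
        raise ValueError("configuration generates no genes")

    log_v = rng.normal(0.0, config.noise_sd, size=(len(gene_ids), n_r + n_n, 5))

    def center_baseline(row: int) -> None:
        # zero the group means of available first-timepoint noise
        for rows in (r_rows, n_rows):
            avail = rows[mask[rows, 0]]
            if avail.size:
                log_v[row, avail, 0] -= log_v[row, avail, 0].mean()

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    late = list(LATE_TIMEPOINTS)

    for g in planted["similar_start_diverging"]:
        row = gene_row[g]
        center_baseline(row)
        log_v[row, r_rows[:, None], late] += math.log(config.divergence_fold)

    for g in planted["up_in_R_down_in_N"]:
        row = gene_row[g]
        center_baseline(row)
        log_v[row, r_rows[:, None], late] += math.log(config.up_fold)
        log_v[row, n_rows[:, None], late] += math.log(config.down_fold)

    for g in planted["up_in_R_flat_in_N"]:
        row = gene_row[g]
        center_baseline(row)
        log_v[row, r_rows[:, None], late] += math.log(config.up_fold)
        # alternating wobble on the available late non-responder cells, one
        # more down than up, so the sign sum lands on -1 (odd availability)
        cells = [(p, t) for p in n_rows for t in late if mask[p, t]]
        n_down = len(cells) // 2 + 1 if cells else 0
        for j, (p, t) in enumerate(cells):
            sign = -1.0 if j < n_down else 1.0
            log_v[row, p, t] += sign * config.flat_wobble

    for name, n_up in (("up_in_6_of_7_responders", 6),
                       ("up_in_5_of_7_responders", 5)):
        for g in planted[name]:
            row = gene_row[g]
            for p in r_rows[:n_up]:
                cells = [t for t in late if mask[p, t]]
                if not cells:
                    cells = [t for t in range(5) if mask[p, t]]
                for t in cells:
                    log_v[row, p, t] += math.log(config.up_fold)

    values = np.exp(log_v)
    values[:, ~mask] = np.nan
    tensor = FoldChangeTensor(gene_ids, patients, values, mask)
    groups = GroupAssignment(r_ids, n_ids)
    truth = SimulationTruth(planted=planted, null_gene_ids=null_ids,
                            groups=groups, config=config)
    return tensor, groups, truth


def simulate_expression(config: SimulationConfig
                        ) -> tuple[ExpressionMatrix, list[SampleMeta],
                                   GroupAssignment, SimulationTruth]:
    """Wrap a simulated cohort into a bead-array style intensity matrix.

    Every patient gets a leukapheresis reference sample (intensity equal to
    the gene's baseline) plus one sample per available treatment time point
    (baseline times the fold change), so the fold-change construction in
    :func:`vaccsig.preprocess.build_fold_changes` round-trips the simulated
    tensor.  Detection p-values are uniformly below threshold (all probes
    detected).
    """
    tensor, groups, truth = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    baseline = np.exp(rng.normal(math.log(300.0), 0.8, size=tensor.n_genes))

    sample_ids: list[str] = []
    metas: list[SampleMeta] = []
    columns: list[np.ndarray] = []
    for pi, patient in enumerate(tensor.patient_ids):
        sid = f"{patient}_leukapheresis"
        sample_ids.append(sid)
        metas.append(SampleMeta(sid, patient, "leukapheresis"))
        columns.append(baseline.copy())
        for t, tp in enumerate(TREATMENT_TIMEPOINTS):
            if not tensor.mask[pi, t]:
                continue
            sid = f"{patient}_{tp}"
            sample_ids.append(sid)
            metas.append(SampleMeta(sid, patient, tp))
            columns.append(baseline * tensor.values[:, pi, t])
    intensities = np.column_stack(columns)
    detection_p = np.full_like(intensities, 0.001)
    matrix = ExpressionMatrix(list(tensor.gene_ids), sample_ids, intensities,
                              detection_p)
    return matrix, metas, groups, truth


def simulate_survival(groups: GroupAssignment, median_r: float,
                      median_n: float, censor_frac: float = 0.0,
                      seed: int = 0) -> list[PatientRecord]:
    """Exponential survival times with the stated group medians.

    Each patient is censored with probability ``censor_frac``; a censored
    patient's follow-up time is uniform on (0, T) where T is the latent
    event time.
    """
    if not (median_r > 0 and median_n > 0):
        raise ValueError("group medians must be positive")
    if not (0 <= censor_frac < 1):
        raise ValueError("censor_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    records = []
    for ids, median, dth in ((sorted(groups.responders), median_r, "positive"),
                             (sorted(groups.non_responders), median_n,
                              "negative")):
        scale = median / math.log(2.0)
        for pid in ids:
            t = rng.exponential(scale)
            died = True
            if censor_frac > 0 and rng.random() < censor_frac:
                died = False
                t *= rng.uniform(0.0, 1.0)
            records.append(PatientRecord(
                patient_id=pid, gender="NA", ajcc_stage="IV", dth=dth,
                survival_months=max(t, 1e-9), died=died))
    return records


def evaluate_recovery(selection: SelectionResult, truth: SimulationTruth
                      ) -> dict[str, object]:
    """Sensitivity / specificity of a selection run against generator truth.

    Per archetype: ``union`` sensitivity counts a planted gene as recovered
    when it appears anywhere in the selection union; ``self`` sensitivity
    requires it to match its own archetype's rule.  The null selection rate
    is the fraction of pure-noise genes appearing in the union.
    """
    union = set(selection.union)
    per_rule_union, per_rule_self = {}, {}
    for name, ids in truth.planted.items():
        if not ids:
            continue
        own = set(selection.per_rule.get(name, []))
        per_rule_union[name] = sum(g in union for g in ids) / len(ids)
        per_rule_self[name] = sum(g in own for g in ids) / len(ids)
    n_null = len(truth.null_gene_ids)
    null_rate = (sum(g in union for g in truth.null_gene_ids) / n_null
                 if n_null else 0.0)
    return {"union_sensitivity": per_rule_union,
            "self_sensitivity": per_rule_self,
            "null_selection_rate": null_rate}
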