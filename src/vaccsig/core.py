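"""Shared domain types, tabular readers/writers and the packaged patient table.

The data model mirrors a small dendritic-cell vaccine trial in advanced
melanoma: each patient contributes a pre-treatment reference blood sample
(taken at leukapheresis) plus up to five treatment samples (before each of
four vaccine doses and at the delayed-type-hypersensitivity evaluation one
month after the last dose).  Expression is measured on a bead-array style
gene x sample intensity matrix with per-probe detection p-values, and the
whole downstream analysis runs on per-gene fold changes relative to the
reference sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TIMEPOINTS",
    "TREATMENT_TIMEPOINTS",
    "ExpressionMatrix",
    "SampleMeta",
    "PatientRecord",
    "FoldChangeTensor",
    "GroupAssignment",
    "SCORE_FIELDS",
    "SelectionRule",
    "RocResult",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_meta",
    "write_sample_meta",
    "load_patient_table",
    "microarray_patient_ids",
    "read_fold_change_tensor",
    "write_fold_change_tensor",
    "read_group_assignment",
    "write_group_assignment",
]

#: Sample schedule: the reference plus the five treatment time points.
TIMEPOINTS = ("leukapheresis", "vac1", "vac2", "vac3", "vac4", "dth_eval")

#: The five post-reference time points, indexed t = 1..5 throughout.
TREATMENT_TIMEPOINTS = TIMEPOINTS[1:]

_DTH_CODES = {"+": "positive", "-": "negative", "NT": "not_tested",
              "positive": "positive", "negative": "negative",
              "not_tested": "not_tested"}

_STAGES = ("IIIA", "IIIB", "IIIC", "IV")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with optional detection p-values.

    ``intensities`` holds non-negative fluorescence values with shape
    ``(len(gene_ids), len(sample_ids))``; ``detection_p`` (same shape, or
    None) holds per-probe probabilities that the signal is background.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    detection_p: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if np.any(self.intensities < 0):
            g, s = np.argwhere(self.intensities < 0)[0]
            raise ValueError(
                f"negative intensity for gene {self.gene_ids[g]!r} in sample "
                f"{self.sample_ids[s]!r}"
            )
        if self.detection_p is not None:
            self.detection_p = np.asarray(self.detection_p, dtype=float)
            if self.detection_p.shape != self.intensities.shape:
                raise ValueError("detection_p shape does not match intensities")
            if np.any((self.detection_p < 0) | (self.detection_p > 1)):
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)


@dataclass(frozen=True)
class SampleMeta:
    """Maps one array column to a (patient, time point) slot."""

    sample_id: str
    patient_id: str
    timepoint: str

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"unknown timepoint {self.timepoint!r} for sample "
                f"{self.sample_id!r}; expected one of {TIMEPOINTS}"
            )


@dataclass
class PatientRecord:
    """One trial patient: demographics, DTH outcome and survival follow-up.

    ``dth`` is the delayed-type-hypersensitivity skin-test result against the
    vaccine lysate ("positive" means induration/erythema >= 5 mm); patients
    who died before the test could be performed carry "not_tested".
    ``immunological_group`` and ``clinical_group`` are derived labels set by
    :mod:`vaccsig.survival` classifiers.
    """

    patient_id: str
    gender: str
    ajcc_stage: str
    dth: str
    survival_months: float
    died: bool
    microarray: bool = False
    immunological_group: str | None = None
    clinical_group: str | None = None

    def __post_init__(self) -> None:
        if self.dth not in ("positive", "negative", "not_tested"):
            raise ValueError(
                f"unknown DTH symbol {self.dth!r} for patient {self.patient_id!r}"
            )
        if self.ajcc_stage not in _STAGES:
            raise ValueError(
                f"unknown AJCC stage {self.ajcc_stage!r} for patient "
                f"{self.patient_id!r}"
            )
        if not self.survival_months > 0:
            raise ValueError(
                f"non-positive survival ({self.survival_months}) for patient "
                f"{self.patient_id!r}"
            )


@dataclass
class FoldChangeTensor:
    """Per-gene, per-patient, per-time fold changes vs the reference sample.

    ``values[i, p, t]`` is gene i's intensity in patient p's sample at
    treatment time point t (t = 0..4 meaning vac1..dth_eval) divided by that
    patient's reference intensity.  ``mask[p, t]`` is False where the sample
    was never collected; ``values`` is NaN there.
    """

    gene_ids: list[str]
    patient_ids: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.patient_ids = list(self.patient_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_t = len(TREATMENT_TIMEPOINTS)
        expected = (len(self.gene_ids), len(self.patient_ids), n_t)
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != expected {expected}"
            )
        if self.mask.shape != (len(self.patient_ids), n_t):
            raise ValueError(
                f"mask shape {self.mask.shape} != expected "
                f"{(len(self.patient_ids), n_t)}"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.patient_ids, "patient id")
        avail = self.values[:, self.mask]
        if avail.size and not np.all(avail > 0):
            raise ValueError("fold changes must be positive where available")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def patient_indices(self, patient_ids: Iterable[str]) -> np.ndarray:
        order = {p: i for i, p in enumerate(self.patient_ids)}
        return np.array(sorted(order[p] for p in patient_ids), dtype=int)


@dataclass(frozen=True)
class GroupAssignment:
    """Disjoint responder (R) / non-responder (N) patient id sets."""

    responders: frozenset[str]
    non_responders: frozenset[str]

    def __init__(self, responders: Iterable[str], non_responders: Iterable[str]):
        object.__setattr__(self, "responders", frozenset(responders))
        object.__setattr__(self, "non_responders", frozenset(non_responders))
        if self.responders & self.non_responders:
            overlap = sorted(self.responders & self.non_responders)
            raise ValueError(f"patients in both groups: {overlap}")
        if not self.responders or not self.non_responders:
            raise ValueError("both groups must be non-empty")


#: The nine per-gene time-course scores, in canonical column order.
SCORE_FIELDS = (
    "sim", "diff26", "tscoreR", "tscoreN", "SignifR", "SignifN",
    "absFCR", "absFCN", "NumSigPos", "NumSigNeg",
)

_COMPARATORS = ("<", ">", "=", ">=", "<=")


@dataclass(frozen=True)
class SelectionRule:
    """Conjunction of threshold predicates over score-table columns."""

    name: str
    predicates: tuple[tuple[str, str, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicates", tuple(
            (str(f), str(op), float(th)) for f, op, th in self.predicates
        ))
        for fld, op, th in self.predicates:
            if op not in _COMPARATORS:
                raise ValueError(f"unknown comparator {op!r} in rule {self.name!r}")
            if not np.isfinite(th):
                raise ValueError(f"non-finite threshold in rule {self.name!r}")


@dataclass(frozen=True)
class RocResult:
    """ROC summary at the Youden-optimal operating point.

    ``sensitivity``/``specificity`` are percentages achieved simultaneously
    at ``cutoff`` under the convention "value >= cutoff predicts responder".
    ``degenerate`` flags constant pooled input (AUC pinned at 0.5).
    """

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    p_value: float
    degenerate: bool = False

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 100.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)


def read_expression_matrix(path: str | Path,
                           detection_path: str | Path | None = None
                           ) -> ExpressionMatrix:
    """Read a tab-separated intensity matrix (genes in rows, header of sample
    ids, first column gene id), optionally paired with a detection-p file of
    identical layout."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    df = _read_matrix_tsv(path)
    detection = None
    if detection_path is not None:
        dp = _read_matrix_tsv(Path(detection_path))
        if list(dp.index) != list(df.index) or list(dp.columns) != list(df.columns):
            raise ValueError(
                "detection-p file layout does not match the intensity file"
            )
        detection = dp.to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        intensities=df.to_numpy(dtype=float),
        detection_p=detection,
    )


def _read_matrix_tsv(path: Path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"empty matrix file: {path}")
    header = rows[0]
    n_cols = len(header)
    ids, data = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}: ragged row at line {lineno} "
                f"({len(row)} fields, expected {n_cols})"
            )
        ids.append(row[0])
        try:
            data.append([float(x) for x in row[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value at line {lineno}: {exc}")
    _check_unique(ids, "gene id")
    return pd.DataFrame(data, index=ids, columns=header[1:])


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            detection_path: str | Path | None = None) -> None:
    df = pd.DataFrame(matrix.intensities, index=matrix.gene_ids,
                      columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="gene_id")
    if detection_path is not None:
        if matrix.detection_p is None:
            raise ValueError("matrix has no detection p-values to write")
        pd.DataFrame(matrix.detection_p, index=matrix.gene_ids,
                     columns=matrix.sample_ids).to_csv(
            detection_path, sep="\t", index_label="gene_id")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata CSV with columns sample_id, patient_id, timepoint."""
    df = pd.read_csv(path, dtype=str)
    required = {"sample_id", "patient_id", "timepoint"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    metas = [SampleMeta(r.sample_id, r.patient_id, r.timepoint)
             for r in df.itertuples()]
    slots = [(m.patient_id, m.timepoint) for m in metas]
    if len(slots) != len(set(slots)):
        dup = next(s for s in slots if slots.count(s) > 1)
        raise ValueError(f"more than one sample for patient/timepoint {dup}")
    _check_unique([m.sample_id for m in metas], "sample id")
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame([(m.sample_id, m.patient_id, m.timepoint) for m in metas],
                 columns=["sample_id", "patient_id", "timepoint"]
                 ).to_csv(path, index=False)


def load_patient_table(path: str | Path | None = None) -> list[PatientRecord]:
    """Load the clinical patient table (defaults to the packaged 28-patient
    cohort transcribed from the trial's clinical-characteristics table).

    Expected CSV columns: patient_id, gender, ajcc_stage, dth (one of
    ``+``/``-``/``NT`` or the spelled-out labels), survival_months (positive,
    fractional months), died (0/1 boolean), optional microarray (0/1).
    """
    if path is None:
        ref = resources.files("vaccsig").joinpath("data/patients.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str)
    records = []
    for r in df.itertuples():
        dth = _DTH_CODES.get(str(r.dth).strip())
        if dth is None:
            raise ValueError(
                f"unknown DTH symbol {r.dth!r} for patient {r.patient_id!r}"
            )
        records.append(PatientRecord(
            patient_id=str(r.patient_id),
            gender=str(r.gender),
            ajcc_stage=str(r.ajcc_stage),
            dth=dth,
            survival_months=float(r.survival_months),
            died=_parse_bool(r.died),
            microarray=_parse_bool(getattr(r, "microarray", "0")),
        ))
    _check_unique([r.patient_id for r in records], "patient id")
    return records


def _parse_bool(x) -> bool:
    s = str(x).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot parse boolean value {x!r}")


def microarray_patient_ids(records: Iterable[PatientRecord]) -> set[str]:
    """Patient ids profiled on the expression arrays (flagged in the table)."""
    return {r.patient_id for r in records if r.microarray}


def write_fold_change_tensor(tensor: FoldChangeTensor, path: str | Path) -> None:
    """Write a tensor as long TSV: gene, patient, timepoint, value (available
    cells only)."""
    rows = []
    for g, gene in enumerate(tensor.gene_ids):
        for p, patient in enumerate(tensor.patient_ids):
            for t, tp in enumerate(TREATMENT_TIMEPOINTS):
                if tensor.mask[p, t]:
                    rows.append((gene, patient, tp, tensor.values[g, p, t]))
    pd.DataFrame(rows, columns=["gene", "patient", "timepoint", "value"]
                 ).to_csv(path, sep="\t", index=False)


def read_fold_change_tensor(path: str | Path) -> FoldChangeTensor:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "patient": str,
                                            "timepoint": str})
    genes = list(dict.fromkeys(df["gene"]))
    patients = list(dict.fromkeys(df["patient"]))
    tp_idx = {tp: i for i, tp in enumerate(TREATMENT_TIMEPOINTS)}
    g_idx = {g: i for i, g in enumerate(genes)}
    p_idx = {p: i for i, p in enumerate(patients)}
    n_t = len(TREATMENT_TIMEPOINTS)
    values = np.full((len(genes), len(patients), n_t), np.nan)
    filled = np.zeros((len(genes), len(patients), n_t), dtype=bool)
    for r in df.itertuples():
        if r.timepoint not in tp_idx:
            raise ValueError(f"unknown timepoint {r.timepoint!r} in {path}")
        values[g_idx[r.gene], p_idx[r.patient], tp_idx[r.timepoint]] = r.value
        filled[g_idx[r.gene], p_idx[r.patient], tp_idx[r.timepoint]] = True
    # a (patient, timepoint) cell is available iff present for every gene
    mask = filled.all(axis=0)
    if filled.any(axis=0)[~mask].any():
        raise ValueError(f"{path}: cells present for some genes but not others")
    return FoldChangeTensor(genes, patients, values, mask)


def read_group_assignment(path: str | Path) -> GroupAssignment:
    """Read a CSV with columns patient_id, group (responder/non_responder)."""
    df = pd.read_csv(path, dtype=str)
    if not {"patient_id", "group"}.issubset(df.columns):
        raise ValueError("group file must have columns patient_id, group")
    r = set(df.loc[df["group"] == "responder", "patient_id"])
    n = set(df.loc[df["group"] == "non_responder", "patient_id"])
    unknown = set(df["group"]) - {"responder", "non_responder"}
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    return GroupAssignment(r, n)


def write_group_assignment(groups: GroupAssignment, path: str | Path) -> None:
    rows = [(p, "responder") for p in sorted(groups.responders)]
    rows += [(p, "non_responder") for p in sorted(groups.non_responders)]
    pd.DataFrame(rows, columns=["patient_id", "group"]).to_csv(path, index=False)
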