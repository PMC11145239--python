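"""Cohort containers and readers.

The analysis consumes three tab-separated tables:

* a raw count matrix (genes as rows, samples as columns, header = sample ids),
* a clinical table (patient_id, os_days, event, age, rcbv_hat_median with an
  empty cell meaning "no MRI perfusion data"),
* a gene annotation table (gene_id, free-text description).

Patients are partitioned into vascularity groups from the median relative
cerebral blood volume of the high-angiogenic tumor habitat (rCBV_HAT):
values above a threshold (default 7) define the High Vascularity (HV) group,
values at or below it the Moderate Vascularity (MV) group, and patients
without MRI data form the unknown-vascularity (-V) group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

GROUP_HV = "HV"
GROUP_MV = "MV"
GROUP_UNKNOWN = "-V"


@dataclass
class CountMatrix:
    """Nonnegative integer gene x sample counts with per-sample library sizes.

    ``library_size`` is the column sum over the *full* gene set present at
    construction time; it is carried along unchanged when genes are later
    filtered, because CPM normalization is always relative to the total
    sequencing depth of the sample, not to whichever gene subset survives
    filtering.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer
    library_size: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = _duplicates(self.gene_ids)
            raise DataError(f"duplicate gene ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise DataError(f"duplicate sample ids: {dupes[:5]}")
        if self.counts.size and self.counts.min() < 0:
            g, s = np.argwhere(self.counts < 0)[0]
            raise DataError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded):
                raise DataError("counts must be integers")
            self.counts = rounded.astype(np.int64)
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_size = np.asarray(self.library_size)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        """Return a new matrix restricted to ``gene_ids``; library sizes kept."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise DataError(f"unknown gene ids: {missing[:5]}")
        rows = [index[g] for g in gene_ids]
        return CountMatrix(
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            counts=self.counts[rows],
            library_size=self.library_size.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise DataError(f"unknown sample ids: {missing[:5]}")
        cols = [index[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, cols],
            library_size=self.library_size[cols],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)
        df.index.name = "gene_id"
        return df


@dataclass
class PatientRecord:
    """Clinical covariates for one patient/sample.

    ``vascular_group`` is derived (see :func:`assign_vascular_groups`) and is
    ``-V`` exactly when ``rcbv_hat_median`` is missing (NaN).
    """

    patient_id: str
    os_days: float = math.nan  # overall survival, days
    event: float = math.nan  # 1 = death observed, 0 = censored
    age: float = math.nan  # years
    rcbv_hat_median: float = math.nan
    vascular_group: str | None = None

    @property
    def survival_valid(self) -> bool:
        """True when the record can enter survival estimation."""
        return (
            not math.isnan(self.os_days)
            and not math.isnan(self.event)
            and self.os_days >= 0
            and self.event in (0.0, 1.0)
        )

    @property
    def has_rcbv(self) -> bool:
        return not math.isnan(self.rcbv_hat_median)


@dataclass
class Cohort:
    counts: CountMatrix
    patients: list[PatientRecord]
    annotation: dict[str, str]

    def __post_init__(self) -> None:
        by_id = {p.patient_id for p in self.patients}
        if len(by_id) != len(self.patients):
            raise DataError("duplicate patient ids in clinical table")
        unmatched = [s for s in self.counts.sample_ids if s not in by_id]
        if unmatched:
            raise DataError(
                f"count-matrix samples without a clinical record: {unmatched[:5]}"
            )

    @property
    def n_samples(self) -> int:
        return self.counts.n_samples

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def patients_by_group(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {GROUP_HV: [], GROUP_MV: [], GROUP_UNKNOWN: []}
        for p in self.patients:
            if p.vascular_group is not None:
                out[p.vascular_group].append(p.patient_id)
        return out


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


def _read_counts(path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene_ids = [str(g) for g in df.index]
    dupes = _duplicates(gene_ids)
    if dupes:
        raise DataError(f"duplicated gene row(s) in {path}: {dupes[:5]}")
    sample_ids = [str(c) for c in df.columns]
    col_dupes = _duplicates(sample_ids)
    if col_dupes:
        # more than one aliquot per patient: keep the first, deterministically
        logger.warning(
            "duplicate sample columns %s in %s; keeping first occurrence",
            col_dupes[:5],
            path,
        )
        keep_idx, seen = [], set()
        for i, s in enumerate(sample_ids):
            if s not in seen:
                keep_idx.append(i)
                seen.add(s)
        df = df.iloc[:, keep_idx]
        sample_ids = [str(c) for c in df.columns]
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float))
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise DataError(
            f"non-numeric count at gene {gene_ids[g]!r}, sample {sample_ids[s]!r}"
        )
    return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=values)


def _read_clinical(path) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "os_days", "event", "age"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise DataError(f"clinical table missing column(s): {sorted(missing_cols)}")
    if "rcbv_hat_median" not in df.columns:
        df["rcbv_hat_median"] = math.nan
    records = []
    for i, row in df.iterrows():
        pid = row["patient_id"]
        if pd.isna(pid) or str(pid).strip() == "":
            raise DataError(f"clinical row {i}: empty patient_id")
        records.append(
            PatientRecord(
                patient_id=str(pid),
                os_days=_to_float(row["os_days"], f"row {i} os_days"),
                event=_to_float(row["event"], f"row {i} event"),
                age=_to_float(row["age"], f"row {i} age"),
                rcbv_hat_median=_to_float(
                    row["rcbv_hat_median"], f"row {i} rcbv_hat_median"
                ),
            )
        )
    return records


def _to_float(value, where: str) -> float:
    if pd.isna(value) or (isinstance(value, str) and value.strip() in ("", "NA")):
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise DataError(f"clinical table, {where}: cannot parse {value!r}") from exc


def _read_annotation(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"gene_id", "description"} <= set(df.columns):
        raise DataError("annotation table must have columns gene_id, description")
    dupes = _duplicates(list(df["gene_id"]))
    if dupes:
        raise DataError(f"duplicated gene id(s) in annotation: {dupes[:5]}")
    return dict(zip(df["gene_id"], df["description"]))


def read_cohort(counts_path, clinical_path, annotation_path) -> Cohort:
    """Read and cross-validate the three input tables.

    Samples lacking a survival time or event flag are retained (they still
    contribute to expression analysis and scoring) but are flagged unusable
    for survival estimation via :attr:`PatientRecord.survival_valid`.
    Gzip-compressed counts are accepted (by file extension).
    """
    counts = _read_counts(counts_path)
    patients = _read_clinical(clinical_path)
    annotation = _read_annotation(annotation_path)
    unannotated = [g for g in counts.gene_ids if g not in annotation]
    if unannotated:
        raise DataError(f"genes without annotation: {unannotated[:5]}")
    n_invalid = sum(not p.survival_valid for p in patients)
    if n_invalid:
        logger.info("%d patient(s) lack usable survival data; retained", n_invalid)
    return Cohort(counts=counts, patients=patients, annotation=annotation)


def build_cohort(
    counts: CountMatrix,
    clinical: pd.DataFrame,
    annotation: Mapping[str, str] | pd.DataFrame,
) -> Cohort:
    """Assemble a Cohort from in-memory objects (same validation as read_cohort)."""
    if isinstance(annotation, pd.DataFrame):
        annotation = dict(zip(annotation["gene_id"], annotation["description"]))
    records = []
    for i, row in clinical.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                os_days=_to_float(row.get("os_days", math.nan), f"row {i} os_days"),
                event=_to_float(row.get("event", math.nan), f"row {i} event"),
                age=_to_float(row.get("age", math.nan), f"row {i} age"),
                rcbv_hat_median=_to_float(
                    row.get("rcbv_hat_median", math.nan), f"row {i} rcbv"
                ),
            )
        )
    return Cohort(counts=counts, patients=records, annotation=dict(annotation))


def assign_vascular_groups(
    cohort: Cohort, threshold: float = 7.0, inclusive: bool = False
) -> Cohort:
    """Assign HV / MV / -V labels from the rCBV_HAT median.

    HV is defined by *exceeding* the threshold (strict ``>``); a value exactly
    at the threshold goes to MV. Pass ``inclusive=True`` for ``>=`` semantics.
    Missing rCBV always maps to -V. Returns the same cohort with
    ``vascular_group`` set on every patient record.
    """
    if not threshold > 0:
        raise ConfigurationError(f"rCBV threshold must be > 0, got {threshold}")
    for p in cohort.patients:
        if not p.has_rcbv:
            p.vascular_group = GROUP_UNKNOWN
            continue
        if p.rcbv_hat_median < 0:
            raise DataError(
                f"patient {p.patient_id}: negative rCBV {p.rcbv_hat_median}"
            )
        if inclusive:
            is_hv = p.rcbv_hat_median >= threshold
        else:
            is_hv = p.rcbv_hat_median > threshold
        p.vascular_group = GROUP_HV if is_hv else GROUP_MV
    sizes = {g: len(ids) for g, ids in cohort.patients_by_group().items()}
    logger.info("vascular groups: %s", sizes)
    return cohort
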