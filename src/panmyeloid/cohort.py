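"""Patient records, delimited-text cohort I/O and feature-vector assembly.

The on-disk format is two tab-separated tables: a *cohort table* with one
row per patient (diagnosis, age, karyotype flags, CBC, smear and outcome
columns) and a long-format *mutation table* keyed by ``patient_id`` with
one row per surviving somatic mutation event.  Empty cells are missing
values; zero is a legitimate measurement and is never treated as missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panels import variable_to_gene
from .schema import DIAGNOSES, FeatureSchema

#: optional per-patient outcome / annotation columns of the cohort table
OUTCOME_COLUMNS = (
    "eln_class", "ipssr_score", "cr", "mrd", "os_time", "os_event",
    "mrc_flag", "secondary_type_flag", "m3_flag", "mdseb_flag",
    "denovo_flag", "standard_induction_flag",
    "blasts_pretreatment", "blasts_posttreatment",
)


class SchemaError(ValueError):
    """Raised when an input table does not conform to the cohort schema."""


@dataclass
class MutationEvent:
    """One surviving somatic mutation event, keyed by gene variable."""

    patient_id: str
    gene_variable: str
    vaf: float | None = None
    flt3_ar_class: str | None = None  # {"high", "low"} for FLT3-ITD only

    @property
    def gene(self) -> str:
        return variable_to_gene(self.gene_variable)


@dataclass
class PatientRecord:
    patient_id: str
    diagnosis: str
    age: float
    karyotype_flags: dict[str, int] = field(default_factory=dict)
    cbc: dict[str, float | None] = field(default_factory=dict)
    smear: dict[str, float | None] = field(default_factory=dict)
    mutation_events: list[MutationEvent] = field(default_factory=list)
    eln_class: str | None = None
    ipssr_score: float | None = None
    cr: int | None = None
    mrd: float | None = None
    os_time: float | None = None
    os_event: int | None = None
    mrc_flag: int = 0
    secondary_type_flag: int = 0
    m3_flag: int = 0
    mdseb_flag: int = 0
    denovo_flag: int = 1
    standard_induction_flag: int = 1
    blasts_pretreatment: float | None = None
    blasts_posttreatment: float | None = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"patient {self.patient_id}: age must be >= 0")
        for name, flag in self.karyotype_flags.items():
            if flag not in (0, 1):
                raise ValueError(
                    f"patient {self.patient_id}: karyotype flag {name!r} "
                    f"must be 0/1, got {flag!r}"
                )

    def carries(self, gene_variable: str) -> bool:
        return any(e.gene_variable == gene_variable for e in self.mutation_events)

    @property
    def gene_variables(self) -> set[str]:
        return {e.gene_variable for e in self.mutation_events}


# ---------------------------------------------------------------------------
# table I/O


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _opt_float(value):
    return None if _is_missing(value) else float(value)


def _opt_int(value):
    return None if _is_missing(value) else int(float(value))


def load_cohort(
    path: str | Path,
    schema: FeatureSchema,
    mutations: str | Path | None = None,
) -> list[PatientRecord]:
    """Read a cohort TSV (and optionally its mutation table).

    Raises :class:`SchemaError` naming the offending row for unknown
    diagnosis labels and for duplicate patient ids.  Diagnosis labels are
    whitespace-trimmed before validation.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = ["patient_id", "diagnosis", "age"]
    missing_cols = [c for c in required + list(schema.karyotype) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort table lacks columns: {missing_cols[:5]}")

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in seen:
            raise SchemaError(f"row {idx}: duplicate patient_id {pid!r}")
        seen.add(pid)
        diagnosis = str(row["diagnosis"]).strip()
        if diagnosis not in DIAGNOSES:
            raise SchemaError(
                f"row {idx} (patient {pid!r}): unknown diagnosis "
                f"{row['diagnosis']!r}"
            )
        rec = PatientRecord(
            patient_id=pid,
            diagnosis=diagnosis,
            age=float(row["age"]),
            karyotype_flags={k: int(row[k]) for k in schema.karyotype},
            cbc={k: _opt_float(row.get(k)) for k in schema.cbc},
            smear={k: _opt_float(row.get(k)) for k in schema.smear},
            eln_class=None if _is_missing(row.get("eln_class")) else str(row["eln_class"]),
            ipssr_score=_opt_float(row.get("ipssr_score")),
            cr=_opt_int(row.get("cr")),
            mrd=_opt_float(row.get("mrd")),
            os_time=_opt_float(row.get("os_time")),
            os_event=_opt_int(row.get("os_event")),
            mrc_flag=_opt_int(row.get("mrc_flag")) or 0,
            secondary_type_flag=_opt_int(row.get("secondary_type_flag")) or 0,
            m3_flag=_opt_int(row.get("m3_flag")) or 0,
            mdseb_flag=_opt_int(row.get("mdseb_flag")) or 0,
            denovo_flag=1 if _is_missing(row.get("denovo_flag")) else int(row["denovo_flag"]),
            standard_induction_flag=(
                1 if _is_missing(row.get("standard_induction_flag"))
                else int(row["standard_induction_flag"])
            ),
            blasts_pretreatment=_opt_float(row.get("blasts_pretreatment")),
            blasts_posttreatment=_opt_float(row.get("blasts_posttreatment")),
        )
        records.append(rec)

    if mutations is not None:
        attach_mutations(records, load_mutations(mutations))
    return records


def load_mutations(path: str | Path) -> list[MutationEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    events = []
    for _, row in df.iterrows():
        events.append(
            MutationEvent(
                patient_id=str(row["patient_id"]),
                gene_variable=str(row["variable_class"]),
                vaf=_opt_float(row.get("vaf")),
                flt3_ar_class=(
                    None if _is_missing(row.get("flt3_ar")) else str(row["flt3_ar"])
                ),
            )
        )
    return events


def attach_mutations(
    records: Sequence[PatientRecord], events: Iterable[MutationEvent]
) -> None:
    by_id = {r.patient_id: r for r in records}
    for event in events:
        rec = by_id.get(event.patient_id)
        if rec is None:
            raise SchemaError(
                f"mutation table references unknown patient {event.patient_id!r}"
            )
        rec.mutation_events.append(event)


def write_cohort(
    records: Sequence[PatientRecord], path: str | Path, schema: FeatureSchema
) -> None:
    rows = []
    for r in records:
        row: dict = {"patient_id": r.patient_id, "diagnosis": r.diagnosis, "age": r.age}
        row.update({k: r.karyotype_flags.get(k, 0) for k in schema.karyotype})
        row.update({k: r.cbc.get(k) for k in schema.cbc})
        row.update({k: r.smear.get(k) for k in schema.smear})
        for col in OUTCOME_COLUMNS:
            row[col] = getattr(r, col)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_mutations(records: Sequence[PatientRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        for e in r.mutation_events:
            rows.append(
                {
                    "patient_id": e.patient_id,
                    "gene": e.gene,
                    "variable_class": e.gene_variable,
                    "vaf": e.vaf,
                    "flt3_ar": e.flt3_ar_class,
                }
            )
    pd.DataFrame(rows, columns=["patient_id", "gene", "variable_class", "vaf", "flt3_ar"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# feature assembly


def cohort_means(records: Sequence[PatientRecord], schema: FeatureSchema) -> dict[str, float]:
    """Per-feature means over non-missing values of the continuous block.

    Used for mean imputation.  A feature missing for every patient gets
    mean 0.0 so that imputation stays defined.
    """
    means: dict[str, float] = {"age": float(np.mean([r.age for r in records]))}
    for block, getter in (("cbc", lambda r: r.cbc), ("smear", lambda r: r.smear)):
        for name in getattr(schema, block):
            values = [getter(r).get(name) for r in records]
            present = [v for v in values if v is not None]
            means[name] = float(np.mean(present)) if present else 0.0
    return means


def assemble_features(
    record: PatientRecord,
    means: Mapping[str, float],
    schema: FeatureSchema,
) -> np.ndarray:
    """Assemble one patient's ordered feature vector with mean imputation.

    Gene and karyotype indicators are coded 0/1 (any surviving mutation
    event in a gene variable maps to 1); missing continuous values are
    replaced by the cohort mean of that feature.
    """
    for name in schema.continuous:
        if name not in means:
            raise KeyError(f"cohort means lack schema feature {name!r}")
    carried = record.gene_variables
    values = [1.0 if g in carried else 0.0 for g in schema.gene_variables]
    values += [float(record.karyotype_flags.get(k, 0)) for k in schema.karyotype]
    values.append(record.age if record.age is not None else means["age"])
    for name in schema.cbc:
        v = record.cbc.get(name)
        values.append(means[name] if v is None else v)
    for name in schema.smear:
        v = record.smear.get(name)
        values.append(means[name] if v is None else v)
    out = np.asarray(values, dtype=float)
    assert out.shape == (schema.size,)
    return out


def feature_matrix(
    records: Sequence[PatientRecord], schema: FeatureSchema
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Feature matrix for a whole cohort (rows indexed by patient_id)."""
    means = cohort_means(records, schema)
    X = np.vstack([assemble_features(r, means, schema) for r in records])
    df = pd.DataFrame(X, index=[r.patient_id for r in records], columns=schema.names)
    return df, means
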