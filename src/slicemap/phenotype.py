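"""Demographic preprocessing for ADHD-200-style phenotype tables.

Stages, applied in order:

1. quality-control filtering — a row is dropped only when *both* site QC
   flags (QC_Athena, QC_NIAK) are 0 (missing counts as questionable only
   when the other flag is also 0/missing); unparseable QC values drop the
   row outright;
2. record validation — the diagnostic label must be one of {0, 1, 2, 3}
   and age, gender, handedness and Full4 IQ must be present and inside
   configurable valid ranges;
3. LD_OR_ODD derivation — 1 when a learning disorder or oppositional
   defiant disorder appears among the free-text secondary diagnoses;
4. label binarisation — 0 stays typically-developing, any subtype
   (1 combined, 2 hyperactive-impulsive, 3 inattentive) becomes 1;
5. attribute normalisation — min-max scaling of the continuous attributes
   to [0, 1], fitted on training subjects only and clipped on held-out
   subjects; binary attributes pass through unchanged.

Every exclusion is recorded in an audit trail (subject_id, stage, reason)
that can be written as TSV.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhenotypeRecord", "ValidRanges", "CovariateScaler",
    "read_phenotype_csv", "qc_filter", "validate_record", "derive_ld_or_odd",
    "binarize_label", "prepare_phenotype", "write_audit",
    "COVARIATE_NAMES", "DEFAULT_LD_ODD_VOCABULARY",
]

logger = logging.getLogger(__name__)

COVARIATE_NAMES = ("age_norm", "gender", "handedness_norm", "iq_norm", "ld_or_odd")

DEFAULT_LD_ODD_VOCABULARY = ("LD", "ODD", "learning disorder", "oppositional defiant")


@dataclass
class PhenotypeRecord:
    """One subject's raw demographic row; ``None`` marks a missing value.

    Fields that failed to parse at all (non-numeric text in a numeric
    column) are listed in ``parse_errors``.
    """

    subject_id: str
    qc_athena: int | None = None
    qc_niak: int | None = None
    dx_label: int | None = None
    age: float | None = None
    gender: float | None = None
    handedness: float | None = None
    full4_iq: float | None = None
    secondary_dx: str = ""
    parse_errors: set = field(default_factory=set)


@dataclass(frozen=True)
class ValidRanges:
    """Acceptance windows for the validated attributes.

    The source tables never print their legal ranges, so these are
    deliberately generous paediatric-cohort defaults and fully
    configurable: age in (0, 30] years, Full4 IQ in (40, 200), gender
    binary, handedness (categorical codes or Edinburgh-style scores)
    in [-2, 3].
    """

    age: tuple[float, float] = (0.0, 30.0)
    iq: tuple[float, float] = (40.0, 200.0)
    handedness: tuple[float, float] = (-2.0, 3.0)
    gender_values: tuple[float, ...] = (0.0, 1.0)
    dx_values: tuple[int, ...] = (0, 1, 2, 3)


def _num(value, errors: set, fieldname: str, cast=float):
    if value is None or (isinstance(value, float) and np.isnan(value)) or str(value).strip() == "":
        return None
    try:
        return cast(float(value))
    except (TypeError, ValueError):
        errors.add(fieldname)
        return None


def read_phenotype_csv(path: str | Path) -> list[PhenotypeRecord]:
    """Parse the comma-separated, headered phenotype dialect.

    Missing values are empty fields; numeric columns that contain
    non-numeric junk are flagged in ``parse_errors`` rather than raising.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        errs: set = set()
        rec = PhenotypeRecord(
            subject_id=str(row.get("Subject_ID", "")),
            qc_athena=_num(row.get("QC_Athena"), errs, "qc_athena", int),
            qc_niak=_num(row.get("QC_NIAK"), errs, "qc_niak", int),
            dx_label=_num(row.get("DX"), errs, "dx_label", int),
            age=_num(row.get("Age"), errs, "age"),
            gender=_num(row.get("Gender"), errs, "gender"),
            handedness=_num(row.get("Handedness"), errs, "handedness"),
            full4_iq=_num(row.get("Full4_IQ"), errs, "full4_iq"),
            secondary_dx=str(row.get("Secondary_DX", "")),
            parse_errors=errs,
        )
        records.append(rec)
    return records


def qc_filter(records: list[PhenotypeRecord], audit: list | None = None) -> list[PhenotypeRecord]:
    """Drop rows whose two QC flags are both questionable.

    A flag is questionable when it is 0, or missing while the other flag
    is also 0/missing; a row with an unparseable QC value is excluded and
    logged. Order is preserved.
    """
    kept = []
    for rec in records:
        if "qc_athena" in rec.parse_errors or "qc_niak" in rec.parse_errors:
            logger.warning("subject %s: unparseable QC value, excluded", rec.subject_id)
            if audit is not None:
                audit.append((rec.subject_id, "qc_filter", "unparseable QC value"))
            continue
        a_bad = rec.qc_athena in (0, None)
        n_bad = rec.qc_niak in (0, None)
        if a_bad and n_bad:
            if audit is not None:
                audit.append((rec.subject_id, "qc_filter", "both QC flags questionable"))
            continue
        kept.append(rec)
    return kept


def validate_record(rec: PhenotypeRecord,
                    valid_ranges: ValidRanges = ValidRanges()) -> tuple[bool, str | None]:
    """Accept/reject one QC-passed record; the reason names the field."""
    vr = valid_ranges
    if rec.dx_label is None or rec.dx_label not in vr.dx_values or "dx_label" in rec.parse_errors:
        return False, "dx_label"
    for name, value, ok in (
        ("age", rec.age, lambda v: vr.age[0] < v <= vr.age[1]),
        ("gender", rec.gender, lambda v: v in vr.gender_values),
        ("handedness", rec.handedness, lambda v: vr.handedness[0] <= v <= vr.handedness[1]),
        ("full4_iq", rec.full4_iq, lambda v: vr.iq[0] < v < vr.iq[1]),
    ):
        if value is None or name in rec.parse_errors or not ok(value):
            return False, name
    return True, None


def derive_ld_or_odd(secondary_dx: str,
                     vocabulary: tuple[str, ...] = DEFAULT_LD_ODD_VOCABULARY) -> int:
    """1 iff a vocabulary entry occurs as whole tokens in the free text."""
    text = (secondary_dx or "").lower()
    for term in vocabulary:
        if re.search(r"(?<!\w)" + re.escape(term.lower()) + r"(?!\w)", text):
            return 1
    return 0


def binarize_label(dx_label: int) -> int:
    """0 stays typically developing; any ADHD subtype (1, 2, 3) becomes 1."""
    if dx_label not in (0, 1, 2, 3):
        raise ValueError(f"dx_label must be validated to 0..3 before binarisation, got {dx_label!r}")
    return 0 if dx_label == 0 else 1


class CovariateScaler:
    """Min-max scaling of the continuous personal attributes to [0, 1].

    Fit on the training subjects of a fold only; transformed held-out
    values are clipped into [0, 1]. Binary attributes (gender, LD_OR_ODD)
    pass through untouched. A constant attribute on the fitting set maps
    to 0 everywhere, with a logged warning.
    """

    CONTINUOUS = ("age", "handedness", "full4_iq")

    def __init__(self):
        self.mins_: dict[str, float] | None = None
        self.maxs_: dict[str, float] | None = None

    def fit(self, attrs: pd.DataFrame) -> "CovariateScaler":
        self.mins_, self.maxs_ = {}, {}
        for col in self.CONTINUOUS:
            lo, hi = float(attrs[col].min()), float(attrs[col].max())
            if hi == lo:
                logger.warning("attribute %r is constant on the fitting set; mapping to 0", col)
            self.mins_[col], self.maxs_[col] = lo, hi
        return self

    def transform(self, attrs: pd.DataFrame) -> pd.DataFrame:
        """Return the 5-component covariate table, every entry in [0, 1]."""
        if self.mins_ is None:
            raise RuntimeError("CovariateScaler.transform called before fit")
        out = pd.DataFrame(index=attrs.index)
        for col, name in (("age", "age_norm"), ("handedness", "handedness_norm"),
                          ("full4_iq", "iq_norm")):
            lo, hi = self.mins_[col], self.maxs_[col]
            if hi == lo:
                out[name] = 0.0
            else:
                out[name] = np.clip((attrs[col] - lo) / (hi - lo), 0.0, 1.0)
        out["gender"] = attrs["gender"].astype(float)
        out["ld_or_odd"] = attrs["ld_or_odd"].astype(float)
        return out[list(COVARIATE_NAMES)]

    def fit_transform(self, attrs: pd.DataFrame) -> pd.DataFrame:
        return self.fit(attrs).transform(attrs)


def prepare_phenotype(csv_path: str | Path,
                      valid_ranges: ValidRanges = ValidRanges(),
                      vocabulary: tuple[str, ...] = DEFAULT_LD_ODD_VOCABULARY,
                      ) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Full demographic pipeline: CSV -> validated raw-attribute table.

    Returns ``(table, audit)``. The table has one row per surviving
    subject with columns ``subject_id``, ``label`` (binarised), and the
    raw attributes ``age``, ``gender``, ``handedness``, ``full4_iq``,
    ``ld_or_odd``. Scaling is *not* applied here: it belongs inside each
    training fold (see :class:`CovariateScaler`).
    """
    audit: list[tuple[str, str, str]] = []
    records = read_phenotype_csv(csv_path)
    records = qc_filter(records, audit=audit)
    rows = []
    for rec in records:
        ok, reason = validate_record(rec, valid_ranges)
        if not ok:
            audit.append((rec.subject_id, "validate", f"invalid {reason}"))
            continue
        rows.append(dict(
            subject_id=rec.subject_id,
            label=binarize_label(rec.dx_label),
            age=rec.age, gender=rec.gender, handedness=rec.handedness,
            full4_iq=rec.full4_iq,
            ld_or_odd=derive_ld_or_odd(rec.secondary_dx, vocabulary),
        ))
    return pd.DataFrame(rows), audit


def write_audit(audit: list[tuple[str, str, str]], path: str | Path) -> None:
    pd.DataFrame(audit, columns=["subject_id", "stage", "reason"]).to_csv(
        path, sep="\t", index=False)
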