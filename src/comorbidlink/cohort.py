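"""Patient-level cohort ingestion and sex-stratified summaries.

The cohort here is an all-case design: every record is a patient diagnosed
with the index cancer, and the quantity of interest per sex stratum is the
proportion of those cases that also carry the metabolic exposure (diabetes).
That proportion seeds the population-scaled co-occurrence model in
:mod:`comorbidlink.cooccur`.

Note on nomenclature: because the cohort contains only cases, the stratum
proportion is formally P(exposure | case, sex).  Upstream epidemiological
reports sometimes label the same number "P(case | exposure)"; the value
computed here is the within-cohort exposure proportion, whatever the label.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")

#: default CSV column names; override via ``column_map`` in :func:`load_cohort`
DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "sex": "sex",
    "age": "age",
    "dm_status": "DM",
    "t_stage": "T_stage",
    "n_stage": "N_stage",
    "m_stage": "M_stage",
    "subtype": "subtype",
}

_REQUIRED = ("sex", "age", "dm_status")

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n"}


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: demographics, exposure status and optional staging."""

    patient_id: str
    sex: str
    age: int
    dm_status: bool
    t_stage: int | None = None
    n_stage: int | None = None
    m_stage: int | None = None
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0 <= self.age <= 130:
            raise ValueError(f"age {self.age} outside [0, 130]")
        for name in ("t_stage", "n_stage", "m_stage"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class CohortSummary:
    """Counts and moments describing a cohort (sex, exposure, age, staging)."""

    n_total: int
    n_by_sex: dict[str, int]
    dm_by_sex: dict[str, int]
    age_mean: float
    age_sd: float
    stage_tables: dict[str, dict[int, int]]

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


@dataclass(frozen=True)
class ConditionalProbability:
    """An exposure proportion within one sex stratum, kept as a ratio."""

    sex: str
    numerator: int
    denominator: int
    value: float = field(init=False)

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")
        object.__setattr__(self, "value", self.numerator / self.denominator)


def _parse_bool(token: object) -> bool:
    s = str(token).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValueError(f"cannot parse boolean from {token!r}")


def _parse_optional_stage(token: object) -> int | None:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return None
    s = str(token).strip()
    if s == "" or s.lower() in {"na", "nan", "none"}:
        return None
    return int(float(s))


def load_cohort(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[PatientRecord]:
    """Read a patient table from CSV/TSV into validated records.

    Rows that fail validation (unknown sex, unparseable age, ...) are
    skipped and reported with their file line number through the module
    logger; a missing required column is a hard error.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row.
    column_map:
        Overrides for :data:`DEFAULT_COLUMNS` (logical name -> file column).
    delimiter:
        Field delimiter; inferred from the filename suffix when omitted
        (``.tsv`` -> tab, else comma).
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","

    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [cols[k] for k in _REQUIRED if cols[k] not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")

    records: list[PatientRecord] = []
    for idx, row in frame.iterrows():
        line_no = int(idx) + 2  # header is line 1
        try:
            records.append(
                PatientRecord(
                    patient_id=str(
                        row.get(cols["patient_id"], f"row{line_no}") or f"row{line_no}"
                    ),
                    sex=str(row[cols["sex"]]).strip().lower(),
                    age=int(float(row[cols["age"]])),
                    dm_status=_parse_bool(row[cols["dm_status"]]),
                    t_stage=_parse_optional_stage(row.get(cols["t_stage"])),
                    n_stage=_parse_optional_stage(row.get(cols["n_stage"])),
                    m_stage=_parse_optional_stage(row.get(cols["m_stage"])),
                    subtype=(str(row[cols["subtype"]]) or None)
                    if cols["subtype"] in frame.columns
                    else None,
                )
            )
        except (ValueError, KeyError) as exc:
            logger.warning("line %d rejected: %s", line_no, exc)
    return records


def write_cohort(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records back to CSV with the default column names."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "sex": r.sex,
                "age": r.age,
                "DM": int(r.dm_status),
                "T_stage": r.t_stage if r.t_stage is not None else "",
                "N_stage": r.n_stage if r.n_stage is not None else "",
                "M_stage": r.m_stage if r.m_stage is not None else "",
                "subtype": r.subtype or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Tabulate the cohort: per-sex counts, exposure counts, age moments,
    and stage frequency tables.

    The age standard deviation uses the sample (n-1) denominator; a
    single-record cohort reports ``age_sd = 0.0``.
    """
    if not records:
        raise ValueError("empty cohort")
    n_by_sex = {s: 0 for s in SEXES}
    dm_by_sex = {s: 0 for s in SEXES}
    stage_tables: dict[str, dict[int, int]] = {
        "t_stage": {},
        "n_stage": {},
        "m_stage": {},
    }
    ages = np.array([r.age for r in records], dtype=float)
    for r in records:
        n_by_sex[r.sex] += 1
        if r.dm_status:
            dm_by_sex[r.sex] += 1
        for name in stage_tables:
            v = getattr(r, name)
            if v is not None:
                stage_tables[name][v] = stage_tables[name].get(v, 0) + 1
    sd = float(np.std(ages, ddof=1)) if len(ages) > 1 else 0.0
    return CohortSummary(
        n_total=len(records),
        n_by_sex=n_by_sex,
        dm_by_sex=dm_by_sex,
        age_mean=float(np.mean(ages)),
        age_sd=sd,
        stage_tables={k: dict(sorted(v.items())) for k, v in stage_tables.items()},
    )


def conditional_probability(
    records: Sequence[PatientRecord], sex: str
) -> ConditionalProbability:
    """Exposure proportion in one sex stratum of an all-case cohort.

    numerator = diabetic cases of that sex, denominator = all cases of that
    sex.  The value is kept at full precision; round only for display.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    stratum = [r for r in records if r.sex == sex]
    if not stratum:
        raise ValueError(f"no records for stratum {sex!r}")
    num = sum(r.dm_status for r in stratum)
    return ConditionalProbability(sex=sex, numerator=num, denominator=len(stratum))
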