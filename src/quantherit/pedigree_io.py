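"""Reading, validation, eligibility filtering, and result writing.

Input dialect: two tab-delimited tables with named headers.

* pedigree: ``individual_id, father_id, mother_id, sex, cohort`` — sex coded
  ``F``/``M``, parent ids empty when unknown.
* exams: ``individual_id, exam_index, age, value, on_lipid_meds`` — one row
  per phenotype measurement, medication flag 0/1.

Validation enforces referential integrity (every exam and parent id resolves),
uniqueness of ids and of (individual, exam) keys, and acyclicity of the parent
links.  Eligibility filtering mirrors the usual lipid-study criteria: exams
under a minimum age or taken on lipid-lowering medication are excluded.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CohortData",
    "PedigreeFormatError",
    "PedigreeValidationError",
    "read_tables",
    "apply_eligibility",
    "write_results",
]

PEDIGREE_COLUMNS = ["individual_id", "father_id", "mother_id", "sex", "cohort"]
EXAM_COLUMNS = ["individual_id", "exam_index", "age", "value", "on_lipid_meds"]


class PedigreeFormatError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class PedigreeValidationError(ValueError):
    """The tables parse but violate a referential or structural invariant."""


@dataclass
class CohortData:
    """Validated pedigree + longitudinal exam tables."""

    individuals: pd.DataFrame
    exams: pd.DataFrame

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_exams(self) -> int:
        return len(self.exams)

    def cohorts(self) -> list[str]:
        return sorted(self.individuals["cohort"].unique())


def _read_tsv(path, required, kind):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{kind} table not found: {path}")
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise PedigreeFormatError(
            f"{kind} table {path} is missing required column(s): {', '.join(missing)}"
        )
    extra = [c for c in table.columns if c not in required]
    if extra:
        log.warning("%s table: ignoring unknown column(s) %s", kind, extra)
    return table[required]


def _check_acyclic(ped: pd.DataFrame) -> None:
    parent = {
        r.individual_id: [p for p in (r.father_id, r.mother_id) if p]
        for r in ped.itertuples(index=False)
    }
    state: dict[str, int] = {}  # 0 in progress, 1 done

    def visit(node: str, stack: list[str]) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            raise PedigreeValidationError(
                "pedigree contains an ancestry cycle: " + " -> ".join(cycle)
            )
        state[node] = 0
        stack.append(node)
        for p in parent.get(node, []):
            visit(p, stack)
        stack.pop()
        state[node] = 1

    for node in parent:
        visit(node, [])


def read_tables(pedigree_path, exam_path) -> CohortData:
    """Read and validate the pedigree and exam tables."""
    ped = _read_tsv(pedigree_path, PEDIGREE_COLUMNS, "pedigree")
    exams = _read_tsv(exam_path, EXAM_COLUMNS, "exam")

    if ped["individual_id"].duplicated().any():
        dup = ped.loc[ped["individual_id"].duplicated(), "individual_id"].tolist()
        raise PedigreeValidationError(f"duplicate individual ids: {dup}")
    if (ped["individual_id"] == "").any():
        raise PedigreeValidationError("empty individual_id in pedigree")
    bad_sex = set(ped["sex"]) - {"F", "M"}
    if bad_sex:
        raise PedigreeFormatError(f"sex must be F or M, found {sorted(bad_sex)}")

    ids = set(ped["individual_id"])
    for col in ("father_id", "mother_id"):
        dangling = sorted(set(ped.loc[ped[col] != "", col]) - ids)
        if dangling:
            raise PedigreeValidationError(
                f"{col} references unknown individual(s): {dangling}"
            )
    self_parent = ped[
        (ped["individual_id"] == ped["father_id"])
        | (ped["individual_id"] == ped["mother_id"])
    ]
    if len(self_parent):
        raise PedigreeValidationError(
            f"individual(s) listed as their own parent: "
            f"{self_parent['individual_id'].tolist()}"
        )
    _check_acyclic(ped)

    unknown = sorted(set(exams["individual_id"]) - ids)
    if unknown:
        raise PedigreeValidationError(
            f"exam rows reference unknown individual(s): {unknown}"
        )
    try:
        exams = exams.assign(
            exam_index=exams["exam_index"].astype(int),
            age=exams["age"].astype(float),
            value=exams["value"].astype(float),
            on_lipid_meds=exams["on_lipid_meds"].astype(int).astype(bool),
        )
    except ValueError as exc:
        raise PedigreeFormatError(f"exam table field cannot be parsed: {exc}") from exc
    if exams.duplicated(["individual_id", "exam_index"]).any():
        raise PedigreeValidationError("duplicate (individual_id, exam_index) rows")
    if (exams["age"] <= 0).any():
        raise PedigreeValidationError("exam ages must be positive")
    if not np.isfinite(exams["value"]).all():
        raise PedigreeValidationError("non-finite phenotype values")

    ped = ped.assign(female=(ped["sex"] == "F").astype(int))
    return CohortData(individuals=ped.reset_index(drop=True), exams=exams.reset_index(drop=True))


def apply_eligibility(
    data: CohortData, min_age: float = 16.0, medication_scope: str = "exam"
) -> CohortData:
    """Drop under-age and on-medication exam records, then empty individuals.

    ``medication_scope='exam'`` removes only the medicated exams (default);
    ``'subject'`` removes every exam of anyone ever medicated.
    """
    if medication_scope not in ("exam", "subject"):
        raise ValueError("medication_scope must be 'exam' or 'subject'")
    exams = data.exams
    keep = (exams["age"] >= min_age) & (~exams["on_lipid_meds"])
    if medication_scope == "subject":
        medicated = set(exams.loc[exams["on_lipid_meds"], "individual_id"])
        keep = (exams["age"] >= min_age) & (~exams["individual_id"].isin(medicated))
    removed = int((~keep).sum())
    exams = exams[keep].reset_index(drop=True)
    if len(exams) == 0:
        raise PedigreeValidationError("no eligible subjects after filtering")
    with_exams = set(exams["individual_id"])
    individuals = data.individuals  # keep full pedigree for link resolution
    dropped = data.n_individuals - len(
        individuals[individuals["individual_id"].isin(with_exams)]
    )
    log.info(
        "eligibility: removed %d exam record(s); %d individual(s) have no "
        "remaining exams", removed, dropped,
    )
    return CohortData(individuals=individuals, exams=exams)


def write_results(tables: dict, out_dir) -> dict[str, Path]:
    """Write result tables (DataFrame -> CSV, mapping -> JSON) deterministically."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            table.to_csv(path, index=False, float_format="%.10g")
        else:
            path = out_dir / f"{name}.json"
            path.write_text(json.dumps(table, indent=2, sort_keys=True, default=float) + "\n")
        written[name] = path
    return written
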