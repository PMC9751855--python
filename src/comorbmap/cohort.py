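"""Child-level cohort records and tabular I/O.

A :class:`CohortTable` holds one :class:`ChildRecord` per child: group
membership (EPT vs term-born), the covariates used by the adjusted
regression models (sex, mother's education, neonatal brain injury,
neonatal morbidity), the eight Touwen dysfunction flags, and raw scores on
the 19 score-bearing domains.  Any score or the whole Touwen examination
may be missing; missingness is explicit (``None``), never encoded as a
sentinel value.

The on-disk format is a flat CSV/TSV with one row per child and an empty
cell for a missing value; ``write_cohort`` → ``read_cohort`` is an identity
on values and missingness.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

from .registry import DEFAULT_REGISTRY, TOUWEN_DOMAINS, DomainRegistry


class Group(str, enum.Enum):
    EPT = "EPT"
    TERM = "TERM"


class Education(enum.IntEnum):
    """Mother's education, ordinal."""

    HIGH_SCHOOL_OR_LOWER = 0
    BACHELOR = 1
    MASTER_OR_HIGHER = 2


@dataclass
class ChildRecord:
    """One child's group, covariates, Touwen flags and raw domain scores."""

    child_id: str
    group: Group
    sex: str  # "M" or "F"
    mother_education: Education
    brain_injury: bool  # intraventricular haemorrhage grade III–IV
    morbidity: bool  # verified sepsis and/or BPD and/or NEC
    #: dysfunction flag per Touwen functional domain; None = exam missing
    touwen_domains: tuple[bool, ...] | None = None
    #: domain abbreviation -> raw score on the native scale; absent = missing
    scores: dict[str, float] = field(default_factory=dict)
    #: auxiliary scores (e.g. IQ subtests) used only by composite imputation
    aux_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.touwen_domains is not None and len(self.touwen_domains) != 8:
            raise ValueError(
                f"touwen_domains needs exactly 8 flags, got {len(self.touwen_domains)}"
            )
        if "MND" in self.scores:
            raise ValueError("MND is derived from the Touwen flags, never stored raw")

    def score(self, domain: str) -> float | None:
        return self.scores.get(domain)


@dataclass
class CohortTable:
    """All children of a two-group cohort plus the domain registry."""

    children: list[ChildRecord]
    registry: DomainRegistry = DEFAULT_REGISTRY
    #: (child_id, domain, imputed_value) entries appended by imputation ops
    imputation_log: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.child_id for c in self.children]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate child_ids: {dupes}")
        valid = set(self.registry.abbreviations) - {"MND"}
        for c in self.children:
            unknown = set(c.scores) - valid
            if unknown:
                raise ValueError(
                    f"child {c.child_id}: unknown score domains {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.children)

    def group(self, group: Group | str) -> list[ChildRecord]:
        group = Group(group)
        return [c for c in self.children if c.group is group]

    def copy(self) -> "CohortTable":
        children = [
            replace(c, scores=dict(c.scores), aux_scores=dict(c.aux_scores))
            for c in self.children
        ]
        return CohortTable(children, self.registry, list(self.imputation_log))


# ---------------------------------------------------------------------------
# file format

_TOUWEN_COLS = [f"touwen_{i}" for i in range(1, 9)]
_FIXED_COLS = ["child_id", "group", "sex", "mother_education",
               "brain_injury", "morbidity"] + _TOUWEN_COLS

_EDU_LABELS = {
    Education.HIGH_SCHOOL_OR_LOWER: "high-school-or-lower",
    Education.BACHELOR: "bachelor",
    Education.MASTER_OR_HIGHER: "master-or-higher",
}
_EDU_FROM_LABEL = {v: k for k, v in _EDU_LABELS.items()}


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as CSV (or TSV if the suffix is ``.tsv``)."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    score_cols = [d.abbreviation for d in cohort.registry.score_domains]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(_FIXED_COLS + score_cols)
        for c in cohort.children:
            touwen = (
                ["" for _ in range(8)]
                if c.touwen_domains is None
                else [str(int(f)) for f in c.touwen_domains]
            )
            row = [
                c.child_id, c.group.value, c.sex, _EDU_LABELS[c.mother_education],
                str(int(c.brain_injury)), str(int(c.morbidity)), *touwen,
            ]
            for col in score_cols:
                v = c.scores.get(col)
                row.append("" if v is None else repr(float(v)))
            writer.writerow(row)


def _parse_bool(cell: str, where: str) -> bool:
    if cell in ("0", "1"):
        return cell == "1"
    if cell.lower() in ("true", "false"):
        return cell.lower() == "true"
    raise ValueError(f"{where}: expected 0/1 boolean, got {cell!r}")


def read_cohort(path: str | Path,
                registry: DomainRegistry = DEFAULT_REGISTRY) -> CohortTable:
    """Read a cohort table written by :func:`write_cohort`.

    Empty cells are missing values.  Unknown score columns are rejected with
    the list of valid abbreviations; non-numeric scores are reported with
    their row and column.
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() == ".tsv" else ","
    valid_scores = [d.abbreviation for d in registry.score_domains]
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader)
        missing_fixed = [c for c in _FIXED_COLS if c not in header]
        if missing_fixed:
            raise ValueError(f"missing required columns: {missing_fixed}")
        score_cols = [c for c in header if c not in _FIXED_COLS]
        unknown = [c for c in score_cols if c not in valid_scores]
        if unknown:
            raise ValueError(
                f"unknown domain columns {unknown}; valid codes: "
                + ", ".join(valid_scores)
            )
        idx = {c: header.index(c) for c in header}
        children = []
        for rownum, row in enumerate(reader, start=2):
            cid = row[idx["child_id"]]
            touwen_cells = [row[idx[c]] for c in _TOUWEN_COLS]
            if all(cell == "" for cell in touwen_cells):
                touwen = None
            else:
                touwen = tuple(
                    _parse_bool(cell, f"row {rownum} ({cid}), {col}")
                    for cell, col in zip(touwen_cells, _TOUWEN_COLS)
                )
            scores: dict[str, float] = {}
            for col in score_cols:
                cell = row[idx[col]]
                if cell == "":
                    continue
                try:
                    scores[col] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"row {rownum}, column {col}: non-numeric score {cell!r}"
                    ) from None
            edu_cell = row[idx["mother_education"]]
            try:
                edu = (_EDU_FROM_LABEL[edu_cell] if edu_cell in _EDU_FROM_LABEL
                       else Education(int(edu_cell)))
            except (KeyError, ValueError):
                raise ValueError(
                    f"row {rownum}: bad mother_education {edu_cell!r}"
                ) from None
            children.append(ChildRecord(
                child_id=cid,
                group=Group(row[idx["group"]]),
                sex=row[idx["sex"]],
                mother_education=edu,
                brain_injury=_parse_bool(row[idx["brain_injury"]],
                                         f"row {rownum}, brain_injury"),
                morbidity=_parse_bool(row[idx["morbidity"]],
                                      f"row {rownum}, morbidity"),
                touwen_domains=touwen,
                scores=scores,
            ))
    return CohortTable(children, registry)
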