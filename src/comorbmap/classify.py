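"""Impairment classification: raw scores -> 20-domain binary matrix.

Per-instrument cutoffs (impaired = performance more than 1 SD below test
norms on the native scale):

* MABC-2 and NEPSY-II: standard/scaled score <= 7 (16th percentile);
* SIPT: z-score < -1.0 — strictly below by default, since a score of
  exactly -1.0 sits on the boundary between typical and mild dysfunction;
  ``sipt_inclusive=True`` counts it as impaired instead;
* Touwen: dysfunction in 1–2 of the eight functional domains is simple
  minor neurological dysfunction (MND), in more than two complex MND;
  simple and complex are pooled as impaired.

Missing data never counts as impaired: an unobserved score (or an
incomplete Touwen examination) leaves the cell unobserved and excluded
from every downstream denominator.  The two imputation operations mirror
the reference study's handling of non-systematic missingness: a group
median for skewed score distributions, and a mean of available sibling
subtests for composite scores.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, replace

import numpy as np

from .cohort import ChildRecord, CohortTable, Group
from .registry import DomainRegistry, DomainSpec, Instrument


class MNDCategory(str, enum.Enum):
    NORMAL = "NORMAL"
    SIMPLE = "SIMPLE"
    COMPLEX = "COMPLEX"


@dataclass(frozen=True)
class MNDStatus:
    status: MNDCategory
    n_dysfunctional: int

    @property
    def impaired(self) -> bool:
        """Simple and complex MND pool as impairment."""
        return self.status is not MNDCategory.NORMAL


def classify_mnd(touwen_domains) -> MNDStatus | None:
    """Categorise the Touwen examination from its eight dysfunction flags.

    0 dysfunctional domains -> NORMAL, 1–2 -> SIMPLE, more than 2 ->
    COMPLEX.  A missing examination (``None``) or any missing flag yields
    ``None`` — the status is indeterminate rather than guessed from a
    partial count.
    """
    if touwen_domains is None:
        return None
    flags = tuple(touwen_domains)
    if len(flags) != 8:
        raise ValueError(f"expected exactly 8 Touwen flags, got {len(flags)}")
    if any(f is None for f in flags):
        return None
    n = sum(bool(f) for f in flags)
    if n == 0:
        cat = MNDCategory.NORMAL
    elif n <= 2:
        cat = MNDCategory.SIMPLE
    else:
        cat = MNDCategory.COMPLEX
    return MNDStatus(cat, n)


def is_impaired(score: float | None, spec: DomainSpec, *,
                sipt_inclusive: bool = False) -> bool | None:
    """Apply the instrument cutoff to one score; ``None`` stays ``None``."""
    if score is None:
        return None
    lo, hi = spec.valid_range
    if not lo <= score <= hi:
        raise ValueError(
            f"{spec.abbreviation}: score {score} outside valid range [{lo}, {hi}]")
    if spec.instrument in (Instrument.MABC2, Instrument.NEPSY2):
        return score <= 7
    if spec.instrument is Instrument.SIPT:
        return score <= -1.0 if sipt_inclusive else score < -1.0
    raise ValueError(f"{spec.abbreviation} is not scored directly")


def impute_group_median(cohort: CohortTable, domain: str,
                        group: Group | str) -> CohortTable:
    """Fill missing scores in one group/domain with the group median.

    Returns a new cohort; each filled cell is appended to the cohort's
    ``imputation_log``.  Idempotent: a cohort with no missing values in the
    target group/domain is returned unchanged (modulo the copy).
    """
    group = Group(group)
    cohort.registry[domain]  # validates the abbreviation
    if domain == "MND":
        raise ValueError("MND has no raw score to impute")
    observed = [c.scores[domain] for c in cohort.group(group)
                if domain in c.scores]
    if not observed:
        raise ValueError(
            f"no observed {domain} value in group {group.value}; cannot impute")
    med = statistics.median(observed)
    out = cohort.copy()
    for child in out.children:
        if child.group is group and domain not in child.scores:
            child.scores[domain] = med
            out.imputation_log.append((child.child_id, domain, med))
    return out


def impute_subtest_mean(record: ChildRecord, composite_members: list[str],
                        target: str) -> ChildRecord:
    """Fill a missing composite member with the mean of its observed siblings.

    Looks keys up in ``scores`` first, then ``aux_scores``; the target is
    written wherever its siblings live.  A record whose target is already
    observed is returned unchanged.
    """
    def lookup(key):
        if key in record.scores:
            return record.scores[key], "scores"
        if key in record.aux_scores:
            return record.aux_scores[key], "aux"
        return None, None

    if lookup(target)[0] is not None:
        return record
    values = [v for v, _ in (lookup(m) for m in composite_members if m != target)
              if v is not None]
    if not values:
        raise ValueError(
            f"{record.child_id}: no observed member of {composite_members} "
            f"to impute {target}")
    mean = sum(values) / len(values)
    new = replace(record, scores=dict(record.scores),
                  aux_scores=dict(record.aux_scores))
    bucket = ("scores" if target in set(new.scores) | {
        d for d in composite_members if d in new.scores} else "aux")
    if bucket == "scores":
        new.scores[target] = mean
    else:
        new.aux_scores[target] = mean
    return new


@dataclass
class ImpairmentMatrix:
    """Children x 20 boolean impairment calls with an observed mask.

    ``calls`` is ``False`` wherever ``observed`` is ``False``: a missing
    score never counts as impaired, and downstream denominators follow the
    observed mask.
    """

    child_ids: list[str]
    domains: tuple[str, ...]
    calls: np.ndarray  # bool, n x 20
    observed: np.ndarray  # bool, n x 20
    groups: np.ndarray  # object array of Group values
    registry: DomainRegistry

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.calls.shape != self.observed.shape:
            raise ValueError("calls and observed must have identical shape")
        if self.calls.shape != (len(self.child_ids), len(self.domains)):
            raise ValueError("matrix shape inconsistent with ids/domains")
        if np.any(self.calls & ~self.observed):
            raise ValueError("impairment call on an unobserved cell")

    def __len__(self) -> int:
        return len(self.child_ids)

    def group_mask(self, group: Group | str) -> np.ndarray:
        group = Group(group)
        return np.array([g == group for g in self.groups], dtype=bool)

    def column(self, domain: str) -> int:
        return self.domains.index(domain)

    def rates(self, group: Group | str) -> dict[str, float]:
        """Per-domain impairment rate over observed cells in one group."""
        m = self.group_mask(group)
        out = {}
        for j, d in enumerate(self.domains):
            obs = self.observed[m, j]
            out[d] = float(self.calls[m, j].sum() / obs.sum()) if obs.any() else float("nan")
        return out


def build_impairment_matrix(cohort: CohortTable, *,
                            sipt_inclusive: bool = False) -> ImpairmentMatrix:
    """Classify every child on all 20 domains.

    The MND column derives from the Touwen flags (simple + complex pooled);
    the 19 score columns apply the instrument cutoffs.  Missing inputs
    propagate to the observed mask.
    """
    registry = cohort.registry
    domains = registry.abbreviations
    n = len(cohort.children)
    calls = np.zeros((n, len(domains)), dtype=bool)
    observed = np.zeros((n, len(domains)), dtype=bool)
    for i, child in enumerate(cohort.children):
        for j, spec in enumerate(registry):
            if spec.abbreviation == "MND":
                status = classify_mnd(child.touwen_domains)
                if status is not None:
                    observed[i, j] = True
                    calls[i, j] = status.impaired
            else:
                verdict = is_impaired(child.score(spec.abbreviation), spec,
                                      sipt_inclusive=sipt_inclusive)
                if verdict is not None:
                    observed[i, j] = True
                    calls[i, j] = verdict
    groups = np.array([c.group for c in cohort.children], dtype=object)
    return ImpairmentMatrix(
        child_ids=[c.child_id for c in cohort.children],
        domains=domains, calls=calls, observed=observed,
        groups=groups, registry=registry)


def write_impairment_matrix(matrix: ImpairmentMatrix, path) -> None:
    """TSV writer: one row per child, cells 0/1/NA, registry column order."""
    with open(path, "w") as fh:
        fh.write("child_id\tgroup\t" + "\t".join(matrix.domains) + "\n")
        for i, cid in enumerate(matrix.child_ids):
            cells = [
                ("1" if matrix.calls[i, j] else "0") if matrix.observed[i, j] else "NA"
                for j in range(len(matrix.domains))
            ]
            fh.write(f"{cid}\t{matrix.groups[i].value}\t" + "\t".join(cells) + "\n")
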