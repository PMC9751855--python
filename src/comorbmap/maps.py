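"""Impairment-burden profiles and co-occurrence relationship maps.

The burden of a child is the number of domains (out of the 20) in which
they are impaired; the burden histogram per group is the bar-chart profile
of multimorbidity.  A relationship map is a graph over the 20 domains for
one group: each node carries the count of children impaired in that domain
and each edge the count of children impaired in *both* connected domains,
displayed only when the pair count reaches a threshold (1, 5 and 10 in the
reference analysis).  An "impaired test pair" is an unordered domain pair
whose pair count is at least the threshold.

Children with a missing call in either domain of a pair contribute nothing
to that pair, consistent with missing-never-impaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ImpairmentMatrix
from .cohort import Group
from .registry import DomainRegistry


@dataclass
class BurdenProfile:
    """Per-child impairment counts and the per-group histogram."""

    per_child: dict[str, int]
    groups: dict[str, str]  # child_id -> group label
    n_observed: dict[str, int]  # per child, observed-domain denominator

    def histogram(self, group: Group | str) -> dict[int, int]:
        label = Group(group).value
        out: dict[int, int] = {}
        for cid, b in self.per_child.items():
            if self.groups[cid] == label:
                out[b] = out.get(b, 0) + 1
        return dict(sorted(out.items()))

    def burdens(self, group: Group | str) -> list[int]:
        label = Group(group).value
        return [b for cid, b in self.per_child.items()
                if self.groups[cid] == label]

    def mean_burden(self, group: Group | str) -> float:
        vals = self.burdens(group)
        return float(np.mean(vals)) if vals else float("nan")

    def max_burden(self, group: Group | str) -> int:
        vals = self.burdens(group)
        if not vals:
            raise ValueError(f"group {Group(group).value} is empty")
        return max(vals)


def burden_profile(matrix: ImpairmentMatrix) -> BurdenProfile:
    """Count impaired domains per child (missing cells never count)."""
    if len(matrix) == 0:
        raise ValueError("empty impairment matrix")
    counts = matrix.calls.sum(axis=1)
    observed = matrix.observed.sum(axis=1)
    return BurdenProfile(
        per_child={cid: int(c) for cid, c in zip(matrix.child_ids, counts)},
        groups={cid: g.value for cid, g in zip(matrix.child_ids, matrix.groups)},
        n_observed={cid: int(o) for cid, o in zip(matrix.child_ids, observed)},
    )


@dataclass(frozen=True)
class ExceedanceResult:
    """Children whose burden strictly exceeds the reference group's max."""

    reference_group: str
    reference_max: int
    flagged: dict[str, bool]  # non-reference children only
    count: int
    proportion: float


def exceeds_reference_max(profile: BurdenProfile,
                          reference_group: Group | str = Group.TERM) -> ExceedanceResult:
    """Flag non-reference children with burden above the reference maximum."""
    ref = Group(reference_group).value
    ref_max = profile.max_burden(ref)
    flagged = {cid: b > ref_max for cid, b in profile.per_child.items()
               if profile.groups[cid] != ref}
    n = sum(flagged.values())
    return ExceedanceResult(
        reference_group=ref, reference_max=ref_max, flagged=flagged,
        count=n, proportion=n / len(flagged) if flagged else float("nan"))


@dataclass
class CooccurrenceGraph:
    """Node and pair counts of co-occurring impairments for one group."""

    domains: tuple[str, ...]
    node_counts: dict[str, int]
    pair_matrix: np.ndarray  # symmetric int matrix, zero diagonal
    group: str
    n_children: int
    registry: DomainRegistry
    thresholds: tuple[int, ...] = (1, 5, 10)

    def pair_count(self, d1: str, d2: str) -> int:
        i, j = self.domains.index(d1), self.domains.index(d2)
        if i == j:
            raise ValueError("pair counts are undefined on the diagonal")
        return int(self.pair_matrix[i, j])

    def max_pair_count(self) -> int:
        return int(self.pair_matrix.max(initial=0))

    def to_networkx(self, k: int = 1):
        """The thresholded map as a weighted :class:`networkx.Graph`."""
        import networkx as nx

        g = nx.Graph(group=self.group, threshold=k)
        for d in self.domains:
            g.add_node(d, count=self.node_counts[d])
        for d1, d2, c in edges_at_threshold(self, k):
            g.add_edge(d1, d2, weight=c)
        return g


def pair_counts(matrix: ImpairmentMatrix, group: Group | str) -> CooccurrenceGraph:
    """Count, for every unordered domain pair, children impaired in both."""
    mask = matrix.group_mask(group)
    if not mask.any():
        raise ValueError(f"group {Group(group).value} not present in matrix")
    calls = matrix.calls[mask].astype(np.int64)
    pair = calls.T @ calls
    np.fill_diagonal(pair, 0)
    node = {d: int(calls[:, j].sum()) for j, d in enumerate(matrix.domains)}
    return CooccurrenceGraph(
        domains=matrix.domains, node_counts=node, pair_matrix=pair,
        group=Group(group).value, n_children=int(mask.sum()),
        registry=matrix.registry)


def edges_at_threshold(graph: CooccurrenceGraph,
                       k: int) -> list[tuple[str, str, int]]:
    """Unordered pairs with pair count >= k, in registry layout order."""
    if k < 1:
        raise ValueError("threshold k must be >= 1")
    edges = []
    nd = len(graph.domains)
    for i in range(nd):
        for j in range(i + 1, nd):
            c = int(graph.pair_matrix[i, j])
            if c >= k:
                edges.append((graph.domains[i], graph.domains[j], c))
    return edges


def total_impaired_pairs(graph: CooccurrenceGraph, k: int = 1) -> int:
    """Number of distinct domain pairs with at least ``k`` co-occurring children."""
    return len(edges_at_threshold(graph, k))


def incidence_sum(graph: CooccurrenceGraph, k: int = 1) -> int:
    """Secondary statistic: summed child counts over pairs at threshold ``k``."""
    return sum(c for _, _, c in edges_at_threshold(graph, k))


@dataclass(frozen=True)
class JointImpairment:
    """Per-child conjunction of impairment over a set of domains."""

    domains: tuple[str, ...]
    per_child: dict[str, bool]
    evaluable: dict[str, bool]  # all listed domains observed
    group_counts: dict[str, int]
    group_evaluable: dict[str, int]
    group_sizes: dict[str, int]


def joint_impairment(matrix: ImpairmentMatrix,
                     domains: list[str]) -> JointImpairment:
    """True per child iff impaired in ALL listed domains (all observed)."""
    for d in domains:
        if d not in matrix.domains:
            raise KeyError(
                f"unknown domain {d!r}; valid: {', '.join(matrix.domains)}")
    cols = [matrix.column(d) for d in domains]
    all_obs = matrix.observed[:, cols].all(axis=1)
    all_imp = matrix.calls[:, cols].all(axis=1) & all_obs
    per_child = {cid: bool(v) for cid, v in zip(matrix.child_ids, all_imp)}
    evaluable = {cid: bool(v) for cid, v in zip(matrix.child_ids, all_obs)}
    counts: dict[str, int] = {}
    evals: dict[str, int] = {}
    sizes: dict[str, int] = {}
    for cid, g in zip(matrix.child_ids, matrix.groups):
        label = g.value
        sizes[label] = sizes.get(label, 0) + 1
        counts[label] = counts.get(label, 0) + per_child[cid]
        evals[label] = evals.get(label, 0) + evaluable[cid]
    return JointImpairment(tuple(domains), per_child, evaluable,
                           counts, evals, sizes)
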