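"""Two-step mixed-type clustering with a log-likelihood distance.

The engine mirrors the classic two-stage procedure: a single sequential
pass condenses records into preclusters (sufficient-statistic summaries),
then standard agglomerative merging of the preclusters builds a full merge
trace, and the number of clusters is selected with the Schwarz-Bayesian
information criterion (BIC), optionally refined by the jump in merge
distances. Cluster quality is reported as a mean silhouette computed with
the same log-likelihood distance.

Distance. For a cluster v over K_c continuous and K_k categorical
variables, define

    xi_v = -N_v * [ sum_k 1/2 * ln(s2_pooled_k + s2_vk) + sum_k E_vk ]

where s2_vk is the within-cluster (maximum-likelihood) variance of
continuous variable k, s2_pooled_k its variance over all data (an offset
that keeps the log finite on constant clusters), and E_vk the natural-log
entropy of categorical variable k within v. The distance between clusters
a and b is

    d(a, b) = xi_a + xi_b - xi_{a u b}  >= 0,

the decrease in log-likelihood caused by merging, under per-cluster
independence of variables. BIC for a partition into J clusters is

    BIC(J) = -2 * sum_v xi_v + m_J * ln N,
    m_J = J * (2*K_c + sum_k (L_k - 1)),

with L_k the number of categories of variable k in the whole dataset.
Missing values are excluded from a variable's entropy (and variance)
denominator; they are never imputed.

Records are mappings ``{variable: value}`` (``None`` = missing), described
by a :class:`VariableSchema`. For the frailty instrument all variables are
categorical indicator levels, but the continuous path is fully supported.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "VariableSchema",
    "ClusterSummary",
    "MergeTrace",
    "ClusterPartition",
    "RuleTable",
    "summarize",
    "loglik_distance",
    "precluster",
    "agglomerate",
    "bic",
    "select_k",
    "quality",
    "two_step",
    "derive_dimension_rules",
]

_TOL = 1e-9


@dataclass(frozen=True)
class VariableSchema:
    categorical: tuple[str, ...] = ()
    continuous: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.categorical and not self.continuous:
            raise ValueError("schema needs at least one variable")
        dup = set(self.categorical) & set(self.continuous)
        if dup:
            raise ValueError(f"variables declared both ways: {sorted(dup)}")

    @staticmethod
    def indicators(n: int, prefix: str = "x") -> "VariableSchema":
        """Schema for ``n`` positional categorical indicators."""
        return VariableSchema(categorical=tuple(f"{prefix}{i}" for i in range(n)))


@dataclass
class ClusterSummary:
    """Mergeable sufficient statistics of one cluster.

    ``categorical_counts[var]`` maps category -> count over non-missing
    members; ``continuous_sums[var]`` holds (count, sum, sum-of-squares)
    over non-missing members. ``summary(A u B)`` is the elementwise sum, so
    clustering can proceed from summaries alone.
    """

    n_members: int
    categorical_counts: dict[str, Counter]
    continuous_sums: dict[str, tuple[int, float, float]]
    members: list[int] = field(default_factory=list)

    def merge(self, other: "ClusterSummary") -> "ClusterSummary":
        if set(self.categorical_counts) != set(other.categorical_counts) or set(
            self.continuous_sums
        ) != set(other.continuous_sums):
            raise ValueError("cannot merge summaries over different variable sets")
        cats = {
            v: self.categorical_counts[v] + other.categorical_counts[v]
            for v in self.categorical_counts
        }
        conts = {
            v: tuple(
                a + b
                for a, b in zip(self.continuous_sums[v], other.continuous_sums[v])
            )
            for v in self.continuous_sums
        }
        return ClusterSummary(
            n_members=self.n_members + other.n_members,
            categorical_counts=cats,
            continuous_sums=conts,
            members=self.members + other.members,
        )


def summarize(
    records: Sequence[Mapping[str, Hashable]],
    schema: VariableSchema,
    members: Optional[Sequence[int]] = None,
) -> ClusterSummary:
    """Condense records into a :class:`ClusterSummary`."""
    if not records:
        raise ValueError("cannot summarize an empty cluster")
    cats: dict[str, Counter] = {v: Counter() for v in schema.categorical}
    conts: dict[str, tuple[int, float, float]] = {
        v: (0, 0.0, 0.0) for v in schema.continuous
    }
    for rec in records:
        for v in schema.categorical:
            val = rec.get(v)
            if val is not None:
                cats[v][val] += 1
        for v in schema.continuous:
            val = rec.get(v)
            if val is not None:
                n, s, ss = conts[v]
                conts[v] = (n + 1, s + float(val), ss + float(val) ** 2)
    return ClusterSummary(
        n_members=len(records),
        categorical_counts=cats,
        continuous_sums=conts,
        members=list(members) if members is not None else [],
    )


def _entropy(counter: Counter) -> float:
    total = sum(counter.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counter.values():
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def _variance(stats: tuple[int, float, float]) -> float:
    n, s, ss = stats
    if n == 0:
        return 0.0
    return max(ss / n - (s / n) ** 2, 0.0)


def _xi(summary: ClusterSummary, pooled_var: Mapping[str, float]) -> float:
    if summary.n_members == 0:
        raise ValueError("empty cluster")
    term = 0.0
    for v, stats in summary.continuous_sums.items():
        term += 0.5 * math.log(pooled_var[v] + _variance(stats))
    for counter in summary.categorical_counts.values():
        term += _entropy(counter)
    return -summary.n_members * term


def _pooled_variances(total: ClusterSummary) -> dict[str, float]:
    return {v: _variance(stats) for v, stats in total.continuous_sums.items()}


def loglik_distance(
    a: ClusterSummary,
    b: ClusterSummary,
    pooled_var: Optional[Mapping[str, float]] = None,
) -> float:
    """Log-likelihood merge cost d(a,b) = xi_a + xi_b - xi_{a u b} (>= 0).

    ``pooled_var`` (whole-data variance per continuous variable) is required
    only when continuous variables are present.
    """
    merged = a.merge(b)
    if pooled_var is None:
        if a.continuous_sums:
            pooled_var = _pooled_variances(merged)
        else:
            pooled_var = {}
    d = _xi(a, pooled_var) + _xi(b, pooled_var) - _xi(merged, pooled_var)
    if d < -_TOL:
        raise AssertionError(f"negative merge distance {d}")
    return max(d, 0.0)


# ------------------------------------------------------------ precluster --


def _singleton(rec: Mapping, schema: VariableSchema, index: int) -> ClusterSummary:
    return summarize([rec], schema, members=[index])


def precluster(
    records: Sequence[Mapping[str, Hashable]],
    schema: VariableSchema,
    distance_threshold: float = 0.0,
    max_preclusters: int = 512,
) -> list[ClusterSummary]:
    """Sequential preclustering pass.

    Each record joins its nearest existing precluster when the merge
    distance is within ``distance_threshold``, otherwise it founds a new
    one. If the precluster count overflows ``max_preclusters`` the threshold
    is raised by half and the preclusters are rebuilt from their own
    summaries. The default threshold 0 groups exactly the identical
    profiles, which is the natural granularity for ordinal indicator data.
    """
    if not records:
        raise ValueError("no records to precluster")
    if max_preclusters < 1:
        raise ValueError("max_preclusters must be positive")
    total = summarize(records, schema)
    pooled = _pooled_variances(total)
    items: list[ClusterSummary] = [
        _singleton(rec, schema, i) for i, rec in enumerate(records)
    ]
    threshold = float(distance_threshold)
    while True:
        clusters = _sequential_pass(items, threshold, pooled)
        if len(clusters) <= max_preclusters:
            return clusters
        threshold = threshold * 1.5 if threshold > 0 else 1.0
        items = clusters


def _sequential_pass(
    items: Sequence[ClusterSummary],
    threshold: float,
    pooled: Mapping[str, float],
) -> list[ClusterSummary]:
    clusters: list[ClusterSummary] = []
    for item in items:
        best_j, best_d = -1, math.inf
        for j, c in enumerate(clusters):
            d = loglik_distance(c, item, pooled)
            if d < best_d:
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= threshold + _TOL:
            clusters[best_j] = clusters[best_j].merge(item)
        else:
            clusters.append(item)
    return clusters


# ----------------------------------------------------------- agglomerate --


@dataclass
class MergeTrace:
    """Full greedy agglomeration of the preclusters down to one cluster.

    ``merges[t]`` = (id_a, id_b, distance) joins two active clusters into a
    new cluster with id ``n_preclusters + t`` (linkage convention); the
    distances are the minimum pairwise log-likelihood distance at each step.
    ``bic_by_k`` evaluates the criterion on the partition obtained by
    cutting the trace at every cluster count k.
    """

    n_preclusters: int
    merges: list[tuple[int, int, float]]
    bic_by_k: dict[int, float]
    selected_k: Optional[int] = None

    def partition_at(self, k: int) -> list[list[int]]:
        """Precluster index groups of the k-cluster cut of the trace."""
        if not 1 <= k <= self.n_preclusters:
            raise ValueError(f"k={k} outside [1, {self.n_preclusters}]")
        groups = {i: [i] for i in range(self.n_preclusters)}
        for t in range(self.n_preclusters - k):
            a, b, _ = self.merges[t]
            groups[self.n_preclusters + t] = groups.pop(a) + groups.pop(b)
        return [sorted(g) for g in sorted(groups.values())]


def agglomerate(preclusters: Sequence[ClusterSummary]) -> MergeTrace:
    """Greedy pairwise merging by minimum log-likelihood distance.

    Records every merge and its distance, and evaluates BIC at each cluster
    count on the way. Ties break on the lowest (a, b) id pair so the trace
    is deterministic.
    """
    if not preclusters:
        raise ValueError("no preclusters to agglomerate")
    m = len(preclusters)
    total = preclusters[0]
    for pc in preclusters[1:]:
        total = total.merge(pc)
    pooled = _pooled_variances(total)
    n_total = total.n_members
    m_per_cluster = _params_per_cluster(total)

    active: dict[int, ClusterSummary] = dict(enumerate(preclusters))
    merges: list[tuple[int, int, float]] = []
    bic_by_k = {m: _bic_of(active.values(), pooled, n_total, m_per_cluster)}
    next_id = m
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            d = loglik_distance(active[a], active[b], pooled)
            if best is None or d < best[0] - _TOL:
                best = (d, a, b)
        d, a, b = best
        active[next_id] = active.pop(a).merge(active.pop(b))
        merges.append((a, b, d))
        bic_by_k[len(active)] = _bic_of(active.values(), pooled, n_total, m_per_cluster)
        next_id += 1
    return MergeTrace(n_preclusters=m, merges=merges, bic_by_k=bic_by_k)


def _params_per_cluster(total: ClusterSummary) -> int:
    cats = sum(
        max(len(counter), 1) - 1 for counter in total.categorical_counts.values()
    )
    return 2 * len(total.continuous_sums) + cats


def _bic_of(
    summaries: Iterable[ClusterSummary],
    pooled: Mapping[str, float],
    n_total: int,
    m_per_cluster: int,
) -> float:
    summaries = list(summaries)
    ll = sum(_xi(s, pooled) for s in summaries)
    return -2.0 * ll + len(summaries) * m_per_cluster * math.log(n_total)


def bic(
    partition: Sequence[ClusterSummary],
    pooled_var: Optional[Mapping[str, float]] = None,
) -> float:
    """Schwarz-Bayesian criterion of an explicit partition (lower is better)."""
    if not partition:
        raise ValueError("empty partition")
    if any(s.n_members == 0 for s in partition):
        raise ValueError("empty cluster in partition")
    total = partition[0]
    for s in partition[1:]:
        total = total.merge(s)
    pooled = dict(pooled_var) if pooled_var is not None else _pooled_variances(total)
    return _bic_of(partition, pooled, total.n_members, _params_per_cluster(total))


# -------------------------------------------------------------- select_k --


def select_k(
    trace: MergeTrace,
    k_max: int = 15,
    k_fixed: Optional[int] = None,
) -> int:
    """Pick the number of clusters.

    A fixed k (the "defined in advance" mode) is honored as-is. Otherwise
    the k in [1, k_max] minimizing BIC wins; among k whose BIC is within 2%
    of the minimum, the one with the largest ratio of successive merge
    distances (cost of merging below k over cost of reaching k) is
    preferred — the classic distance-jump refinement. Ties go to the
    smallest k.
    """
    m = trace.n_preclusters
    if k_fixed is not None:
        if not 1 <= k_fixed <= m:
            raise ValueError(f"k_fixed={k_fixed} exceeds the {m} precluster(s)")
        trace.selected_k = k_fixed
        return k_fixed
    ks = [k for k in range(1, min(k_max, m) + 1)]
    bmin = min(trace.bic_by_k[k] for k in ks)
    band = abs(bmin) * 0.02
    candidates = [k for k in ks if trace.bic_by_k[k] <= bmin + band]
    if len(candidates) > 1:

        def ratio(k: int) -> float:
            # merges[m-k-1] creates the k-cluster solution; merges[m-k]
            # destroys it. Large ratio = k is a natural stopping point.
            if k == m or k == 1:
                return -math.inf
            d_reach = trace.merges[m - k - 1][2]
            d_below = trace.merges[m - k][2]
            if d_reach <= _TOL:
                return math.inf if d_below > _TOL else 0.0
            return d_below / d_reach

        best = max(candidates, key=lambda k: (ratio(k), -k))
        if math.isfinite(ratio(best)) or ratio(best) == math.inf:
            trace.selected_k = best
            return best
    trace.selected_k = min(k for k in candidates if trace.bic_by_k[k] == bmin)
    return trace.selected_k


# ---------------------------------------------------------------- quality --


@dataclass
class ClusterPartition:
    assignment: np.ndarray  # record index -> label in 1..k
    k: int
    quality: float

    def __post_init__(self) -> None:
        labels = set(int(v) for v in self.assignment)
        if labels and labels != set(range(1, self.k + 1)):
            raise ValueError("labels must be contiguous 1..k")


def quality(
    assignment: Sequence[int],
    records: Sequence[Mapping[str, Hashable]],
    schema: VariableSchema,
) -> float:
    """Mean silhouette under the log-likelihood distance, in [-1, 1].

    Distances are between singleton summaries; for the report scale the
    caller may clamp to [0, 1] (``max(q, 0.0)``). Computed on unique
    profiles with multiplicity weights, so it stays cheap on large cohorts
    of low-cardinality indicator data. Records in singleton clusters
    contribute silhouette 0, the usual convention.
    """
    assignment = np.asarray(assignment, dtype=int)
    if len(assignment) != len(records):
        raise ValueError("assignment and records lengths differ")
    labels = np.unique(assignment)
    if len(labels) < 2:
        raise ValueError("quality is undefined for fewer than 2 clusters")

    total = summarize(records, schema)
    pooled = _pooled_variances(total)

    def key(rec: Mapping) -> tuple:
        return tuple(rec.get(v) for v in schema.categorical) + tuple(
            rec.get(v) for v in schema.continuous
        )

    # weight of each (profile, label) pair
    weights: Counter = Counter()
    profiles: dict[tuple, ClusterSummary] = {}
    for i, rec in enumerate(records):
        k_ = key(rec)
        weights[(k_, int(assignment[i]))] += 1
        if k_ not in profiles:
            profiles[k_] = _singleton(rec, schema, i)
    uniq = sorted(profiles, key=repr)
    dmat = {
        (u, v): loglik_distance(profiles[u], profiles[v], pooled)
        for u, v in itertools.combinations(uniq, 2)
    }

    def dist(u: tuple, v: tuple) -> float:
        if u == v:
            return 0.0
        return dmat[(u, v)] if (u, v) in dmat else dmat[(v, u)]

    cluster_sizes = {int(l): int(np.sum(assignment == l)) for l in labels}
    s_total = 0.0
    for (u, lab), w in weights.items():
        n_own = cluster_sizes[lab]
        if n_own <= 1:
            continue  # silhouette 0
        # co-members with the same profile sit at distance 0, so summing
        # over all (v, lab) entries already handles them
        a = sum(wv * dist(u, v) for (v, lv), wv in weights.items() if lv == lab)
        a_mean = a / (n_own - 1)
        b_mean = math.inf
        for other in labels:
            other = int(other)
            if other == lab:
                continue
            b = sum(wv * dist(u, v) for (v, lv), wv in weights.items() if lv == other)
            b_mean = min(b_mean, b / cluster_sizes[other])
        denom = max(a_mean, b_mean)
        s = 0.0 if denom == 0 else (b_mean - a_mean) / denom
        s_total += w * s
    return s_total / len(records)


# ------------------------------------------------------------- pipeline ---


def two_step(
    records: Sequence[Mapping[str, Hashable]],
    schema: VariableSchema,
    k_fixed: Optional[int] = None,
    k_max: int = 15,
    distance_threshold: float = 0.0,
    max_preclusters: int = 512,
) -> tuple[ClusterPartition, MergeTrace]:
    """Precluster, agglomerate, select k, and assign records to clusters."""
    pcs = precluster(records, schema, distance_threshold, max_preclusters)
    trace = agglomerate(pcs)
    k = select_k(trace, k_max=k_max, k_fixed=k_fixed)
    groups = trace.partition_at(k)
    assignment = np.zeros(len(records), dtype=int)
    for label, group in enumerate(groups, start=1):
        for pc_idx in group:
            for rec_idx in pcs[pc_idx].members:
                assignment[rec_idx] = label
    q = quality(assignment, records, schema) if k >= 2 else float("nan")
    return ClusterPartition(assignment=assignment, k=k, quality=q), trace


# ------------------------------------------------------- dimension rules --


@dataclass(frozen=True)
class RuleTable:
    """Maps an observed indicator combination to its cluster-derived score.

    Unseen combinations map to the worst score — the conservative choice
    for a clinical alert.
    """

    dimension: str
    mapping: Mapping[tuple, int]
    worst: int

    def score_for(self, combo: Sequence) -> int:
        return self.mapping.get(tuple(combo), self.worst)

    def to_rows(self) -> list[tuple]:
        return sorted((*k, v) for k, v in self.mapping.items())


def derive_dimension_rules(
    partition: ClusterPartition,
    records: Sequence[Mapping[str, Hashable]],
    schema: VariableSchema,
    target_levels: int,
    dimension: str = "",
) -> RuleTable:
    """Turn a k-cluster partition of indicator combinations into scores.

    Clusters are ordered by mean indicator severity (the per-record sum of
    indicator levels, missing counted at the variable's worst observed
    level) and assigned scores 0 .. target_levels-1 in that order, so the
    mildest cluster scores 0.
    """
    if partition.k != target_levels:
        raise ValueError(
            f"partition has {partition.k} clusters but {target_levels} score "
            "levels were requested"
        )
    variables = schema.categorical + schema.continuous
    # severity encoding: numeric levels as-is; purely nominal variables get
    # deterministic 0..L-1 codes in sorted category order (their ordering is
    # arbitrary, but ties across clusters still break reproducibly)
    encode: dict[str, dict] = {}
    for v in variables:
        observed = sorted(
            {r[v] for r in records if r.get(v) is not None}, key=repr
        )
        try:
            encode[v] = {val: float(val) for val in observed}
        except (TypeError, ValueError):
            encode[v] = {val: float(i) for i, val in enumerate(observed)}
    worst_level = {v: max(encode[v].values(), default=0.0) for v in variables}

    def severity(rec: Mapping) -> float:
        return sum(
            encode[v][rec[v]] if rec.get(v) is not None else worst_level[v]
            for v in variables
        )

    by_label: dict[int, list[float]] = {l: [] for l in range(1, partition.k + 1)}
    combos: dict[int, set[tuple]] = {l: set() for l in by_label}
    for i, rec in enumerate(records):
        lab = int(partition.assignment[i])
        by_label[lab].append(severity(rec))
        combos[lab].add(tuple(rec.get(v) for v in variables))
    order = sorted(by_label, key=lambda l: (float(np.mean(by_label[l])), l))
    mapping: dict[tuple, int] = {}
    for score, lab in enumerate(order):
        for combo in combos[lab]:
            mapping[combo] = score
    return RuleTable(dimension=dimension, mapping=mapping, worst=target_levels - 1)
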