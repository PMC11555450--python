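"""Clustering engine: distance, preclustering, agglomeration, BIC, quality."""

import itertools
import math

import numpy as np
import pytest

from efrailch.twostep import (
    VariableSchema,
    agglomerate,
    bic,
    derive_dimension_rules,
    loglik_distance,
    precluster,
    quality,
    select_k,
    summarize,
    two_step,
)

BIN2 = VariableSchema.indicators(2)
BIN1 = VariableSchema(categorical=("x0",))


def recs(*rows, prefix="x"):
    return [{f"{prefix}{i}": v for i, v in enumerate(row)} for row in rows]


def random_summaries(rng, n_vars=3, n_rows=4):
    schema = VariableSchema.indicators(n_vars)
    rows = [
        {f"x{i}": int(rng.integers(0, 3)) for i in range(n_vars)}
        for _ in range(n_rows)
    ]
    return summarize(rows[: n_rows // 2], schema), summarize(rows[n_rows // 2 :], schema)


# ------------------------------------------------------------- distance ---


def test_identical_singletons_merge_at_zero_cost():
    a, b = (summarize(recs((0, 1)), BIN2) for _ in range(2))
    assert loglik_distance(a, b) == pytest.approx(0.0, abs=1e-12)


def test_one_binary_disagreement_costs_two_ln_two():
    # xi of each singleton is 0; the merged cluster has one 50/50 binary
    # variable, entropy ln 2 over 2 members -> xi_merged = -2 ln 2.
    a = summarize(recs((0,)), BIN1)
    b = summarize(recs((1,)), BIN1)
    assert loglik_distance(a, b) == pytest.approx(2 * math.log(2), rel=1e-12)


def test_distance_symmetric_and_nonnegative_on_random_summaries():
    rng = np.random.default_rng(3)
    for _ in range(20):
        a, b = random_summaries(rng)
        d1, d2 = loglik_distance(a, b), loglik_distance(b, a)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert d1 >= 0.0


def test_distance_with_continuous_variables_nonnegative():
    schema = VariableSchema(categorical=("c",), continuous=("z",))
    rows_a = [{"c": 0, "z": 0.1}, {"c": 0, "z": 0.3}]
    rows_b = [{"c": 1, "z": 2.0}, {"c": 1, "z": 2.2}]
    pooled = {"z": float(np.var([0.1, 0.3, 2.0, 2.2]))}
    d = loglik_distance(summarize(rows_a, schema), summarize(rows_b, schema), pooled)
    assert d > 0


def test_variable_set_mismatch_raises():
    a = summarize(recs((0,)), BIN1)
    b = summarize(recs((0, 1)), BIN2)
    with pytest.raises(ValueError):
        loglik_distance(a, b)


def test_summary_mergeability():
    schema = VariableSchema.indicators(2)
    rows = recs((0, 1), (1, 1), (0, 0), (2, 1))
    merged = summarize(rows[:2], schema).merge(summarize(rows[2:], schema))
    direct = summarize(rows, schema)
    assert merged.n_members == direct.n_members
    assert merged.categorical_counts == direct.categorical_counts


# ------------------------------------------------------------ precluster --


def test_two_distinct_profiles_give_two_preclusters():
    rows = recs(*([(0, 0)] * 5 + [(2, 2)] * 5))
    pcs = precluster(rows, BIN2, distance_threshold=0.5)
    assert len(pcs) == 2
    assert sorted(pc.n_members for pc in pcs) == [5, 5]


def test_identical_records_collapse_to_one_precluster():
    rows = recs(*([(1, 1)] * 8))
    assert len(precluster(rows, BIN2)) == 1


def test_infinite_threshold_always_merges():
    rng = np.random.default_rng(0)
    rows = recs(*[tuple(rng.integers(0, 3, 2)) for _ in range(15)])
    assert len(precluster(rows, BIN2, distance_threshold=math.inf)) == 1


def test_precluster_cap_raises_threshold_and_rebuilds():
    rng = np.random.default_rng(1)
    rows = recs(*[tuple(rng.integers(0, 3, size=3)) for _ in range(60)],
                prefix="x")
    schema = VariableSchema.indicators(3)
    pcs = precluster(rows, schema, distance_threshold=0.0, max_preclusters=5)
    assert len(pcs) <= 5
    assert sum(pc.n_members for pc in pcs) == 60
    # membership survives the rebuild
    assert sorted(i for pc in pcs for i in pc.members) == list(range(60))


def test_precluster_empty_input_raises():
    with pytest.raises(ValueError):
        precluster([], BIN2)


# ----------------------------------------------------------- agglomerate --


def test_first_merge_joins_the_closest_pair():
    # clusters of identical profiles at "positions" 0, 1, 4 on one ordinal
    # variable: 0 and 1 overlap-free but closest in entropy terms
    schema = VariableSchema(categorical=("x0",))
    rows = recs((0,), (0,), (1,), (1,), (4,), (4,))
    pcs = precluster(rows, schema)
    assert len(pcs) == 3
    trace = agglomerate(pcs)
    # all three pairwise merge costs are equal for purely nominal data,
    # so the tie-break must pick the lowest id pair
    assert trace.merges[0][:2] == (0, 1)


def test_single_precluster_gives_empty_trace():
    pcs = precluster(recs((0, 0), (0, 0)), BIN2)
    trace = agglomerate(pcs)
    assert trace.merges == []
    assert trace.n_preclusters == 1


def test_greedy_merge_is_global_minimum_at_each_step():
    """On <=8 preclusters every greedy merge must pick the globally closest
    pair (brute force over all active pairs)."""
    rng = np.random.default_rng(8)
    schema = VariableSchema.indicators(3)
    for trial in range(5):
        rows = recs(*[tuple(rng.integers(0, 3, 3)) for _ in range(30)])
        pcs = precluster(rows, schema)[:8]
        if len(pcs) < 3:
            continue
        trace = agglomerate(pcs)
        active = {i: pcs[i] for i in range(len(pcs))}
        next_id = len(pcs)
        for a, b, dist in trace.merges:
            best = min(
                loglik_distance(active[i], active[j])
                for i, j in itertools.combinations(sorted(active), 2)
            )
            assert dist == pytest.approx(best, abs=1e-9)
            active[next_id] = active.pop(a).merge(active.pop(b))
            next_id += 1


# ------------------------------------------------------------------ BIC ---


def test_bic_hand_value_one_cluster_binary_half_split():
    # xi = -4 ln 2; BIC = -2 xi + 1 * (2-1) * ln 4 = 8 ln 2 + ln 4
    summary = summarize(recs((0,), (0,), (1,), (1,)), BIN1)
    expected = 8 * math.log(2) + math.log(4)
    assert bic([summary]) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(6.9315, abs=1e-4)


def test_bic_zero_entropy_equals_penalty_only():
    rows = recs(*([(1, 2)] * 6))
    summary = summarize(rows, BIN2)
    # one category observed per variable -> L_k - 1 = 0 -> penalty 0
    assert bic([summary]) == pytest.approx(0.0, abs=1e-12)
    # with two observed categories the penalty is m_J ln N
    rows = recs(*([(1, 1)] * 5 + [(0, 0)] * 1))
    one = summarize(rows, BIN2)
    split = [summarize(rows[:5], BIN2), summarize(rows[5:], BIN2)]
    assert bic(split) == pytest.approx(2 * 2 * math.log(6), rel=1e-12)


def test_bic_prefers_splitting_separated_groups():
    rows = recs(*([(0, 0, 0)] * 20 + [(2, 2, 2)] * 20))
    schema = VariableSchema.indicators(3)
    whole = summarize(rows, schema)
    halves = [summarize(rows[:20], schema), summarize(rows[20:], schema)]
    assert bic(halves) < bic([whole])


# ------------------------------------------------------------- select_k ---


def test_two_profile_groups_select_two_clusters():
    rows = recs(*([(0, 0, 0)] * 20 + [(2, 2, 2)] * 20))
    schema = VariableSchema.indicators(3)
    trace = agglomerate(precluster(rows, schema))
    assert select_k(trace) == 2


def test_identical_records_select_one_cluster():
    trace = agglomerate(precluster(recs(*([(1, 1)] * 10)), BIN2))
    assert select_k(trace) == 1


def test_k_fixed_is_honored_and_validated():
    rng = np.random.default_rng(4)
    rows = recs(*[tuple(rng.integers(0, 3, 2)) for _ in range(40)])
    trace = agglomerate(precluster(rows, BIN2))
    assert trace.n_preclusters >= 3
    assert select_k(trace, k_fixed=3) == 3
    with pytest.raises(ValueError):
        select_k(trace, k_fixed=trace.n_preclusters + 1)


def _set_partitions(items):
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def test_bic_optimal_k_matches_exhaustive_partition_search():
    """For <=8 distinct profiles the k chosen from the greedy trace must
    equal the cluster count of the globally BIC-optimal set partition."""
    schema = VariableSchema.indicators(3)
    rows = recs(
        *([(0, 0, 0)] * 12 + [(0, 0, 1)] * 9 + [(2, 2, 2)] * 10 + [(2, 2, 1)] * 8)
    )
    pcs = precluster(rows, schema)
    assert 2 <= len(pcs) <= 8
    best_bic, best_k = math.inf, None
    for part in _set_partitions(list(range(len(pcs)))):
        summaries = []
        for group in part:
            s = pcs[group[0]]
            for idx in group[1:]:
                s = s.merge(pcs[idx])
            summaries.append(s)
        b = bic(summaries)
        if b < best_bic - 1e-9:
            best_bic, best_k = b, len(part)
    trace = agglomerate(pcs)
    k = select_k(trace)
    assert k == best_k
    assert min(trace.bic_by_k.values()) == pytest.approx(best_bic, rel=1e-9)


def test_bic_by_k_matches_direct_evaluation_of_cut_partitions():
    rng = np.random.default_rng(12)
    rows = recs(*[tuple(rng.integers(0, 2, 3)) for _ in range(50)])
    schema = VariableSchema.indicators(3)
    pcs = precluster(rows, schema)
    trace = agglomerate(pcs)
    for k in range(1, trace.n_preclusters + 1):
        groups = trace.partition_at(k)
        summaries = []
        for g in groups:
            s = pcs[g[0]]
            for idx in g[1:]:
                s = s.merge(pcs[idx])
            summaries.append(s)
        assert trace.bic_by_k[k] == pytest.approx(bic(summaries), rel=1e-9)


# -------------------------------------------------------------- quality ---


def test_pure_separated_clusters_have_quality_one():
    rows = recs(*([(0, 0)] * 4 + [(2, 2)] * 4))
    labels = [1] * 4 + [2] * 4
    assert quality(labels, rows, BIN2) == pytest.approx(1.0)


def test_quality_matches_brute_force_silhouette():
    rows = recs((0, 0), (0, 1), (0, 0), (2, 2), (2, 1), (1, 2))
    labels = [1, 1, 1, 2, 2, 2]
    # brute force from the full pairwise distance matrix
    singles = [summarize([r], BIN2) for r in rows]
    d = [[loglik_distance(a, b) if i != j else 0.0 for j, b in enumerate(singles)]
         for i, a in enumerate(singles)]
    sil = []
    for i in range(6):
        own = [j for j in range(6) if labels[j] == labels[i] and j != i]
        other = [j for j in range(6) if labels[j] != labels[i]]
        a = sum(d[i][j] for j in own) / len(own)
        b = sum(d[i][j] for j in other) / len(other)
        sil.append((b - a) / max(a, b))
    assert quality(labels, rows, BIN2) == pytest.approx(np.mean(sil), abs=1e-12)


def test_random_labels_on_homogeneous_data_score_low():
    rng = np.random.default_rng(9)
    rows = recs(*[tuple(rng.integers(0, 2, 4)) for _ in range(60)])
    schema = VariableSchema.indicators(4)
    qs = []
    for seed in range(10):
        labels = np.random.default_rng(seed).integers(1, 3, size=60)
        if len(set(labels)) < 2:
            continue
        qs.append(quality(labels, rows, schema))
    assert np.mean(qs) <= 0.1


def test_quality_requires_two_clusters():
    with pytest.raises(ValueError):
        quality([1, 1, 1], recs((0, 0), (0, 1), (1, 1)), BIN2)


# ------------------------------------------------------ rules / pipeline --


def test_rule_scores_follow_severity_order():
    rows = recs(*([(0, 0, 0, 0)] * 10 + [(0, 0, 1, 1)] * 8 + [(2, 2, 2, 2)] * 6))
    schema = VariableSchema.indicators(4)
    partition, trace = two_step(rows, schema, k_fixed=3)
    assert partition.k == 3
    table = derive_dimension_rules(partition, rows, schema, target_levels=3,
                                   dimension="cognition")
    assert table.score_for((0, 0, 0, 0)) == 0
    assert table.score_for((0, 0, 1, 1)) == 1
    assert table.score_for((2, 2, 2, 2)) == 2
    # unseen combinations fall to the worst score
    assert table.score_for((1, 0, 2, 1)) == 2


def test_single_combination_clusters_give_bijection():
    rows = recs((0, 0), (1, 1), (2, 2))
    partition, _ = two_step(rows, BIN2, k_fixed=3)
    table = derive_dimension_rules(partition, rows, BIN2, target_levels=3)
    scores = {table.score_for(tuple(r.values())) for r in rows}
    assert scores == {0, 1, 2}


def test_rule_table_level_mismatch_raises():
    rows = recs(*([(0, 0)] * 5 + [(1, 1)] * 5))
    partition, _ = two_step(rows, BIN2, k_fixed=2)
    with pytest.raises(ValueError):
        derive_dimension_rules(partition, rows, BIN2, target_levels=3)


def test_two_step_assignment_is_contiguous_and_complete():
    rng = np.random.default_rng(21)
    rows = recs(*[tuple(rng.integers(0, 3, 4)) for _ in range(80)])
    schema = VariableSchema.indicators(4)
    partition, trace = two_step(rows, schema, k_max=6)
    assert len(partition.assignment) == 80
    assert set(partition.assignment) == set(range(1, partition.k + 1))
    assert trace.selected_k == partition.k
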