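"""Aggregation, max-normalization, ranking and reference-panel classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from secscreen.phenotype import (
    ReferencePanel,
    SPRecord,
    aggregate_replicates,
    classify_clone,
    collapse_repeated,
    distinguishability_groups,
    normalize_by_max,
    rank_sps,
)


def test_aggregate_replicates_closed_forms():
    assert aggregate_replicates([5, 5, 5]) == (5.0, 0.0)
    mean, sd = aggregate_replicates([4, 6])
    assert (mean, sd) == (5.0, pytest.approx(np.sqrt(2)))
    assert aggregate_replicates([3.2]) == (3.2, 0.0)
    with pytest.raises(ValueError):
        aggregate_replicates([])


def test_aggregate_recovers_normal_parameters_within_three_se():
    rng = np.random.default_rng(77)
    mu, sigma, n = 5.0, 1.5, 4000
    mean, sd = aggregate_replicates(rng.normal(mu, sigma, n).tolist())
    assert abs(mean - mu) < 3 * sigma / np.sqrt(n)
    assert abs(sd - sigma) < 3 * sigma / np.sqrt(2 * (n - 1))


def test_fixture_normalization_anchors(cg_records):
    normed = {r.sp_id: r for r in normalize_by_max(cg_records) if r.sp_id in ("Epr", "Vpr", "LipB")}
    # Epr appears twice; the 13.1 isolate is the series maximum
    assert max(r.relative_activity_pct for r in normalize_by_max(cg_records)) == 100.0
    vpr = [r for r in normalize_by_max(cg_records) if r.sp_id == "Vpr"][0]
    assert vpr.relative_activity_pct == pytest.approx(80.2, abs=0.1)
    lipb = [r for r in normalize_by_max(cg_records) if r.sp_id == "LipB"][0]
    assert lipb.relative_activity_pct == pytest.approx(70.2, abs=0.1)


@given(scale=st.floats(0.01, 1000.0))
def test_normalization_scale_invariance(scale):
    base = [
        SPRecord("a", "h", 2.0, 0.2),
        SPRecord("b", "h", 8.0, 0.4),
        SPRecord("c", "h", 4.0, 0.1),
    ]
    scaled = [
        SPRecord(r.sp_id, r.host, r.mean_activity * scale, r.sd_activity * scale) for r in base
    ]
    for r1, r2 in zip(normalize_by_max(base), normalize_by_max(scaled)):
        assert r1.relative_activity_pct == pytest.approx(r2.relative_activity_pct, rel=1e-9)


def test_normalization_idempotent_and_per_host(cg_records, bs_records):
    once = normalize_by_max(cg_records + bs_records)
    twice = normalize_by_max(once)
    assert [r.relative_activity_pct for r in once] == [r.relative_activity_pct for r in twice]
    # each host series gets its own maximum
    for host in ("C_glutamicum", "B_subtilis"):
        assert max(r.relative_activity_pct for r in once if r.host == host) == 100.0


def test_normalization_rejects_dead_series():
    with pytest.raises(ValueError):
        normalize_by_max([SPRecord("a", "h", 0.0), SPRecord("b", "h", 0.0)])


def test_ranking_fixture_top3_and_edge_cases(cg_records):
    ranked = rank_sps(cg_records)
    assert [r.sp_id for r in ranked[:3]] == ["Epr", "YwfM", "Bpr"]
    single = [SPRecord("x", "h", 1.0)]
    assert rank_sps(single) == single
    seq = [SPRecord(s, "h", v) for s, v in zip("abcd", (1.0, 2.0, 3.0, 4.0))]
    assert [r.sp_id for r in rank_sps(seq)] == ["d", "c", "b", "a"]
    # ties break lexicographically
    tied = [SPRecord("z", "h", 2.0), SPRecord("a", "h", 2.0)]
    assert [r.sp_id for r in rank_sps(tied)] == ["a", "z"]


def test_collapse_repeated_averages_isolates(cg_records):
    collapsed = {r.sp_id: r for r in collapse_repeated(cg_records)}
    assert collapsed["Epr"].mean_activity == pytest.approx((13.1 + 7.8) / 2)
    assert collapsed["YwfM"].mean_activity == pytest.approx(11.2)
    assert len(collapsed) == 40  # distinct SPs in the table


def test_classification_self_consistency(panel):
    """Every panel mean classified against its own panel finds itself."""
    for sp_id, mean, _ in panel.entries:
        res = classify_clone(mean, panel, k_sigma=2.0)
        assert sp_id in res.assigned
        assert not res.nearest_only


def test_best_sp_identified_safely_but_overlapping_pair_is_ambiguous(panel):
    """The top secretor is a safe singleton call; the two phenotypically
    overlapping panel strains cannot be resolved by activity alone."""
    by_id = {sp: (m, sd) for sp, m, sd in panel.entries}
    res = classify_clone(by_id["NprE"][0], panel, k_sigma=2.0)
    assert res.assigned == frozenset({"NprE"}) and res.unambiguous
    midway = (by_id["AmyE"][0] + by_id["YwmC"][0]) / 2
    res = classify_clone(midway, panel, k_sigma=2.0)
    assert res.assigned == frozenset({"AmyE", "YwmC"})


def test_single_entry_panel_always_assigns_it():
    panel1 = ReferencePanel((("OnlySP", 3.0, 0.5),))
    far = classify_clone(30.0, panel1, k_sigma=2.0)
    assert far.assigned == frozenset({"OnlySP"}) and far.nearest_only


def test_distinguishability_groups(panel):
    groups = distinguishability_groups(panel, k_sigma=2.0)
    non_singletons = [g for g in groups if len(g) > 1]
    assert non_singletons == [frozenset({"AmyE", "YwmC"})]
    disjoint = ReferencePanel((("a", 0.0, 0.1), ("b", 10.0, 0.1), ("c", 20.0, 0.1)))
    assert all(len(g) == 1 for g in distinguishability_groups(disjoint, 2.0))
    identical = ReferencePanel((("a", 5.0, 0.5), ("b", 5.0, 0.5), ("c", 5.0, 0.5)))
    assert distinguishability_groups(identical, 2.0) == [frozenset({"a", "b", "c"})]


def test_classification_accuracy_at_four_sigma_separation():
    """Panel means 4 combined SDs apart: >= 95% of noisy clones classify
    correctly at k_sigma = 2 (candidate set contains the true identity)."""
    sd = 0.5
    means = [2.0 + i * 4 * np.sqrt(2) * sd for i in range(5)]
    panel = ReferencePanel(tuple((f"sp{i}", m, sd) for i, m in enumerate(means)))
    rng = np.random.default_rng(101)
    n, correct = 2000, 0
    for _ in range(n):
        true_idx = rng.integers(0, len(means))
        activity = rng.normal(means[true_idx], sd)
        res = classify_clone(activity, panel, k_sigma=2.0, clone_sd=sd)
        if f"sp{true_idx}" in res.assigned:
            correct += 1
    assert correct / n >= 0.95


def test_classify_validation(panel):
    with pytest.raises(ValueError):
        classify_clone(1.0, panel, k_sigma=0.0)
    with pytest.raises(ValueError):
        ReferencePanel(())
    with pytest.raises(ValueError):
        ReferencePanel((("a", 1.0, -0.1),))
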