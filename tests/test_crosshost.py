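"""Cross-host pairing, correlation and concordance labelling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from secscreen.crosshost import (
    PairedSPRecord,
    concordance_classes,
    correlation,
    pair_hosts,
)
from secscreen.phenotype import SPRecord, normalize_by_max


def pearson_oracle(xs, ys):
    """Hand-coded product-moment coefficient (independent of scipy)."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(xs, ys):
    return pearson_oracle(midranks(xs), midranks(ys))


@pytest.fixture(scope="module")
def campaign_pairs(campaign_table):
    """Pairs built from the fixture's *printed* relative activities."""
    records = {"a": [], "b": []}
    for _, r in campaign_table.frame.iterrows():
        key = "a" if r["host"] == "C_glutamicum" else "b"
        records[key].append(
            SPRecord(
                sp_id=r["sp_id"],
                host=r["host"],
                mean_activity=float(r["activity_U_per_mL"]),
                relative_activity_pct=float(r["relative_pct"]),
            )
        )
    pairs, _, _ = pair_hosts(records["a"], records["b"])
    return pairs


def test_pairing_matches_printed_rows(campaign_pairs):
    by_sp = {p.sp_id: p for p in campaign_pairs}
    assert (by_sp["YwfM"].rel_host_a, by_sp["YwfM"].rel_host_b) == (85.5, 7.7)
    assert (by_sp["Pel"].rel_host_a, by_sp["Pel"].rel_host_b) == (14.5, 57.2)
    assert len(campaign_pairs) == 40


def test_identical_series_pair_on_the_diagonal():
    recs = normalize_by_max(
        [SPRecord(s, "h", v) for s, v in zip("abc", (1.0, 2.0, 4.0))]
    )
    other = [SPRecord(r.sp_id, "h2", r.mean_activity, relative_activity_pct=r.relative_activity_pct) for r in recs]
    pairs, only_a, only_b = pair_hosts(recs, other)
    assert all(p.rel_host_a == p.rel_host_b for p in pairs)
    assert only_a == only_b == []


def test_pairing_requires_normalized_series(cg_records, bs_records):
    with pytest.raises(ValueError):
        pair_hosts(cg_records, normalize_by_max(bs_records))


def test_perfect_and_inverted_correlation():
    up = [PairedSPRecord(f"s{i}", float(x), float(x)) for i, x in enumerate((5, 30, 60, 90))]
    down = [PairedSPRecord(f"s{i}", float(x), 100.0 - x) for i, x in enumerate((5, 30, 60, 90))]
    cu, cd = correlation(up), correlation(down)
    assert (cu.pearson_r, cu.spearman_rho) == (pytest.approx(1.0), pytest.approx(1.0))
    assert (cd.pearson_r, cd.spearman_rho) == (pytest.approx(-1.0), pytest.approx(-1.0))


def test_correlation_matches_independent_oracle(campaign_pairs):
    xs = [p.rel_host_a for p in campaign_pairs]
    ys = [p.rel_host_b for p in campaign_pairs]
    summary = correlation(campaign_pairs)
    assert summary.pearson_r == pytest.approx(pearson_oracle(xs, ys), abs=1e-12)
    assert summary.spearman_rho == pytest.approx(spearman_oracle(xs, ys), abs=1e-12)
    assert -1.0 <= summary.pearson_r <= 1.0 and -1.0 <= summary.spearman_rho <= 1.0


@given(a=st.floats(0.01, 0.9), b=st.floats(0.0, 5.0))
def test_correlation_invariant_under_positive_affine_maps(a, b):
    base = [PairedSPRecord(f"s{i}", float(x), float(y))
            for i, (x, y) in enumerate([(5, 80), (30, 20), (60, 55), (90, 10), (45, 45)])]
    mapped = [PairedSPRecord(p.sp_id, a * p.rel_host_a + b, p.rel_host_b) for p in base]
    c0, c1 = correlation(base), correlation(mapped)
    assert c0.pearson_r == pytest.approx(c1.pearson_r, rel=1e-9)
    assert c0.spearman_rho == pytest.approx(c1.spearman_rho, rel=1e-9)


def test_zero_variance_reported_as_undefined():
    flat = [PairedSPRecord(f"s{i}", 50.0, float(y)) for i, y in enumerate((1, 2, 3))]
    summary = correlation(flat)
    assert summary.undefined_reason is not None
    assert math.isnan(summary.pearson_r)
    with pytest.raises(ValueError):
        correlation(flat[:2])


def test_spearman_recovers_generating_rank_correlation():
    """Bivariate normal with Pearson r = 2 sin(pi*rho/6) has population
    Spearman rho; the estimate lands within ~3 SE."""
    rho = 0.5
    r = 2 * math.sin(math.pi * rho / 6)
    n = 800
    rng = np.random.default_rng(55)
    z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
    # squash into [0, 100] monotonically: Spearman is rank-invariant
    from scipy.special import expit

    pairs = [
        PairedSPRecord(f"s{i}", 100 * expit(x), 100 * expit(y)) for i, (x, y) in enumerate(z)
    ]
    est = correlation(pairs).spearman_rho
    se = 1.03 / math.sqrt(n - 3)
    assert abs(est - rho) < 3 * se


def test_concordance_labels_for_study_examples(campaign_pairs):
    labelled, counts = concordance_classes(campaign_pairs)
    by_sp = {p.sp_id: p.concordance_class for p in labelled}
    assert by_sp["YwfM"] == "discordant_a_high"  # strong in C. glutamicum only
    assert by_sp["Bpr"] == "concordant_high"
    assert sum(counts.values()) == len(campaign_pairs)


def test_concordance_edge_and_symmetry():
    pairs = [
        PairedSPRecord("dead", 0.0, 0.0),
        PairedSPRecord("aonly", 90.0, 5.0),
        PairedSPRecord("bonly", 5.0, 90.0),
        PairedSPRecord("both", 80.0, 70.0),
    ]
    labelled, _ = concordance_classes(pairs)
    by_sp = {p.sp_id: p.concordance_class for p in labelled}
    assert by_sp == {
        "dead": "concordant_low",
        "aonly": "discordant_a_high",
        "bonly": "discordant_b_high",
        "both": "concordant_high",
    }
    swapped = [PairedSPRecord(p.sp_id, p.rel_host_b, p.rel_host_a) for p in pairs]
    labelled_swap, _ = concordance_classes(swapped)
    flip = {"discordant_a_high": "discordant_b_high", "discordant_b_high": "discordant_a_high"}
    for p, q in zip(labelled, labelled_swap):
        assert q.concordance_class == flip.get(p.concordance_class, p.concordance_class)
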