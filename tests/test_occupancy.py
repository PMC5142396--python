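"""Closed-form occupancy model against brute-force enumeration and scipy."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import binom

from secscreen.occupancy import (
    LibraryDesign,
    MultiplicityDistribution,
    PickPlan,
    coverage_probability,
    expected_multiplicity_spectrum,
    multiplicity_pmf,
    required_picks,
    round_half_away,
)


def enumerate_campaigns(n, N):
    """Exhaustive enumeration of all N^n equiprobable pick sequences.

    Returns (pmf over member-0 multiplicity, coverage of member 0,
    mean multiplicity spectrum).  Independent oracle for every closed form.
    """
    pmf = np.zeros(n + 1)
    covered = 0
    spectrum = np.zeros(n + 1)
    total = N**n
    for seq in itertools.product(range(N), repeat=n):
        counts = np.bincount(seq, minlength=N)
        pmf[counts[0]] += 1
        if counts[0] >= 1:
            covered += 1
        for m in range(n + 1):
            spectrum[m] += np.count_nonzero(counts == m)
    return pmf / total, covered / total, spectrum / total


@pytest.mark.parametrize("n,N", [(4, 2), (5, 3), (6, 3), (7, 4)])
def test_closed_forms_match_exhaustive_enumeration(n, N):
    pmf_oracle, coverage_oracle, spectrum_oracle = enumerate_campaigns(n, N)
    for m in range(n + 1):
        assert multiplicity_pmf(n, N, m) == pytest.approx(pmf_oracle[m], abs=1e-12)
    assert coverage_probability(n, N) == pytest.approx(coverage_oracle, abs=1e-12)
    spectrum = expected_multiplicity_spectrum(n, N)
    for m in range(n + 1):
        assert spectrum[m] == pytest.approx(spectrum_oracle[m], abs=1e-10)


@pytest.mark.parametrize("n,N,m", [(66, 148, 0), (66, 148, 1), (66, 148, 5), (30, 7, 12)])
def test_pmf_matches_independent_binomial(n, N, m):
    assert multiplicity_pmf(n, N, m) == pytest.approx(binom.pmf(m, n, 1 / N), rel=1e-12)


def test_campaign_scale_probabilities():
    """Per-SP hit probabilities for the 66-of-148 campaign; the exact binomial
    yields 0.287/0.063/0.009/0.001 at three decimals for m=1..4."""
    values = [round_half_away(multiplicity_pmf(66, 148, m), 3) for m in range(1, 5)]
    assert values == [0.287, 0.063, 0.009, 0.001]


def test_zero_picks_and_degenerate_weight():
    assert multiplicity_pmf(0, 148, 0) == 1.0
    assert multiplicity_pmf(10, 5, 10, weight=1.0) == 1.0


@pytest.mark.parametrize(
    "call",
    [
        lambda: multiplicity_pmf(5, 3, 6),
        lambda: multiplicity_pmf(5, 3, -1),
        lambda: multiplicity_pmf(5, 0, 1),
        lambda: coverage_probability(-1, 10),
        lambda: required_picks(1.0, 10),
        lambda: required_picks(-0.1, 10),
    ],
)
def test_domain_errors(call):
    with pytest.raises(ValueError):
        call()


@given(n=st.integers(0, 400), N=st.integers(1, 500))
def test_pmf_normalization(n, N):
    assert math.fsum(multiplicity_pmf(n, N, m) for m in range(n + 1)) == pytest.approx(
        1.0, abs=1e-9
    )


@given(n=st.integers(0, 300), N=st.integers(2, 300))
def test_coverage_monotone_in_picks_and_library_size(n, N):
    before, after = coverage_probability(n, N), coverage_probability(n + 1, N)
    assert after >= before
    if before < 1.0 - 1e-12:  # strictly increasing until float saturation
        assert after > before
    assert coverage_probability(n, N) >= coverage_probability(n, N + 1)


@pytest.mark.parametrize("k", [1, 3, 4])
def test_coverage_depends_only_on_oversampling_asymptotically(k):
    limit = 1.0 - math.exp(-k)
    errs = [abs(coverage_probability(k * N, N) - limit) for N in (50, 500, 5000)]
    assert errs[0] > errs[1] > errs[2]
    assert errs[2] < 1e-4


def test_threefold_and_fourfold_oversampling_coverage():
    assert round_half_away(coverage_probability(3 * 148, 148), 2) == 0.95
    assert round_half_away(coverage_probability(4 * 148, 148), 2) == 0.98


@given(target=st.floats(0.0, 0.999), N=st.integers(1, 400))
def test_required_picks_is_minimal(target, N):
    n = required_picks(target, N)
    assert coverage_probability(n, N) >= target
    if n > 0:
        assert coverage_probability(n - 1, N) < target


def test_required_picks_edges():
    assert required_picks(0.0, 148) == 0
    assert required_picks(0.5, 1) == 1
    # linear-scan oracle at the design point
    n_scan = 0
    while coverage_probability(n_scan, 148) < 0.95:
        n_scan += 1
    assert required_picks(0.95, 148) == n_scan


def test_expected_spectrum_conserves_picks():
    spectrum = expected_multiplicity_spectrum(66, 148)
    assert sum(m * v for m, v in spectrum.items()) == pytest.approx(66.0, abs=1e-9)
    assert spectrum[1] == pytest.approx(148 * multiplicity_pmf(66, 148, 1))


def test_library_design_validation():
    uniform = LibraryDesign(4)
    assert uniform.uniform and np.allclose(uniform.weights, 0.25)
    with pytest.raises(ValueError):
        LibraryDesign(0)
    with pytest.raises(ValueError):
        LibraryDesign(3, np.array([0.5, 0.6, 0.1]))
    with pytest.raises(ValueError):
        LibraryDesign(2, np.array([-0.1, 1.1]))


def test_pick_plan_and_multiplicity_distribution_invariants():
    plan = PickPlan(66, 148)
    assert plan.oversampling_factor == pytest.approx(66 / 148)
    md = MultiplicityDistribution({1: 25, 2: 9, 3: 5, 4: 2}, n_picks=66)
    assert sum(m * c for m, c in md.counts.items()) == 66
    with pytest.raises(ValueError):
        MultiplicityDistribution({1: 10}, n_picks=66)


def test_round_half_away_matches_printed_convention():
    assert round_half_away(0.2874, 3) == 0.287
    assert round_half_away(0.95073, 2) == 0.95
    assert round_half_away(0.0635, 3) == 0.064
    assert round_half_away(-0.0635, 3) == -0.064
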