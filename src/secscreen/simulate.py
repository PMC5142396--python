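"""Monte-Carlo simulation of the clone-picking process.

One campaign is ``n`` independent categorical draws from the library's weight
vector; a replicate study repeats the campaign many times and summarises the
per-multiplicity member counts (min/mean/max), mirroring how picking
simulations are used to judge whether an observed multiplicity census is
compatible with an equiprobable library transfer.

Seed policy: every replicate ``i`` of a study draws from its own substream
``numpy.random.default_rng([seed, i])``.  Adding replicates therefore never
changes earlier ones, and any single replicate can be regenerated in
isolation.  ``simulate_picks(plan, library, seed)`` is replicate 0 of the
study with that seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy import LibraryDesign, MultiplicityDistribution, PickPlan

__all__ = [
    "SimulationResult",
    "simulate_picks",
    "replicate_campaigns",
    "empirical_relative_occurrence",
    "member_multiplicity_frequency",
    "dirichlet_weights",
]


@dataclass(frozen=True)
class SimulationResult:
    """Replicate campaign spectra plus a per-multiplicity range summary.

    ``summary`` has one row per multiplicity ``m`` observed in any replicate,
    with columns ``count_min``, ``count_mean``, ``count_max`` (members hit
    exactly ``m`` times) and ``relative_occurrence_mean`` (mean of
    ``count/n_picks``).
    """

    replicate_spectra: list[MultiplicityDistribution]
    summary: pd.DataFrame
    seed: int

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_spectra)


def _campaign_rng(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(replicate)])


def _draw_members(
    rng: np.random.Generator, n_picks: int, weights: np.ndarray
) -> np.ndarray:
    """n independent categorical draws of member indices.

    Shared by the simulator and the synthetic-campaign generator so that a
    generated campaign's multiplicity spectrum is exactly a simulator draw.
    """
    return rng.choice(len(weights), size=n_picks, p=weights)


def _draw_member_counts(
    rng: np.random.Generator, n_picks: int, weights: np.ndarray
) -> np.ndarray:
    """n independent categorical draws, returned as per-member hit counts."""
    return np.bincount(_draw_members(rng, n_picks, weights), minlength=len(weights))


def _census(member_counts: np.ndarray, n_picks: int) -> MultiplicityDistribution:
    hit = member_counts[member_counts > 0]
    mult, n_members = np.unique(hit, return_counts=True)
    return MultiplicityDistribution(
        counts=dict(zip(mult.tolist(), n_members.tolist())),
        n_picks=n_picks,
        member_counts=member_counts,
    )


def simulate_picks(
    plan: PickPlan, library: LibraryDesign, seed: int, *, replicate: int = 0
) -> MultiplicityDistribution:
    """Simulate one picking campaign and return its multiplicity census.

    The returned distribution retains ``member_counts`` so that per-member
    questions (e.g. "was member 0 hit exactly once?") remain answerable.
    Identical ``(seed, replicate)`` gives bit-identical results.
    """
    if plan.library_size != library.n_members:
        raise ValueError(
            f"plan is for a library of {plan.library_size} members, "
            f"got one with {library.n_members}"
        )
    rng = _campaign_rng(seed, replicate)
    member_counts = _draw_member_counts(rng, plan.n_picks, library.weights)
    return _census(member_counts, plan.n_picks)


def replicate_campaigns(
    plan: PickPlan, library: LibraryDesign, replicates: int, seed: int
) -> SimulationResult:
    """Run ``replicates`` independent campaigns and summarise their spectra.

    The per-``m`` mean member count converges (at the usual 1/sqrt(R) rate) to
    ``expected_multiplicity_spectrum`` under uniform weights; min/max give the
    "number range" a single real campaign may plausibly produce.
    """
    if int(replicates) != replicates or replicates < 1:
        raise ValueError(f"replicates must be a positive integer, got {replicates}")
    spectra = [
        simulate_picks(plan, library, seed, replicate=i) for i in range(replicates)
    ]
    all_m = sorted({m for s in spectra for m in s.counts})
    rows = []
    for m in all_m:
        counts = np.array([s.counts.get(m, 0) for s in spectra])
        rows.append(
            {
                "m": m,
                "count_min": int(counts.min()),
                "count_mean": float(counts.mean()),
                "count_max": int(counts.max()),
                "relative_occurrence_mean": float(counts.mean() / plan.n_picks)
                if plan.n_picks
                else np.nan,
            }
        )
    summary = pd.DataFrame(rows, columns=["m", "count_min", "count_mean", "count_max", "relative_occurrence_mean"]).set_index("m")
    return SimulationResult(replicate_spectra=spectra, summary=summary, seed=int(seed))


def empirical_relative_occurrence(
    observed: MultiplicityDistribution | dict[int, int], n_picks: int | None = None
) -> dict[int, float]:
    """Relative occurrence of members hit exactly ``m`` times: count / picks.

    The denominator is the number of *picked clones*, not the number of
    members — this is the convention used when a sequenced campaign is
    compared against per-member probabilities, and it is kept distinct from
    ``multiplicity_pmf`` on purpose.  ``n_picks`` may be given explicitly for
    censuses whose rows are known to be incomplete (e.g. a transcribed table
    listing fewer rows than clones were sequenced).
    """
    if isinstance(observed, MultiplicityDistribution):
        counts = observed.counts
        n = observed.n_picks if n_picks is None else int(n_picks)
    else:
        counts = {int(m): int(c) for m, c in observed.items()}
        n = sum(m * c for m, c in counts.items()) if n_picks is None else int(n_picks)
    if n < 1:
        raise ValueError("relative occurrence needs at least one pick")
    return {m: c / n for m, c in sorted(counts.items())}


def member_multiplicity_frequency(
    plan: PickPlan,
    library: LibraryDesign,
    member: int,
    m: int,
    replicates: int,
    seed: int,
) -> tuple[float, float]:
    """Fraction of replicate campaigns in which ``member`` is hit exactly ``m`` times.

    Streams over the same per-replicate substreams as ``replicate_campaigns``
    (so both views of a study agree draw for draw) without retaining the
    spectra.  Returns ``(frequency, monte_carlo_standard_error)``.
    """
    if not 0 <= member < library.n_members:
        raise ValueError(f"member index {member} outside library of {library.n_members}")
    if int(replicates) != replicates or replicates < 1:
        raise ValueError(f"replicates must be a positive integer, got {replicates}")
    hits = 0
    for i in range(replicates):
        rng = _campaign_rng(seed, i)
        counts = _draw_member_counts(rng, plan.n_picks, library.weights)
        if counts[member] == m:
            hits += 1
    freq = hits / replicates
    se = float(np.sqrt(freq * (1.0 - freq) / replicates))
    return freq, se


def dirichlet_weights(
    n_members: int, concentration: float, seed: int
) -> np.ndarray:
    """Symmetric-Dirichlet weight vector modelling unequal member abundance.

    ``concentration`` is the single overdispersion knob: large values
    approach uniform weights, small values concentrate probability on few
    members (as after biased pooled cloning).
    """
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    rng = np.random.default_rng([int(seed), 0x5EC])
    return rng.dirichlet(np.full(n_members, float(concentration)))
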