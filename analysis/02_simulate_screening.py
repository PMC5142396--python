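#!/usr/bin/env python
"""Monte-Carlo simulation of the clone-picking procedure.

Simulates many replicate campaigns of 66 picks from a 148-member library and
compares the per-multiplicity member-count ranges with the closed-form
expectation, both for an equiprobable library and for one with
Dirichlet-overdispersed member weights (unequal plasmid abundance after
pooled cloning), which inflates repeat hits — one candidate explanation for
empirical multiple-hit rates running above the equiprobable model.
"""

import numpy as np
import pandas as pd

from secscreen.io import write_csv_atomic
from secscreen.occupancy import LibraryDesign, PickPlan, expected_multiplicity_spectrum
from secscreen.simulate import dirichlet_weights, replicate_campaigns

N, PICKS, REPLICATES, SEED = 148, 66, 10_000, 1


def main() -> None:
    plan = PickPlan(PICKS, N)
    expected = expected_multiplicity_spectrum(PICKS, N)

    uniform = replicate_campaigns(plan, LibraryDesign(N), REPLICATES, SEED)
    biased_lib = LibraryDesign(N, dirichlet_weights(N, concentration=1.0, seed=SEED))
    biased = replicate_campaigns(plan, biased_lib, REPLICATES, SEED)

    table = uniform.summary.join(
        biased.summary, lsuffix="_uniform", rsuffix="_dirichlet", how="outer"
    )
    table["expected_members_uniform"] = [expected.get(m, 0.0) for m in table.index]
    write_csv_atomic(table.reset_index(), "results/simulation_spectra.csv")

    print(f"{REPLICATES} simulated campaigns of {PICKS} picks from {N} members (seed {SEED}):")
    for m in sorted(expected):
        if expected[m] < 0.05 and m > 0:
            continue
        row = uniform.summary.loc[m] if m in uniform.summary.index else None
        if row is not None and m >= 1:
            print(
                f"  m={m}: members hit exactly m times "
                f"range [{int(row['count_min'])}, {int(row['count_max'])}], "
                f"mean {row['count_mean']:.2f} vs analytic {expected[m]:.2f}"
            )

    def repeats(result):
        return np.mean(
            [sum(c for m, c in s.counts.items() if m >= 2) for s in result.replicate_spectra]
        )

    print(
        f"Members hit >= twice per campaign: uniform {repeats(uniform):.2f}, "
        f"Dirichlet-biased {repeats(biased):.2f} — abundance bias inflates repeat hits."
    )
    print("Wrote results/simulation_spectra.csv")


if __name__ == "__main__":
    main()
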