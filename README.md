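# secscreen

Statistics and data reduction for signal-peptide (SP) library screening
campaigns in secretory protein expression.

When a library of N Sec signal peptides fused to a target enzyme is
transformed into an expression host, single colonies are picked at random,
cultivated, and scored by extracellular enzyme activity. `secscreen`
implements the quantitative backbone of such a campaign:

* **Occupancy / coverage design** — picking is sampling with replacement, so
  the number of times a designated library member is recovered among *n*
  picks is `X ~ Binomial(n, 1/N)`:
  `P(X = m) = C(n, m) (1/N)^m (1 − 1/N)^(n−m)`, and coverage
  `P(X ≥ 1) = 1 − (1 − 1/N)^n ≈ 1 − e^(−n/N)` for large N. Threefold
  oversampling covers a member with probability ≈ 0.95, fourfold ≈ 0.98.
* **Monte-Carlo screening simulation** — replicate campaigns with uniform or
  Dirichlet-biased member weights, with per-multiplicity member-count ranges.
* **Kinetic assay reduction** — p-nitrophenylpalmitate (pNPP) traces (A410
  every 25 s) reduced to volumetric cutinase activity via OLS slope,
  blanking, and Beer–Lambert conversion
  `activity [U/mL] = slope/(ε·d) · (V_rxn/V_smp) · dilution`
  with ε = 15 cm²/µmol; U/mL is numerically identical to kU/L.
* **Phenotyping** — replicate aggregation (mean, sample SD), per-host
  max-normalization to relative activities, ranking, and interval-overlap
  classification of unknown clones against a reference panel.
* **Cross-host comparison** — per-SP pairing of relative activities between
  two hosts, Pearson/Spearman correlation, and concordant/discordant labels
  for SPs whose performance does or does not transfer between hosts.

A transcription of a published two-host cutinase screening table
ships as a fixture, and a synthetic-campaign generator (library weights,
true activities, picks, replicate noise, kinetic traces) makes every stage
testable end to end with a known ground truth.

## Worked example

```python
>>> from secscreen import multiplicity_pmf, coverage_probability, required_picks
>>> [round(multiplicity_pmf(66, 148, m), 3) for m in (1, 2, 3, 4)]
[0.287, 0.063, 0.009, 0.001]
>>> round(coverage_probability(3 * 148, 148), 3)
0.951
>>> required_picks(0.95, 148)
442
```

Picking 66 clones from a 148-member library, a given SP is recovered exactly
once with probability 0.287 and twice with 0.063; covering any designated SP
with 95% probability needs 442 picks (threefold oversampling).

The analysis drivers under `analysis/` (numbered in pipeline order) rerun
the campaign analyses and write tables under `results/`. For example:

```
$ python analysis/05_crosshost_comparison.py
Paired 40 SPs across hosts (unmatched: 0 vs 0).
Pearson r = 0.566, Spearman rho = 0.628
Concordance classes: {'concordant_high': 4, 'concordant_low': 26, 'discordant_a_high': 10, 'discordant_b_high': 0}
Discordant SPs (strong in one host only):
  ...
  YwfM: C. glutamicum 85.5% vs B. subtilis 8.5%
```

Ten of 40 SPs secrete well in one host and poorly in the other — the
practical reason an SP library must be re-screened when the expression host
changes. (The positive rank correlation is driven by SPs inactive in both
hosts; see `docs/methods.md`.)

A `secscreen` command-line tool exposes the same stages
(`design | simulate | assay | phenotype | classify | compare | synth | run`);
try `secscreen design -N 148 -n 66`.

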