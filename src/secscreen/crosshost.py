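"""Cross-host comparison of per-SP secretion performance.

Relative activities (percent of each host's own series maximum) are paired
per signal peptide between two expression hosts, summarised by Pearson and
Spearman correlation, and labelled by a concordance class:

* ``discordant_a_high`` / ``discordant_b_high`` — the two relatives differ by
  more than a fold-ratio threshold (denominators floored to avoid blow-up
  near zero); these are the "diametrical" SPs that perform well in one host
  and poorly in the other.
* ``concordant_high`` / ``concordant_low`` — otherwise, split by whether both
  relatives clear a high-performance threshold.

No significance test is attached: with campaign-sized SP panels the absence
of correlation is an effect-size statement, so both coefficients are always
reported and left to the reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

from .phenotype import SPRecord, collapse_repeated

__all__ = [
    "PairedSPRecord",
    "ComparisonSummary",
    "CONCORDANCE_CLASSES",
    "pair_hosts",
    "correlation",
    "concordance_classes",
]

CONCORDANCE_CLASSES = (
    "concordant_high",
    "concordant_low",
    "discordant_a_high",
    "discordant_b_high",
)


@dataclass(frozen=True)
class PairedSPRecord:
    sp_id: str
    rel_host_a: float
    rel_host_b: float
    concordance_class: str | None = None

    def __post_init__(self) -> None:
        for v in (self.rel_host_a, self.rel_host_b):
            if not -1e-9 <= v <= 100 + 1e-9:
                raise ValueError("relative activities must lie in [0, 100] percent")
        if self.concordance_class is not None and self.concordance_class not in CONCORDANCE_CLASSES:
            raise ValueError(f"unknown concordance class {self.concordance_class!r}")


@dataclass(frozen=True)
class ComparisonSummary:
    pearson_r: float
    spearman_rho: float
    n_pairs: int
    class_counts: dict[str, int]
    undefined_reason: str | None = None

    def __post_init__(self) -> None:
        if self.undefined_reason is None:
            for name, v in (("pearson_r", self.pearson_r), ("spearman_rho", self.spearman_rho)):
                if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                    raise ValueError(f"{name} outside [-1, 1]: {v}")


def pair_hosts(
    records_a: list[SPRecord],
    records_b: list[SPRecord],
    *,
    collapse: bool = True,
) -> tuple[list[PairedSPRecord], list[str], list[str]]:
    """Inner-join two max-normalized host series on sp_id.

    Repeated isolates of an SP are collapsed by the mean of their relative
    activities before joining (``collapse=False`` keeps only SPs that are
    unique in both series, for a per-clone view).  Returns the pairs plus the
    sp_ids present only in one host.
    """
    for name, recs in (("a", records_a), ("b", records_b)):
        if any(r.relative_activity_pct is None for r in recs):
            raise ValueError(f"host {name} series must be max-normalized before pairing")
    if collapse:
        records_a = collapse_repeated(records_a)
        records_b = collapse_repeated(records_b)
    else:
        records_a = [r for r in records_a if sum(x.sp_id == r.sp_id for x in records_a) == 1]
        records_b = [r for r in records_b if sum(x.sp_id == r.sp_id for x in records_b) == 1]
    rel_a = {r.sp_id: r.relative_activity_pct for r in records_a}
    rel_b = {r.sp_id: r.relative_activity_pct for r in records_b}
    shared = sorted(rel_a.keys() & rel_b.keys())
    if not shared:
        raise ValueError("no shared sp_ids between the two host series")
    pairs = [PairedSPRecord(sp, rel_a[sp], rel_b[sp]) for sp in shared]
    only_a = sorted(rel_a.keys() - rel_b.keys())
    only_b = sorted(rel_b.keys() - rel_a.keys())
    return pairs, only_a, only_b


def correlation(pairs: list[PairedSPRecord]) -> ComparisonSummary:
    """Pearson on the relative values and Spearman on mid-ranked ranks."""
    if len(pairs) < 3:
        raise ValueError(f"correlation needs at least 3 pairs, got {len(pairs)}")
    xs = [p.rel_host_a for p in pairs]
    ys = [p.rel_host_b for p in pairs]
    counts = _count_classes(pairs)
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return ComparisonSummary(
            pearson_r=math.nan,
            spearman_rho=math.nan,
            n_pairs=len(pairs),
            class_counts=counts,
            undefined_reason="zero variance in at least one host series",
        )
    pearson = float(stats.pearsonr(xs, ys).statistic)
    spearman = float(stats.spearmanr(xs, ys).statistic)
    return ComparisonSummary(pearson, spearman, len(pairs), counts)


def _count_classes(pairs: list[PairedSPRecord]) -> dict[str, int]:
    counts = {c: 0 for c in CONCORDANCE_CLASSES}
    for p in pairs:
        if p.concordance_class is not None:
            counts[p.concordance_class] += 1
    return counts


def concordance_classes(
    pairs: list[PairedSPRecord],
    high_threshold_pct: float = 50.0,
    ratio_threshold: float = 4.0,
    *,
    floor_pct: float = 2.0,
) -> tuple[list[PairedSPRecord], dict[str, int]]:
    """Label each pair and tally the classes.

    A pair is discordant when the floored relatives differ by more than
    ``ratio_threshold``-fold; the floor (percentage points) keeps ratios
    finite for SPs inactive in one host.  Swapping hosts exchanges the two
    discordant labels and fixes the concordant ones.
    """
    if high_threshold_pct <= 0 or ratio_threshold <= 0 or floor_pct <= 0:
        raise ValueError("thresholds must be positive")
    labelled = []
    for p in pairs:
        fa = max(p.rel_host_a, floor_pct)
        fb = max(p.rel_host_b, floor_pct)
        if fa / fb > ratio_threshold:
            cls = "discordant_a_high"
        elif fb / fa > ratio_threshold:
            cls = "discordant_b_high"
        elif p.rel_host_a >= high_threshold_pct and p.rel_host_b >= high_threshold_pct:
            cls = "concordant_high"
        else:
            cls = "concordant_low"
        labelled.append(replace(p, concordance_class=cls))
    return labelled, _count_classes(labelled)
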