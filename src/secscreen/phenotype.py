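"""Replicate aggregation, max-normalization, ranking and clone classification.

Secretion phenotypes are summarised per signal peptide (SP) and host as the
mean and sample SD of replicate extracellular activities, expressed both in
U/mL and as *relative activity*: percent of the maximum mean within the same
host's data series.  Normalization is always per host series — relative
values are never compared across hosts except through the dedicated
cross-host module.

Classification of a clone with unknown insert against a reference panel of
strains with known inserts uses an interval-overlap rule: a panel entry is a
candidate when the clone activity falls within ``mean ± k·sd`` (SDs of clone
and panel entry combined in quadrature).  Panel entries whose intervals
mutually overlap form indistinguishability groups — phenotyping alone cannot
resolve them and plasmid sequencing is required.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from statistics import fmean

import numpy as np

__all__ = [
    "SPRecord",
    "ReferencePanel",
    "ClassificationResult",
    "aggregate_replicates",
    "normalize_by_max",
    "rank_sps",
    "classify_clone",
    "distinguishability_groups",
    "collapse_repeated",
]


@dataclass(frozen=True)
class SPRecord:
    """Per-SP, per-host aggregated activity; repeated isolates stay separate rows."""

    sp_id: str
    host: str
    mean_activity: float
    sd_activity: float = 0.0
    n_replicates: int = 0
    replicate_activities: tuple[float, ...] = ()
    relative_activity_pct: float | None = None
    relative_sd_pct: float | None = None

    def __post_init__(self) -> None:
        if self.sd_activity < 0:
            raise ValueError("SD must be non-negative")
        if self.relative_activity_pct is not None and not -1e-9 <= self.relative_activity_pct <= 100 + 1e-9:
            raise ValueError("relative activity must lie in [0, 100] percent")

    @classmethod
    def from_replicates(cls, sp_id: str, host: str, values: list[float]) -> "SPRecord":
        mean, sd = aggregate_replicates(values)
        return cls(
            sp_id=sp_id,
            host=host,
            mean_activity=mean,
            sd_activity=sd,
            n_replicates=len(values),
            replicate_activities=tuple(float(v) for v in values),
        )


@dataclass(frozen=True)
class ReferencePanel:
    """Known-insert strains anchoring classification; includes a no-insert control."""

    entries: tuple[tuple[str, float, float], ...]  # (sp_id, mean, sd)

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("a reference panel needs at least one entry")
        if any(sd < 0 for _, _, sd in self.entries):
            raise ValueError("panel SDs must be non-negative")
        ids = [sp for sp, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("panel sp_ids must be unique")

    @property
    def sp_ids(self) -> tuple[str, ...]:
        return tuple(sp for sp, _, _ in self.entries)


@dataclass(frozen=True)
class ClassificationResult:
    clone_id: str
    assigned: frozenset[str]
    score_per_candidate: dict[str, float] = field(compare=False)
    nearest_only: bool = False

    @property
    def unambiguous(self) -> bool:
        return len(self.assigned) == 1 and not self.nearest_only


def aggregate_replicates(values: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator; 0 for a single value)."""
    if len(values) == 0:
        raise ValueError("cannot aggregate an empty replicate list")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd


def normalize_by_max(records: list[SPRecord]) -> list[SPRecord]:
    """Attach relative activities: 100 × mean / max(mean), one host series at a time.

    The argmax record gets exactly 100.0; SDs are scaled by the same factor.
    Idempotent, and invariant under rescaling of the whole series.
    """
    if not records:
        return []
    hosts = {r.host for r in records}
    if len(hosts) > 1:
        out: list[SPRecord] = []
        for host in sorted(hosts):
            out.extend(normalize_by_max([r for r in records if r.host == host]))
        return out
    max_mean = max(r.mean_activity for r in records)
    if max_mean <= 0:
        raise ValueError("cannot normalize a series whose maximum activity is not positive")
    return [
        replace(
            r,
            relative_activity_pct=100.0 * r.mean_activity / max_mean,
            relative_sd_pct=100.0 * r.sd_activity / max_mean,
        )
        for r in records
    ]


def rank_sps(records: list[SPRecord]) -> list[SPRecord]:
    """Sort descending by mean activity; ties break lexicographically by sp_id."""
    return sorted(records, key=lambda r: (-r.mean_activity, r.sp_id))


def collapse_repeated(records: list[SPRecord]) -> list[SPRecord]:
    """Collapse repeated isolates of the same SP (within a host) by the mean.

    Means — and relative activities, when present — are averaged with equal
    weight per isolate; the collapsed SD is the mean of the isolate SDs (a
    summary of assay precision, not a pooled estimate).
    """
    out: list[SPRecord] = []
    for host in sorted({r.host for r in records}):
        by_sp: dict[str, list[SPRecord]] = {}
        for r in records:
            if r.host == host:
                by_sp.setdefault(r.sp_id, []).append(r)
        for sp_id, group in sorted(by_sp.items()):
            rel = (
                fmean(g.relative_activity_pct for g in group)
                if all(g.relative_activity_pct is not None for g in group)
                else None
            )
            out.append(
                SPRecord(
                    sp_id=sp_id,
                    host=host,
                    mean_activity=fmean(g.mean_activity for g in group),
                    sd_activity=fmean(g.sd_activity for g in group),
                    n_replicates=sum(g.n_replicates for g in group),
                    relative_activity_pct=rel,
                )
            )
    return out


def _combined_sd(panel_sd: float, clone_sd: float) -> float:
    return math.hypot(panel_sd, clone_sd)


def classify_clone(
    activity: float,
    panel: ReferencePanel,
    k_sigma: float = 2.0,
    *,
    clone_sd: float = 0.0,
    clone_id: str = "clone",
) -> ClassificationResult:
    """Assign candidate SP identities to a clone from its activity alone.

    A panel entry is a candidate when ``|activity - mean| <= k_sigma * s``
    with ``s`` the quadrature combination of the entry's SD and the clone's
    own SD.  Scores are standardized distances ``|activity - mean| / s``.
    If no interval contains the activity the nearest entry (by standardized
    distance, ties broken lexicographically) is returned with
    ``nearest_only=True`` — an assignment is always made, but flagged.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    if clone_sd < 0:
        raise ValueError("clone SD must be non-negative")
    scores: dict[str, float] = {}
    candidates: set[str] = set()
    for sp_id, mean, sd in panel.entries:
        s = _combined_sd(sd, clone_sd)
        dist = abs(activity - mean)
        scores[sp_id] = dist / s if s > 0 else (0.0 if dist == 0 else math.inf)
        if dist <= k_sigma * s or (s == 0 and dist == 0):
            candidates.add(sp_id)
    if candidates:
        return ClassificationResult(clone_id, frozenset(candidates), scores, nearest_only=False)
    nearest = min(scores, key=lambda sp: (scores[sp], sp))
    return ClassificationResult(clone_id, frozenset({nearest}), scores, nearest_only=True)


def distinguishability_groups(
    panel: ReferencePanel, k_sigma: float = 2.0
) -> list[frozenset[str]]:
    """Partition panel SPs into groups of mutually confusable phenotypes.

    Two entries overlap when their ``mean ± k_sigma·sd`` intervals intersect,
    i.e. ``|m_i - m_j| <= k_sigma (sd_i + sd_j)``; groups are the transitive
    closure of pairwise overlap.  Any group of size > 1 marks phenotypes that
    activity alone cannot separate (sequencing required).
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    ids = list(panel.sp_ids)
    parent = {sp: sp for sp in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (sp_i, m_i, sd_i) in enumerate(panel.entries):
        for sp_j, m_j, sd_j in panel.entries[i + 1 :]:
            if abs(m_i - m_j) <= k_sigma * (sd_i + sd_j):
                parent[find(sp_i)] = find(sp_j)
    groups: dict[str, set[str]] = {}
    for sp in ids:
        groups.setdefault(find(sp), set()).add(sp)
    return sorted((frozenset(g) for g in groups.values()), key=lambda g: sorted(g)[0])
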