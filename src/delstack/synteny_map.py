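"""Synteny-anchored deletion-interval inference and conservation calls.

Deletion mutants produced by heavy-ion irradiation lose contiguous blocks of
sequence.  The physical extent of a deletion removing a target gene can be
bracketed by assaying the intactness of a panel of flanking markers laid out
at known distances in a syntenic model genome: the deletion covers at least
the outermost markers shown to be deleted (minimum span) and at most the gap
between the nearest flanking markers shown to be intact (maximum span).
Markers with no informative call are skipped on both bounds; if no intact
marker exists on one side, the maximum is open on that side.

The module also classifies per-gene synteny conservation from generic
homology-hit tables (conserved / translocated / uncertain) and sums unique
scaffold lengths to estimate the physical size of a conserved region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

__all__ = [
    "Marker",
    "MarkerPanel",
    "IntactnessProfile",
    "DeletionInterval",
    "SyntenyHit",
    "SyntenyCall",
    "ScaffoldRecord",
    "infer_deletion_interval",
    "classify_synteny",
    "estimate_region_size",
]

INTACT = "intact"
DELETED = "deleted"
UNKNOWN = "unknown"
_STATUSES = {INTACT, DELETED, UNKNOWN}


@dataclass(frozen=True)
class Marker:
    """A flanking-marker gene at a signed kb offset from the anchor.

    Negative offsets are "Up" (towards the distal end of the short arm),
    positive offsets "Down"; the anchor gene sits at offset 0.
    """

    gene_id: str
    offset_kb: float
    label: str = ""


@dataclass
class MarkerPanel:
    """Ordered marker panel including the anchor at offset 0."""

    markers: List[Marker]

    def __post_init__(self) -> None:
        offsets = [m.offset_kb for m in self.markers]
        if len(set(offsets)) != len(offsets):
            raise ValueError("marker offsets must be unique within a panel")
        if 0.0 not in offsets:
            raise ValueError("panel must contain the anchor marker at offset 0")
        self.markers = sorted(self.markers, key=lambda m: m.offset_kb)

    @property
    def anchor(self) -> Marker:
        return next(m for m in self.markers if m.offset_kb == 0.0)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def by_gene(self) -> Dict[str, Marker]:
        return {m.gene_id: m for m in self.markers}


@dataclass
class IntactnessProfile:
    """Per-marker intact/deleted/unknown calls for one mutant x subgenome."""

    mutant_id: str
    subgenome: str
    calls: Dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.calls.values() if s not in _STATUSES}
        if bad:
            raise ValueError(f"invalid intactness statuses: {sorted(bad)}")


@dataclass
class DeletionInterval:
    """Bracketed deletion span in kb.

    ``max_size`` is None when the deleted run extends past the last assayed
    marker with no intact marker beyond it on at least one side (open-ended).
    """

    min_size: float
    max_size: Optional[float]
    up_bound_marker: str
    down_bound_marker: str
    up_open: bool = False
    down_open: bool = False
    up_edge_kb: float = 0.0  # outermost deleted marker offsets (the min bracket)
    down_edge_kb: float = 0.0

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise ValueError("min_size must be non-negative")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")


def infer_deletion_interval(
    profile: IntactnessProfile, panel: MarkerPanel
) -> DeletionInterval:
    """Bracket a deletion span from flanking-marker intactness calls.

    The minimum span runs between the outermost deleted markers of the
    contiguous deleted run containing the anchor (unknown calls are
    transparent; an intact call terminates the run).  The maximum span
    extends, on each side, to the nearest marker beyond the run with a
    definite intact call; if none exists the maximum is open on that side.
    Deleted markers separated from the anchor run by an intact marker are
    excluded with a non-contiguity warning (possible rearrangement).
    """
    if not profile.calls:
        raise ValueError("empty intactness profile")
    by_gene = panel.by_gene()
    foreign = set(profile.calls) - set(by_gene)
    if foreign:
        raise ValueError(f"profile calls genes not on the panel: {sorted(foreign)}")
    status = {m.gene_id: profile.calls.get(m.gene_id, UNKNOWN) for m in panel}
    anchor = panel.anchor
    if status[anchor.gene_id] != DELETED:
        raise ValueError(
            f"anchor marker {anchor.gene_id} is not called deleted "
            f"({status[anchor.gene_id]}); no deletion to bracket"
        )

    markers = list(panel)  # sorted by offset
    anchor_idx = next(i for i, m in enumerate(markers) if m.offset_kb == 0.0)

    def walk(direction: int):
        """Walk from the anchor outwards; return (run edge, intact bound)."""
        edge = anchor_idx
        i = anchor_idx + direction
        intact_bound: Optional[int] = None
        while 0 <= i < len(markers):
            s = status[markers[i].gene_id]
            if s == DELETED:
                if intact_bound is not None:
                    warnings.warn(
                        f"non-contiguous deletion: {markers[i].gene_id} is deleted "
                        f"beyond intact marker {markers[intact_bound].gene_id}; "
                        "excluded from the interval (possible rearrangement)"
                    )
                    # remaining markers on this side are ignored
                    i += direction
                    continue
                edge = i
            elif s == INTACT and intact_bound is None:
                intact_bound = i
            i += direction
        return edge, intact_bound

    up_edge, up_bound = walk(-1)
    down_edge, down_bound = walk(+1)

    min_size = markers[down_edge].offset_kb - markers[up_edge].offset_kb
    up_open = up_bound is None
    down_open = down_bound is None
    if up_open or down_open:
        max_size = None
    else:
        max_size = markers[down_bound].offset_kb - markers[up_bound].offset_kb
    return DeletionInterval(
        min_size=min_size,
        max_size=max_size,
        up_bound_marker=markers[up_bound].gene_id if up_bound is not None else "none assayed",
        down_bound_marker=markers[down_bound].gene_id if down_bound is not None else "none assayed",
        up_open=up_open,
        down_open=down_open,
        up_edge_kb=markers[up_edge].offset_kb,
        down_edge_kb=markers[down_edge].offset_kb,
    )


@dataclass(frozen=True)
class SyntenyHit:
    """One homology hit: query gene vs a chromosome-arm subject."""

    query_gene: str
    subject_arm: str
    identity: float  # percent
    align_length: int
    e_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.identity <= 100.0):
            raise ValueError("identity must be in (0, 100]")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")


@dataclass
class SyntenyCall:
    query_gene: str
    status: str  # conserved | translocated | uncertain
    evidence_arms: List[str] = field(default_factory=list)


def _best_hit_per_arm(hits: Iterable[SyntenyHit]) -> Dict[str, SyntenyHit]:
    """Single best hit per arm: lowest e-value, ties by identity then length."""
    best: Dict[str, SyntenyHit] = {}
    for h in hits:
        cur = best.get(h.subject_arm)
        if cur is None or (h.e_value, -h.identity, -h.align_length) < (
            cur.e_value,
            -cur.identity,
            -cur.align_length,
        ):
            best[h.subject_arm] = h
    return best


def classify_synteny(
    hits: Sequence[SyntenyHit], target_arms: Set[str]
) -> SyntenyCall:
    """Conserved / translocated / uncertain from homology hits of one gene.

    No hit on any target arm means the gene has moved (translocated).  A
    target-arm hit counts as a likely homoeologue when no off-target arm has
    a best hit of both equal-or-greater identity and equal-or-greater length;
    one such arm suffices for a conserved call.  If every target-arm hit is
    matched or beaten off-target, conservation is uncertain.
    """
    if not target_arms:
        raise ValueError("target_arms must be non-empty")
    queries = {h.query_gene for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits span multiple query genes: {sorted(queries)}")
    if not hits:
        warnings.warn("no hits at all for query gene: translocated with zero evidence")
        return SyntenyCall(query_gene="", status="translocated")
    gene = hits[0].query_gene
    best = _best_hit_per_arm(hits)
    on_target = {arm: h for arm, h in best.items() if arm in target_arms}
    off_target = [h for arm, h in best.items() if arm not in target_arms]
    if not on_target:
        return SyntenyCall(query_gene=gene, status="translocated")
    evidence = []
    for arm, h in sorted(on_target.items()):
        beaten = any(
            o.identity >= h.identity and o.align_length >= h.align_length
            for o in off_target
        )
        if not beaten:
            evidence.append(arm)
    if evidence:
        return SyntenyCall(query_gene=gene, status="conserved", evidence_arms=evidence)
    return SyntenyCall(query_gene=gene, status="uncertain")


@dataclass
class ScaffoldRecord:
    scaffold_id: str
    length: int
    genes: Set[str]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("scaffold length must be >= 1")
        self.genes = set(self.genes)


def estimate_region_size(
    calls: Sequence[SyntenyCall], scaffolds: Sequence[ScaffoldRecord]
) -> int:
    """Sum of lengths of distinct scaffolds carrying >= 1 conserved gene."""
    conserved = {c.query_gene for c in calls if c.status == "conserved"}
    seen: Set[str] = set()
    total = 0
    for sc in scaffolds:
        if sc.scaffold_id in seen:
            continue
        if sc.genes & conserved:
            seen.add(sc.scaffold_id)
            total += sc.length
    return total
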