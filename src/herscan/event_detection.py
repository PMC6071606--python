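"""Classification of chromosomal events from per-individual dosage vectors.

A homoeologous exchange replaces a segment of one subgenome with the
corresponding segment of the other, so it appears in marker dosage as a run
of allele losses on one chromosome mirrored by a run of allele gains on the
homoeologous interval of the partner chromosome, both arising in the same
parental meiosis.  Unpaired runs are segmental deletions or duplications;
runs covering (nearly) all informative markers of a chromosome are
whole-chromosome aneuploidies.  Events are further classified by inheritance
(de novo / segregating / fixed), assigned a parent of origin, and annotated
with breakpoint uncertainty intervals and their relation to the centromere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

from .genotyping import Dosage
from .probe_annotation import HomoeologyBlock, project_interval

__all__ = [
    "Direction",
    "EventType",
    "Inheritance",
    "CentromereRelation",
    "ChromosomeModel",
    "MarkerCall",
    "CandidateRun",
    "Region",
    "Event",
    "find_aberrant_runs",
    "match_reciprocal",
    "detect_aneuploidy",
    "classify_inheritance",
    "classify_population_inheritance",
    "assign_parent_of_origin",
    "breakpoint_interval",
    "annotate_centromere",
    "detect_events",
    "detect_fixed_marker_events",
    "reciprocal_overlap",
]

DEFAULT_MIN_RUN = 3
DEFAULT_GAP_TOLERANCE = 1
DEFAULT_ANEUPLOID_FRACTION = 0.95
DEFAULT_OVERLAP_FRACTION = 0.5
DEFAULT_FIXED_FRACTION = 0.95
DEFAULT_CENTROMERE_WINDOW = 1_000_000
LOW_CONFIDENCE_MAX_LOCI = 9  # 3..9 supporting loci -> retained but flagged


class Direction(str, Enum):
    GAIN = "gain"
    LOSS = "loss"


class EventType(str, Enum):
    HER = "HeR"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    ANEUPLOID_GAIN = "aneuploid_gain"
    ANEUPLOID_LOSS = "aneuploid_loss"


class Inheritance(str, Enum):
    DE_NOVO = "de_novo"
    SEGREGATING = "segregating"
    FIXED = "fixed"
    UNCLASSIFIED = "unclassified"


class CentromereRelation(str, Enum):
    SPANS = "spans"
    BREAKPOINT_AT_CENTROMERE = "breakpoint_at_centromere"
    NONE = "none"


@dataclass(frozen=True)
class ChromosomeModel:
    name: str
    length: int
    centromere: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.centromere
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"centromere {self.centromere} outside [1, {self.length}] on {self.name}"
            )


@dataclass(frozen=True)
class MarkerCall:
    """One informative marker's dosage call for one individual."""

    probe_id: str
    chromosome: str
    position: int
    dosage: Dosage


@dataclass(frozen=True)
class CandidateRun:
    individual_id: str
    chromosome: str
    direction: Direction
    parent_of_origin: str
    first_position: int
    last_position: int
    n_support_loci: int
    probe_ids: tuple[str, ...] = ()

    @property
    def interval(self) -> tuple[int, int]:
        return (self.first_position, self.last_position)


@dataclass(frozen=True)
class Region:
    chromosome: str
    start: int
    end: int
    n_support_loci: int = 0

    @property
    def size_mb(self) -> float:
        return (self.end - self.start + 1) / 1e6


@dataclass(frozen=True)
class Event:
    event_id: str
    individual_id: str
    type: EventType
    gain_region: Optional[Region] = None
    loss_region: Optional[Region] = None
    inheritance: Inheritance = Inheritance.UNCLASSIFIED
    parent_of_origin: str = "unknown"
    population_id: str = ""
    breakpoint_intervals: tuple[tuple[int, int], ...] = ()
    centromere_relation: CentromereRelation = CentromereRelation.NONE
    low_confidence: bool = False
    flagged: bool = False  # ambiguous pairing or conflicting attribution

    def __post_init__(self) -> None:
        if self.type is EventType.HER:
            if self.gain_region is None or self.loss_region is None:
                raise ValueError("HeR events require both gain and loss regions")
        elif self.gain_region is None and self.loss_region is None:
            raise ValueError("event carries no region")

    @property
    def regions(self) -> list[Region]:
        return [r for r in (self.gain_region, self.loss_region) if r is not None]

    @property
    def n_support_loci(self) -> int:
        return min(r.n_support_loci for r in self.regions)

    @property
    def size_mb(self) -> float:
        return max(r.size_mb for r in self.regions)


_DOSAGE_DIRECTION: dict[Dosage, tuple[Direction, str]] = {
    Dosage.LOSS_P1: (Direction.LOSS, "parent1"),
    Dosage.LOSS_P2: (Direction.LOSS, "parent2"),
    Dosage.GAIN_P1: (Direction.GAIN, "parent1"),
    Dosage.GAIN_P2: (Direction.GAIN, "parent2"),
}


def find_aberrant_runs(
    calls: Sequence[MarkerCall],
    individual_id: str = "",
    min_run: int = DEFAULT_MIN_RUN,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
) -> list[CandidateRun]:
    """Find maximal runs of same-direction aberrant dosage along a chromosome.

    ``calls`` must be sorted by position and restricted to informative
    markers of a single chromosome.  A run starts and ends on an aberrant
    call of one (direction, parent-of-origin) class, may absorb up to
    ``gap_tolerance`` interior unknown calls, and is broken by any balanced
    call or any aberrant call of a different class.  Runs with fewer than
    ``min_run`` supporting loci are dropped.  The scan is greedy left to
    right: each starting aberrant call is extended as far as allowed, and
    scanning resumes after an emitted run.
    """
    if any(b.position < a.position for a, b in zip(calls, calls[1:])):
        raise ValueError("marker calls must be sorted by position")
    chroms = {c.chromosome for c in calls}
    if len(chroms) > 1:
        raise ValueError(f"calls span multiple chromosomes: {sorted(chroms)}")

    runs: list[CandidateRun] = []
    i = 0
    n = len(calls)
    while i < n:
        key = _DOSAGE_DIRECTION.get(calls[i].dosage)
        if key is None:
            i += 1
            continue
        end, support = _extend_run(calls, i, key, gap_tolerance)
        if len(support) >= min_run:
            runs.append(
                CandidateRun(
                    individual_id=individual_id,
                    chromosome=calls[i].chromosome,
                    direction=key[0],
                    parent_of_origin=key[1],
                    first_position=calls[i].position,
                    last_position=calls[end].position,
                    n_support_loci=len(support),
                    probe_ids=tuple(calls[k].probe_id for k in support),
                )
            )
            i = end + 1
        else:
            i += 1
    return runs


def _extend_run(
    calls: Sequence[MarkerCall],
    start: int,
    key: tuple[Direction, str],
    gap_tolerance: int,
) -> tuple[int, list[int]]:
    """Longest valid run from ``start``: last index and supporting indices."""
    support = [start]
    end = start
    gaps_used = 0
    pending_unknowns = 0  # unknowns count only once bridged by a matching call
    for j in range(start + 1, len(calls)):
        k = _DOSAGE_DIRECTION.get(calls[j].dosage)
        if k == key:
            gaps_used += pending_unknowns
            pending_unknowns = 0
            support.append(j)
            end = j
        elif calls[j].dosage is Dosage.UNKNOWN:
            if gaps_used + pending_unknowns + 1 > gap_tolerance:
                break
            pending_unknowns += 1
        else:
            break
    return end, support


def match_reciprocal(
    runs: Sequence[CandidateRun],
    homoeology_map: Sequence[HomoeologyBlock],
    min_support: int = DEFAULT_MIN_RUN,
    population_id: str = "",
    _id_counter: Optional[itertools.count] = None,
) -> list[Event]:
    """Pair reciprocal gain/loss runs into exchange events.

    A loss run and a gain run of one individual pair into a single exchange
    event iff both lie on homoeologous blocks, the projection of one run
    through the block overlaps the other run, and they share a parent of
    origin.  Each run participates in at most one pairing (greedy, largest
    projected overlap first).  Unpaired losses become deletions, unpaired
    gains duplications.
    """
    ids = _id_counter if _id_counter is not None else itertools.count()
    individuals = {r.individual_id for r in runs}
    if len(individuals) > 1:
        raise ValueError("match_reciprocal operates on one individual's runs")

    gains = [r for r in runs if r.direction is Direction.GAIN]
    losses = [r for r in runs if r.direction is Direction.LOSS]

    candidates: list[tuple[int, int, int, bool]] = []  # (overlap, gi, li, ambiguous)
    for gi, g in enumerate(gains):
        for li, l in enumerate(losses):
            if g.parent_of_origin != l.parent_of_origin:
                continue
            overlap, ambiguous = _projected_overlap(g, l, homoeology_map)
            if overlap > 0:
                candidates.append((overlap, gi, li, ambiguous))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    events: list[Event] = []
    used_g: set[int] = set()
    used_l: set[int] = set()
    for overlap, gi, li, ambiguous in candidates:
        if gi in used_g or li in used_l:
            continue
        g, l = gains[gi], losses[li]
        if min(g.n_support_loci, l.n_support_loci) < min_support:
            continue
        used_g.add(gi)
        used_l.add(li)
        events.append(
            _event_from_runs(
                next(ids), EventType.HER, gain=g, loss=l,
                population_id=population_id, flagged=ambiguous,
            )
        )
    for gi, g in enumerate(gains):
        if gi not in used_g:
            events.append(
                _event_from_runs(
                    next(ids), EventType.DUPLICATION, gain=g,
                    population_id=population_id,
                )
            )
    for li, l in enumerate(losses):
        if li not in used_l:
            events.append(
                _event_from_runs(
                    next(ids), EventType.DELETION, loss=l,
                    population_id=population_id,
                )
            )
    return events


def _projected_overlap(
    gain: CandidateRun, loss: CandidateRun, blocks: Sequence[HomoeologyBlock]
) -> tuple[int, bool]:
    """Best base-pair overlap between the gain run and the loss run projected
    through any homoeology block; flags pairings supported by >1 block."""
    best = 0
    n_supporting = 0
    for block in blocks:
        proj = project_interval(
            block, loss.chromosome, loss.first_position, loss.last_position
        )
        if proj is None or proj[0] != gain.chromosome:
            continue
        lo = max(proj[1], gain.first_position)
        hi = min(proj[2], gain.last_position)
        if lo <= hi:
            n_supporting += 1
            best = max(best, hi - lo + 1)
    return best, n_supporting > 1


def _region_from_run(run: CandidateRun) -> Region:
    return Region(
        chromosome=run.chromosome,
        start=run.first_position,
        end=run.last_position,
        n_support_loci=run.n_support_loci,
    )


def _event_from_runs(
    index: int,
    etype: EventType,
    gain: Optional[CandidateRun] = None,
    loss: Optional[CandidateRun] = None,
    population_id: str = "",
    flagged: bool = False,
) -> Event:
    primary = gain or loss
    assert primary is not None
    n_support = min(r.n_support_loci for r in (gain, loss) if r is not None)
    return Event(
        event_id=f"ev{index:05d}",
        individual_id=primary.individual_id,
        type=etype,
        gain_region=_region_from_run(gain) if gain else None,
        loss_region=_region_from_run(loss) if loss else None,
        parent_of_origin=primary.parent_of_origin,
        population_id=population_id,
        low_confidence=n_support <= LOW_CONFIDENCE_MAX_LOCI,
        flagged=flagged,
    )


def detect_aneuploidy(
    runs: Sequence[CandidateRun],
    informative_counts: Mapping[str, int],
    aneuploid_fraction: float = DEFAULT_ANEUPLOID_FRACTION,
    population_id: str = "",
    _id_counter: Optional[itertools.count] = None,
) -> tuple[list[Event], list[CandidateRun]]:
    """Split whole-chromosome runs into aneuploid events before HeR pairing.

    A run whose supporting loci cover at least ``aneuploid_fraction`` of the
    chromosome's informative markers is a whole-chromosome gain or loss; it
    is emitted as an aneuploid event and removed from the segmental runs so
    it can never pair into an exchange.  An individual may carry several
    aneuploid events.
    """
    ids = _id_counter if _id_counter is not None else itertools.count()
    # aggregate over runs of one class on one chromosome: sporadic no-calls can
    # fragment a whole-chromosome run, but the summed support still covers the
    # chromosome's informative markers
    grouped: dict[tuple[str, str, Direction, str], list[CandidateRun]] = {}
    for run in runs:
        key = (run.individual_id, run.chromosome, run.direction,
               run.parent_of_origin)
        grouped.setdefault(key, []).append(run)

    events: list[Event] = []
    segmental: list[CandidateRun] = []
    for (individual_id, chromosome, direction, parent), group in grouped.items():
        total = informative_counts.get(chromosome, 0)
        support = sum(r.n_support_loci for r in group)
        if total > 0 and support >= aneuploid_fraction * total:
            merged = CandidateRun(
                individual_id=individual_id,
                chromosome=chromosome,
                direction=direction,
                parent_of_origin=parent,
                first_position=min(r.first_position for r in group),
                last_position=max(r.last_position for r in group),
                n_support_loci=support,
                probe_ids=tuple(p for r in group for p in r.probe_ids),
            )
            etype = (
                EventType.ANEUPLOID_GAIN
                if direction is Direction.GAIN
                else EventType.ANEUPLOID_LOSS
            )
            events.append(
                _event_from_runs(
                    next(ids), etype,
                    gain=merged if direction is Direction.GAIN else None,
                    loss=merged if direction is Direction.LOSS else None,
                    population_id=population_id,
                )
            )
        else:
            segmental.extend(group)
    return events, segmental


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the longer interval length (0 when disjoint)."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    if lo > hi:
        return 0.0
    longer = max(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return (hi - lo + 1) / longer


def _same_event(a: Event, b: Event, overlap_fraction: float) -> bool:
    if a.type is not b.type or a.parent_of_origin != b.parent_of_origin:
        return False
    for ra, rb in ((a.gain_region, b.gain_region), (a.loss_region, b.loss_region)):
        if (ra is None) != (rb is None):
            return False
        if ra is None:
            continue
        if ra.chromosome != rb.chromosome:
            return False
        if reciprocal_overlap((ra.start, ra.end), (rb.start, rb.end)) < overlap_fraction:
            return False
    return True


def classify_inheritance(
    event: Event,
    population_events: Sequence[Event],
    population_size: int,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> Inheritance:
    """Classify one event by how many individuals of its population share it.

    Present in exactly one individual: de novo (arose in the sampled
    meiosis).  Present in more than one but not all: segregating
    (heterozygous, not yet fixed, in a parent).  Present in every individual:
    fixed.  Populations of fewer than two individuals cannot be classified.
    """
    if population_size < 2:
        return Inheritance.UNCLASSIFIED
    carriers = {
        e.individual_id
        for e in population_events
        if _same_event(event, e, overlap_fraction)
    }
    carriers.add(event.individual_id)
    if len(carriers) == 1:
        return Inheritance.DE_NOVO
    if len(carriers) >= population_size:
        return Inheritance.FIXED
    return Inheritance.SEGREGATING


def classify_population_inheritance(
    events: Sequence[Event],
    population_size: int,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
) -> list[Event]:
    """Attach inheritance classes to every event of one population."""
    return [
        replace(
            e,
            inheritance=classify_inheritance(
                e, events, population_size, overlap_fraction
            ),
        )
        for e in events
    ]


def assign_parent_of_origin(
    event: Event,
    parent1_id: str = "parent1",
    parent2_id: str = "parent2",
) -> Event:
    """Resolve the run-level parent attribution to a concrete parent id.

    Dosage semantics already attribute each run to the meiosis of one parent:
    deletions to the parent whose allele is absent, duplications/gains to the
    parent whose allele is doubled; an exchange inherits the shared
    attribution of its paired runs (pairing requires agreement, so a
    conflicting event arriving here is flagged, never dropped).
    """
    mapping = {"parent1": parent1_id, "parent2": parent2_id}
    resolved = mapping.get(event.parent_of_origin, event.parent_of_origin)
    return replace(event, parent_of_origin=resolved)


def breakpoint_interval(
    event: Event,
    marker_positions: Mapping[str, Sequence[int]],
    chromosome_models: Mapping[str, ChromosomeModel],
) -> Event:
    """Attach breakpoint uncertainty intervals to an event.

    For each edge of each region the interval runs from the outermost
    affected probe to the nearest flanking informative probe (which, being
    outside the run, carried an expected call), truncated to [1, chromosome
    length] when the run reaches the end of the informative map.
    """
    intervals: list[tuple[int, int]] = []
    for region in event.regions:
        positions = sorted(marker_positions.get(region.chromosome, ()))
        model = chromosome_models.get(region.chromosome)
        length = model.length if model else (positions[-1] if positions else region.end)
        before = [p for p in positions if p < region.start]
        after = [p for p in positions if p > region.end]
        left = (before[-1], region.start) if before else (1, region.start)
        right = (region.end, after[0]) if after else (region.end, length)
        intervals.extend([left, right])
    return replace(event, breakpoint_intervals=tuple(intervals))


def annotate_centromere(
    event: Event,
    chromosome_models: Mapping[str, ChromosomeModel],
    proximity_window: int = DEFAULT_CENTROMERE_WINDOW,
) -> Event:
    """Annotate an event's relation to the centromere of its chromosome(s).

    ``spans`` when a region strictly contains the centromere interval (takes
    precedence); ``breakpoint_at_centromere`` when any breakpoint interval
    lies within ``proximity_window`` of the centromere; ``none`` otherwise.
    """
    relation = CentromereRelation.NONE
    for region in event.regions:
        model = chromosome_models.get(region.chromosome)
        if model is None:
            continue
        c_start, c_end = model.centromere
        if region.start < c_start and region.end > c_end:
            return replace(event, centromere_relation=CentromereRelation.SPANS)
    for region in event.regions:
        model = chromosome_models.get(region.chromosome)
        if model is None:
            continue
        c_start, c_end = model.centromere
        for lo, hi in event.breakpoint_intervals or (
            (region.start, region.start), (region.end, region.end)
        ):
            if lo <= c_end + proximity_window and hi >= c_start - proximity_window:
                relation = CentromereRelation.BREAKPOINT_AT_CENTROMERE
    return replace(event, centromere_relation=relation)


def detect_events(
    calls_by_individual: Mapping[str, Sequence[MarkerCall]],
    homoeology_map: Sequence[HomoeologyBlock],
    chromosome_models: Mapping[str, ChromosomeModel],
    informative_counts: Mapping[str, int],
    marker_positions: Mapping[str, Sequence[int]],
    population_id: str = "",
    min_run: int = DEFAULT_MIN_RUN,
    gap_tolerance: int = DEFAULT_GAP_TOLERANCE,
    aneuploid_fraction: float = DEFAULT_ANEUPLOID_FRACTION,
    overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    parent1_id: str = "parent1",
    parent2_id: str = "parent2",
) -> list[Event]:
    """Full per-population event pipeline.

    For each individual: run-finding per chromosome, aneuploidy splitting,
    reciprocal pairing; then population-level inheritance classification,
    parent attribution, breakpoint intervals and centromere annotation.
    """
    ids = itertools.count()
    events: list[Event] = []
    for individual_id, calls in calls_by_individual.items():
        by_chrom: dict[str, list[MarkerCall]] = {}
        for call in calls:
            by_chrom.setdefault(call.chromosome, []).append(call)
        runs: list[CandidateRun] = []
        for chrom in sorted(by_chrom):
            chrom_calls = sorted(by_chrom[chrom], key=lambda c: c.position)
            runs.extend(
                find_aberrant_runs(
                    chrom_calls, individual_id, min_run=min_run,
                    gap_tolerance=gap_tolerance,
                )
            )
        aneuploid_events, segmental = detect_aneuploidy(
            runs, informative_counts, aneuploid_fraction,
            population_id=population_id, _id_counter=ids,
        )
        events.extend(aneuploid_events)
        events.extend(
            match_reciprocal(
                segmental, homoeology_map, min_support=min_run,
                population_id=population_id, _id_counter=ids,
            )
        )

    events = classify_population_inheritance(
        events, population_size=len(calls_by_individual),
        overlap_fraction=overlap_fraction,
    )
    out: list[Event] = []
    for event in events:
        event = assign_parent_of_origin(event, parent1_id, parent2_id)
        event = breakpoint_interval(event, marker_positions, chromosome_models)
        event = annotate_centromere(event, chromosome_models)
        out.append(event)
    return out


def detect_fixed_marker_events(
    displaced_fraction: Mapping[str, tuple[str, int, Direction, float]],
    homoeology_map: Sequence[HomoeologyBlock],
    fixed_fraction: float = DEFAULT_FIXED_FRACTION,
    min_run: int = DEFAULT_MIN_RUN,
    population_id: str = "",
) -> list[Event]:
    """Detect events fixed in a parent from marker-level population summaries.

    ``displaced_fraction`` maps probe id to (chromosome, position, direction,
    fraction of callable progeny displaced from the expected heterozygous
    cluster in that direction).  Markers with fraction >= ``fixed_fraction``
    are aberrant for the whole family; runs of at least ``min_run`` such
    markers become fixed events, paired through the homoeology map exactly
    like per-individual runs.
    """
    calls: dict[str, list[MarkerCall]] = {}
    for probe_id, (chrom, pos, direction, fraction) in displaced_fraction.items():
        if fraction >= fixed_fraction:
            dosage = Dosage.GAIN_P1 if direction is Direction.GAIN else Dosage.LOSS_P1
        else:
            dosage = Dosage.BALANCED
        calls.setdefault(chrom, []).append(MarkerCall(probe_id, chrom, pos, dosage))

    runs: list[CandidateRun] = []
    for chrom in sorted(calls):
        chrom_calls = sorted(calls[chrom], key=lambda c: c.position)
        runs.extend(
            find_aberrant_runs(
                chrom_calls, individual_id=population_id, min_run=min_run,
                gap_tolerance=0,
            )
        )
    events = match_reciprocal(runs, homoeology_map, min_support=min_run,
                              population_id=population_id)
    return [replace(e, inheritance=Inheritance.FIXED, parent_of_origin="unknown")
            for e in events]
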