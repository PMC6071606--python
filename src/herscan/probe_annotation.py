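"""Probe subgenome classification and homoeology map construction.

Array probes are classified by alignment identity against the two diploid
progenitor genomes (A and C).  Probes with a confident hit in exactly one
subgenome are genome-specific and usable for genotyping; probes hitting both
genomes above the specificity threshold cannot be assigned and are excluded
downstream.  Probes with a cross-genome hit above a (lower) homoeology
threshold additionally anchor the A<->C homoeology map: runs of consecutive
probes whose cross-genome partners are collinear define syntenic blocks used
to match reciprocal gain/loss events between subgenomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "Subgenome",
    "Specificity",
    "Orientation",
    "GenomeHit",
    "ProbeLocus",
    "HomoeologyBlock",
    "subgenome_of_chromosome",
    "classify_specificity",
    "assign_homoeologous_locus",
    "annotate_probes",
    "build_homoeology_map",
    "project_interval",
]

DEFAULT_HIGH_THRESH = 0.90
DEFAULT_MIN_IDENTITY = 0.50
DEFAULT_MIN_BLOCK_PROBES = 5
DEFAULT_MAX_GAP = 2_000_000


class Subgenome(str, Enum):
    A = "A"
    C = "C"


class Specificity(str, Enum):
    A_SPECIFIC = "A_specific"
    C_SPECIFIC = "C_specific"
    DUAL = "dual"
    UNASSIGNED = "unassigned"


class Orientation(str, Enum):
    SAME = "same"
    INVERTED = "inverted"


def subgenome_of_chromosome(chromosome: str) -> Subgenome:
    """Infer the subgenome from a chromosome name prefix ("A1" -> A)."""
    prefix = chromosome[:1].upper()
    try:
        return Subgenome(prefix)
    except ValueError:
        raise ValueError(f"cannot infer subgenome from chromosome {chromosome!r}")


@dataclass(frozen=True)
class GenomeHit:
    """One alignment hit of a probe's flanking sequence to a diploid genome."""

    probe_id: str
    subgenome: Subgenome
    chromosome: str
    position: int  # 1-based
    identity: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(
                f"identity must be in [0, 1], got {self.identity} for {self.probe_id}"
            )
        if subgenome_of_chromosome(self.chromosome) is not self.subgenome:
            raise ValueError(
                f"chromosome {self.chromosome!r} does not match subgenome "
                f"{self.subgenome.value!r}"
            )


@dataclass(frozen=True)
class ProbeLocus:
    """A probe's resolved genomic assignment and cross-genome partner."""

    probe_id: str
    specificity: Specificity
    primary_locus: Optional[tuple[str, int]] = None  # (chromosome, position)
    homoeologous_locus: Optional[tuple[str, int]] = None

    @property
    def is_informative(self) -> bool:
        """Usable for genotyping: genome-specific with a known position."""
        return (
            self.specificity in (Specificity.A_SPECIFIC, Specificity.C_SPECIFIC)
            and self.primary_locus is not None
        )


@dataclass(frozen=True)
class HomoeologyBlock:
    """A syntenic interval pair between an A and a C chromosome.

    Intervals are 1-based inclusive.  ``a_probe_positions`` and
    ``c_probe_positions`` hold, probe by probe and in primary order, the
    anchoring coordinates on each side; they are used for interval projection.
    """

    block_id: str
    a_interval: tuple[str, int, int]
    c_interval: tuple[str, int, int]
    orientation: Orientation
    n_probes: int
    probe_ids: tuple[str, ...] = ()
    a_probe_positions: tuple[int, ...] = field(default=(), repr=False)
    c_probe_positions: tuple[int, ...] = field(default=(), repr=False)

    def interval_on(self, subgenome: Subgenome) -> tuple[str, int, int]:
        return self.a_interval if subgenome is Subgenome.A else self.c_interval


def _best_hits_per_subgenome(
    hits: Sequence[GenomeHit],
) -> dict[Subgenome, GenomeHit]:
    """Best hit per subgenome; ties broken by (chromosome, position)."""
    probe_ids = {h.probe_id for h in hits}
    if len(probe_ids) > 1:
        raise ValueError(f"hits span multiple probes: {sorted(probe_ids)}")
    best: dict[Subgenome, GenomeHit] = {}
    for hit in sorted(hits, key=lambda h: (h.chromosome, h.position)):
        cur = best.get(hit.subgenome)
        if cur is None or hit.identity > cur.identity:
            best[hit.subgenome] = hit
    return best


def classify_specificity(
    hits: Sequence[GenomeHit], high_thresh: float = DEFAULT_HIGH_THRESH
) -> Specificity:
    """Classify a probe's subgenome specificity from its alignment hits.

    A probe is specific to one subgenome when its best identity there strictly
    exceeds ``high_thresh`` while the best identity in the other subgenome
    does not; exceeding the threshold in both genomes makes it ``dual`` and it
    is excluded from genotyping.  An empty hit list is ``unassigned``.
    """
    if not hits:
        return Specificity.UNASSIGNED
    best = _best_hits_per_subgenome(hits)
    a_high = Subgenome.A in best and best[Subgenome.A].identity > high_thresh
    c_high = Subgenome.C in best and best[Subgenome.C].identity > high_thresh
    if a_high and c_high:
        return Specificity.DUAL
    if a_high:
        return Specificity.A_SPECIFIC
    if c_high:
        return Specificity.C_SPECIFIC
    return Specificity.UNASSIGNED


def assign_homoeologous_locus(
    hits: Sequence[GenomeHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    high_thresh: float = DEFAULT_HIGH_THRESH,
) -> ProbeLocus:
    """Resolve a probe to its primary locus and optional cross-genome partner.

    The primary locus is the best hit in the assigned subgenome; the
    homoeologous locus is the best hit in the opposite subgenome when that
    hit's identity is at least ``min_identity``.  Probes that are not
    genome-specific carry no loci.
    """
    if not hits:
        return ProbeLocus(probe_id="", specificity=Specificity.UNASSIGNED)
    specificity = classify_specificity(hits, high_thresh=high_thresh)
    probe_id = hits[0].probe_id
    if specificity in (Specificity.UNASSIGNED, Specificity.DUAL):
        return ProbeLocus(probe_id=probe_id, specificity=specificity)
    best = _best_hits_per_subgenome(hits)
    own = Subgenome.A if specificity is Specificity.A_SPECIFIC else Subgenome.C
    other = Subgenome.C if own is Subgenome.A else Subgenome.A
    primary = best[own]
    homoeologous: Optional[tuple[str, int]] = None
    if other in best and best[other].identity >= min_identity:
        homoeologous = (best[other].chromosome, best[other].position)
    return ProbeLocus(
        probe_id=probe_id,
        specificity=specificity,
        primary_locus=(primary.chromosome, primary.position),
        homoeologous_locus=homoeologous,
    )


def annotate_probes(
    hits: Iterable[GenomeHit],
    high_thresh: float = DEFAULT_HIGH_THRESH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[ProbeLocus]:
    """Annotate every probe present in ``hits`` (grouped by probe id)."""
    by_probe: dict[str, list[GenomeHit]] = {}
    for hit in hits:
        by_probe.setdefault(hit.probe_id, []).append(hit)
    return [
        assign_homoeologous_locus(
            probe_hits, min_identity=min_identity, high_thresh=high_thresh
        )
        for _, probe_hits in sorted(by_probe.items())
    ]


def _monotone_direction(values: Sequence[int]) -> Optional[int]:
    """+1 if non-decreasing, -1 if non-increasing, 0 if constant, None if neither."""
    up = all(b >= a for a, b in zip(values, values[1:]))
    down = all(b <= a for a, b in zip(values, values[1:]))
    if up and down:
        return 0
    if up:
        return 1
    if down:
        return -1
    return None


def build_homoeology_map(
    loci: Iterable[ProbeLocus],
    min_block_probes: int = DEFAULT_MIN_BLOCK_PROBES,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[HomoeologyBlock]:
    """Merge collinear probe pairings into homoeology blocks.

    Probes carrying both a primary and a homoeologous position are ordered by
    primary position per primary chromosome.  A block is a maximal run of
    consecutive probes that (a) share the same (primary chromosome, partner
    chromosome) pair, (b) have partner positions monotone in one direction,
    and (c) have no gap larger than ``max_gap`` on either side.  Runs shorter
    than ``min_block_probes`` are discarded.  The scan is greedy left to
    right, so every retained probe belongs to exactly one block.
    """
    anchored = [
        loc
        for loc in loci
        if loc.primary_locus is not None and loc.homoeologous_locus is not None
    ]
    by_chrom: dict[str, list[ProbeLocus]] = {}
    for loc in anchored:
        by_chrom.setdefault(loc.primary_locus[0], []).append(loc)

    blocks: list[HomoeologyBlock] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda l: (l.primary_locus[1], l.probe_id))
        i = 0
        n = len(group)
        while i < n:
            run = [group[i]]
            direction: Optional[int] = 0
            j = i + 1
            while j < n:
                prev, cur = group[j - 1], group[j]
                if cur.homoeologous_locus[0] != prev.homoeologous_locus[0]:
                    break
                if cur.primary_locus[1] - prev.primary_locus[1] > max_gap:
                    break
                if abs(cur.homoeologous_locus[1] - prev.homoeologous_locus[1]) > max_gap:
                    break
                step = cur.homoeologous_locus[1] - prev.homoeologous_locus[1]
                step_dir = 0 if step == 0 else (1 if step > 0 else -1)
                if direction == 0:
                    direction = step_dir
                elif step_dir != 0 and step_dir != direction:
                    break
                run.append(cur)
                j += 1
            if len(run) >= min_block_probes:
                blocks.append(_make_block(run, len(blocks)))
            i = j
    return blocks


def _make_block(run: Sequence[ProbeLocus], index: int) -> HomoeologyBlock:
    primary_chrom = run[0].primary_locus[0]
    partner_chrom = run[0].homoeologous_locus[0]
    primary_pos = [loc.primary_locus[1] for loc in run]
    partner_pos = [loc.homoeologous_locus[1] for loc in run]
    direction = _monotone_direction(partner_pos)
    orientation = Orientation.INVERTED if direction == -1 else Orientation.SAME

    primary_iv = (primary_chrom, min(primary_pos), max(primary_pos))
    partner_iv = (partner_chrom, min(partner_pos), max(partner_pos))
    if subgenome_of_chromosome(primary_chrom) is Subgenome.A:
        a_iv, c_iv = primary_iv, partner_iv
        a_pos, c_pos = primary_pos, partner_pos
    else:
        a_iv, c_iv = partner_iv, primary_iv
        a_pos, c_pos = partner_pos, primary_pos
    return HomoeologyBlock(
        block_id=f"blk{index:04d}_{primary_chrom}_{partner_chrom}",
        a_interval=a_iv,
        c_interval=c_iv,
        orientation=orientation,
        n_probes=len(run),
        probe_ids=tuple(loc.probe_id for loc in run),
        a_probe_positions=tuple(a_pos),
        c_probe_positions=tuple(c_pos),
    )


def project_interval(
    block: HomoeologyBlock, chromosome: str, start: int, end: int
) -> Optional[tuple[str, int, int]]:
    """Project an interval through a block onto the partner chromosome.

    The interval must lie (at least partially) on one of the block's
    chromosomes; the overlapping part is mapped linearly onto the partner
    interval, honoring the block orientation.  Returns None when the interval
    does not intersect the block.
    """
    if chromosome == block.a_interval[0]:
        src, dst = block.a_interval, block.c_interval
    elif chromosome == block.c_interval[0]:
        src, dst = block.c_interval, block.a_interval
    else:
        return None
    lo = max(start, src[1])
    hi = min(end, src[2])
    if lo > hi:
        return None
    span_src = max(src[2] - src[1], 1)
    span_dst = dst[2] - dst[1]

    def _map(pos: int) -> int:
        frac = (pos - src[1]) / span_src
        if block.orientation is Orientation.INVERTED:
            frac = 1.0 - frac
        return int(round(dst[1] + frac * span_dst))

    p1, p2 = _map(lo), _map(hi)
    return (dst[0], min(p1, p2), max(p1, p2))
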