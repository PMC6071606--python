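"""Synthetic testcross populations with planted chromosomal events.

Generates (a) a pseudo-allotetraploid marker map with homoeologous A/C
blocks, (b) per-meiosis planted events (terminal/interstitial exchanges,
segmental deletions/duplications, whole-chromosome aneuploidies) at
configurable rates, (c) two-channel intensity records rendered from the
resulting genotypes with Gaussian theta noise, state-dependent R and a
missing-record rate, and (d) windowed depth profiles with planted
copy-ratio intervals.  A truth catalog in the analysis event schema makes
round-trip recovery measurable.

All randomness flows from a single seed through hierarchically spawned
generator streams (one per parent x meiosis, one for marker assignment, one
for rendering), so enlarging the population does not perturb earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .event_detection import (
    ChromosomeModel,
    Direction,
    Event,
    EventType,
    Inheritance,
    Region,
)
from .probe_annotation import HomoeologyBlock, Orientation, project_interval

__all__ = [
    "CHROMOSOME_LENGTHS_MB",
    "MarkerMap",
    "EventRates",
    "SimConfig",
    "SimulatedPopulation",
    "default_marker_map",
    "simulate_meiosis",
    "simulate_population",
    "render_intensities",
    "simulate_depth",
    "compare_regions",
]

# A1-A10 / C1-C9 pseudo-chromosome lengths (Mb)
CHROMOSOME_LENGTHS_MB: dict[str, float] = {
    "A1": 21.7, "A2": 29.6, "A3": 35.8, "A4": 21.1, "A5": 25.7,
    "A6": 26.1, "A7": 25.5, "A8": 21.7, "A9": 40.5, "A10": 17.9,
    "C1": 45.6, "C2": 47.3, "C3": 67.8, "C4": 55.1, "C5": 48.7,
    "C6": 40.8, "C7": 48.8, "C8": 44.7, "C9": 56.0,
}

DEFAULT_CLUSTER_CENTERS: dict[str, float] = {
    "AA": 0.05, "AAB": 0.275, "AB": 0.5, "ABB": 0.725, "BB": 0.95,
    "A0": 0.05, "B0": 0.95,
}


@dataclass
class MarkerMap:
    """Chromosome models, probe positions and homoeology blocks."""

    models: dict[str, ChromosomeModel]
    probes: pd.DataFrame  # columns: probe_id, chromosome, position
    blocks: list[HomoeologyBlock]

    def positions(self, chromosome: str) -> np.ndarray:
        sel = self.probes[self.probes["chromosome"] == chromosome]
        return sel["position"].to_numpy()

    def probe_ids(self, chromosome: str) -> np.ndarray:
        sel = self.probes[self.probes["chromosome"] == chromosome]
        return sel["probe_id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        return list(self.models)


def default_marker_map(
    n_probes_per_chromosome: int = 1000,
    centromere_width: int = 400_000,
) -> MarkerMap:
    """19-chromosome pseudo-tetraploid map with evenly spaced probes.

    Homoeology blocks pair A1..A8 with C1..C8 along their full lengths; A9
    pairs with the top half of C9 and A10 with the bottom half (the one
    split pairing of the default karyotype).  Centromeres sit mid-chromosome.
    """
    models: dict[str, ChromosomeModel] = {}
    rows = []
    for chrom, mb in CHROMOSOME_LENGTHS_MB.items():
        length = int(mb * 1e6)
        mid = length // 2
        models[chrom] = ChromosomeModel(
            chrom, length, (mid - centromere_width // 2, mid + centromere_width // 2)
        )
        positions = np.linspace(1, length, n_probes_per_chromosome).astype(int)
        positions = np.unique(positions)
        for k, pos in enumerate(positions):
            rows.append((f"{chrom}_{k:05d}", chrom, int(pos)))
    probes = pd.DataFrame(rows, columns=["probe_id", "chromosome", "position"])

    blocks: list[HomoeologyBlock] = []
    for i in range(1, 9):
        a, c = f"A{i}", f"C{i}"
        blocks.append(
            HomoeologyBlock(
                block_id=f"blk_{a}_{c}",
                a_interval=(a, 1, models[a].length),
                c_interval=(c, 1, models[c].length),
                orientation=Orientation.SAME,
                n_probes=0,
            )
        )
    c9_len = models["C9"].length
    blocks.append(
        HomoeologyBlock(
            block_id="blk_A9_C9top",
            a_interval=("A9", 1, models["A9"].length),
            c_interval=("C9", 1, c9_len // 2),
            orientation=Orientation.SAME,
            n_probes=0,
        )
    )
    blocks.append(
        HomoeologyBlock(
            block_id="blk_A10_C9bot",
            a_interval=("A10", 1, models["A10"].length),
            c_interval=("C9", c9_len // 2 + 1, c9_len),
            orientation=Orientation.SAME,
            n_probes=0,
        )
    )
    return MarkerMap(models=models, probes=probes, blocks=blocks)


@dataclass(frozen=True)
class EventRates:
    """Per-meiosis probabilities of planting one event of each class."""

    her_terminal: float = 0.0
    her_interstitial: float = 0.0
    deletion: float = 0.0
    duplication: float = 0.0
    aneuploid_gain: float = 0.0
    aneuploid_loss: float = 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "her_terminal": self.her_terminal,
            "her_interstitial": self.her_interstitial,
            "deletion": self.deletion,
            "duplication": self.duplication,
            "aneuploid_gain": self.aneuploid_gain,
            "aneuploid_loss": self.aneuploid_loss,
        }

    def __post_init__(self) -> None:
        values = self.as_dict()
        if any(v < 0 for v in values.values()):
            raise ValueError(f"negative event rate in {values}")
        if sum(values.values()) > 1.0 + 1e-12:
            raise ValueError(f"per-meiosis event rates sum above 1: {values}")


@dataclass
class SimConfig:
    seed: int
    n_individuals: int = 20
    marker_map: Optional[MarkerMap] = None  # None -> default_marker_map()
    rates: EventRates = field(default_factory=EventRates)
    cluster_centers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_CENTERS)
    )
    theta_noise_sd: float = 0.0
    nc_rate: float = 0.0
    fraction_monomorphic: float = 0.1
    fraction_null_parent: float = 0.02
    r_mean: float = 1.0
    r_noise_sd: float = 0.05
    hemizygote_r_fraction: float = 0.6
    null_r: float = 0.02
    min_event_probes: int = 10  # informative probes required under a planted event
    max_segment_fraction: float = 0.5
    depth_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.theta_noise_sd < 0 or self.depth_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    def map_or_default(self) -> MarkerMap:
        return self.marker_map if self.marker_map is not None else default_marker_map()


@dataclass(frozen=True)
class PlantedEvent:
    """One event planted in one parental meiosis (probe-span coordinates)."""

    type: EventType
    parent: str  # 'parent1' | 'parent2'
    meiosis_id: str
    gain: Optional[tuple[str, int, int]] = None  # (chromosome, start, end) bp
    loss: Optional[tuple[str, int, int]] = None

    @property
    def chromosomes(self) -> set[str]:
        return {r[0] for r in (self.gain, self.loss) if r is not None}


@dataclass
class SimulatedPopulation:
    config: SimConfig
    marker_map: MarkerMap
    intensities: pd.DataFrame  # individual_id, probe_id, theta, r
    markers: pd.DataFrame  # probe_id, chromosome, position, status, parent1_allele
    truth: list[Event]
    parent1_id: str = "P1"
    parent2_id: str = "P2"

    @property
    def individual_ids(self) -> list[str]:
        n = self.config.n_individuals
        return [f"I{i:03d}" for i in range(1, n + 1)]

    def informative_counts(self) -> dict[str, int]:
        inf = self.markers[self.markers["status"] == "informative"]
        return inf.groupby("chromosome").size().to_dict()


_EVENT_CLASSES = (
    "her_terminal",
    "her_interstitial",
    "deletion",
    "duplication",
    "aneuploid_gain",
    "aneuploid_loss",
)


def _draw_event_class(rates: EventRates, rng: np.random.Generator) -> Optional[str]:
    probs = [getattr(rates, name) for name in _EVENT_CLASSES]
    p_none = 1.0 - sum(probs)
    choice = rng.choice(len(probs) + 1, p=probs + [max(p_none, 0.0)])
    return _EVENT_CLASSES[choice] if choice < len(probs) else None


def _informative_in_span(
    marker_map: MarkerMap,
    informative: Mapping[str, np.ndarray],
    chrom: str,
    start: int,
    end: int,
) -> int:
    pos = marker_map.positions(chrom)
    mask = (pos >= start) & (pos <= end) & informative[chrom]
    return int(mask.sum())


def simulate_meiosis(
    parent: str,
    marker_map: MarkerMap,
    rates: EventRates,
    rng: np.random.Generator,
    informative: Mapping[str, np.ndarray],
    min_event_probes: int = 10,
    max_segment_fraction: float = 0.5,
    meiosis_id: str = "",
    forbidden_chromosomes: frozenset[str] = frozenset(),
    max_tries: int = 100,
) -> tuple[dict[str, np.ndarray], list[PlantedEvent]]:
    """Simulate one parental meiosis: gamete dosage effects plus planted events.

    Returns a per-chromosome int8 vector over probes (+1 gained allele, -1
    lost, 0 balanced) and the planted-event records.  At most one event per
    meiosis is planted (drawn from the per-class rates); geometry is
    resampled until the affected span covers at least ``min_event_probes``
    informative probes on every affected chromosome and avoids
    ``forbidden_chromosomes`` (used to keep the two gametes of one
    individual from interfering on a shared chromosome).
    """
    effects = {
        chrom: np.zeros(len(marker_map.positions(chrom)), dtype=np.int8)
        for chrom in marker_map.chromosomes
    }
    klass = _draw_event_class(rates, rng)
    if klass is None:
        return effects, []

    planted: Optional[PlantedEvent] = None
    for _ in range(max_tries):
        candidate = _plant(klass, parent, marker_map, rng, max_segment_fraction,
                           meiosis_id)
        if candidate is None:
            continue
        if candidate.chromosomes & forbidden_chromosomes:
            continue
        ok = all(
            _informative_in_span(marker_map, informative, *region) >= min_event_probes
            for region in (candidate.gain, candidate.loss)
            if region is not None
        )
        if ok:
            planted = candidate
            break
    if planted is None:
        return effects, []

    for region, delta in ((planted.gain, 1), (planted.loss, -1)):
        if region is None:
            continue
        chrom, start, end = region
        pos = marker_map.positions(chrom)
        effects[chrom][(pos >= start) & (pos <= end)] = delta
    return effects, [planted]


def _plant(
    klass: str,
    parent: str,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    max_segment_fraction: float,
    meiosis_id: str,
) -> Optional[PlantedEvent]:
    chroms = marker_map.chromosomes
    if klass in ("aneuploid_gain", "aneuploid_loss"):
        chrom = chroms[rng.integers(len(chroms))]
        length = marker_map.models[chrom].length
        region = (chrom, 1, length)
        gain = region if klass == "aneuploid_gain" else None
        loss = region if klass == "aneuploid_loss" else None
        etype = (
            EventType.ANEUPLOID_GAIN if klass == "aneuploid_gain"
            else EventType.ANEUPLOID_LOSS
        )
        return PlantedEvent(etype, parent, meiosis_id, gain=gain, loss=loss)

    if klass in ("deletion", "duplication"):
        chrom = chroms[rng.integers(len(chroms))]
        length = marker_map.models[chrom].length
        frac = rng.uniform(0.03, max_segment_fraction)
        size = max(int(frac * length), 1)
        start = int(rng.integers(1, max(length - size, 2)))
        region = (chrom, start, min(start + size - 1, length))
        if klass == "deletion":
            return PlantedEvent(EventType.DELETION, parent, meiosis_id, loss=region)
        return PlantedEvent(EventType.DUPLICATION, parent, meiosis_id, gain=region)

    # exchange: pick a block, pick which side gains
    block = marker_map.blocks[rng.integers(len(marker_map.blocks))]
    gain_side = rng.choice(["a", "c"])
    src = block.a_interval if gain_side == "a" else block.c_interval
    chrom, b_start, b_end = src
    span = b_end - b_start
    if klass == "her_terminal":
        frac = rng.uniform(0.05, 0.45)
        if rng.random() < 0.5:
            region = (chrom, b_start, b_start + int(frac * span))
        else:
            region = (chrom, b_end - int(frac * span), b_end)
    else:  # interstitial
        f1, f2 = sorted(rng.uniform(0.05, 0.95, size=2))
        if f2 - f1 < 0.03:
            return None
        region = (chrom, b_start + int(f1 * span), b_start + int(f2 * span))
    partner = project_interval(block, *region)
    if partner is None:
        return None
    return PlantedEvent(EventType.HER, parent, meiosis_id, gain=region, loss=partner)


def _assign_markers(marker_map: MarkerMap, config: SimConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Assign per-marker status and parental allele orientation."""
    n = len(marker_map.probes)
    u = rng.random(n)
    status = np.where(
        u < config.fraction_monomorphic,
        "monomorphic",
        np.where(
            u < config.fraction_monomorphic + config.fraction_null_parent,
            "null_parent",
            "informative",
        ),
    )
    parent1_allele = np.where(rng.random(n) < 0.5, "A", "B")
    null_parent = np.where(rng.random(n) < 0.5, "parent1", "parent2")
    out = marker_map.probes.copy()
    out["status"] = status
    out["parent1_allele"] = parent1_allele
    out["null_parent"] = null_parent
    return out


def simulate_population(config: SimConfig) -> SimulatedPopulation:
    """Simulate a full testcross family: truth catalog plus intensity table."""
    marker_map = config.map_or_default()
    root = np.random.SeedSequence(config.seed)
    markers_ss, render_ss, meiosis_ss = root.spawn(3)
    markers_rng = np.random.default_rng(markers_ss)

    markers = _assign_markers(marker_map, config, markers_rng)
    informative = {
        chrom: (markers.loc[markers["chromosome"] == chrom, "status"]
                == "informative").to_numpy()
        for chrom in marker_map.chromosomes
    }

    individual_ids = [f"I{i:03d}" for i in range(1, config.n_individuals + 1)]
    truth: list[Event] = []
    effects_by_individual: dict[str, tuple[dict, dict]] = {}
    event_counter = 0
    for i, ind in enumerate(individual_ids):
        # two independent streams per individual, stable under population growth
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(10, i))
        rng1 = np.random.default_rng(child.spawn(1)[0])
        rng2 = np.random.default_rng(child.spawn(1)[0])
        eff1, planted1 = simulate_meiosis(
            "parent1", marker_map, config.rates, rng1, informative,
            config.min_event_probes, config.max_segment_fraction,
            meiosis_id=f"{ind}.m1",
        )
        busy = frozenset().union(*(p.chromosomes for p in planted1)) if planted1 else frozenset()
        eff2, planted2 = simulate_meiosis(
            "parent2", marker_map, config.rates, rng2, informative,
            config.min_event_probes, config.max_segment_fraction,
            meiosis_id=f"{ind}.m2", forbidden_chromosomes=busy,
        )
        effects_by_individual[ind] = (eff1, eff2)
        for planted in (*planted1, *planted2):
            truth.append(
                _truth_event(planted, marker_map, informative, ind,
                             f"tr{event_counter:05d}")
            )
            event_counter += 1

    render_rng = np.random.default_rng(render_ss)
    intensities = render_intensities(
        effects_by_individual, markers, config, render_rng
    )
    return SimulatedPopulation(
        config=config, marker_map=marker_map, intensities=intensities,
        markers=markers, truth=truth,
    )


def _truth_event(
    planted: PlantedEvent,
    marker_map: MarkerMap,
    informative: Mapping[str, np.ndarray],
    individual_id: str,
    event_id: str,
) -> Event:
    """Express a planted event as outermost affected informative probes."""

    def region_of(span: Optional[tuple[str, int, int]]) -> Optional[Region]:
        if span is None:
            return None
        chrom, start, end = span
        pos = marker_map.positions(chrom)
        mask = (pos >= start) & (pos <= end) & informative[chrom]
        hit = pos[mask]
        return Region(chrom, int(hit[0]), int(hit[-1]), int(mask.sum()))

    return Event(
        event_id=event_id,
        individual_id=individual_id,
        type=planted.type,
        gain_region=region_of(planted.gain),
        loss_region=region_of(planted.loss),
        inheritance=Inheritance.DE_NOVO,
        parent_of_origin=planted.parent,
    )


def _amplifying_allele(parent1_allele: str, null_parent: str) -> str:
    """Allele carried by the amplifying parent of a null-allele marker."""
    if null_parent == "parent1":
        return "B" if parent1_allele == "A" else "A"
    return parent1_allele


def _combined_genotype(copies_a: int, copies_b: int) -> str:
    table = {
        (1, 1): "AB", (1, 0): "A0", (0, 1): "B0",
        (2, 1): "AAB", (1, 2): "ABB",
        (2, 0): "AA", (0, 2): "BB", (2, 2): "AB", (0, 0): "null",
    }
    return table[(copies_a, copies_b)]


def render_intensities(
    effects_by_individual: Mapping[str, tuple[Mapping[str, np.ndarray],
                                              Mapping[str, np.ndarray]]],
    markers: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Render theta/R intensity records for parents and progeny.

    Theta is the state's cluster center plus truncated Gaussian noise; R is
    the state-dependent level (hemizygous states reduced, null states near
    zero) with multiplicative noise.  Progeny records are dropped at the
    configured missing rate.
    """
    centers = config.cluster_centers
    rows: list[tuple[str, str, float, float]] = []

    probe_ids = markers["probe_id"].to_numpy()
    status = markers["status"].to_numpy()
    p1_allele = markers["parent1_allele"].to_numpy()
    null_parent = markers["null_parent"].to_numpy()
    chrom_of = markers["chromosome"].to_numpy()
    # per-chromosome probe index within chromosome
    idx_in_chrom = markers.groupby("chromosome").cumcount().to_numpy()

    n_markers = len(markers)

    def emit(ind: str, k: int, state: str, r_level: float) -> None:
        theta = centers.get(state, 0.5)
        if config.theta_noise_sd > 0:
            theta += rng.normal(0.0, config.theta_noise_sd)
        theta = min(max(theta, 0.0), 1.0)
        r = r_level * config.r_mean
        if config.r_noise_sd > 0 and r > 0:
            r *= max(1.0 + rng.normal(0.0, config.r_noise_sd), 0.0)
        rows.append((ind, probe_ids[k], theta, r))

    # parents
    for k in range(n_markers):
        if status[k] == "monomorphic":
            emit("P1", k, "AA", 1.0)
            emit("P2", k, "AA", 1.0)
        elif status[k] == "null_parent":
            # the amplifying parent keeps its orientation allele; the other
            # parent's locus is absent
            amp_allele = _amplifying_allele(p1_allele[k], null_parent[k])
            amp_state = "AA" if amp_allele == "A" else "BB"
            if null_parent[k] == "parent1":
                emit("P1", k, "null", config.null_r)
                emit("P2", k, amp_state, 1.0)
            else:
                emit("P1", k, amp_state, 1.0)
                emit("P2", k, "null", config.null_r)
        else:
            emit("P1", k, "AA" if p1_allele[k] == "A" else "BB", 1.0)
            emit("P2", k, "BB" if p1_allele[k] == "A" else "AA", 1.0)

    # progeny
    hemi = config.hemizygote_r_fraction
    r_by_state = {"AA": 1.0, "AB": 1.0, "BB": 1.0, "AAB": 1.2, "ABB": 1.2,
                  "A0": hemi, "B0": hemi, "null": config.null_r}
    for ind, (eff1, eff2) in effects_by_individual.items():
        drop = rng.random(n_markers) < config.nc_rate if config.nc_rate > 0 else None
        for k in range(n_markers):
            if drop is not None and drop[k]:
                continue
            if status[k] == "monomorphic":
                state = "AA"
            elif status[k] == "null_parent":
                # progeny inherit the amplifying parent's allele only
                amp_allele = _amplifying_allele(p1_allele[k], null_parent[k])
                state = "A0" if amp_allele == "A" else "B0"
            else:
                chrom = chrom_of[k]
                g1 = int(eff1[chrom][idx_in_chrom[k]])
                g2 = int(eff2[chrom][idx_in_chrom[k]])
                c1, c2 = 1 + g1, 1 + g2
                if p1_allele[k] == "A":
                    ca, cb = c1, c2
                else:
                    ca, cb = c2, c1
                state = _combined_genotype(ca, cb)
            emit(ind, k, state, r_by_state.get(state, 1.0))

    return pd.DataFrame(rows, columns=["individual_id", "probe_id", "theta", "r"])


def simulate_depth(
    models: Mapping[str, ChromosomeModel],
    fixed_events: Sequence[tuple[str, int, int, float]],
    window_size: int = 100_000,
    depth_mean: float = 30.0,
    noise_sd: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Windowed depth profile with planted copy-ratio intervals.

    ``fixed_events`` lists (chromosome, start, end, copy_ratio) intervals;
    reciprocal pairs must be passed explicitly (one gain plus one loss).
    Noise is multiplicative Gaussian.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rows = []
    for chrom, model in models.items():
        starts = np.arange(1, model.length + 1, window_size)
        ends = np.minimum(starts + window_size - 1, model.length)
        ratio = np.ones(len(starts))
        for ev_chrom, ev_start, ev_end, copy_ratio in fixed_events:
            if ev_chrom != chrom:
                continue
            mask = (starts <= ev_end) & (ends >= ev_start)
            ratio[mask] = copy_ratio
        depth = depth_mean * ratio
        if noise_sd > 0:
            depth = depth * np.maximum(1.0 + rng.normal(0.0, noise_sd, len(depth)), 0.0)
        for s, e, d in zip(starts, ends, depth):
            rows.append((chrom, int(s), int(e), float(d)))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "raw_depth"])


def compare_regions(
    truth: Sequence[Event],
    detected: Sequence[Event],
    min_coverage: float = 0.5,
) -> dict[str, float]:
    """Region-level sensitivity and false-discovery rate against a truth set.

    Each event contributes its gain and/or loss regions, labeled by
    direction.  A truth region is recovered when same-direction detected
    regions on its chromosome jointly cover >= ``min_coverage`` of it; a
    detected region is a false discovery when same-direction truth regions
    cover < ``min_coverage`` of it.  Robust to run fragmentation from
    no-call gaps, unlike exact event-by-event matching.
    """

    def regions_of(events: Sequence[Event]) -> list[tuple[str, Direction, int, int]]:
        out = []
        for e in events:
            if e.gain_region is not None:
                g = e.gain_region
                out.append((g.chromosome, Direction.GAIN, g.start, g.end))
            if e.loss_region is not None:
                l = e.loss_region
                out.append((l.chromosome, Direction.LOSS, l.start, l.end))
        return out

    def coverage(target: tuple[str, Direction, int, int],
                 pool: Sequence[tuple[str, Direction, int, int]]) -> float:
        chrom, direction, start, end = target
        pieces = [
            (max(start, s), min(end, e))
            for c, d, s, e in pool
            if c == chrom and d == direction and s <= end and e >= start
        ]
        if not pieces:
            return 0.0
        pieces.sort()
        covered = 0
        cur_lo, cur_hi = pieces[0]
        for lo, hi in pieces[1:]:
            if lo > cur_hi + 1:
                covered += cur_hi - cur_lo + 1
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        covered += cur_hi - cur_lo + 1
        return covered / (end - start + 1)

    truth_regions = regions_of(truth)
    detected_regions = regions_of(detected)
    recovered = sum(
        1 for t in truth_regions if coverage(t, detected_regions) >= min_coverage
    )
    false_pos = sum(
        1 for d in detected_regions if coverage(d, truth_regions) < min_coverage
    )
    sensitivity = recovered / len(truth_regions) if truth_regions else 1.0
    fdr = false_pos / len(detected_regions) if detected_regions else 0.0
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_truth_regions": float(len(truth_regions)),
        "n_detected_regions": float(len(detected_regions)),
    }
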