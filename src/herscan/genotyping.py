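"""Parental-anchored genotype calling from two-channel array intensities.

Each marker assay yields a theta value (relative allele dosage, 0 = all A
allele, 1 = all B allele) and a total intensity R per individual.  In a
testcross between opposite homozygotes the expected progeny cluster is the
central heterozygote AB; copy-number aberrations displace individuals into
extra clusters: single-allele A0/B0 individuals fall into a parental
homozygous cluster, three-dose AAB/ABB individuals fall between AB and a
parent.  Calling is anchored on the two parents (no de novo cluster
discovery) and is theta-driven; R is used to detect non-amplifying (null)
parental loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from statistics import median
from typing import Optional, Sequence

__all__ = [
    "Genotype",
    "MarkerPattern",
    "Dosage",
    "IntensityRecord",
    "MarkerClassification",
    "GenotypeCall",
    "GenotypingConfig",
    "classify_marker",
    "call_progeny_genotype",
    "call_marker",
    "derive_dosage",
]


class Genotype(str, Enum):
    AA = "AA"
    AB = "AB"
    BB = "BB"
    A0 = "A0"
    B0 = "B0"
    AAB = "AAB"
    ABB = "ABB"
    NC = "NC"


class MarkerPattern(str, Enum):
    MONOMORPHIC = "monomorphic"
    STANDARD_3_CLUSTER = "standard_3_cluster"
    MULTI_CLUSTER = "multi_cluster"
    NULL_PARENT = "null_parent"
    FAILED = "failed"


class Dosage(str, Enum):
    BALANCED = "balanced"
    LOSS_P1 = "loss_of_parent1_allele"
    LOSS_P2 = "loss_of_parent2_allele"
    GAIN_P1 = "gain_of_parent1_allele"
    GAIN_P2 = "gain_of_parent2_allele"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class IntensityRecord:
    individual_id: str
    probe_id: str
    theta: float
    r: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta out of [0, 1]: {self.theta}")
        if self.r < 0:
            raise ValueError(f"negative R: {self.r}")


@dataclass(frozen=True)
class GenotypingConfig:
    """Cluster geometry and calling thresholds.

    theta_aa_max / theta_bb_min bound the parental homozygous clusters;
    r_amplification_floor is the fraction of the marker median R below which
    a parent is considered non-amplifying (null allele); no_call_distance is
    the maximum theta distance to the nearest cluster center for a confident
    call; hemizygote_r_fraction is the expected relative R of single-allele
    states (used by the simulator and the optional hemizygote check).
    """

    theta_aa_max: float = 0.15
    theta_bb_min: float = 0.85
    r_amplification_floor: float = 0.2
    no_call_distance: float = 0.08
    hemizygote_r_fraction: float = 0.6
    min_cluster_size: int = 3  # progeny needed to re-estimate a 3-dose center

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_aa_max < 0.5 < self.theta_bb_min < 1.0:
            raise ValueError(
                "thresholds must satisfy 0 < theta_aa_max < 0.5 < theta_bb_min < 1"
            )


@dataclass(frozen=True)
class MarkerClassification:
    probe_id: str
    pattern: MarkerPattern
    parent1_genotype: Genotype
    parent2_genotype: Genotype
    cluster_centers: dict[Genotype, float] = field(default_factory=dict)

    @property
    def is_polymorphic(self) -> bool:
        return self.pattern in (
            MarkerPattern.STANDARD_3_CLUSTER,
            MarkerPattern.MULTI_CLUSTER,
        )

    @property
    def parent1_allele(self) -> Optional[str]:
        """'A' or 'B': which allele parent 1 carries (polymorphic markers)."""
        if self.parent1_genotype is Genotype.AA:
            return "A"
        if self.parent1_genotype is Genotype.BB:
            return "B"
        return None


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    probe_id: str
    genotype: Genotype
    confidence: float  # theta distance to assigned center; lower is better

    def __post_init__(self) -> None:
        if self.confidence < 0:
            raise ValueError("confidence must be >= 0")


def _parent_summary(records: Sequence[IntensityRecord]) -> tuple[float, float]:
    """Median theta and R over (replicated) parent wells."""
    return (median(r.theta for r in records), median(r.r for r in records))


def _homozygous_genotype(theta: float, config: GenotypingConfig) -> Optional[Genotype]:
    if theta < config.theta_aa_max:
        return Genotype.AA
    if theta > config.theta_bb_min:
        return Genotype.BB
    return None


def _base_centers(p1_theta: float, p2_theta: float, g1: Genotype) -> dict[Genotype, float]:
    aa = p1_theta if g1 is Genotype.AA else p2_theta
    bb = p2_theta if g1 is Genotype.AA else p1_theta
    ab = (aa + bb) / 2.0
    return {
        Genotype.AA: aa,
        Genotype.AAB: (aa + ab) / 2.0,
        Genotype.AB: ab,
        Genotype.ABB: (ab + bb) / 2.0,
        Genotype.BB: bb,
    }


def classify_marker(
    parent1_records: Sequence[IntensityRecord],
    parent2_records: Sequence[IntensityRecord],
    progeny_records: Sequence[IntensityRecord],
    config: GenotypingConfig = GenotypingConfig(),
) -> MarkerClassification:
    """Classify one marker's cluster pattern from parents and progeny.

    Patterns: ``monomorphic`` (parents share a homozygous cluster),
    ``null_parent`` (one parent's R below the amplification floor),
    ``standard_3_cluster`` (opposite homozygous parents, all progeny within
    the no-call radius of the AA/AB/BB anchors), ``multi_cluster``
    (additional progeny groupings between AB and a parent, re-estimated as
    1-D group medians when populated by >= ``min_cluster_size`` progeny), or
    ``failed`` (parents uncallable).
    """
    if not parent1_records or not parent2_records:
        raise ValueError("need at least one record per parent")
    if not progeny_records:
        raise ValueError("need at least one progeny record")
    probe_id = parent1_records[0].probe_id

    p1_theta, p1_r = _parent_summary(parent1_records)
    p2_theta, p2_r = _parent_summary(parent2_records)
    all_r = [rec.r for rec in (*parent1_records, *parent2_records, *progeny_records)]
    marker_median_r = median(all_r)
    if marker_median_r <= 0:
        return MarkerClassification(
            probe_id, MarkerPattern.FAILED, Genotype.NC, Genotype.NC
        )

    floor = config.r_amplification_floor * marker_median_r
    p1_null = p1_r < floor
    p2_null = p2_r < floor
    if p1_null != p2_null:  # exactly one parent fails to amplify
        amplifying_theta = p2_theta if p1_null else p1_theta
        g = _homozygous_genotype(amplifying_theta, config) or Genotype.NC
        g1 = Genotype.NC if p1_null else g
        g2 = g if p1_null else Genotype.NC
        centers = {g: amplifying_theta} if g is not Genotype.NC else {}
        return MarkerClassification(
            probe_id, MarkerPattern.NULL_PARENT, g1, g2, centers
        )
    if p1_null and p2_null:
        return MarkerClassification(
            probe_id, MarkerPattern.FAILED, Genotype.NC, Genotype.NC
        )

    g1 = _homozygous_genotype(p1_theta, config)
    g2 = _homozygous_genotype(p2_theta, config)
    if g1 is None or g2 is None:
        return MarkerClassification(
            probe_id, MarkerPattern.FAILED, Genotype.NC, Genotype.NC
        )
    if g1 is g2:
        return MarkerClassification(
            probe_id, MarkerPattern.MONOMORPHIC, g1, g2,
            {g1: (p1_theta + p2_theta) / 2.0},
        )

    centers = _base_centers(p1_theta, p2_theta, g1)
    centers = _reestimate_centers(progeny_records, centers, config)

    multi = False
    for rec in progeny_records:
        nearest = min(centers, key=lambda g: abs(centers[g] - rec.theta))
        if abs(centers[nearest] - rec.theta) > config.no_call_distance:
            continue
        if nearest in (Genotype.AAB, Genotype.ABB):
            multi = True
            break
        if nearest in (Genotype.AA, Genotype.BB):
            multi = True  # progeny in a parental cluster: A0/B0 segregation
            break
    pattern = MarkerPattern.MULTI_CLUSTER if multi else MarkerPattern.STANDARD_3_CLUSTER
    return MarkerClassification(probe_id, pattern, g1, g2, centers)


def _reestimate_centers(
    progeny_records: Sequence[IntensityRecord],
    centers: dict[Genotype, float],
    config: GenotypingConfig,
) -> dict[Genotype, float]:
    """Replace anchor-derived centers by the progeny group median wherever a
    cluster of >= min_cluster_size progeny is populated.

    The parental anchors only locate the clusters; their own assay noise
    would otherwise propagate into every distance.  Two passes: a robust
    median against the anchors, then a mean against the refined centers.
    Sparse clusters keep the anchored center (midpoints for the 3-dose
    states)."""
    out = dict(centers)
    for estimator in (median, lambda xs: sum(xs) / len(xs)):
        ref = dict(out)
        for state in ref:
            members = [
                rec.theta
                for rec in progeny_records
                if min(ref, key=lambda g: abs(ref[g] - rec.theta)) is state
                and abs(ref[state] - rec.theta) <= config.no_call_distance
            ]
            if len(members) >= config.min_cluster_size:
                out[state] = estimator(members)
    return out


def call_progeny_genotype(
    record: IntensityRecord,
    classification: MarkerClassification,
    config: GenotypingConfig = GenotypingConfig(),
) -> GenotypeCall:
    """Call one progeny record by nearest-center assignment.

    Assignment is over the five theta centers {AA, AAB, AB, ABB, BB}; a
    progeny record landing in a parental homozygous cluster carries a single
    inherited allele and is called A0 (AA cluster) or B0 (BB cluster).
    A distance above the no-call radius yields NC.
    """
    if not classification.is_polymorphic:
        raise ValueError(
            f"marker {classification.probe_id} is {classification.pattern.value}; "
            "progeny calling requires a polymorphic marker"
        )
    centers = classification.cluster_centers
    nearest = min(centers, key=lambda g: abs(centers[g] - record.theta))
    distance = abs(centers[nearest] - record.theta)
    if distance > config.no_call_distance:
        return GenotypeCall(record.individual_id, record.probe_id, Genotype.NC, distance)
    if nearest is Genotype.AA:
        nearest = Genotype.A0
    elif nearest is Genotype.BB:
        nearest = Genotype.B0
    return GenotypeCall(record.individual_id, record.probe_id, nearest, distance)


def call_marker(
    parent1_records: Sequence[IntensityRecord],
    parent2_records: Sequence[IntensityRecord],
    progeny_records: Sequence[IntensityRecord],
    config: GenotypingConfig = GenotypingConfig(),
) -> tuple[MarkerClassification, list[GenotypeCall]]:
    """Classify a marker and, when polymorphic, call all progeny records."""
    classification = classify_marker(
        parent1_records, parent2_records, progeny_records, config
    )
    if not classification.is_polymorphic:
        return classification, []
    calls = [
        call_progeny_genotype(rec, classification, config) for rec in progeny_records
    ]
    return classification, calls


_DOSAGE_BY_ALLELE: dict[tuple[Genotype, str], Dosage] = {
    # (progeny genotype, allele carried by parent 1) -> dosage
    (Genotype.A0, "A"): Dosage.LOSS_P2,  # B allele absent; parent2 carried B
    (Genotype.A0, "B"): Dosage.LOSS_P1,
    (Genotype.B0, "A"): Dosage.LOSS_P1,
    (Genotype.B0, "B"): Dosage.LOSS_P2,
    (Genotype.AAB, "A"): Dosage.GAIN_P1,  # A allele doubled; parent1 carried A
    (Genotype.AAB, "B"): Dosage.GAIN_P2,
    (Genotype.ABB, "A"): Dosage.GAIN_P2,
    (Genotype.ABB, "B"): Dosage.GAIN_P1,
}


def derive_dosage(call: GenotypeCall, parent1_allele: str) -> Dosage:
    """Map an 8-state genotype call to a copy-dosage class.

    ``parent1_allele`` is the array allele ('A' or 'B') carried by parent 1
    at this marker.  AB is balanced; A0/B0 mark loss of the allele the other
    parent should have contributed; AAB/ABB mark gain of the doubled allele's
    parent; NC and parental homozygous calls are unknown.
    """
    if parent1_allele not in ("A", "B"):
        raise ValueError(f"parent1_allele must be 'A' or 'B', got {parent1_allele!r}")
    if call.genotype is Genotype.AB:
        return Dosage.BALANCED
    return _DOSAGE_BY_ALLELE.get((call.genotype, parent1_allele), Dosage.UNKNOWN)
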