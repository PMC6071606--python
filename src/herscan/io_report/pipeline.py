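"""Population-scale orchestration: intensities -> genotypes -> events.

The scalar genotyping operations define the calling semantics; this module
provides a vectorized per-marker path (numpy over the progeny of one marker
at a time) for whole-array throughput, plus the glue that turns genotype
calls into dosage vectors and runs event detection.  Equivalence of the
vectorized path with the scalar operations is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ..event_detection import (
    ChromosomeModel,
    Event,
    MarkerCall,
    detect_events,
)
from ..genotyping import Dosage, Genotype, GenotypingConfig, MarkerPattern
from ..probe_annotation import HomoeologyBlock

__all__ = [
    "GENOTYPE_ORDER",
    "PopulationCalls",
    "call_population",
    "genotype_matrix_frame",
    "dosage_matrix",
    "marker_calls_by_individual",
    "analyze_population",
]

# fixed code order for compact genotype matrices
GENOTYPE_ORDER: tuple[Genotype, ...] = (
    Genotype.AA, Genotype.AB, Genotype.BB, Genotype.A0, Genotype.B0,
    Genotype.AAB, Genotype.ABB, Genotype.NC,
)
_CODE_OF = {g: i for i, g in enumerate(GENOTYPE_ORDER)}
_NC_CODE = _CODE_OF[Genotype.NC]

# nearest-center states in theta order; AA/BB hits become A0/B0 for progeny
_CENTER_STATES = (Genotype.AA, Genotype.AAB, Genotype.AB, Genotype.ABB, Genotype.BB)
_CENTER_TO_CALL = np.array(
    [_CODE_OF[Genotype.A0], _CODE_OF[Genotype.AAB], _CODE_OF[Genotype.AB],
     _CODE_OF[Genotype.ABB], _CODE_OF[Genotype.B0]],
    dtype=np.int8,
)

_DOSAGE_ORDER: tuple[Dosage, ...] = (
    Dosage.BALANCED, Dosage.LOSS_P1, Dosage.LOSS_P2, Dosage.GAIN_P1,
    Dosage.GAIN_P2, Dosage.UNKNOWN,
)
_DOSAGE_CODE = {d: i for i, d in enumerate(_DOSAGE_ORDER)}


@dataclass
class PopulationCalls:
    """Vectorized genotyping result for one testcross population."""

    probe_ids: np.ndarray  # (n_markers,)
    individual_ids: list[str]  # progeny only
    patterns: np.ndarray  # (n_markers,) MarkerPattern values as str
    parent1_allele: np.ndarray  # (n_markers,) 'A'/'B'/'' per marker
    codes: np.ndarray  # (n_markers, n_progeny) int8 indices into GENOTYPE_ORDER
    confidence: np.ndarray  # same shape, theta distance to assigned center

    @property
    def informative(self) -> np.ndarray:
        return np.isin(
            self.patterns,
            (MarkerPattern.STANDARD_3_CLUSTER.value, MarkerPattern.MULTI_CLUSTER.value),
        )


def call_population(
    intensities: pd.DataFrame,
    parent1_id: str,
    parent2_id: str,
    config: GenotypingConfig = GenotypingConfig(),
) -> PopulationCalls:
    """Genotype all markers of a population from a long-format intensity table.

    Parent records anchor the cluster centers (replicates reduced by
    median); progeny are assigned to the nearest of the five theta centers,
    with missing records and distant assignments coded NC.
    """
    individual_ids = sorted(
        set(intensities["individual_id"]) - {parent1_id, parent2_id}
    )
    sample_order = [parent1_id, parent2_id, *individual_ids]
    col_of = {s: i for i, s in enumerate(sample_order)}

    theta_w = _pivot(intensities, "theta", col_of)
    r_w = _pivot(intensities, "r", col_of)
    probe_ids = theta_w.index.to_numpy()
    theta = theta_w.to_numpy(dtype=float)
    r = r_w.to_numpy(dtype=float)

    n_markers, _ = theta.shape
    n_progeny = len(individual_ids)
    patterns = np.full(n_markers, MarkerPattern.FAILED.value, dtype=object)
    parent1_allele = np.full(n_markers, "", dtype=object)
    codes = np.full((n_markers, n_progeny), _NC_CODE, dtype=np.int8)
    confidence = np.zeros((n_markers, n_progeny), dtype=float)

    for k in range(n_markers):
        patterns[k], parent1_allele[k], codes[k], confidence[k] = _call_one_marker(
            theta[k], r[k], config
        )
    return PopulationCalls(
        probe_ids=probe_ids,
        individual_ids=individual_ids,
        patterns=np.asarray(patterns, dtype=object),
        parent1_allele=np.asarray(parent1_allele, dtype=object),
        codes=codes,
        confidence=confidence,
    )


def _pivot(df: pd.DataFrame, value: str, col_of: Mapping[str, int]) -> pd.DataFrame:
    wide = df.pivot_table(
        index="probe_id", columns="individual_id", values=value, aggfunc="median"
    )
    ordered = sorted(col_of, key=col_of.get)
    return wide.reindex(columns=ordered)


def _call_one_marker(
    theta_row: np.ndarray, r_row: np.ndarray, config: GenotypingConfig
) -> tuple[str, str, np.ndarray, np.ndarray]:
    """Single-marker classification + progeny calls on raw sample vectors.

    Element 0/1 of the rows are the two parents; the rest are progeny.
    Mirrors the scalar classify_marker / call_progeny_genotype semantics.
    """
    n_progeny = len(theta_row) - 2
    nc_codes = np.full(n_progeny, _NC_CODE, dtype=np.int8)
    zeros = np.zeros(n_progeny)

    p1_theta, p2_theta = theta_row[0], theta_row[1]
    p1_r, p2_r = r_row[0], r_row[1]
    if np.isnan(p1_theta) or np.isnan(p2_theta):
        return MarkerPattern.FAILED.value, "", nc_codes, zeros

    finite_r = r_row[~np.isnan(r_row)]
    median_r = float(np.median(finite_r)) if len(finite_r) else 0.0
    if median_r <= 0:
        return MarkerPattern.FAILED.value, "", nc_codes, zeros
    floor = config.r_amplification_floor * median_r
    p1_null, p2_null = p1_r < floor, p2_r < floor
    if p1_null and p2_null:
        return MarkerPattern.FAILED.value, "", nc_codes, zeros
    if p1_null or p2_null:
        return MarkerPattern.NULL_PARENT.value, "", nc_codes, zeros

    g1 = _homozygote(p1_theta, config)
    g2 = _homozygote(p2_theta, config)
    if g1 is None or g2 is None:
        return MarkerPattern.FAILED.value, "", nc_codes, zeros
    if g1 == g2:
        return MarkerPattern.MONOMORPHIC.value, "", nc_codes, zeros

    aa = p1_theta if g1 == "AA" else p2_theta
    bb = p2_theta if g1 == "AA" else p1_theta
    ab = (aa + bb) / 2.0
    centers = np.array([aa, (aa + ab) / 2.0, ab, (ab + bb) / 2.0, bb])

    prog_theta = theta_row[2:]
    present = ~np.isnan(prog_theta)

    # re-estimate centers from populated progeny clusters (>= min_cluster_size):
    # robust median pass against the anchors, then a mean refinement
    for estimator in (np.median, np.mean):
        dist = np.abs(prog_theta[:, None] - centers[None, :])
        nearest = np.nanargmin(np.where(present[:, None], dist, np.inf), axis=1)
        new_centers = centers.copy()
        for ci in range(len(centers)):
            members = present & (nearest == ci) & (
                np.abs(prog_theta - centers[ci]) <= config.no_call_distance
            )
            if members.sum() >= config.min_cluster_size:
                new_centers[ci] = float(estimator(prog_theta[members]))
        centers = new_centers
    dist = np.abs(prog_theta[:, None] - centers[None, :])
    nearest = np.nanargmin(np.where(present[:, None], dist, np.inf), axis=1)
    best_dist = np.where(present, dist[np.arange(len(nearest)), nearest], 0.0)

    called = present & (best_dist <= config.no_call_distance)
    codes = np.where(called, _CENTER_TO_CALL[nearest], _NC_CODE).astype(np.int8)

    multi = bool(np.any(called & np.isin(nearest, (0, 1, 3, 4))))
    pattern = (
        MarkerPattern.MULTI_CLUSTER.value if multi
        else MarkerPattern.STANDARD_3_CLUSTER.value
    )
    allele = "A" if g1 == "AA" else "B"
    return pattern, allele, codes, best_dist


def _homozygote(theta: float, config: GenotypingConfig) -> Optional[str]:
    if theta < config.theta_aa_max:
        return "AA"
    if theta > config.theta_bb_min:
        return "BB"
    return None


def genotype_matrix_frame(calls: PopulationCalls) -> pd.DataFrame:
    """Markers x individuals matrix of 8-state codes (NC for uninformative)."""
    lookup = np.array([g.value for g in GENOTYPE_ORDER], dtype=object)
    values = lookup[calls.codes]
    values[~calls.informative, :] = Genotype.NC.value
    return pd.DataFrame(values, index=calls.probe_ids, columns=calls.individual_ids)


_DOSAGE_LOOKUP = np.full((len(GENOTYPE_ORDER), 2), _DOSAGE_CODE[Dosage.UNKNOWN],
                         dtype=np.int8)
# columns: parent1 carries allele A (0) or B (1)
_DOSAGE_LOOKUP[_CODE_OF[Genotype.AB], :] = _DOSAGE_CODE[Dosage.BALANCED]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.A0], 0] = _DOSAGE_CODE[Dosage.LOSS_P2]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.A0], 1] = _DOSAGE_CODE[Dosage.LOSS_P1]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.B0], 0] = _DOSAGE_CODE[Dosage.LOSS_P1]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.B0], 1] = _DOSAGE_CODE[Dosage.LOSS_P2]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.AAB], 0] = _DOSAGE_CODE[Dosage.GAIN_P1]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.AAB], 1] = _DOSAGE_CODE[Dosage.GAIN_P2]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.ABB], 0] = _DOSAGE_CODE[Dosage.GAIN_P2]
_DOSAGE_LOOKUP[_CODE_OF[Genotype.ABB], 1] = _DOSAGE_CODE[Dosage.GAIN_P1]


def dosage_matrix(calls: PopulationCalls) -> np.ndarray:
    """Per-(marker, progeny) dosage codes in _DOSAGE_ORDER indexing."""
    allele_col = np.where(calls.parent1_allele == "A", 0, 1)
    dosage = _DOSAGE_LOOKUP[calls.codes, allele_col[:, None]]
    dosage[~calls.informative, :] = _DOSAGE_CODE[Dosage.UNKNOWN]
    return dosage


def marker_calls_by_individual(
    calls: PopulationCalls,
    marker_positions: pd.DataFrame,
) -> dict[str, list[MarkerCall]]:
    """Expand dosage codes into per-individual sorted MarkerCall vectors.

    ``marker_positions`` columns: probe_id, chromosome, position.  Only
    informative (polymorphic) markers are included; a missing or no-call
    genotype yields an UNKNOWN dosage entry so run finding can bridge it.
    """
    dosage = dosage_matrix(calls)
    info = pd.DataFrame({"probe_id": calls.probe_ids}).merge(
        marker_positions, on="probe_id", how="left"
    )
    if info["chromosome"].isna().any():
        missing = info.loc[info["chromosome"].isna(), "probe_id"].head()
        raise ValueError(f"no positions for probes like {list(missing)}")
    keep = calls.informative
    order = np.lexsort(
        (info["position"].to_numpy(), info["chromosome"].to_numpy().astype(str))
    )
    order = order[keep[order]]
    chroms = info["chromosome"].to_numpy()[order]
    positions = info["position"].to_numpy()[order]
    probe_ids = calls.probe_ids[order]

    out: dict[str, list[MarkerCall]] = {}
    for j, individual in enumerate(calls.individual_ids):
        d = dosage[order, j]
        out[individual] = [
            MarkerCall(
                probe_id=str(probe_ids[k]),
                chromosome=str(chroms[k]),
                position=int(positions[k]),
                dosage=_DOSAGE_ORDER[d[k]],
            )
            for k in range(len(order))
        ]
    return out


def analyze_population(
    intensities: pd.DataFrame,
    marker_positions: pd.DataFrame,
    homoeology_map: Sequence[HomoeologyBlock],
    chromosome_models: Mapping[str, ChromosomeModel],
    parent1_id: str,
    parent2_id: str,
    population_id: str = "",
    genotyping_config: GenotypingConfig = GenotypingConfig(),
    **detect_kwargs,
) -> tuple[list[Event], PopulationCalls]:
    """Full analysis for one population: genotype, dose, detect, classify."""
    calls = call_population(intensities, parent1_id, parent2_id, genotyping_config)
    by_individual = marker_calls_by_individual(calls, marker_positions)

    informative_probe_ids = set(calls.probe_ids[calls.informative].astype(str))
    inf_positions = marker_positions[
        marker_positions["probe_id"].astype(str).isin(informative_probe_ids)
    ]
    informative_counts = inf_positions.groupby("chromosome").size().to_dict()
    positions_by_chrom = {
        chrom: sorted(grp["position"].tolist())
        for chrom, grp in inf_positions.groupby("chromosome")
    }

    events = detect_events(
        by_individual,
        homoeology_map,
        chromosome_models,
        informative_counts,
        positions_by_chrom,
        population_id=population_id,
        parent1_id=parent1_id,
        parent2_id=parent2_id,
        **detect_kwargs,
    )
    return events, calls
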