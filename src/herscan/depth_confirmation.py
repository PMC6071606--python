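"""Read-depth confirmation of fixed homoeologous exchanges.

Whole-genome sequencing depth is binned into windows, normalized per
chromosome, and segmented: maximal runs of windows deviating by at least
``sd_multiplier`` standard deviations from the chromosomal mean in one
direction are called as gain/loss segments.  A gain segment on one subgenome
that projects (through the homoeology map) onto a loss segment on the
partner subgenome is a candidate fixed exchange.

Works on window tables only; alignment and binning happen upstream
(bedGraph / 4-column TSV input).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .event_detection import Direction, Event, EventType, Inheritance, Region
from .probe_annotation import HomoeologyBlock, project_interval

__all__ = [
    "DepthSegment",
    "normalize_depth",
    "call_depth_segments",
    "pair_homoeologous_segments",
]

DEFAULT_SD_MULTIPLIER = 1.5
DEFAULT_MIN_WINDOWS = 5
TRIM_SD = 3.0

WINDOW_COLUMNS = ["chromosome", "start", "end", "raw_depth"]


@dataclass(frozen=True)
class DepthSegment:
    chromosome: str
    start: int
    end: int
    direction: Direction
    mean_z: float
    n_windows: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def normalize_depth(windows: pd.DataFrame, robust: bool = False) -> pd.DataFrame:
    """Normalize window depths per chromosome.

    Adds ``normalized_depth`` (raw depth over the chromosome center — mean,
    or median with ``robust``) plus per-chromosome ``center_norm`` and
    ``sd_norm`` columns used by segmentation.  The SD is computed after a
    single trimming pass discarding windows beyond 3 SD, so that large true
    events (up to whole chromosomes) do not inflate the null spread.
    """
    missing = [c for c in WINDOW_COLUMNS if c not in windows.columns]
    if missing:
        raise ValueError(f"window table lacks columns {missing}")
    out = windows.reset_index(drop=True).copy()
    normalized = np.full(len(out), np.nan)
    centers = np.full(len(out), np.nan)
    sds = np.full(len(out), np.nan)
    raw_all = out["raw_depth"].to_numpy(dtype=float)
    for chrom, idx in out.groupby("chromosome", sort=False).indices.items():
        raw = raw_all[idx]
        center = float(np.median(raw)) if robust else float(np.mean(raw))
        if center <= 0:
            raise ValueError(f"chromosome {chrom} has no coverage (center {center})")
        norm = raw / center
        mean0, sd0 = float(np.mean(norm)), float(np.std(norm))
        if sd0 > 0:
            keep = np.abs(norm - mean0) <= TRIM_SD * sd0
            if keep.sum() >= 2:
                mean0, sd0 = float(np.mean(norm[keep])), float(np.std(norm[keep]))
        normalized[idx] = norm
        centers[idx] = mean0
        sds[idx] = sd0
    out["normalized_depth"] = normalized
    out["center_norm"] = centers
    out["sd_norm"] = sds
    return out


def call_depth_segments(
    windows: pd.DataFrame,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> list[DepthSegment]:
    """Call deviant segments from normalized windows.

    A segment is a maximal run of at least ``min_windows`` consecutive
    windows whose normalized depth deviates from the chromosomal mean by at
    least ``sd_multiplier`` SD, all in the same direction (gain above the
    mean, loss below).
    """
    if "normalized_depth" not in windows.columns:
        raise ValueError("call normalize_depth first")
    segments: list[DepthSegment] = []
    for chrom, grp in windows.groupby("chromosome", sort=False):
        grp = grp.sort_values("start")
        sd = float(grp["sd_norm"].iloc[0])
        mean = float(grp["center_norm"].iloc[0])
        if sd <= 0:
            continue
        z = (grp["normalized_depth"].to_numpy() - mean) / sd
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        state = np.where(z >= sd_multiplier, 1, np.where(z <= -sd_multiplier, -1, 0))
        i = 0
        n = len(state)
        while i < n:
            if state[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < n and state[j + 1] == state[i]:
                j += 1
            if j - i + 1 >= min_windows:
                segments.append(
                    DepthSegment(
                        chromosome=str(chrom),
                        start=int(starts[i]),
                        end=int(ends[j]),
                        direction=Direction.GAIN if state[i] == 1 else Direction.LOSS,
                        mean_z=float(np.mean(z[i : j + 1])),
                        n_windows=int(j - i + 1),
                    )
                )
            i = j + 1
    return segments


def pair_homoeologous_segments(
    segments: Sequence[DepthSegment],
    homoeology_map: Sequence[HomoeologyBlock],
    population_id: str = "",
) -> tuple[list[Event], list[DepthSegment]]:
    """Pair gain and loss depth segments through the homoeology map.

    A gain segment pairs with a loss segment when the projection of the loss
    through any block overlaps the gain; pairs are emitted as fixed-exchange
    candidate events (greedy, largest projected overlap first; each segment
    pairs at most once).  Returns (candidate events, unpaired segments).
    """
    gains = [s for s in segments if s.direction is Direction.GAIN]
    losses = [s for s in segments if s.direction is Direction.LOSS]
    candidates: list[tuple[int, int, int]] = []
    for gi, g in enumerate(gains):
        for li, l in enumerate(losses):
            overlap = _best_projected_overlap(g, l, homoeology_map)
            if overlap > 0:
                candidates.append((overlap, gi, li))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    events: list[Event] = []
    used_g: set[int] = set()
    used_l: set[int] = set()
    for _, gi, li in candidates:
        if gi in used_g or li in used_l:
            continue
        used_g.add(gi)
        used_l.add(li)
        g, l = gains[gi], losses[li]
        events.append(
            Event(
                event_id=f"fx{len(events):04d}",
                individual_id=population_id or "population",
                type=EventType.HER,
                gain_region=Region(g.chromosome, g.start, g.end, g.n_windows),
                loss_region=Region(l.chromosome, l.start, l.end, l.n_windows),
                inheritance=Inheritance.FIXED,
                population_id=population_id,
            )
        )
    unpaired = [s for i, s in enumerate(gains) if i not in used_g]
    unpaired += [s for i, s in enumerate(losses) if i not in used_l]
    return events, unpaired


def _best_projected_overlap(
    gain: DepthSegment, loss: DepthSegment, blocks: Sequence[HomoeologyBlock]
) -> int:
    best = 0
    for block in blocks:
        proj = project_interval(block, loss.chromosome, loss.start, loss.end)
        if proj is None or proj[0] != gain.chromosome:
            continue
        lo = max(proj[1], gain.start)
        hi = min(proj[2], gain.end)
        if lo <= hi:
            best = max(best, hi - lo + 1)
    return best
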