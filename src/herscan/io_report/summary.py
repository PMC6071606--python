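"""Aggregation of classified events into per-line and per-chromosome tables.

Conventions: exchange (HeR) events are counted once per event in line
tallies but contribute one gain and one loss entry to chromosome tallies;
aneuploid events are counted per affected chromosome; events with unknown
parent attribution go to an "unattributed" row rather than being dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ..event_detection import Event, EventType, Inheritance, Region
from ..probe_annotation import Subgenome, subgenome_of_chromosome

__all__ = [
    "PopulationInfo",
    "LineSummary",
    "ChromosomeSummary",
    "summarize_by_line",
    "summarize_by_chromosome",
    "derived_statistics",
    "mb_by_chromosome",
    "events_from_count_tables",
]

UNATTRIBUTED = "unattributed"


@dataclass(frozen=True)
class PopulationInfo:
    population_id: str
    line_parent: str
    tester_parent: str
    n_individuals: int


@dataclass(frozen=True)
class LineSummary:
    line_id: str
    n_individuals: int
    duplication: int = 0
    deletion: int = 0
    her: int = 0
    aneuploid: int = 0

    @property
    def total(self) -> int:
        return self.duplication + self.deletion + self.her + self.aneuploid


@dataclass(frozen=True)
class ChromosomeSummary:
    chromosome: str
    duplication: int = 0
    deletion: int = 0
    her_gain: int = 0
    her_loss: int = 0
    aneuploid: int = 0
    aneuploid_gain: int = 0  # subcounts of the aneuploid column
    aneuploid_loss: int = 0

    @property
    def total(self) -> int:
        return (self.duplication + self.deletion + self.her_gain
                + self.her_loss + self.aneuploid)


def _de_novo(events: Iterable[Event]) -> list[Event]:
    return [e for e in events if e.inheritance is Inheritance.DE_NOVO]


def summarize_by_line(
    events: Sequence[Event],
    populations: Sequence[PopulationInfo],
) -> list[LineSummary]:
    """Tally de novo events per parent of origin.

    One row per line parent, plus a single row for the common tester
    (accumulated over all populations, with the total individual count) and,
    when needed, an ``unattributed`` row.
    """
    testers = {p.tester_parent for p in populations}
    if len(testers) > 1:
        raise ValueError(f"multiple tester parents: {sorted(testers)}")
    tester = next(iter(testers)) if testers else None

    counts: dict[str, dict[str, int]] = {}
    for p in populations:
        counts.setdefault(
            p.line_parent, {"duplication": 0, "deletion": 0, "her": 0, "aneuploid": 0}
        )
    if tester is not None:
        counts.setdefault(
            tester, {"duplication": 0, "deletion": 0, "her": 0, "aneuploid": 0}
        )

    for event in _de_novo(events):
        parent = event.parent_of_origin
        if parent not in counts:
            parent = UNATTRIBUTED
            counts.setdefault(
                parent, {"duplication": 0, "deletion": 0, "her": 0, "aneuploid": 0}
            )
        key = {
            EventType.DUPLICATION: "duplication",
            EventType.DELETION: "deletion",
            EventType.HER: "her",
            EventType.ANEUPLOID_GAIN: "aneuploid",
            EventType.ANEUPLOID_LOSS: "aneuploid",
        }[event.type]
        counts[parent][key] += 1

    n_by_line = {p.line_parent: p.n_individuals for p in populations}
    total_individuals = sum(p.n_individuals for p in populations)
    rows = []
    for line_id, c in counts.items():
        if line_id == tester:
            n = total_individuals
        else:
            n = n_by_line.get(line_id, 0)
        rows.append(LineSummary(line_id, n, **c))
    return rows


def summarize_by_chromosome(
    events: Sequence[Event], append_total: bool = True
) -> list[ChromosomeSummary]:
    """Tally de novo events per chromosome.

    Exchange events contribute a gain on the gained chromosome and a loss on
    the lost one; a totals row (chromosome = "TOTAL") is appended.
    """
    counts: dict[str, dict[str, int]] = {}

    def bump(chrom: str, key: str) -> None:
        row = counts.setdefault(
            chrom,
            {"duplication": 0, "deletion": 0, "her_gain": 0, "her_loss": 0,
             "aneuploid": 0, "aneuploid_gain": 0, "aneuploid_loss": 0},
        )
        row[key] += 1

    for event in _de_novo(events):
        if event.type is EventType.HER:
            bump(event.gain_region.chromosome, "her_gain")
            bump(event.loss_region.chromosome, "her_loss")
        elif event.type is EventType.DUPLICATION:
            bump(event.gain_region.chromosome, "duplication")
        elif event.type is EventType.DELETION:
            bump(event.loss_region.chromosome, "deletion")
        elif event.type is EventType.ANEUPLOID_GAIN:
            bump(event.gain_region.chromosome, "aneuploid")
            bump(event.gain_region.chromosome, "aneuploid_gain")
        elif event.type is EventType.ANEUPLOID_LOSS:
            bump(event.loss_region.chromosome, "aneuploid")
            bump(event.loss_region.chromosome, "aneuploid_loss")

    rows = [
        ChromosomeSummary(chrom, **counts[chrom]) for chrom in sorted(
            counts, key=_chromosome_sort_key
        )
    ]
    if append_total:
        rows.append(
            ChromosomeSummary(
                "TOTAL",
                duplication=sum(r.duplication for r in rows),
                deletion=sum(r.deletion for r in rows),
                her_gain=sum(r.her_gain for r in rows),
                her_loss=sum(r.her_loss for r in rows),
                aneuploid=sum(r.aneuploid for r in rows),
                aneuploid_gain=sum(r.aneuploid_gain for r in rows),
                aneuploid_loss=sum(r.aneuploid_loss for r in rows),
            )
        )
    return rows


def _chromosome_sort_key(chrom: str) -> tuple[str, int]:
    prefix = chrom[:1]
    try:
        return (prefix, int(chrom[1:]))
    except ValueError:
        return (prefix, 0)


def derived_statistics(
    chromosome_summaries: Sequence[ChromosomeSummary],
    line_summaries: Optional[Sequence[LineSummary]] = None,
    events: Optional[Sequence[Event]] = None,
    her_pair: tuple[str, str] = ("A1", "C1"),
    tester_id: Optional[str] = None,
) -> dict[str, object]:
    """Named statistics derived from the per-chromosome (and per-line) tallies.

    Percent shares of exchange gains are floored to whole percent (exact
    fractions reported alongside); ratios are undefined (None) when there
    are no exchange events rather than zero.  The named-pair exchange count
    requires the event list (pairing is not recoverable from marginal
    counts).
    """
    per_chrom = [s for s in chromosome_summaries if s.chromosome != "TOTAL"]

    def is_a(chrom: str) -> bool:
        return subgenome_of_chromosome(chrom) is Subgenome.A

    her_total = sum(s.her_gain for s in per_chrom)
    her_loss_total = sum(s.her_loss for s in per_chrom)
    dup_total = sum(s.duplication for s in per_chrom)
    del_total = sum(s.deletion for s in per_chrom)
    aneuploid_total = sum(s.aneuploid for s in per_chrom)

    a_her_gain = sum(s.her_gain for s in per_chrom if is_a(s.chromosome))
    stats: dict[str, object] = {
        "her_events": her_total,
        "her_gain_total": her_total,
        "her_loss_total": her_loss_total,
        "duplication_events": dup_total,
        "deletion_events": del_total,
        "aneuploid_events": aneuploid_total,
        "gain_or_loss_only_events": dup_total + del_total + aneuploid_total,
        "distinct_de_novo_events": dup_total + del_total + aneuploid_total + her_total,
    }

    if her_total > 0:
        fraction = a_her_gain / her_total
        stats["a_genome_her_gain_fraction"] = fraction
        stats["a_genome_her_gain_share_pct"] = math.floor(100 * fraction)
    else:
        stats["a_genome_her_gain_fraction"] = None
        stats["a_genome_her_gain_share_pct"] = None

    for genome, pred in (("a", is_a), ("c", lambda c: not is_a(c))):
        rows = [s for s in per_chrom if pred(s.chromosome)]
        stats[f"{genome}_genome_deletions"] = sum(s.deletion for s in rows)
        stats[f"{genome}_genome_gains_total"] = sum(
            s.duplication + s.her_gain + s.aneuploid_gain for s in rows
        )
        stats[f"{genome}_genome_losses_total"] = sum(
            s.deletion + s.her_loss + s.aneuploid_loss for s in rows
        )
        stats[f"{genome}_genome_aneuploid_gains"] = sum(s.aneuploid_gain for s in rows)
        stats[f"{genome}_genome_aneuploid_losses"] = sum(s.aneuploid_loss for s in rows)

    if line_summaries is not None:
        rows = [s for s in line_summaries if s.line_id != UNATTRIBUTED]
        if tester_id is not None:
            line_rows = [s for s in rows if s.line_id != tester_id]
        elif len(rows) > 1:
            # the common tester appears in every population, so its row
            # carries the largest individual count; drop that one row
            tester_row = max(rows, key=lambda s: s.n_individuals)
            line_rows = [s for s in rows if s is not tester_row]
        else:
            line_rows = rows
        individuals = sum(s.n_individuals for s in line_rows)
        stats["individuals"] = individuals
        stats["meioses"] = 2 * individuals

    if events is not None:
        pair = frozenset(her_pair)
        pair_count = sum(
            1
            for e in _de_novo(events)
            if e.type is EventType.HER
            and {e.gain_region.chromosome, e.loss_region.chromosome} == pair
        )
        stats["her_pair"] = "/".join(her_pair)
        stats["her_pair_events"] = pair_count
        stats["her_pair_share_pct"] = (
            round(100 * pair_count / her_total) if her_total else None
        )
        stats["aneuploid_a1_a2_c1_c2"] = sum(
            s.aneuploid for s in per_chrom
            if s.chromosome in ("A1", "A2", "C1", "C2")
        )
    return stats


def mb_by_chromosome(events: Sequence[Event]) -> pd.DataFrame:
    """Mb gained/lost per chromosome per category (event spans summed)."""
    rows: dict[tuple[str, str], float] = {}

    def add(region: Optional[Region], category: str) -> None:
        if region is None:
            return
        key = (region.chromosome, category)
        rows[key] = rows.get(key, 0.0) + region.size_mb

    for e in _de_novo(events):
        if e.type is EventType.HER:
            add(e.gain_region, "her_gain_mb")
            add(e.loss_region, "her_loss_mb")
        elif e.type is EventType.DUPLICATION:
            add(e.gain_region, "duplication_mb")
        elif e.type is EventType.DELETION:
            add(e.loss_region, "deletion_mb")
        elif e.type is EventType.ANEUPLOID_GAIN:
            add(e.gain_region, "aneuploid_gain_mb")
        elif e.type is EventType.ANEUPLOID_LOSS:
            add(e.loss_region, "aneuploid_loss_mb")

    df = pd.DataFrame(
        [(c, cat, mb) for (c, cat), mb in rows.items()],
        columns=["chromosome", "category", "mb"],
    )
    if df.empty:
        return df
    out = df.pivot_table(index="chromosome", columns="category", values="mb",
                         fill_value=0.0, aggfunc="sum")
    return out.reset_index().rename_axis(None, axis=1)


def events_from_count_tables(
    segmental_counts: pd.DataFrame,
    her_pair_counts: pd.DataFrame,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> list[Event]:
    """Expand per-chromosome count tables into a nominal de novo event list.

    ``segmental_counts`` columns: chromosome, duplication, deletion,
    aneuploid_gain, aneuploid_loss.  ``her_pair_counts`` columns:
    gain_chromosome, loss_chromosome, count.  Each counted event becomes one
    Event with a placeholder span (full chromosome for aneuploids when
    lengths are given, else nominal), one synthetic carrier individual per
    event so population-level tallies treat them as distinct de novo events.
    """
    events: list[Event] = []
    counter = 0

    def span(chrom: str) -> tuple[int, int]:
        if chromosome_lengths and chrom in chromosome_lengths:
            return (1, chromosome_lengths[chrom])
        return (1, 1)

    def new_event(etype: EventType, gain: Optional[str], loss: Optional[str]) -> Event:
        nonlocal counter
        counter += 1
        gain_region = Region(gain, *span(gain)) if gain else None
        loss_region = Region(loss, *span(loss)) if loss else None
        return Event(
            event_id=f"fx{counter:05d}",
            individual_id=f"carrier{counter:05d}",
            type=etype,
            gain_region=gain_region,
            loss_region=loss_region,
            inheritance=Inheritance.DE_NOVO,
        )

    for row in segmental_counts.itertuples(index=False):
        chrom = str(row.chromosome)
        for _ in range(int(row.duplication)):
            events.append(new_event(EventType.DUPLICATION, chrom, None))
        for _ in range(int(row.deletion)):
            events.append(new_event(EventType.DELETION, None, chrom))
        for _ in range(int(getattr(row, "aneuploid_gain", 0))):
            events.append(new_event(EventType.ANEUPLOID_GAIN, chrom, None))
        for _ in range(int(getattr(row, "aneuploid_loss", 0))):
            events.append(new_event(EventType.ANEUPLOID_LOSS, None, chrom))

    for _, row in her_pair_counts.iterrows():
        for _ in range(int(row["count"])):
            events.append(
                new_event(EventType.HER, str(row["gain_chromosome"]),
                          str(row["loss_chromosome"]))
            )
    return events
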