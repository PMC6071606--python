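"""Tab-delimited readers and writers for every pipeline interface.

All text outputs are UTF-8 TSV; metadata lines start with ``#`` and are
skipped on read.  Event tables round-trip losslessly.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from ..event_detection import (
    CentromereRelation,
    ChromosomeModel,
    Event,
    EventType,
    Inheritance,
    Region,
)
from ..genotyping import Genotype
from ..probe_annotation import (
    GenomeHit,
    HomoeologyBlock,
    Orientation,
    ProbeLocus,
    Specificity,
    subgenome_of_chromosome,
)

__all__ = [
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_hits_tsv",
    "read_psl",
    "write_probe_annotation_tsv",
    "read_probe_annotation_tsv",
    "write_homoeology_map_bed",
    "write_homoeology_map_tsv",
    "read_homoeology_map_tsv",
    "read_chromosome_models",
    "write_chromosome_models",
    "read_depth_windows",
    "write_depth_windows",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_events_tsv",
    "read_events_tsv",
    "write_events_bed",
]

PathLike = Union[str, Path]

_INTENSITY_COLUMNS = {"Sample ID": "individual_id", "SNP Name": "probe_id",
                      "Theta": "theta", "R": "r"}


def read_intensity_tsv(path: PathLike) -> pd.DataFrame:
    """Read a long-format intensity export (Sample ID, SNP Name, Theta, R).

    Lowercase column names (individual_id, probe_id, theta, r) are accepted
    as well; an optional GType column is preserved if present.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns=_INTENSITY_COLUMNS)
    required = ["individual_id", "probe_id", "theta", "r"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table {path} lacks columns {missing}")
    return df


def write_intensity_tsv(df: pd.DataFrame, path: PathLike) -> None:
    out = df.rename(columns={v: k for k, v in _INTENSITY_COLUMNS.items()})
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# long-format array intensities\n")
        out.to_csv(fh, sep="\t", index=False)


def read_hits_tsv(path: PathLike) -> list[GenomeHit]:
    """Read simplified alignment hits: probe_id, chromosome, position, identity."""
    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            GenomeHit(
                probe_id=str(row.probe_id),
                subgenome=subgenome_of_chromosome(str(row.chromosome)),
                chromosome=str(row.chromosome),
                position=int(row.position),
                identity=float(row.identity),
            )
        )
    return hits


def read_psl(path: PathLike) -> list[GenomeHit]:
    """Read standard 21-column BLAT PSL alignments.

    Identity is matches (plus repeat matches) over aligned bases; the hit
    position is the 1-based target start.  Header/separator lines are
    skipped.  Target names must carry an A/C chromosome prefix.
    """
    hits: list[GenomeHit] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 21 or not fields[0].isdigit():
                continue
            matches = int(fields[0])
            mismatches = int(fields[1])
            rep_matches = int(fields[2])
            n_count = int(fields[3])
            aligned = matches + mismatches + rep_matches + n_count
            identity = (matches + rep_matches) / aligned if aligned else 0.0
            probe_id = fields[9]
            t_name = fields[13]
            t_start = int(fields[15]) + 1  # PSL is 0-based half-open
            hits.append(
                GenomeHit(
                    probe_id=probe_id,
                    subgenome=subgenome_of_chromosome(t_name),
                    chromosome=t_name,
                    position=t_start,
                    identity=identity,
                )
            )
    return hits


def write_probe_annotation_tsv(loci: Sequence[ProbeLocus], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# probe subgenome annotation\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["probe_id", "specificity", "chromosome", "position",
             "homoeologous_chromosome", "homoeologous_position"]
        )
        for loc in loci:
            chrom, pos = loc.primary_locus or ("", "")
            hchrom, hpos = loc.homoeologous_locus or ("", "")
            writer.writerow(
                [loc.probe_id, loc.specificity.value, chrom, pos, hchrom, hpos]
            )


def read_probe_annotation_tsv(path: PathLike) -> list[ProbeLocus]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    loci = []
    for row in df.itertuples(index=False):
        primary = (
            (row.chromosome, int(float(row.position)))
            if row.chromosome else None
        )
        homoeologous = (
            (row.homoeologous_chromosome, int(float(row.homoeologous_position)))
            if row.homoeologous_chromosome else None
        )
        loci.append(
            ProbeLocus(
                probe_id=row.probe_id,
                specificity=Specificity(row.specificity),
                primary_locus=primary,
                homoeologous_locus=homoeologous,
            )
        )
    return loci


def write_homoeology_map_bed(
    blocks: Sequence[HomoeologyBlock], prefix: PathLike
) -> tuple[Path, Path]:
    """Write the homoeology map as two BED6 files (A side and C side) keyed
    by block id.  BED is 0-based half-open."""
    prefix = Path(prefix)
    a_path = prefix.with_suffix(".a.bed")
    c_path = prefix.with_suffix(".c.bed")
    with open(a_path, "w", encoding="utf-8") as fa, \
            open(c_path, "w", encoding="utf-8") as fc:
        for block in blocks:
            strand = "+" if block.orientation is Orientation.SAME else "-"
            a_chrom, a_start, a_end = block.a_interval
            c_chrom, c_start, c_end = block.c_interval
            fa.write(f"{a_chrom}\t{a_start - 1}\t{a_end}\t{block.block_id}"
                     f"\t{block.n_probes}\t+\n")
            fc.write(f"{c_chrom}\t{c_start - 1}\t{c_end}\t{block.block_id}"
                     f"\t{block.n_probes}\t{strand}\n")
    return a_path, c_path


def write_homoeology_map_tsv(blocks: Sequence[HomoeologyBlock], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# homoeology blocks (1-based inclusive intervals)\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["block_id", "a_chromosome", "a_start", "a_end",
                         "c_chromosome", "c_start", "c_end", "orientation",
                         "n_probes"])
        for b in blocks:
            writer.writerow([b.block_id, *b.a_interval, *b.c_interval,
                             b.orientation.value, b.n_probes])


def read_homoeology_map_tsv(path: PathLike) -> list[HomoeologyBlock]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        HomoeologyBlock(
            block_id=str(row.block_id),
            a_interval=(str(row.a_chromosome), int(row.a_start), int(row.a_end)),
            c_interval=(str(row.c_chromosome), int(row.c_start), int(row.c_end)),
            orientation=Orientation(row.orientation),
            n_probes=int(row.n_probes),
        )
        for row in df.itertuples(index=False)
    ]


def read_chromosome_models(path: PathLike) -> dict[str, ChromosomeModel]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return {
        str(row.chromosome): ChromosomeModel(
            name=str(row.chromosome),
            length=int(row.length),
            centromere=(int(row.centromere_start), int(row.centromere_end)),
        )
        for row in df.itertuples(index=False)
    }


def write_chromosome_models(
    models: Mapping[str, ChromosomeModel], path: PathLike
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# chromosome models\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["chromosome", "length", "centromere_start",
                         "centromere_end"])
        for model in models.values():
            writer.writerow([model.name, model.length, *model.centromere])


def read_depth_windows(path: PathLike) -> pd.DataFrame:
    """Read a bedGraph or headered 4-column TSV into a window table.

    bedGraph intervals (0-based half-open) are converted to 1-based
    inclusive coordinates.
    """
    first = ""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                first = line
                break
    has_header = "chromosome" in first
    if has_header:
        df = pd.read_csv(path, sep="\t", comment="#")
        need = ["chromosome", "start", "end", "raw_depth"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"depth table {path} lacks columns {missing}")
        return df[need]
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chromosome", "start", "end", "raw_depth"],
        skiprows=1 if first.startswith("track") else 0,
    )
    df["start"] = df["start"].astype(int) + 1  # bedGraph -> 1-based inclusive
    return df


def write_depth_windows(df: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# windowed depth (1-based inclusive)\n")
        df.to_csv(fh, sep="\t", index=False)


def write_genotype_matrix(
    matrix: pd.DataFrame, path: PathLike
) -> None:
    """Write a markers x individuals matrix of 8-state genotype codes."""
    bad = set(matrix.to_numpy().ravel()) - {g.value for g in Genotype} - {""}
    if bad:
        raise ValueError(f"non-genotype codes in matrix: {sorted(bad)[:5]}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# genotype matrix: rows are markers, columns individuals\n")
        matrix.to_csv(fh, sep="\t", index=True, index_label="probe_id")


def read_genotype_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col="probe_id",
                       dtype=str).fillna("NC")


_EVENT_FIELDS = [
    "event_id", "population_id", "individual_id", "type",
    "gain_chromosome", "gain_start", "gain_end", "gain_support",
    "loss_chromosome", "loss_start", "loss_end", "loss_support",
    "inheritance", "parent_of_origin", "breakpoint_intervals",
    "centromere_relation", "low_confidence", "flagged",
]


def write_events_tsv(events: Sequence[Event], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# classified chromosomal events (1-based inclusive)\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EVENT_FIELDS)
        for e in events:
            g = e.gain_region
            l = e.loss_region
            bps = ";".join(f"{lo}-{hi}" for lo, hi in e.breakpoint_intervals)
            writer.writerow([
                e.event_id, e.population_id, e.individual_id, e.type.value,
                g.chromosome if g else "", g.start if g else "",
                g.end if g else "", g.n_support_loci if g else "",
                l.chromosome if l else "", l.start if l else "",
                l.end if l else "", l.n_support_loci if l else "",
                e.inheritance.value, e.parent_of_origin, bps,
                e.centromere_relation.value, int(e.low_confidence),
                int(e.flagged),
            ])


def read_events_tsv(path: PathLike) -> list[Event]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    events = []
    for row in df.itertuples(index=False):
        gain = (
            Region(row.gain_chromosome, int(row.gain_start), int(row.gain_end),
                   int(row.gain_support))
            if row.gain_chromosome else None
        )
        loss = (
            Region(row.loss_chromosome, int(row.loss_start), int(row.loss_end),
                   int(row.loss_support))
            if row.loss_chromosome else None
        )
        bps = tuple(
            (int(part.split("-")[0]), int(part.split("-")[1]))
            for part in row.breakpoint_intervals.split(";")
            if part
        )
        events.append(
            Event(
                event_id=row.event_id,
                population_id=row.population_id,
                individual_id=row.individual_id,
                type=EventType(row.type),
                gain_region=gain,
                loss_region=loss,
                inheritance=Inheritance(row.inheritance),
                parent_of_origin=row.parent_of_origin,
                breakpoint_intervals=bps,
                centromere_relation=CentromereRelation(row.centromere_relation),
                low_confidence=bool(int(row.low_confidence)),
                flagged=bool(int(row.flagged)),
            )
        )
    return events


def write_events_bed(events: Sequence[Event], path: PathLike) -> None:
    """Write one BED6+ row per event region; paired exchange regions share
    the event id in the name field (suffixed :gain / :loss)."""
    with open(path, "w", encoding="utf-8") as fh:
        for e in events:
            for label, region in (("gain", e.gain_region), ("loss", e.loss_region)):
                if region is None:
                    continue
                name = f"{e.event_id}:{label}:{e.type.value}"
                fh.write(
                    f"{region.chromosome}\t{region.start - 1}\t{region.end}"
                    f"\t{name}\t{region.n_support_loci}\t+"
                    f"\t{e.individual_id}\t{e.inheritance.value}"
                    f"\t{e.parent_of_origin}\n"
                )
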