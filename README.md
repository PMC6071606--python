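# herscan

Detection of de novo homoeologous exchanges, segmental
duplications/deletions and aneuploidy in allotetraploid (A/C-subgenome)
testcross populations from genome-wide SNP-array intensity data, plus a
read-depth route for confirming exchanges fixed in a parent line.

An exchange between homoeologous chromosomes that transmits only one
recombined product shows up in marker data as reciprocal dosage change: a
run of allele losses on one chromosome mirrored by a run of gains on the
syntenic interval of its homoeologue, both arising in the same parental
meiosis. `herscan` implements the full path from raw two-channel
intensities to a classified, summarized event catalog:

| module                       | role |
|------------------------------|------|
| `herscan.probe_annotation`   | classify probes by subgenome specificity from alignment hits (>90%/<90% identity rule); build the A↔C homoeology block map from cross-genome probe pairings (≥50% identity) |
| `herscan.genotyping`         | parental-anchored 8-state genotype calling (`AA AB BB A0 B0 AAB ABB NC`) from θ/R intensities; dosage derivation per marker |
| `herscan.event_detection`    | run-finding over dosage vectors (≥3 consecutive aberrant loci, one interior no-call tolerated), reciprocal gain/loss pairing through the homoeology map, aneuploidy splitting, inheritance classification (de novo / segregating / fixed), parent-of-origin attribution, breakpoint intervals, centromere annotation |
| `herscan.depth_confirmation` | per-chromosome depth normalization, 1.5 SD segment calling, homoeologous gain/loss pairing into fixed-exchange candidates |
| `herscan.simdata`            | seeded synthetic testcross families: pseudo-tetraploid marker map, planted events at per-meiosis rates, θ/R rendering, depth profiles, truth catalogs |
| `herscan.io_report`          | TSV/PSL/BED/bedGraph I/O, per-line and per-chromosome summary tables, derived statistics, CLI |

## CLI

```bash
herscan simulate --seed 7 --n-individuals 20 --out-dir sim/
herscan annotate --hits hits.tsv --out-prefix ann          # or --psl file.psl
herscan genotype --intensities sim/intensities.tsv --parent1 P1 --parent2 P2 --out geno.tsv
herscan detect   --intensities sim/intensities.tsv --positions sim/positions.tsv \
                 --map sim/map.tsv --models sim/models.tsv \
                 --parent1 P1 --parent2 P2 --out-prefix res
herscan depth    --windows depth.bedgraph --map sim/map.tsv --out-prefix d
herscan report   --events res.events.tsv --out-prefix rep
```

All commands log to stderr and write data only to files. YAML configuration
(`--config`) can override genotyping thresholds, detection parameters and
simulation rates.

## Formats

- intensities: long-format TSV (`Sample ID`, `SNP Name`, `Theta`, `R`)
- alignment hits: 21-column BLAT PSL or simplified TSV
  (`probe_id chromosome position identity`)
- chromosome models: TSV (`chromosome length centromere_start centromere_end`)
- depth: bedGraph (0-based) or headered TSV (1-based)
- events: TSV (lossless round trip) and BED6+ (exchange events emit paired
  rows sharing an event id)

Coordinates are 1-based inclusive except in BED/bedGraph output.

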