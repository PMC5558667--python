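# bhlhkit

A tested, reusable pipeline for genome-wide basic helix-loop-helix (bHLH)
transcription-factor family analysis:

* **Domain scanning** — mismatch-tolerant alignment of proteomes to a
  per-position consensus profile (19 conserved residues across the basic
  region / helix 1 / loop / helix 2; up to 9 mismatches accepted by default),
  with a variable-length loop and exhaustive, exact window search.
* **DNA-binding classification** — the four-way residue rule (G-box / E-box
  non-G / non-E-box binder / non-DNA-binding) from labeled profile positions
  (His/Lys-9, Glu-13, Arg-16, Arg-17, basic-residue count), plus
  dimerization (Leu-27/Leu-54) and tetramerization (Arg-14/Gln-15/Gln-22)
  flags.
* **Phylogenetics** — p-distance (or Poisson) matrices, neighbor joining
  with deterministic tie-breaking, column-bootstrap support, and subfamily
  extraction at support > 50.
* **Duplication & evolution** — tandem-duplicate calling from full gene
  order (no intervening gene), segmental assignment from synteny blocks,
  Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction implemented from
  scratch, selection classification, and molecular-clock dating
  (T = Ks / 2λ, default λ = 6.5e-9).
* **Gene structure & expression** — spliced-alignment exon inference
  (GT..AG introns), intron-to-domain-position mapping with phases,
  intron-distribution pattern typing (pattern IV = introns at His-9 and
  Val-31 shipped), IUPAC promoter motif scanning, log2 expression matrices
  and 2^(−ΔΔCt) qPCR fold changes.
* **Synthetic data** — seed-deterministic generators with machine-readable
  truth ledgers for every stage (planted domains at controlled mismatch
  counts, codon pairs evolved at a chosen ω, multi-exon gene models,
  duplication layouts, expression/Ct tables), so the whole pipeline is
  exercisable without any downloads.

## Command line

One tool with subcommands (`bhlhkit --help`):

```sh
# self-contained demo: simulate a bundle and run every stage on it
bhlhkit all --out-dir runs/demo --seed 1

# individual stages
bhlhkit simulate --out-dir runs/demo --seed 1
bhlhkit scan     --out-dir runs/demo runs/demo/proteome.fasta
bhlhkit classify --out-dir runs/demo runs/demo/proteome.fasta
bhlhkit phylo    --out-dir runs/demo --bootstrap-reps 1000 runs/demo/proteome.fasta
bhlhkit dup      --out-dir runs/demo --gff runs/demo/layout.gff3 \
                 --blocks runs/demo/blocks.tsv \
                 --proteins runs/demo/layout_proteins.fasta \
                 --family family.txt
bhlhkit expr     --out-dir runs/demo --matrix runs/demo/expression.tsv \
                 --qpcr runs/demo/qpcr.tsv
```

Defaults mirror the published analysis settings: mismatch budget 9, 1000
bootstrap replicates, subfamily support threshold 50, 1500 bp promoter
windows. A flat `key=value` config file can be passed with `--config`;
flags override the file. Every output table header records the tool
version, seed, clock rate and a config hash.

The consensus profile, hydropathy/mass/pKa tables, intron-pattern catalog
and motif dictionary are plain TSV data files under `src/bhlhkit/data/` and
can all be replaced via flags/config.

## Layout

```
src/bhlhkit/
  io_formats.py             FASTA/GFF3/synteny/BED/TSV I/O, coordinates
  domain_scan.py            consensus profile, scanning, physicochemistry
  binding_classify.py       four-way DNA-binding residue rule
  phylogeny.py              distances, NJ, bootstrap, subfamilies
  duplication_evolution.py  tandem/segmental calling, NG86 Ka/Ks, dating
  structure_expression.py   exon inference, intron patterns, motifs, ddCt
  synthetic_data.py         ground-truthed generators
  cli_pipeline.py           click CLI and stage orchestration
  data/                     replaceable TSV resources
tests/                      pytest suite incl. acceptance criteria
scripts/acceptance.py       acceptance report generator
```
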