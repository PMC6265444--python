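# rg4i

Analysis toolkit for RNA G-quadruplex (rG4) interactome studies. It covers
the computational arm of an affinity-proteomics + iCLAE workflow:

- **enrich_ms** — negative-binomial GLM enrichment of unique-peptide-count
  matrices (rG4 bait vs merged mrG4/SL/beads controls), with library-size
  offsets, common-dispersion estimation by adjusted profile likelihood,
  quasi-likelihood moderated testing, BH FDR, and the high-confidence
  (FDR < 0.05) and refined (mean rG4 UPC ≥ 6) interactor filters.
- **garscan** — GAR (glycine-arginine-rich) motif classification of protein
  sequences by contiguous RG/RGG tandem repeats, with foreground-vs-background
  class-frequency tests (Fisher exact + Yates chi-square).
- **iclae_proc** — iCLAE read preprocessing (identical-read collapse, exact
  4-nt barcode demultiplexing with 5-nt UMIs from an N3-XXXX-N2 prefix,
  homopolymer filter, MAPQ ≥ 10 filter, UMI deduplication), per-base
  coverage, rule-based peak calling (coverage > 10, merge gaps < 30 nt,
  drop widths < 30 nt), two-of-three replicate consensus, and 100-nt
  binding-region extraction.
- **rg4map** — (G2-L12)4 G4-motif scanning, peak classification against
  transcript features, shuffle-based category fold enrichment over expressed
  transcripts, WT-vs-mutant peak overlap and differential binding,
  top-quartile/G4/logFC target selection, hypergeometric term enrichment,
  and expression-binding correlation.
- **simulate** — seeded synthetic-data generators (count matrices, G4-planted
  transcriptomes, crosslink reads, GAR-planted proteins) that emit ground
  truth for every stage.
- **formats** — readers/writers for the plain-text dialects the pipeline
  consumes (FASTA/FASTQ, GTF subset, alignment TSV, count matrix + condition
  side-car, FPKM and term-map TSVs). All coordinates are 0-based half-open
  internally.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the desk-scale acceptance battery (oracle
equivalences for the peak caller and G4 scanner, planted-site recovery,
proteomics power/FDR control, WT-vs-mutant G4 contrast, shuffle-enrichment
calibration, statistical cross-checks). Brute-force oracles live in
`tests/oracles.py` and are independent of the package.

## CLI

```sh
rg4i demo --out-dir out/ --seed 1            # full synthetic end-to-end run
rg4i enrich --counts counts.tsv --conditions cond.tsv --out enrich.tsv
rg4i garscan --fasta prot.fa --foreground ids.txt --out gar.tsv
rg4i iclae demux --fastq raw.fastq --barcodes bc.tsv --out-dir demux/
rg4i iclae dedupe --alignments aln.tsv --out dedup.tsv
rg4i iclae peaks --alignments rep1.tsv --alignments rep2.tsv \
    --alignments rep3.tsv --fasta tx.fa --out peaks.bed
rg4i map peaks.bed --annotation ann.tsv --fasta tx.fa --fpkm fpkm.tsv \
    --wt-alignments wt.tsv --mut-alignments mut.tsv --out-dir results/
```

`rg4i demo` writes all intermediate files, a `report.md` with the headline
statistics, and a `run_config.yaml` provenance file; output is byte-identical
for a fixed seed.

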