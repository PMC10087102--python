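# svtarget

A tested, reusable pipeline for identifying the targets of a small
Dicer-dependent guide RNA (such as the 3'-end fragment of vault RNA1-2):

- **`synthetic_data`** — generates every input the pipeline needs: a
  transcriptome with UTR/exon/intron structure, planted guide-binding sites
  with configurable duplex architectures (canonical 5-nt target loop,
  no-loop, seed-only), small-RNA read pileups with a Dicer-dependent
  22–24-nt 3'-fragment peak, and gene universes with an exactly forced
  set overlap.
- **`fragment_coverage`** — per-base coverage (raw or RPM-scaled),
  read-length histograms over the 15–30-nt filter window, and
  Dicer-dependent fragment calling from WT vs knockdown coverage.
- **`guide_model`** — guide sequences, fragment extraction from a parent
  RNA, and composition-preserving controls (5'/3' region shuffles, 5'/3'
  block swap).
- **`duplex_align`** — the target-prediction core: a seed-weighted,
  G:U-wobble-aware local alignment of guide vs transcript windows with
  score (default 150), nearest-neighbour duplex free-energy (default
  −30 kcal/mol) and strict-seed thresholds, plus per-duplex architecture
  classification (pairing extent, central 10-11-12 pair scheme, target-side
  loop length/sequence) and loop-consensus counting.
- **`feature_annotation`** — canonical-transcript selection by confidence
  tags, intron/exon/UTR/junction feature tables, left-outer-join site
  annotation, length-normalised feature percentages, metagene profiles.
- **`enrichment_stats`** — gene-set overlap statistics: representation
  factor, exact hypergeometric upper tail, and a permutation null with
  quantile summaries.

## Command line

```sh
svtarget simulate --config cfg.json --outdir sim/ --seed 3
svtarget fragments --wt sim/reads_wt.bed --kd sim/reads_kd.bed --ref-len 89
svtarget guides --fasta sim/guide.fa --make-controls shuffle5,shuffle3,swap
svtarget scan --guide sim/guide.fa --targets sim/transcripts.fa --sc 150 --en -30
svtarget annotate --sites sites.tsv --gtf sim/annotation.gtf
svtarget enrich --universe u.txt --set-a a.txt --set-b b.txt --perm 1000 --seed 7
```

`simulate` writes a GTF annotation, transcript and guide FASTA, read BEDs
for WT/DicerKD, planted-site truth TSV, and gene-set lists. All on-disk
formats are plain text (GTF 1-based closed, BED 0-based half-open; all
internal APIs 0-based half-open).

## Conventions

- Guides are RNA (ACGU), 5'→3', with 1-based positions (position 1 = 5'
  nucleotide; it is never required to pair). Annotation/FASTA files on disk
  use DNA letters; conversion happens at module boundaries.
- The duplex energy model is a nearest-neighbour stack sum with initiation
  and loop penalties. Its contract is threshold behaviour and monotonicity,
  not parity with any folding package.
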