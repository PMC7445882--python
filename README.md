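# nanoverify

Highly multiplexed nanopore amplicon verification for synthetic DNA
constructs: barcoded-primer design, error-tolerant dual-barcode
demultiplexing, strand-separated alignment, and a strand-concordant
Bayesian SNV caller that separates genuine mutations from strand-biased
systematic sequencing errors. Outputs per-sample VCFs and a summary
table (identity, mutations, indels, coverage, max read depth).

## Why strand concordance

Single-pass nanopore reads carry 5–15% error. Simple pooled consensus
removes most of it, but *systematic* miscalls (sequence-specific signal
or motor-enzyme artifacts) survive averaging and masquerade as SNVs.
Because these artifacts are usually strand-specific, the caller models
forward and reverse reads separately with per-strand binomial
likelihoods (deeper strands weigh more), and only reports an SNV when
both strands independently agree on the same non-reference base with
high combined posterior. Discordant positions retain the template base.

## Layout

- `design` — random barcode candidates, a secondary-structure scoring
  proxy, pairwise-edit-distance filtering, plate/well primer allocation
  (6 forward x 96 reverse = 576 pairs by default).
- `simulate` — nanopore-like read simulator: configurable
  substitution/indel rates, strand-restricted systematic error sites,
  true variants, ground-truth sidecar. Generates every test fixture.
- `demux` — infix-Levenshtein matching of both barcodes at the read
  termini in both orientations; margin rule never guesses on ties.
- `align` — banded affine semi-global aligner (integer scoring, exact
  traceback, verified against a full-matrix DP oracle) feeding a
  per-position, per-strand A/C/G/T/deletion pileup; external SAM import
  for parity with standard aligners.
- `call` — per-strand binomial posteriors, concordance gating,
  strand-bias rejection, indel merging; plus the naive pooled-consensus
  comparator.
- `report` — summary metrics, VCFv4.2 emission, cost utility, and the
  end-to-end `run_pipeline`.

## CLI

```sh
nanoverify design --n-candidates 500 --barcode-len 24 --plates 6 --wells 96 \
    --seed 7 --binding-fwd ATGACC... --binding-rev CAGGAA... -o primers.tsv
nanoverify simulate --ref target.fasta --primers primers.tsv --well 1:B1 \
    --n-fwd 23 --n-rev 23 --sub 0.07 --ins 0.015 --del 0.015 --seed 1 -o reads.fastq
nanoverify demux --fastq reads.fastq --barcodes primers.tsv -o demuxed/
nanoverify align --reads demuxed/plate1_B1.fastq --target target.fasta -o pileup.tsv
nanoverify call --pileup pileup.tsv -o sample.vcf
nanoverify run --fastq reads.fastq --barcodes primers.tsv \
    --targets targets.fasta -o out/        # demux+align+call+summarize
nanoverify cost 2.20 6.6                   # -> 0.33 per kb
```

`run` accepts `--sample-map map.tsv` (sample → target) for verification
mode, `--identify` to pick the best target per sample, and
`--config cfg.yaml` with keys `error_rate, tau, min_depth_per_strand,
max_dist, window, band_width, seed`.

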