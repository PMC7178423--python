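# Methods

`utrtar` makes microRNA target prediction specific to a cellular context by
using bulk RNA-Seq evidence in two ways: it reannotates the distal end of
each protein-coding transcript's 3′-UTR from read coverage (capturing
alternative cleavage and polyadenylation, APA), and it removes predicted
targets whose transcript is not expressed in the sample. Predictions are
canonical seed-match sites; accuracy is assessed against miRNA-mimic
transfection experiments through cumulative log2 fold-change distributions
and one-sided Kolmogorov–Smirnov tests.

## Coordinate conventions

All internal coordinates are 0-based half-open on the forward genome
strand. GTF (1-based closed, Ensembl attribute dialect) is converted at the
parsing boundary; BED12 and bedgraph are native. Transcribed (5′→3′)
orientation is derived from the strand only when sequences or coverage
vectors are extracted. On the minus strand the "distal end" of a 3′-UTR is
the genomically smallest coordinate.

## Replicate merging

Biological replicates arrive as one bedgraph per replicate. The merged
track assigns every base the arithmetic mean of the replicate values, with
bases absent from a file counting as zero — the convention of genome-
coverage emitters, where absence means no reads. The merged representation
uses the atomic intervals of the union of replicate breakpoints, with
equal-valued neighbours coalesced and zero intervals dropped, so it is
canonical: two tracks are equal iff their interval lists are equal.

## Distal-end detection

The detector is a windowed threshold scan oriented 5′→3′ over the
annotated 3′-UTR plus an extension margin:

1. Build the coverage vector over `[utr_start, old_end + E]` (mirrored and
   reversed on the minus strand), where `E` is the extension limit.
   The margin is clipped at the chromosome end and at the nearest boundary
   of a different gene annotated downstream on the same strand, so an
   extension can never run through a neighbouring gene.
2. Compute the proximal reference `r`: mean coverage over the first
   `W` bases of the annotated UTR. If `r` is zero — or below the absolute
   floor `min_cov`, in which case even the first window fails its own
   acceptance test — the transcript is reported `skipped/no_coverage`.
3. Accept windows of length `W` at stride `step` while their mean coverage
   is at least `max(min_cov, f·r)`; stop at the first failing window. This
   makes acceptance contiguous: the proposed region always includes all
   nearer windows.
4. Refine to base resolution: within the last accepted window plus one
   stride of lookahead, the proposed end is one past the last base whose
   coverage meets the threshold. On noise-free step-edge coverage this
   recovers the planted breakpoint exactly; under Poisson noise at ~20×
   it is almost always exact because a covered base essentially never
   falls below one fifth of the local mean and an uncovered base is never
   above it.

The shift is classified as an extension or truncation only when it exceeds
`min_delta` bases; ties and small shifts resolve to `unchanged`, which
keeps reannotation conservative.

Defaults: `W = 100` nt, `step = 50` nt, `min_cov = 1` read/base,
`f = 0.2`, `E = 5000` nt, `min_delta = 50` nt. The window/stride pair is
sized so a UTR of a few hundred bases contains several windows while the
proximal reference remains a stable mean over 100 bases; `f = 0.2` tolerates
up to a fivefold drop from the proximal reference coverage, comfortably separating a retained 3′-UTR isoform
from background under Poisson noise at the depths the detector is meant
for (≥ ~5×). All knobs are user-configurable.

Relative thresholding gives a useful monotonicity: scaling all coverage by
a factor in (0, 1] on noise-free data can only stop the scan earlier (once
values fall under the absolute floor), so reduced sequencing depth can
convert calls toward truncation or skipping but never toward extension.

## Integration rules

Detected ends are integrated under explicit eligibility rules:

- only single-exon 3′-UTR annotations are ever modified;
- transcripts without a 3′-UTR annotation are untouched (no novel UTRs);
- the 5′ edge of the UTR is never moved — only the distal edge;
- truncations are applied only when the transcript's TPM is at least 5
  (default), because low expression produces sporadic coverage and
  spurious truncation calls; extensions are not expression-gated;
- the terminal exon's distal edge moves in lockstep with the UTR edge so
  the UTR remains contained in the exon chain.

Transcripts failing a rule are reported with an explicit skip reason
rather than silently dropped.

## TPM

Transcripts per million is computed in-house from estimated counts and
effective lengths: `rate_i = count_i / efflen_i`,
`tpm_i = 1e6 · rate_i / Σ_j rate_j` (summed with `math.fsum`). The column
sums to 10⁶ and is invariant to uniform scaling of counts. Quantification
itself (pseudoalignment etc.) is out of scope; any headered TSV with
`transcript_id` and `tpm` is accepted, and unknown transcripts look up as
TPM 0 so they fail every expression gate.

## Seed sites

With `S6` the reverse complement of miRNA positions 2–7 and `S7` of 2–8,
each `S6` occurrence in a 5′→3′ UTR sequence is classified once, by
precedence: 8mer (the `S7` extension holds and the base 3′ of the core is
an A), 7mer-m8 (`S7` only), 7mer-A1 (3′ A only), 6mer (neither). The A1
adenosine is required opposite miRNA position 1 regardless of the miRNA's
first base, per the canonical taxonomy. Matches truncated by the UTR
boundary fall back to the strongest fully contained type, and `N` matches
nothing. Context scoring (site accessibility, AU content, conservation) is
deliberately out of scope: the benchmark grouping is by seed match.

Site identity for cross-annotation comparison is the tuple (transcript,
miRNA, site type, chromosome, genomic coordinate of the site's 5′-most
base). Using genomic rather than UTR-offset coordinates means extending or
truncating a UTR elsewhere never relabels an unchanged site. Gained/lost
percentages are relative to the baseline site total and reported as
undefined (None) when that total is zero.

## KS benchmarking

Transcript groups (non-targets, seed targets, expression-filtered targets,
gained/removed targets) are compared through their empirical CDFs of log2
fold change. The first group of a comparison is hypothesised more
repressed, so the one-sided statistic is `d⁺ = sup_x [F₁(x) − F₂(x)]`,
computed over the pooled support. The approximate p-value is the one-sided
asymptotic form `min(1, exp(−2 d² n₁ n₂ / (n₁ + n₂)))`; a permutation
p-value (add-one estimator) is available as a cross-check and agrees with
the asymptotic form within a factor of two wherever the permutation
resolution (1/№ permutations) can represent the p-value. Transcripts in a
group but absent from the fold-change table are dropped with a logged
count; an empty group after the join is an error.

## Synthetic data

The generator emits a complete dataset from one seed: genome FASTA, GTF,
replicate bedgraphs, abundance TSV, miRNA FASTA, log2 fold-change TSV and
a truth table. Genes are laid out on one chromosome with 6 kb intergenic
gaps (larger than the default extension limit plus the largest planted
shift, so search regions never collide), on both strands, with a mix of
single-exon-UTR, multi-exon-UTR and UTR-less transcripts.

Defaults are the study conditions used throughout the tests: 100
transcripts, UTR lengths 600–1200 nt, planted distal-end shifts of
200–600 nt (20% extended, 20% truncated), 20 reads/base mean coverage with
per-base Poisson noise over two replicates, lognormal TPM (median ≈ 20)
with a 20% poorly expressed fraction, and transfection fold changes of
N(−0.5, 0.5²) for true targets versus N(0, 0.5²) otherwise. A uniform-TPM
mode exists for experiments that need flat 20× coverage. Truncated
transcripts receive a planted site in the lost tail only (so they become
removed targets and behave like non-targets in the transfection table);
extended transcripts receive a site in the extension (a gained target,
functional); other transcripts receive a core site with probability 0.6.

Target truth is determined by re-scanning the emitted sequences at the
true UTR extent, so chance background seed matches are captured, not just
planted ones. Coverage is piecewise-constant with optional Poisson noise:
enough to exercise a change-point detector's contract, but it has no
splice structure, positional bias, GC bias or isoform mixtures, so passing
tests demonstrate correctness of the algorithms under their stated model,
not performance on real libraries. Real data additionally violate the
single-breakpoint assumption whenever several 3′-UTR isoforms co-exist;
the detector then reports the most distal well-supported end.

## Numerical and degenerate-input choices

- Window acceptance uses `≥`, and shift classification uses strict
  `> min_delta`, so boundary ties resolve toward `unchanged`.
- `merge_replicates` requires at least one track; empty coverage yields
  `skipped/no_coverage`, never an exception, and a chromosome missing from
  the track is treated as zero coverage.
- An all-zero count table makes TPM undefined and is rejected, as are
  non-positive effective lengths.
- ECDFs reject empty and non-finite input; `d` is clipped to [0, 1] to
  guard floating-point noise only.
- Duplicate miRNA ids are deduplicated (first wins) with a warning;
  duplicate prediction tuples are dropped on construction.

## Problem sizes in the test suite

The suite and the results script run the oracle-equivalence scan on 1000
random UTR/miRNA pairs, breakpoint recovery on 100 transcripts (noisy and
noise-free), TPM conservation on 1000 random tables, the KS brute-force
comparison on 200 sample pairs, null calibration and the removed-target
band on 200 seeded replicates each, and the planted-effect benchmark at
500 targets vs 500 non-targets — sizes at which every stochastic check is
stable across seeds.

## Known limitations

- Only the distal edge of single-exon 3′-UTRs is reannotated; novel UTRs
  and multi-exon UTR remodelling are out of scope by design.
- One distal end per transcript: no isoform-ratio weighting or multiple
  APA-site quantification.
- Non-canonical (seedless) sites and coding-region sites are not
  predicted, and no conservation or context scoring is applied.
- The asymptotic KS p-value is approximate at small sample sizes; use the
  permutation option when group sizes are a few dozen or fewer.
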