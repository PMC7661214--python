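# Methods

`mitolong` reimplements, as a tested pipeline, the computational analysis of
a nanopore sequencing workflow for circular mitochondrial genomes: nuclear
DNA is depleted with exonuclease V (which spares circular molecules), the
surviving mtDNA is amplified by multiple displacement amplification (MDA)
with a targeted primer panel, and the long branched products are sequenced
on a nanopore device. The package covers the analysis side of that workflow
— coordinate conventions for circular references, read QC, long-read
classification, coverage, qPCR enrichment quantification, variant-call
concordance, and primer-panel screening — and pairs it with a synthetic-data
generator that emulates the laboratory inputs so every stage can be
exercised end to end with exact ground truth.

## Circular coordinates (`circref`)

Linear long-read aligners cannot map a read across the origin of a circular
genome. The standard remedy, used throughout, is *pseudo-circularization*:
align against the reference concatenated head-to-tail with itself (length
2L) and fold coordinates back onto the circle mod L. Folding splits an
interval crossing position L into two circular segments and yields, per
read: the reference span with multiplicity (`ref_span`), the distinct
circular bases covered (`distinct_ref_span`), and the aligned read fraction.
A read longer than the circle wraps past one full revolution; the bases it
covers twice equal `max(0, ref_span − L)` for a contiguous alignment — the
canonical example being a 17,501 nt read on a 16,666 bp mitogenome, which
double-covers 835 bp.

Conventions: internal coordinates are 0-based half-open; all file I/O (VCF,
coverage tables, primer sheets) is 1-based. Alignment starts at or beyond L
are normalized by subtracting L before folding, giving every read a
canonical representation; segment strand is inherited unchanged from the
linear alignment. PAF (12-column minimap2 dialect, optional `cg:Z` tag) and
single-end SAM are accepted; SAM parsing is delegated to pysam and PAF is
read directly (no parser for it exists in the supporting libraries).

## Synthetic data (`simkit`)

The generator emulates the study conditions, not an arbitrary simulator:

* **Genome** — a random 16,666 bp circle whose control region contains a
  minisatellite array (29 × `GTGCACCT` by default), the hard region where
  real variant calling degrades. A haplotype differs from the reference at
  `n_haplotype_snps` planted sites, transitions only by default (animal
  mtDNA polymorphism is overwhelmingly transitional); planted sites avoid
  the minisatellite array, which stands in for the always-missed
  control-region indel cases as a hard region.
* **NUMTs** — each nuclear contig carries one segment copied from the
  (doubled) mitogenome with i.i.d. substitutions at `numt_divergence`
  (default 0.02/site). Placement is uniform; no more detailed NUMT model is
  attempted.
* **Exonuclease treatment** — Bernoulli survival per molecule: circular
  molecules at 0.5 (the treatment costs about half of the mtDNA), linear at
  0.001.
* **Read lengths** — log-normal with σ² = ln(N50/median), calibrated to a
  median of 1741 nt and N50 of 3137 nt (so μ = ln 1741, σ ≈ 0.768). Lengths
  are clipped to [200, 2L]; an mtDNA read is additionally capped at
  2L − start, the longest contiguous interval representable on the doubled
  reference (this is also what a linear aligner could recover there and
  affects ~0.2% of reads at these settings).
* **Rolling-circle and 2D-like reads** — an mtDNA read longer than L wraps,
  its truth alignment spanning more than one revolution. With probability
  `chimera_2d_rate` (default 0.03, within the 3–6% chimerism range reported
  for MDA in short-read literature; the nanopore prevalence is unknown and
  the rate is a free parameter, not a claim) the read is 2D-like: in read
  orientation it is S + revcomp(prefix of S), with the prefix fraction drawn
  Uniform(0.3, 1.0) — the second pass of the molecule is usually truncated.
  The second pass re-reads the corresponding reference sub-interval with
  *independent* errors, as a fresh pass of the same molecule would.
* **Errors and qualities** — per-base substitution/insertion/deletion at
  (0.05, 0.02, 0.03); deletion probability is multiplied by
  `homopolymer_del_boost` (default 2) inside homopolymer runs of ≥ 3, the
  dominant nanopore failure mode. Per-read mean quality is drawn
  Normal(11, 1) truncated to [2, 40] with ±3 per-base jitter — qualities are
  descriptive of the target mean-quality regime (per-library means of
  ~10.9–11.5) and are deliberately decoupled from the error process, whose
  rates are set explicitly.
* **Truth** — every mtDNA read carries its exact alignment (interval on the
  doubled reference, query interval, strand, cigar recording the injected
  edits), planted variants are emitted as a truth VCF, and a per-read origin
  manifest records source (mtDNA/nuDNA/NUMT), chimera flag and revolutions.

All randomness flows through named substreams of one master seed
(`SeedSequence` keyed by seed plus a CRC of the stage name and library
index), so identical configs give byte-identical FASTQ/PAF/VCF outputs and
adding a stage never perturbs earlier draws.

What the generator does *not* model: signal-level nanopore behaviour, MDA
branch topology, template-independent amplification, basecaller- or
alignment-induced error correlations, and reference-dependent alignment
artefacts in repeat regions. Tests passing on these simulations therefore
validate the *analysis arithmetic* (folding, selection rules, the strict
concordance rule, the binomial caller's behaviour under i.i.d. errors) —
they do not certify performance on real nanopore data, where alignment
ambiguity in the minisatellite region is the dominant failure mode.

## Read QC (`readqc`)

Mean read quality is the Phred transform of the mean per-base error
probability, `−10·log10(mean(10^(−q/10)))` — the convention of the common
long-read filtering tools, materially different from averaging Phred values.
The default filter keeps reads ≥ 2000 bp with mean quality ≥ Q10; thresholds
are inclusive (matching common tool flag semantics) with a `strict` switch
for exclusive comparison, and a 1e-9 tolerance protects boundary reads from
float round-off. N50 is the length of the shortest read in the smallest set
of longest reads holding at least half the bases.

## Long-read classification (`longclass`)

A read is selected when its alignments jointly cover **more than** 8000
distinct bases of the circle and **more than** 80% of the read aligns (both
strict). The classification ratio is read length over the length of the
*longest single* alignment; < 1.1 is "normal", 1.1–1.2 inclusive is
"middle", > 1.2 is "high" (boundary assignment to "middle" is switchable).
`multirev` flags any circular position covered ≥ 2 times by the read.
`twod_like` flags two alignments of one read covering the same circular
segment on opposite strands (same-strand tandem compounds optionally
included), where the overlap must be ≥ 50% of the *shorter* segment's span —
scored against the shorter segment because the second pass of a 2D-like
molecule is usually truncated; a both-segments reciprocal rule would be
blind to second passes shorter than half the first. The threshold and
strand rule are this package's own choices, exposed as configuration.

## Coverage (`circcov`)

Depth counts alignment *segments*, so a wrapped read contributes 2 where it
covers the circle twice, consistent with a doubled-reference pileup folded
mod L. Uniformity is summarised as max/min depth (NaN with a warning when
positions are uncovered). Primer "bulges" — local over-amplification around
MDA primer sites — are scored as median depth in a ± window/2 circular
neighbourhood (default window 500 bp, roughly matching the width of observed
bulges) divided by the global median.

## qPCR quantification (`qpcrquant`)

Technical-duplicate Cq pairs are valid when they differ by less than 0.5
cycles, with "undetermined" wells set to Cq 40 *before* the check; the mean
of a valid pair is arithmetic (standard qPCR practice). Per condition, the
three per-amplicon mean Cqs of each class (mt, nu) are aggregated by
geometric mean — kept as stated in the source protocol even though the
arithmetic mean is conventional; a switch provides the arithmetic
alternative. The relative ratio is 2^(gm_nu − gm_mt), assuming 100%
amplification efficiency (no standard-curve data to correct with), and fold
changes are ratios of relative ratios. Note that the exact cancellation of a
constant Cq shift holds only under the arithmetic aggregation; the geometric
convention preserves it approximately.

## Variant concordance (`varconcord`)

The pileup caller is deliberately naive and intended for synthetic data: per
circular position it counts bases from covering reads (walking the cigars,
folding reference positions mod L), calls a SNP when the majority
non-reference base reaches alt fraction ≥ 0.5, and assigns a site quality of
−10·log10 P(X ≥ alt | Binomial(depth, error rate)) capped at 10,000, with a
quality cutoff of 15. Indels are not called — the sequencing precision
regime this emulates precludes reliable small-indel calls. Production
callers are consumed through VCF instead; this caller exists so the
*evaluation procedure* can be tested with exact truth.

The strict concordance rule: for an individual sequenced across several
libraries, a truth variant is a true positive only when called in *every*
library; a miss in even one library makes it a false negative, and any
called variant absent from the truth is a false positive. Precision,
recall, and F1 = 2pr/(p+r) are reported per individual and pooled (counts
summed). Reporting rounds percentages to 1 decimal and scores to 3, half
away from zero. The per-variant presence matrix pools per-library qualities
by maximum (configurable). With a single library the rule reduces to
ordinary call-set concordance.

## Primer panels (`primerpanel`)

Panels follow the MDA design rules: 10–14 nt primers (violations reported,
not fatal), equal numbers per strand, sites evenly spaced on the circle
(scored by the coefficient of variation of circular gaps; no threshold is
asserted, the value is reported). Decoy screening counts exact full-length
matches of each primer and its reverse complement in decoy sequences
(typically NUMT-bearing nuclear contigs) — no thermodynamic or
mismatch-tolerant model, since exclusion in the source protocol was by
sequence match alone. The greedy designer places evenly spaced targets with
alternating strands and takes, at each target, the nearest 10–14-mer that is
unique on the circle (both strands) and absent from all decoys; panels it
emits pass evaluation with no flags by construction.

## Problem sizes and numerical choices

The test and acceptance runs use: length calibration at 50,000 reads
(median/N50 within ±10% of 1741/3137 nt); classification recall at 10,000
error-free reads with a 5% chimera rate (multi-revolution recall 1.0,
chimera recall ≥ 0.99, false-positive rate ≤ 0.001); strict concordance on
7 simulated libraries of 2,500 pure-mtDNA reads each (post-filter per-base
depth ≈ 150–200, 10% total error), requiring recall ≥ 0.95 and precision
≥ 0.99 on 30 planted SNPs; and randomized brute-force cross-checks of the
folding and coverage arithmetic. Degenerate inputs follow explicit rules:
empty read sets yield empty statistics, zero-depth profiles report NaN
uniformity with a warning, p = r = 0 defines F1 as 0 with a warning, and
undefined precision/recall are NaN with warnings rather than exceptions.

## Known limitations

* The caller assumes i.i.d. errors and homoplasmic variants; heteroplasmy
  estimation, phasing and structural variants are out of scope.
* Truth alignments stand in for a real aligner; reference-dependent mapping
  bias (the dominant real-data artefact in the control region) is not
  reproduced.
* qPCR efficiency is fixed at 2; dilution series and melting-curve analysis
  are not modelled.
* The primer designer optimises placement and uniqueness only — no Tm,
  secondary-structure or primer-dimer model.
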