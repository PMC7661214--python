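# mitolong

Analysis tooling for nanopore long-read sequencing of circular mitochondrial
genomes (and other large circular DNAs).

Animal mtDNA is a ~10–20 kb circle that is heavily outnumbered by nuclear
DNA in routine extracts and shadowed by NUMTs — near-identical mtDNA copies
embedded in the nuclear genome. A practical enrichment workflow depletes
linear (nuclear) DNA with exonuclease V, amplifies the surviving circles by
multiple displacement amplification (MDA) with a targeted primer panel, and
sequences the long products on a nanopore device. `mitolong` implements the
computational side of that workflow for geneticists who run it:

* **`circref`** — pseudo-circularization (reference doubled head-to-tail so
  linear aligners can cross the origin) and folding of alignments back onto
  circular coordinates mod L, including multi-revolution arithmetic: a read
  of length ℓ > L double-covers `ℓ − L` bases (a 17,501 nt read on a
  16,666 bp circle double-covers 835 bp). PAF/SAM input.
* **`readqc`** — filtering (length ≥ 2000 nt, mean quality ≥ Q10, where mean
  quality is `−10·log10` of the mean per-base error probability) and read-set
  statistics: mean/median length, N50, mean quality.
* **`longclass`** — selection of long mtDNA reads (> 8000 bp of the circle
  covered, > 80% of the read aligned) and classification by the
  read-length / longest-alignment ratio (`normal` < 1.1 ≤ `middle` ≤ 1.2 <
  `high`), with detection of multi-revolution (rolling-circle) reads and
  "2D-like" inverted chimeras.
* **`circcov`** — per-base circular coverage, max/min uniformity, and primer
  "bulge" annotation.
* **`qpcrquant`** — qPCR Cq validation (duplicates valid below 0.5 cycles,
  undetermined → Cq 40) and ΔCq enrichment: relative mtDNA/nuDNA ratio
  `2^(gm_nu − gm_mt)` from geometric means over three amplicons per class,
  and fold changes between conditions.
* **`varconcord`** — a naive binomial pileup SNP caller for synthetic data,
  and the strict multi-library concordance analysis: a variant is a true
  positive only if called in *every* library of an individual, with
  precision `p = tp/(tp+fp)`, recall `r = tp/(tp+fn)`,
  `F1 = 2pr/(p+r)`, and found-in-all-libraries fractions.
* **`primerpanel`** — evaluation and greedy design of MDA primer panels
  (10–14 nt, strand-balanced, evenly spaced) with exact-match screening
  against NUMT decoys.
* **`simkit`** — a seeded generator emulating the whole experiment: circular
  mitogenome with a minisatellite-bearing control region, transition-only
  haplotype SNPs, NUMT-bearing nuclear contigs, exonuclease survival, and
  MDA nanopore-like reads (log-normal lengths calibrated to median 1741 /
  N50 3137 nt, ~Q11, homopolymer-boosted indels, wrap-around and 2D-like
  chimeric reads) with exact truth alignments, truth VCF and origin
  manifest.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Simulate a library, fold its truth alignments, and classify the long reads:

```python
from mitolong import simkit
from mitolong.circref import group_by_read
from mitolong.longclass import classify_reads

config = simkit.SimulationConfig(seed=2, n_reads=3000, mt_read_fraction=1.0,
                                 error_rates=(0, 0, 0), chimera_2d_rate=0.05)
genomes = simkit.generate_genomes(config)
sim = simkit.simulate_reads(config, genomes)
classes = classify_reads(group_by_read(sim.truth_alignments), genomes.reference)
print(f"selected long reads: {len(classes)}")
print(f"multi-revolution:    {sum(c.multirev for c in classes)}")
print(f"2D-like chimeras:    {sum(c.twod_like for c in classes)}")
wrapped = max(classes, key=lambda c: c.double_covered_bp)
print(f"most wrapped read:   {wrapped.read_length} nt, "
      f"{wrapped.double_covered_bp} bp covered twice")
```

prints

```
selected long reads: 74
multi-revolution:    7
2D-like chimeras:    3
most wrapped read:   24689 nt, 10882 bp covered twice
```

Of 3000 simulated reads, 74 cover more than 8000 bp of the circle with more
than 80% of the read aligned; seven of those cover part of the 16,666 bp
circle more than once (the most extreme, 24,689 nt long, reads 10,882 bp of
the genome at least twice), and three are inverted-chimera ("2D-like")
reads.

The same stages are available as a CLI for file-based work:

```
mitolong simulate --seed 1 --n-reads 20000 --outdir sim/
mitolong qc --fastq sim/reads.fastq --outdir qc/
mitolong classify --paf sim/truth.paf --reference sim/reference.fasta --outdir cls/
mitolong coverage --paf sim/truth.paf --reference sim/reference.fasta --outdir cov/
mitolong call --fastq sim/reads.fastq --paf sim/truth.paf \
              --reference sim/reference.fasta --outdir calls/
mitolong concord --truth-vcf sim/truth.vcf \
                 --calls h1:lib0:calls/calls.vcf --outdir conc/
```

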