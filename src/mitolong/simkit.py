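"""Synthetic-data generator emulating MDA rolling-circle nanopore sequencing
of a circular mitochondrial genome.

The generator reproduces the salient features of the real experiment it
stands in for:

* a ~16.6 kb circular mitogenome with a repeat-rich control region that
  contains a minisatellite array (29 copies of GTGCACCT by default);
* a haplotype carrying planted transition SNPs (animal mtDNA polymorphism is
  overwhelmingly transitional);
* nuclear contigs carrying NUMTs — diverged copies of mitogenome segments
  that confound mapping and primer design;
* exonuclease V treatment as Bernoulli survival of molecules (circular
  molecules survive at ~0.5, linear nuclear DNA is depleted);
* nanopore-like long reads with log-normal lengths calibrated to a median of
  ~1741 bp and N50 of ~3137 bp, substitution/insertion/deletion errors with
  homopolymer-deletion boosting, and per-base qualities targeting a mean
  read quality of ~Q11;
* rolling-circle phenomenology: reads longer than the circle wrap around it
  (multi-revolution reads), and a configurable fraction of reads are
  "2D-like" chimeras that re-read part of the same molecule in the opposite
  orientation;
* exact truth: per-read alignments (with cigars) on the doubled reference,
  planted variants as a truth VCF, and a per-read origin manifest.

All randomness flows through named substreams of a single master seed, so a
fixed config yields byte-identical outputs and adding a stage never perturbs
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from ._util import codes_to_seq, revcomp_codes, rng_for, seq_to_codes
from .circref import CircularReference, CigarOps, LinearAlignment, pseudo_circularize, write_paf
from .readqc import ReadRecord, write_fastq

# Length calibration: for lognormal(mu, sigma), median = e^mu and
# N50 = e^(mu + sigma^2), so sigma^2 = ln(N50/median).
_TARGET_MEDIAN = 1741.0
_TARGET_N50 = 3137.0
_DEFAULT_MU = math.log(_TARGET_MEDIAN)
_DEFAULT_SIGMA = math.sqrt(math.log(_TARGET_N50 / _TARGET_MEDIAN))


@dataclass
class SimulationConfig:
    seed: int = 0
    L: int = 16666
    control_region: tuple[int, int] = (15400, 16660)  # 1-based inclusive bounds
    minisat_motif: str = "GTGCACCT"
    minisat_copies: int = 29
    minisat_start: int = 15950  # 1-based start of the array on the circle
    n_haplotype_snps: int = 30
    transitions_only: bool = True
    n_numts: int = 3
    numt_length_range: tuple[int, int] = (500, 5000)
    numt_divergence: float = 0.02
    nuclear_contig_length: int = 20000
    n_reads: int = 20000
    length_lognormal: tuple[float, float] = (_DEFAULT_MU, _DEFAULT_SIGMA)
    min_read_length: int = 200
    mt_read_fraction: float = 0.4
    chimera_2d_rate: float = 0.03
    error_rates: tuple[float, float, float] = (0.05, 0.02, 0.03)  # sub, ins, del
    homopolymer_del_boost: float = 2.0
    mean_quality_target: float = 11.0
    exo_survival: tuple[float, float] = (0.5, 0.001)  # circular, linear

    def validate(self) -> None:
        if self.L < 1000:
            raise ValueError("L must be >= 1000")
        for p in (self.mt_read_fraction, self.chimera_2d_rate, *self.exo_survival):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(r < 0 for r in self.error_rates):
            raise ValueError("negative error rate")
        if self.numt_length_range[1] > self.L:
            raise ValueError("numt_length_range exceeds genome length")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthVariant:
    position: int  # 1-based circular coordinate
    ref: str
    alt: str
    haplotype: str = "hap1"
    kind: str = "SNP"

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref, self.alt)


@dataclass
class ReadOrigin:
    read_id: str
    source: str  # mtDNA | nuDNA | NUMT
    start: int | None  # 0-based doubled-reference start for mtDNA reads
    length: int
    strand: str
    chimera: bool
    revolutions: float  # ref_span / L for mtDNA reads, 0 otherwise


@dataclass
class Genomes:
    reference: CircularReference
    haplotype: str
    nuclear_contigs: list[tuple[str, str]]
    truth_variants: list[TruthVariant]
    numt_intervals: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class Molecule:
    id: str
    circular: bool


_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T in ACGT codes


def generate_genomes(config: SimulationConfig) -> Genomes:
    """Random mitogenome + haplotype + NUMT-bearing nuclear contigs."""
    config.validate()
    rng = rng_for(config.seed, "genomes")
    L = config.L

    genome = rng.integers(0, 4, size=L, dtype=np.uint8)
    # overwrite the minisatellite array inside the control region
    motif = seq_to_codes(config.minisat_motif)
    array = np.tile(motif, config.minisat_copies)
    ms_start = config.minisat_start - 1
    if ms_start + array.size > L:
        raise ValueError("minisatellite array extends past the genome end")
    genome[ms_start:ms_start + array.size] = array
    ms_end = ms_start + array.size

    # plant transition SNPs on the haplotype, outside the minisatellite
    # (that array is the hard region where real calls degrade)
    candidates = np.setdiff1d(np.arange(L), np.arange(ms_start, ms_end))
    snp_pos = np.sort(rng.choice(candidates, size=config.n_haplotype_snps, replace=False))
    haplotype = genome.copy()
    variants: list[TruthVariant] = []
    for pos in snp_pos:
        ref_code = int(genome[pos])
        if config.transitions_only:
            alt_code = _TRANSITION[ref_code]
        else:
            alt_code = int((ref_code + rng.integers(1, 4)) % 4)
        haplotype[pos] = alt_code
        variants.append(TruthVariant(
            position=int(pos) + 1,
            ref="ACGT"[ref_code],
            alt="ACGT"[alt_code],
        ))

    doubled = np.concatenate([genome, genome])
    contigs: list[tuple[str, str]] = []
    numt_intervals: list[tuple[str, int, int]] = []
    for i in range(config.n_numts):
        contig = rng.integers(0, 4, size=config.nuclear_contig_length, dtype=np.uint8)
        lo, hi = config.numt_length_range
        numt_len = int(rng.integers(lo, hi + 1))
        mt_start = int(rng.integers(0, L))
        numt = doubled[mt_start:mt_start + numt_len].copy()
        if config.numt_divergence > 0:
            mask = rng.random(numt_len) < config.numt_divergence
            shift = rng.integers(1, 4, size=int(mask.sum()))
            numt[mask] = (numt[mask] + shift) % 4
        ins_at = int(rng.integers(0, config.nuclear_contig_length - numt_len))
        contig[ins_at:ins_at + numt_len] = numt
        name = f"nuclear_{i + 1}"
        contigs.append((name, codes_to_seq(contig)))
        numt_intervals.append((name, ins_at, ins_at + numt_len))

    reference = pseudo_circularize(codes_to_seq(genome), ref_id="mito_sim")
    return Genomes(
        reference=reference,
        haplotype=codes_to_seq(haplotype),
        nuclear_contigs=contigs,
        truth_variants=variants,
        numt_intervals=numt_intervals,
    )


def apply_exonuclease(
    config: SimulationConfig,
    pool: Sequence[Molecule],
    rng: np.random.Generator | None = None,
) -> list[Molecule]:
    """Bernoulli survival of molecules under exonuclease V treatment.

    Circular molecules (mtDNA) survive with probability ``exo_survival[0]``
    (default 0.5 — the treatment costs about half of the mtDNA), linear
    molecules with ``exo_survival[1]``.
    """
    config.validate()
    if rng is None:
        rng = rng_for(config.seed, "exonuclease")
    p_circ, p_lin = config.exo_survival
    if not pool:
        return []
    u = rng.random(len(pool))
    return [m for m, x in zip(pool, u) if x < (p_circ if m.circular else p_lin)]


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def _homopolymer_mask(codes: np.ndarray, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs of >= min_run."""
    n = codes.size
    if n == 0:
        return np.zeros(0, dtype=bool)
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])
    mask = np.zeros(n, dtype=bool)
    for s, e in zip(starts[ends - starts >= min_run], ends[ends - starts >= min_run]):
        mask[s:e] = True
    return mask


def _mutate(
    codes: np.ndarray,
    rng: np.random.Generator,
    p_sub: float,
    p_ins: float,
    p_del: float,
    hp_boost: float,
) -> tuple[np.ndarray, CigarOps]:
    """Inject sub/ins/del errors into a template; return read codes + cigar.

    The cigar describes the alignment of the returned sequence to the
    template (M includes mismatches; insertions are single random bases after
    a kept template base; deletions in homopolymer runs are boosted).
    """
    n = codes.size
    if n == 0:
        return codes.copy(), []
    pdel = np.full(n, p_del)
    if hp_boost != 1.0 and p_del > 0:
        pdel[_homopolymer_mask(codes)] = min(0.9, p_del * hp_boost)
    u = rng.random(n)
    del_mask = u < pdel
    kept = ~del_mask
    sub_mask = kept & (rng.random(n) < p_sub)
    ins_mask = kept & (rng.random(n) < p_ins)

    out_main = codes.copy()
    n_sub = int(sub_mask.sum())
    if n_sub:
        out_main[sub_mask] = (out_main[sub_mask] + rng.integers(1, 4, n_sub)) % 4
    ins_bases = rng.integers(0, 4, int(ins_mask.sum()), dtype=np.uint8)

    emit = kept.astype(np.int64) + ins_mask
    offsets = np.concatenate([[0], np.cumsum(emit)[:-1]])
    out = np.empty(int(emit.sum()), dtype=np.uint8)
    out[offsets[kept]] = out_main[kept]
    out[offsets[ins_mask] + 1] = ins_bases

    # cigar: one op per template position (M or D) plus I after inserting bases
    op_emit = 1 + ins_mask
    op_offsets = np.concatenate([[0], np.cumsum(op_emit)[:-1]])
    op_arr = np.empty(int(op_emit.sum()), dtype=np.int8)
    op_arr[op_offsets] = np.where(del_mask, 2, 0)
    op_arr[op_offsets[ins_mask] + 1] = 1
    change = np.flatnonzero(np.diff(op_arr))
    run_ends = np.concatenate([change + 1, [op_arr.size]])
    run_starts = np.concatenate([[0], change + 1])
    ops = [("MID"[op_arr[s]], int(e - s)) for s, e in zip(run_starts, run_ends)]
    return out, ops


def _merge_cigars(a: CigarOps, b: CigarOps) -> CigarOps:
    if a and b and a[-1][0] == b[0][0]:
        return a[:-1] + [(a[-1][0], a[-1][1] + b[0][1])] + b[1:]
    return a + b


@dataclass
class ReadSimulation:
    """Reads with exact truth: alignments, variants, and per-read origins."""

    config: SimulationConfig
    genomes: Genomes
    library: int
    reads: list[ReadRecord] = field(default_factory=list)
    truth_alignments: list[LinearAlignment] = field(default_factory=list)
    origins: list[ReadOrigin] = field(default_factory=list)

    def write_fastq(self, path) -> None:
        write_fastq(self.reads, path)

    def write_truth_paf(self, path) -> None:
        ref = self.genomes.reference
        write_paf(self.truth_alignments, ref.doubled_id, 2 * ref.length, path)

    def write_truth_vcf(self, path) -> None:
        write_truth_vcf(self.genomes, path)

    def write_manifest(self, path) -> None:
        import pandas as pd

        pd.DataFrame([asdict(o) for o in self.origins]).to_csv(path, sep="\t", index=False)


def write_truth_vcf(genomes: Genomes, path) -> None:
    """Planted variants as minimal VCF v4.2 (via pysam)."""
    import pysam

    header = pysam.VariantHeader()
    header.contigs.add(genomes.reference.id, length=genomes.reference.length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(genomes.truth_variants, key=lambda v: v.position):
            rec = vcf.new_record(
                contig=genomes.reference.id,
                start=v.position - 1,
                alleles=(v.ref, v.alt),
            )
            vcf.write(rec)


def simulate_reads(
    config: SimulationConfig,
    genomes: Genomes,
    library: int = 0,
) -> ReadSimulation:
    """Simulate one sequencing library of nanopore-like MDA reads.

    mtDNA reads are drawn from the circular haplotype: a read longer than the
    genome wraps, its truth alignment spanning more than L on the doubled
    reference (capped at 2L - start, the longest interval a linear aligner
    can recover there).  With probability ``chimera_2d_rate`` a read is
    2D-like: its tail re-reads a sub-interval of the same molecule in the
    opposite orientation, with independent errors.  Nuclear reads are drawn
    from the NUMT-bearing contigs and carry no mtDNA truth alignment.
    """
    config.validate()
    sim = ReadSimulation(config=config, genomes=genomes, library=library)
    n = config.n_reads
    if n == 0:
        return sim

    L = config.L
    p_sub, p_ins, p_del = config.error_rates
    hap = seq_to_codes(genomes.haplotype)
    hap_tiled = np.concatenate([hap, hap])
    contig_codes = [seq_to_codes(seq) for _name, seq in genomes.nuclear_contigs]

    rng_len = rng_for(config.seed, "lengths", library)
    rng_org = rng_for(config.seed, "origins", library)
    rng_err = rng_for(config.seed, "errors", library)
    rng_q = rng_for(config.seed, "quality", library)

    mu, sigma = config.length_lognormal
    lengths = np.exp(rng_len.normal(mu, sigma, size=n))
    lengths = np.clip(lengths, config.min_read_length, 2 * L).astype(np.int64)
    is_mt = rng_org.random(n) < config.mt_read_fraction
    is_chimera = is_mt & (rng_org.random(n) < config.chimera_2d_rate)
    starts = rng_org.integers(0, L, size=n)
    strands = np.where(rng_org.random(n) < 0.5, "+", "-")

    mean_qs = np.clip(rng_q.normal(config.mean_quality_target, 1.0, size=n), 2.0, 40.0)

    for i in range(n):
        read_id = f"lib{library}_read{i:06d}"
        length = int(lengths[i])
        strand = str(strands[i])

        if is_mt[i]:
            s = int(starts[i])
            length = min(length, 2 * L - s)
            template = hap_tiled[s:s + length]
            seg_a, cigar_a = _mutate(template, rng_err, p_sub, p_ins, p_del,
                                     config.homopolymer_del_boost)
            read_parts: list[np.ndarray]
            if strand == "+":
                read_parts = [seg_a]
            else:
                read_parts = [revcomp_codes(seg_a)]
            qlen_a = seg_a.size
            # (ref_start, ref_end, strand, query_start, query_end, cigar)
            aln_specs = [(s, s + length, strand, 0, qlen_a, cigar_a)]
            if is_chimera[i]:
                frac = rng_err.uniform(0.3, 1.0)
                k = max(1, int(round(frac * length)))
                # the second pass re-reads a flank of the same molecule in
                # the opposite orientation, with fresh errors
                if strand == "+":
                    b_lo, b_hi = s, s + k
                else:
                    b_lo, b_hi = s + length - k, s + length
                template_b = hap_tiled[b_lo:b_hi]
                seg_b, cigar_b = _mutate(template_b, rng_err, p_sub, p_ins, p_del,
                                         config.homopolymer_del_boost)
                b_strand = "-" if strand == "+" else "+"
                if b_strand == "+":
                    read_parts.append(seg_b)
                else:
                    read_parts.append(revcomp_codes(seg_b))
                aln_specs.append((b_lo, b_hi, b_strand, qlen_a, qlen_a + seg_b.size, cigar_b))
            read_codes = np.concatenate(read_parts)
            read_len = int(read_codes.size)
            sim.truth_alignments.extend(
                LinearAlignment(
                    read_id=read_id, read_length=read_len,
                    ref_start=rs, ref_end=re_, strand=st,
                    read_aligned_bases=qe - qs,
                    query_start=qs, query_end=qe, cigar=cg, mapq=60,
                )
                for rs, re_, st, qs, qe, cg in aln_specs
            )
            sim.origins.append(ReadOrigin(
                read_id=read_id, source="mtDNA", start=int(s), length=read_len,
                strand=strand, chimera=bool(is_chimera[i]),
                revolutions=length / L,
            ))
        else:
            c = int(rng_org.integers(0, len(contig_codes))) if contig_codes else 0
            if not contig_codes:
                continue
            contig = contig_codes[c]
            cs = int(rng_org.integers(0, max(1, contig.size - length)))
            template = contig[cs:cs + length]
            seg, _cigar = _mutate(template, rng_err, p_sub, p_ins, p_del,
                                  config.homopolymer_del_boost)
            read_codes = seg if strand == "+" else revcomp_codes(seg)
            name, numt_lo, numt_hi = genomes.numt_intervals[c] if c < len(
                genomes.numt_intervals) else (genomes.nuclear_contigs[c][0], -1, -1)
            overlaps_numt = cs < numt_hi and cs + template.size > numt_lo
            sim.origins.append(ReadOrigin(
                read_id=read_id, source="NUMT" if overlaps_numt else "nuDNA",
                start=None, length=int(read_codes.size), strand=strand,
                chimera=False, revolutions=0.0,
            ))
            read_len = int(read_codes.size)

        # per-base qualities: read mean near the drawn target, jitter +/-3
        base_q = np.clip(
            np.round(mean_qs[i] + rng_q.integers(-3, 4, size=read_len)),
            2, 40,
        ).astype(int)
        sim.reads.append(ReadRecord(read_id, codes_to_seq(read_codes), base_q.tolist()))

    return sim
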