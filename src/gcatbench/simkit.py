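"""Seeded simulation of mutated diploid genomes and paired-end short reads.

The simulator produces everything a mapper/caller benchmark needs with the
truth embedded: a synthetic reference contig, two mutated haplotypes plus a
truth VCF (SNPs and 1-24 bp indels), and FASTQ reads whose true genomic
placement is encoded losslessly in the read name.  Defaults mirror a widely
used whole-genome simulation setup: per-base mutation probability 0.001,
10% of mutations indels (small 1-10 bp and large 10-24 bp classes), 500 bp
fragments with 50 bp s.d., and 20x coverage.

Randomness is organised as one seeded generator per stage (mutation,
fragmentation, base errors) so that changing one stage's parameters leaves
the other stages' draws untouched.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np

from .errors import InputError, ReadNameError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")

HET = "het"
HOM_ALT = "hom-alt"

SNP = "SNP"
INSERTION = "insertion"
DELETION = "deletion"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reference:
    """A single reference contig (uppercase A/C/G/T)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name or any(c.isspace() for c in self.name):
            raise InputError("contig name must be non-empty without whitespace")
        if set(self.sequence) - set("ACGT"):
            raise InputError("reference sequence must contain only A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MutationModel:
    """Parameters of the germline mutation process applied to the reference.

    mutation_rate
        Per-base probability that a site carries a mutation (default 0.001).
    indel_fraction
        Fraction of mutations that are indels rather than SNPs (default 0.10).
    small_indel_range / large_indel_range
        Inclusive indel-length ranges, default 1-10 bp and 10-24 bp.
    large_indel_fraction
        Fraction of indels drawn from the large range (default 0.1).
    het_probability
        Chance that a mutation is heterozygous, i.e. placed on one randomly
        chosen haplotype instead of both (default 0.5).
    """

    mutation_rate: float = 0.001
    indel_fraction: float = 0.10
    small_indel_range: tuple[int, int] = (1, 10)
    large_indel_range: tuple[int, int] = (10, 24)
    large_indel_fraction: float = 0.1
    het_probability: float = 0.5

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "indel_fraction", "large_indel_fraction",
                     "het_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")
        for name in ("small_indel_range", "large_indel_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise InputError(f"{name} must satisfy 1 <= min <= max")

    @property
    def max_indel_length(self) -> int:
        return max(self.small_indel_range[1], self.large_indel_range[1])


@dataclass(frozen=True, order=True)
class TruthVariant:
    """One simulated (or curated) truth record.

    ``pos`` is 1-based; ``ref``/``alt`` follow the VCF anchor-base
    convention for indels.  ``haplotype`` records which haplotype carries a
    heterozygous variant (0 or 1); it is ``None`` for hom-alt records or
    truth sets that do not carry phasing.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype: str = HET
    haplotype: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise InputError("ref and alt alleles must be non-empty")
        if self.genotype not in (HET, HOM_ALT):
            raise InputError(f"genotype must be '{HET}' or '{HOM_ALT}'")
        if self.genotype == HET and self.haplotype not in (None, 0, 1):
            raise InputError("haplotype must be 0, 1 or None")

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return SNP
        return INSERTION if len(self.alt) > len(self.ref) else DELETION

    @property
    def start0(self) -> int:
        """0-based start of the reference footprint."""
        return self.pos - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end of the reference footprint."""
        return self.pos - 1 + len(self.ref)


@dataclass(frozen=True)
class ReadOrigin:
    """True placement of a simulated read (pair) on the unmutated reference.

    ``start1``/``start2`` are the 1-based leftmost reference coordinates of
    mate 1 / mate 2 — the coordinate a perfect mapper would report as SAM
    POS.  ``start2``/``strand2`` are ``None`` for single-end reads.
    """

    chrom: str
    start1: int
    strand1: str
    start2: Optional[int]
    strand2: Optional[str]
    haplotype: int
    serial: int

    def __post_init__(self) -> None:
        if self.strand1 not in "+-":
            raise InputError("strand1 must be '+' or '-'")
        if (self.start2 is None) != (self.strand2 is None):
            raise InputError("start2 and strand2 must both be set or both absent")
        if self.strand2 is not None and self.strand2 not in "+-":
            raise InputError("strand2 must be '+' or '-'")
        if self.start1 < 1 or (self.start2 is not None and self.start2 < 1):
            raise InputError("start positions are 1-based and must be >= 1")
        if self.haplotype not in (0, 1):
            raise InputError("haplotype must be 0 or 1")
        if self.serial < 0:
            raise InputError("serial must be non-negative")

    def mate(self, index: int) -> tuple[int, str]:
        """Return (start, strand) for mate ``index`` (1 or 2)."""
        if index == 1:
            return self.start1, self.strand1
        if index == 2:
            if self.start2 is None:
                raise InputError("origin is single-end; no mate 2")
            return self.start2, self.strand2  # type: ignore[return-value]
        raise InputError(f"mate index must be 1 or 2, got {index}")


@dataclass(frozen=True)
class LibraryModel:
    """Sequencing-library parameters for read simulation."""

    read_length: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    coverage: float = 20.0
    paired: bool = True
    base_error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise InputError("read_length must be positive")
        if self.coverage <= 0:
            raise InputError("coverage must be positive")
        if self.insert_sd < 0:
            raise InputError("insert_sd must be non-negative")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise InputError("base_error_rate must be in [0, 1)")

    @property
    def quality_char(self) -> str:
        """Flat Phred+33 base-quality character consistent with the error rate."""
        if self.base_error_rate == 0.0:
            q = 40
        else:
            q = min(40, round(-10.0 * math.log10(self.base_error_rate)))
        return chr(33 + q)


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


@dataclass
class DiploidGenome:
    """Two mutated haplotypes of one contig plus the truth that created them."""

    chrom: str
    reference_length: int
    haplotype0: str
    haplotype1: str
    truth: list[TruthVariant]

    def __iter__(self) -> Iterator:
        return iter((self.haplotype0, self.haplotype1, self.truth))

    def haplotype(self, index: int) -> str:
        return self.haplotype0 if index == 0 else self.haplotype1

    def truth_for_haplotype(self, index: int) -> list[TruthVariant]:
        return [v for v in self.truth
                if v.genotype == HOM_ALT or v.haplotype == index]


@dataclass
class ReadSimulation:
    """FASTQ reads plus the per-pair truth channel, in matching order."""

    reads1: list[FastqRead]
    reads2: Optional[list[FastqRead]]
    origins: list[ReadOrigin]

    def __iter__(self) -> Iterator:
        return iter((self.reads1, self.reads2, self.origins))

    @property
    def n_reads(self) -> int:
        return len(self.reads1) + (len(self.reads2) if self.reads2 else 0)


# ---------------------------------------------------------------------------
# reference generation and mutation
# ---------------------------------------------------------------------------

def generate_reference(length: int, gc_content: float = 0.5, seed: int = 0,
                       name: str = "chrsim") -> Reference:
    """Generate a random reference contig with the requested GC content.

    Bases are drawn i.i.d. with P(G) = P(C) = gc_content/2 and
    P(A) = P(T) = (1-gc_content)/2; the draw is deterministic for a fixed
    seed.  ``length`` must be at least 1000 bases — shorter contigs cannot
    host a meaningful read simulation.
    """
    if length < 1000:
        raise InputError(f"reference length must be >= 1000, got {length}")
    if not 0.0 < gc_content < 1.0:
        raise InputError("gc_content must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    at, gc = (1.0 - gc_content) / 2.0, gc_content / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = _BASES[idx].tobytes().decode("ascii")
    return Reference(name=name, sequence=seq)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T sequence."""
    return seq.translate(_COMPLEMENT)[::-1]


def mutate_diploid(ref: Reference, model: MutationModel = MutationModel(),
                   seed: int = 0) -> DiploidGenome:
    """Mutate a reference into two haplotypes and record the truth.

    Each base mutates independently with probability ``model.mutation_rate``.
    A mutation is an indel with probability ``model.indel_fraction``
    (insertion or deletion with equal chance; length from the small range,
    or from the large range with probability ``model.large_indel_fraction``),
    otherwise a SNP.  A mutation is heterozygous (one uniformly chosen
    haplotype) with probability ``model.het_probability``, else hom-alt.

    A proposed mutation whose reference footprint would overlap an existing
    mutation on the same haplotype is rejected and not resampled, so truth
    records never overlap on a haplotype.  Deletions that would run past the
    contig end are likewise rejected.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    L = ref.length
    seq = ref.sequence
    positions = np.flatnonzero(rng.random(L) < model.mutation_rate)

    truth: list[TruthVariant] = []
    # 0-based exclusive end of the last accepted footprint per haplotype
    occupied_end = [0, 0]
    lo_s, hi_s = model.small_indel_range
    lo_l, hi_l = model.large_indel_range

    for pos in positions:
        pos = int(pos)
        is_indel = rng.random() < model.indel_fraction
        anchor = seq[pos]
        if is_indel:
            is_insertion = rng.random() < 0.5
            if rng.random() < model.large_indel_fraction:
                ilen = int(rng.integers(lo_l, hi_l + 1))
            else:
                ilen = int(rng.integers(lo_s, hi_s + 1))
            if is_insertion:
                ins = _BASES[rng.integers(0, 4, size=ilen)].tobytes().decode()
                ref_allele, alt_allele = anchor, anchor + ins
            else:
                ref_allele = seq[pos:pos + ilen + 1]
                alt_allele = anchor
        else:
            others = "ACGT".replace(anchor, "")
            ref_allele, alt_allele = anchor, others[rng.integers(0, 3)]

        is_het = rng.random() < model.het_probability
        hap = int(rng.integers(0, 2)) if is_het else None
        haps = (hap,) if is_het else (0, 1)

        footprint_end = pos + len(ref_allele)
        if footprint_end > L:
            continue  # deletion would run off the contig
        if any(pos < occupied_end[h] for h in haps):
            continue  # overlaps an earlier mutation on a shared haplotype
        for h in haps:
            occupied_end[h] = footprint_end
        truth.append(TruthVariant(
            chrom=ref.name, pos=pos + 1, ref=ref_allele, alt=alt_allele,
            genotype=HET if is_het else HOM_ALT, haplotype=hap))

    hap0, _ = apply_variants(seq, [v for v in truth
                                   if v.genotype == HOM_ALT or v.haplotype == 0])
    hap1, _ = apply_variants(seq, [v for v in truth
                                   if v.genotype == HOM_ALT or v.haplotype == 1])
    return DiploidGenome(chrom=ref.name, reference_length=L,
                         haplotype0=hap0, haplotype1=hap1, truth=truth)


def apply_variants(sequence: str, variants: Sequence[TruthVariant],
                   with_coords: bool = False) -> tuple[str, Optional[np.ndarray]]:
    """Apply sorted, non-overlapping variants to a sequence.

    Returns the mutated sequence and, if ``with_coords``, an int64 array
    giving for every haplotype base the 0-based reference coordinate it
    derives from (inserted bases inherit their anchor's coordinate).
    """
    pieces: list[str] = []
    coords: list[np.ndarray] = []
    cur = 0
    for v in variants:
        p0 = v.start0
        if p0 < cur:
            raise InputError(
                f"variants overlap or are unsorted at {v.chrom}:{v.pos}")
        if v.end0 > len(sequence):
            raise InputError(f"variant at {v.chrom}:{v.pos} exceeds contig end")
        if sequence[p0:v.end0] != v.ref:
            raise InputError(
                f"REF allele mismatch at {v.chrom}:{v.pos}: "
                f"expected {v.ref!r}, sequence has {sequence[p0:v.end0]!r}")
        pieces.append(sequence[cur:p0])
        pieces.append(v.alt)
        if with_coords:
            coords.append(np.arange(cur, p0, dtype=np.int64))
            coords.append(np.full(len(v.alt), p0, dtype=np.int64))
        cur = v.end0
    pieces.append(sequence[cur:])
    if with_coords:
        coords.append(np.arange(cur, len(sequence), dtype=np.int64))
        return "".join(pieces), np.concatenate(coords)
    return "".join(pieces), None


# ---------------------------------------------------------------------------
# read-name truth channel
# ---------------------------------------------------------------------------

_STRAND_CODE = {"+": "F", "-": "R", None: "u"}
_STRAND_DECODE = {"F": "+", "R": "-"}


def encode_read_name(origin: ReadOrigin) -> str:
    """Encode a read origin into a FASTQ/SAM-safe query name.

    The name is ``chrom_start1_strand_start2_strand_hap_serial`` with
    strands written F/R; a single-end origin writes ``0_u`` for mate 2.
    Decoding splits from the right, so contig names may contain
    underscores.
    """
    fields = (origin.chrom, str(origin.start1), _STRAND_CODE[origin.strand1],
              str(origin.start2 or 0), _STRAND_CODE[origin.strand2],
              str(origin.haplotype), str(origin.serial))
    name = "_".join(fields)
    if any(c.isspace() for c in name) or "@" in name:
        raise InputError(f"contig name produces an illegal query name: {name!r}")
    return name


def decode_read_name(name: str) -> ReadOrigin:
    """Invert :func:`encode_read_name`; raises ReadNameError on malformed input."""
    parts = name.rsplit("_", 6)
    if len(parts) != 7:
        raise ReadNameError(
            f"read name {name!r} has {len(parts)} fields, expected 7")
    chrom, s1, f1, s2, f2, hap, serial = parts
    if not chrom:
        raise ReadNameError(f"read name {name!r}: empty contig field")
    try:
        start1 = int(s1)
    except ValueError:
        raise ReadNameError(f"read name {name!r}: bad start1 field {s1!r}") from None
    if f1 not in _STRAND_DECODE:
        raise ReadNameError(f"read name {name!r}: bad strand1 field {f1!r}")
    try:
        start2 = int(s2)
    except ValueError:
        raise ReadNameError(f"read name {name!r}: bad start2 field {s2!r}") from None
    if f2 not in _STRAND_DECODE and f2 != "u":
        raise ReadNameError(f"read name {name!r}: bad strand2 field {f2!r}")
    try:
        hap_i, serial_i = int(hap), int(serial)
    except ValueError:
        raise ReadNameError(
            f"read name {name!r}: bad haplotype/serial fields") from None
    single_end = start2 == 0 and f2 == "u"
    try:
        return ReadOrigin(
            chrom=chrom, start1=start1, strand1=_STRAND_DECODE[f1],
            start2=None if single_end else start2,
            strand2=None if single_end else _STRAND_DECODE.get(f2),
            haplotype=hap_i, serial=serial_i)
    except InputError as exc:
        raise ReadNameError(f"read name {name!r}: {exc}") from None


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(genome: DiploidGenome | Reference,
                   lib: LibraryModel = LibraryModel(),
                   seed: int = 0) -> ReadSimulation:
    """Simulate uniformly placed reads from the two haplotypes.

    The number of pairs is the closed form
    ``round(coverage * reference_length / (2 * read_length))`` (for
    single-end libraries the divisor is ``read_length``).  Each fragment
    picks a haplotype uniformly, a length from N(insert_mean, insert_sd)
    resampled until it fits within [read_length, haplotype length], and a
    uniform start; mate 1 sits on the forward strand with probability 0.5
    (standard FR orientation).  Substitution errors are injected per base at
    ``lib.base_error_rate``.  Origins record the 1-based leftmost
    *reference* coordinate of each mate, which is what a perfect mapper
    would report.
    """
    if isinstance(genome, Reference):
        genome = DiploidGenome(chrom=genome.name,
                               reference_length=genome.length,
                               haplotype0=genome.sequence,
                               haplotype1=genome.sequence, truth=[])
    ss = np.random.SeedSequence(seed)
    frag_rng, err_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    rl = lib.read_length
    ref_seq_len = genome.reference_length
    # Coordinate maps (haplotype base -> reference coordinate) require the
    # unmutated reference; the truth is lossless, so recover it by inverting
    # haplotype 0 and rebuild both haplotypes with coordinates attached.
    reference_seq = _reconstruct_reference(genome)
    haps: list[str] = []
    coord_maps: list[np.ndarray] = []
    for h in (0, 1):
        hseq, coords = apply_variants(reference_seq,
                                      genome.truth_for_haplotype(h),
                                      with_coords=True)
        if hseq != genome.haplotype(h):
            raise InputError("genome haplotypes do not match their truth records")
        haps.append(hseq)
        coord_maps.append(coords)  # type: ignore[arg-type]

    min_hap_len = min(len(h) for h in haps)
    if rl > min_hap_len:
        raise InputError(
            f"read length {rl} exceeds haplotype length {min_hap_len}")

    if lib.paired:
        n_pairs = round(lib.coverage * ref_seq_len / (2 * rl))
    else:
        n_pairs = round(lib.coverage * ref_seq_len / rl)

    qual = lib.quality_char * rl
    e = lib.base_error_rate
    reads1: list[FastqRead] = []
    reads2: list[FastqRead] = []
    origins: list[ReadOrigin] = []

    for serial in range(n_pairs):
        hap = int(frag_rng.integers(0, 2))
        hseq, coords = haps[hap], coord_maps[hap]
        hap_len = len(hseq)
        if lib.paired:
            frag = 0
            while not (rl <= frag <= hap_len):
                frag = round(frag_rng.normal(lib.insert_mean, lib.insert_sd))
            start = int(frag_rng.integers(0, hap_len - frag + 1))
            left = hseq[start:start + rl]
            right = revcomp(hseq[start + frag - rl:start + frag])
            left_pos = int(coords[start]) + 1
            right_pos = int(coords[start + frag - rl]) + 1
            mate1_forward = frag_rng.random() < 0.5
            if mate1_forward:
                seq1, seq2 = left, right
                origin = ReadOrigin(genome.chrom, left_pos, "+",
                                    right_pos, "-", hap, serial)
            else:
                seq1, seq2 = right, left
                origin = ReadOrigin(genome.chrom, right_pos, "-",
                                    left_pos, "+", hap, serial)
            seq1 = _inject_errors(seq1, e, err_rng)
            seq2 = _inject_errors(seq2, e, err_rng)
            name = encode_read_name(origin)
            reads1.append(FastqRead(name, seq1, qual))
            reads2.append(FastqRead(name, seq2, qual))
            origins.append(origin)
        else:
            start = int(frag_rng.integers(0, hap_len - rl + 1))
            forward = frag_rng.random() < 0.5
            seq = hseq[start:start + rl]
            if not forward:
                seq = revcomp(seq)
            origin = ReadOrigin(genome.chrom, int(coords[start]) + 1,
                                "+" if forward else "-", None, None,
                                hap, serial)
            seq = _inject_errors(seq, e, err_rng)
            reads1.append(FastqRead(encode_read_name(origin), seq, qual))
            origins.append(origin)

    return ReadSimulation(reads1=reads1,
                          reads2=reads2 if lib.paired else None,
                          origins=origins)


def _reconstruct_reference(genome: DiploidGenome) -> str:
    """Invert haplotype 0's truth records to recover the reference sequence."""
    pieces: list[str] = []
    cur = 0  # position in haplotype-0 coordinates
    offset = 0  # haplotype coordinate minus reference coordinate so far
    for v in genome.truth_for_haplotype(0):
        h0 = v.start0 + offset
        pieces.append(genome.haplotype0[cur:h0])
        pieces.append(v.ref)
        cur = h0 + len(v.alt)
        offset += len(v.alt) - len(v.ref)
    pieces.append(genome.haplotype0[cur:])
    return "".join(pieces)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

def write_reference_fasta(ref: Reference, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{ref.name}\n")
        for i in range(0, ref.length, width):
            fh.write(ref.sequence[i:i + width] + "\n")


def write_fastq(reads: Sequence[FastqRead], path: str) -> None:
    """Write reads to a gzip FASTQ; output is byte-identical across runs."""
    with open(path, "wb") as raw:
        if path.endswith(".gz"):
            # fixed mtime and no embedded filename keep the bytes reproducible
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw,
                               mtime=0) as fh:
                for r in reads:
                    fh.write(
                        f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n".encode())
        else:
            for r in reads:
                raw.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n".encode())


def write_truth(truth: Sequence[TruthVariant],
                regions: Sequence[tuple[str, int, int]],
                contigs: dict[str, int],
                vcf_path: str, bed_path: str,
                sample: str = "TRUTH") -> None:
    """Write the truth as a VCF 4.2 plus a BED of high-confidence regions.

    Heterozygous genotypes are written phased (``1|0`` for haplotype 0,
    ``0|1`` for haplotype 1, ``0/1`` when the haplotype is unknown) so that
    re-reading the file reproduces the in-memory truth exactly; hom-alt is
    ``1/1``.  BED intervals are 0-based half-open.
    """
    last: tuple[str, int] | None = None
    for v in truth:
        key = (v.chrom, v.pos)
        if last is not None and v.chrom == last[0] and key < last:
            raise InputError("truth records must be sorted by (chrom, pos)")
        last = key
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gcatbench-simkit\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for v in truth:
            if v.genotype == HOM_ALT:
                gt = "1/1"
            elif v.haplotype is None:
                gt = "0/1"
            else:
                gt = "1|0" if v.haplotype == 0 else "0|1"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                     f"GT\t{gt}\n")
    with open(bed_path, "w") as fh:
        for chrom, start, end in regions:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_truth_vcf(path: str) -> list[TruthVariant]:
    """Read a truth (or any single-sample genotype) VCF into TruthVariants.

    Multi-allelic sites are decomposed into biallelic records; alt alleles
    absent from the genotype are dropped.  Phased het genotypes recover the
    haplotype assignment.
    """
    out: list[TruthVariant] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alts = f[0], int(f[1]), f[2], f[3], f[4]
            gt_str = None
            if len(f) >= 10 and "GT" in f[8].split(":"):
                gt_str = f[9].split(":")[f[8].split(":").index("GT")]
            for ai, alt in enumerate(alts.split(","), start=1):
                if alt in (".", "*", "<NON_REF>"):
                    continue
                genotype, hap = HET, None
                if gt_str is not None and gt_str not in (".", "./.", ".|."):
                    phased = "|" in gt_str
                    alleles = gt_str.replace("|", "/").split("/")
                    calls = [a == str(ai) for a in alleles]
                    if not any(calls):
                        continue
                    if all(calls) and len(calls) > 1:
                        genotype = HOM_ALT
                    else:
                        genotype = HET
                        if phased and len(calls) == 2:
                            hap = 0 if calls[0] else 1
                out.append(TruthVariant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                        genotype=genotype, haplotype=hap))
    return out


_ORIGIN_COLUMNS = ("name", "chrom", "start1", "strand1", "start2", "strand2",
                   "haplotype", "serial")


def write_origins(origins: Sequence[ReadOrigin], path: str) -> None:
    """Write read origins as a TSV sidecar (one row per pair/read)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ORIGIN_COLUMNS) + "\n")
        for o in origins:
            fh.write("\t".join((
                encode_read_name(o), o.chrom, str(o.start1), o.strand1,
                str(o.start2) if o.start2 is not None else ".",
                o.strand2 if o.strand2 is not None else ".",
                str(o.haplotype), str(o.serial))) + "\n")


def read_origins(path: str) -> dict[str, ReadOrigin]:
    """Read an origins TSV back into a name -> origin mapping."""
    out: dict[str, ReadOrigin] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ORIGIN_COLUMNS:
            raise InputError(f"unexpected origins header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            origin = ReadOrigin(
                chrom=f[1], start1=int(f[2]), strand1=f[3],
                start2=None if f[4] == "." else int(f[4]),
                strand2=None if f[5] == "." else f[5],
                haplotype=int(f[6]), serial=int(f[7]))
            out[f[0]] = origin
    return out
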