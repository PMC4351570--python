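"""Benchmark a variant call set against a truth set on high-confidence regions.

The comparison follows the standard truth-set protocol for germline small
variants: both call sets are decomposed to biallelic records, left-trimmed
and left-aligned against the reference; evaluation is restricted to the
high-confidence regions in which the truth set asserts a genotype at every
base; complex regions — windows containing a truth indel plus another truth
variant, whose representation is mapper/caller-dependent — are excluded; a
test call matching a truth record on position and alleles (and genotype, in
genotype-aware mode) is a true positive, an unmatched test call a false
positive, an unmatched truth record a false negative; and every confident
base not covered by a variant in either set counts as a true negative.

Because almost all confident bases are homozygous reference, specificity
TN/(TN+FP) is nearly saturated at 100%; the precision rate TP/(TP+FP) is
usually the more informative statistic and both are reported.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .errors import InputError
from .intervals import IntervalSet
from .simkit import HET, HOM_ALT, Reference, TruthVariant

ConfidentRegions = IntervalSet
ExclusionSet = IntervalSet

DEFAULT_EXCLUSION_WINDOW = 10


@dataclass(frozen=True, order=True)
class CallRecord:
    """One biallelic, normalized call from a test VCF.

    ``quality`` is the record's variant quality (QUAL) and ``depth`` the
    per-sample read depth (DP), either of which a caller may omit.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: Optional[str] = field(default=None, compare=False)
    quality: Optional[float] = field(default=None, compare=False)
    depth: Optional[int] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise InputError("ref and alt alleles must be non-empty")

    @property
    def vclass(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        return self.pos - 1 + len(self.ref)


VariantLike = Union[CallRecord, TruthVariant]


@dataclass
class VariantComparison:
    """TP/FP/FN record lists, the per-base TN count and exclusion tallies."""

    tp: list[CallRecord]
    fp: list[CallRecord]
    fn: list[TruthVariant]
    tn_count: int
    excluded_test_count: int
    excluded_truth_count: int
    genotype_aware: bool = True

    @property
    def tp_count(self) -> int:
        return len(self.tp)

    @property
    def fp_count(self) -> int:
        return len(self.fp)

    @property
    def fn_count(self) -> int:
        return len(self.fn)


@dataclass(frozen=True)
class MetricSet:
    """Precision, sensitivity and specificity as fractions in [0, 1].

    An undefined ratio (0/0) is ``None``, never 0 or 1.
    """

    precision: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]

    @staticmethod
    def _pct(v: Optional[float]) -> Optional[float]:
        return None if v is None else round(100.0 * v, 2)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision_pct": self._pct(self.precision),
            "sensitivity_pct": self._pct(self.sensitivity),
            "specificity_pct": self._pct(self.specificity),
        }


@dataclass(frozen=True)
class QualityRocPoint:
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def fpr(self) -> Optional[float]:
        d = self.fp + self.tn
        return self.fp / d if d else None


@dataclass(frozen=True)
class QualityRocCurve:
    points: tuple[QualityRocPoint, ...]

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class DepthStratum:
    """TP/FP counts and precision for one read-depth bin.

    ``lo``/``hi`` are ``None`` for the stratum collecting records without a
    usable depth annotation.
    """

    lo: Optional[int]
    hi: Optional[int]
    tp: int
    fp: int

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _get_seq(ref, chrom: str, start0: int, end0: int) -> str:
    """Fetch reference sequence from a Reference, mapping, or pyfaidx.Fasta."""
    if isinstance(ref, Reference):
        if chrom != ref.name:
            raise InputError(f"contig {chrom!r} not in reference {ref.name!r}")
        return ref.sequence[start0:end0]
    if isinstance(ref, Mapping):
        return ref[chrom][start0:end0]
    return str(ref[chrom][start0:end0]).upper()  # pyfaidx-style


def normalize_record(rec: VariantLike, ref) -> VariantLike:
    """Trim shared allele bases and left-align one record against ``ref``.

    Shared trailing bases are removed first, then shared leading bases (the
    position advances); a length-changing allele pair is shifted left while
    its last base equals the reference base preceding it, and finally given
    a single anchor base.  The result is the canonical, minimal VCF
    representation; applying the function twice changes nothing.
    """
    pos0, ref_a, alt_a = rec.pos - 1, rec.ref, rec.alt
    if ref_a == alt_a:
        raise InputError(
            f"record at {rec.chrom}:{rec.pos} has identical alleles")
    if _get_seq(ref, rec.chrom, pos0, pos0 + len(ref_a)) != ref_a:
        raise InputError(
            f"REF allele mismatch at {rec.chrom}:{rec.pos} ({ref_a!r})")

    while True:
        if ref_a and alt_a and ref_a[-1] == alt_a[-1]:
            ref_a, alt_a = ref_a[:-1], alt_a[:-1]
        elif (not ref_a or not alt_a) and pos0 > 0:
            prev = _get_seq(ref, rec.chrom, pos0 - 1, pos0)
            ref_a, alt_a = prev + ref_a, prev + alt_a
            pos0 -= 1
        else:
            break
    if not ref_a or not alt_a:
        # empty allele at contig start: re-anchor on the following base
        nxt = _get_seq(ref, rec.chrom,
                       pos0 + len(ref_a), pos0 + len(ref_a) + 1)
        ref_a, alt_a = ref_a + nxt, alt_a + nxt
    while len(ref_a) >= 2 and len(alt_a) >= 2 and ref_a[0] == alt_a[0]:
        ref_a, alt_a = ref_a[1:], alt_a[1:]
        pos0 += 1

    return dataclasses.replace(rec, pos=pos0 + 1, ref=ref_a, alt=alt_a)


def normalize_calls(records: Iterable[VariantLike], ref) -> list[VariantLike]:
    """Normalize and sort a call set; idempotent by construction."""
    out = [normalize_record(r, ref) for r in records]
    out.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return out


def _check_normalized(records: Sequence[VariantLike], sample: int = 100) -> None:
    last_key = None
    for r in records[:sample]:
        key = (r.chrom, r.pos)
        if last_key is not None and r.chrom == last_key[0] and key < last_key:
            raise InputError("records are not sorted; normalize them first")
        last_key = key
        if len(r.ref) > 1 and len(r.alt) > 1 and r.ref[-1] == r.alt[-1]:
            raise InputError(
                f"record at {r.chrom}:{r.pos} carries a shared allele suffix; "
                "normalize the call set first")
        if len(r.ref) == len(r.alt) > 1 and r.ref[0] == r.alt[0]:
            raise InputError(
                f"record at {r.chrom}:{r.pos} carries a shared allele prefix; "
                "normalize the call set first")


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def build_exclusions(truth: Sequence[TruthVariant],
                     window: int = DEFAULT_EXCLUSION_WINDOW) -> ExclusionSet:
    """Exclude complex regions: a truth indel with another variant nearby.

    Whenever a truth indel and another truth variant start within
    ``window - 1`` bases of each other, the interval spanning both variants'
    reference footprints is excluded from the comparison (such nearby
    SNP+indel combinations are represented differently by different mappers
    and callers).  Intervals are merged before being returned.
    """
    ivs: list[tuple[str, int, int]] = []
    n = len(truth)
    order = sorted(range(n), key=lambda i: (truth[i].chrom, truth[i].pos))
    for a in range(n):
        i = order[a]
        if truth[i].vclass == "SNP":
            continue
        for b in range(n):
            j = order[b]
            if i == j:
                continue
            u, v = truth[i], truth[j]
            if u.chrom != v.chrom:
                continue
            if abs(u.start0 - v.start0) <= window - 1:
                ivs.append((u.chrom, min(u.start0, v.start0),
                            max(u.end0, v.end0)))
    return IntervalSet(ivs)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def count_true_negatives(regions: ConfidentRegions,
                         truth: Iterable[VariantLike],
                         test: Iterable[VariantLike]) -> int:
    """Confident bases not covered by any variant in either set."""
    footprints = [(r.chrom, r.start0, r.end0) for r in truth]
    footprints += [(r.chrom, r.start0, r.end0) for r in test]
    return regions.total_bases - regions.covered_length(footprints)


def _evaluable(rec: VariantLike, regions: ConfidentRegions,
               exclusions: Optional[ExclusionSet]) -> bool:
    if not regions.contains(rec.chrom, rec.start0, rec.end0):
        return False
    if exclusions is not None and \
            exclusions.overlaps(rec.chrom, rec.start0, rec.end0):
        return False
    return True


def compare(test: Sequence[CallRecord], truth: Sequence[TruthVariant],
            regions: ConfidentRegions,
            exclusions: Optional[ExclusionSet] = None,
            genotype_aware: bool = True) -> VariantComparison:
    """Classify test calls into TP/FP and truth records into TP/FN.

    Calls whose footprint leaves the confident regions or touches an
    excluded interval are set aside (counted in the ``excluded_*`` tallies,
    never as TP/FP/FN).  A test call matching an evaluable truth record on
    (chrom, pos, ref, alt) is a TP; in genotype-aware mode a matching allele
    with the wrong genotype counts as one FP and one FN.  Each truth record
    can absorb at most one test call.  The TN count covers every confident
    base untouched by either set.
    """
    _check_normalized(test)
    _check_normalized(truth)

    truth_eval: list[TruthVariant] = []
    excluded_truth = 0
    for t in truth:
        if _evaluable(t, regions, exclusions):
            truth_eval.append(t)
        else:
            excluded_truth += 1

    by_key: dict[tuple, list[int]] = {}
    for i, t in enumerate(truth_eval):
        by_key.setdefault((t.chrom, t.pos, t.ref, t.alt), []).append(i)
    matched = [False] * len(truth_eval)

    tp: list[CallRecord] = []
    fp: list[CallRecord] = []
    excluded_test = 0
    for c in test:
        if not _evaluable(c, regions, exclusions):
            excluded_test += 1
            continue
        hit = None
        for i in by_key.get((c.chrom, c.pos, c.ref, c.alt), ()):
            if matched[i]:
                continue
            if genotype_aware and c.genotype is not None and \
                    truth_eval[i].genotype != c.genotype:
                continue
            hit = i
            break
        if hit is None:
            fp.append(c)
        else:
            matched[hit] = True
            tp.append(c)

    fn = [t for i, t in enumerate(truth_eval) if not matched[i]]
    tn = count_true_negatives(regions, truth, test)
    return VariantComparison(tp=tp, fp=fp, fn=fn, tn_count=tn,
                             excluded_test_count=excluded_test,
                             excluded_truth_count=excluded_truth,
                             genotype_aware=genotype_aware)


def metrics(comparison: VariantComparison) -> MetricSet:
    """Precision TP/(TP+FP), sensitivity TP/(TP+FN), specificity TN/(TN+FP)."""
    tp, fp = comparison.tp_count, comparison.fp_count
    fn, tn = comparison.fn_count, comparison.tn_count
    return MetricSet(
        precision=tp / (tp + fp) if tp + fp else None,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
    )


def quality_roc(comparison: VariantComparison) -> QualityRocCurve:
    """ROC-like curve over the variant quality score.

    At each threshold t (one point per distinct quality, descending), calls
    with quality >= t keep their TP/FP status; calls below t are treated as
    not made, so a demoted TP becomes a FN and a demoted FP adds to the TN
    pool.  Calls without a quality score sit below every explicit threshold
    (they are never silently dropped); the final, lowest point therefore
    reproduces the unthresholded counts exactly.
    """
    NOQ = float("-inf")
    tp_q = [c.quality if c.quality is not None else NOQ for c in comparison.tp]
    fp_q = [c.quality if c.quality is not None else NOQ for c in comparison.fp]
    thresholds = sorted(set(tp_q) | set(fp_q), reverse=True)
    points: list[QualityRocPoint] = []
    fn0, tn0 = comparison.fn_count, comparison.tn_count
    tp_total, fp_total = len(tp_q), len(fp_q)
    for t in thresholds:
        tp_t = sum(1 for q in tp_q if q >= t)
        fp_t = sum(1 for q in fp_q if q >= t)
        points.append(QualityRocPoint(
            threshold=t, tp=tp_t, fp=fp_t,
            fn=fn0 + (tp_total - tp_t), tn=tn0 + (fp_total - fp_t)))
    return QualityRocCurve(points=tuple(points))


def stratify_by_depth(comparison: VariantComparison,
                      bin_edges: Sequence[int]) -> list[DepthStratum]:
    """Per-depth-bin TP/FP counts and precision.

    Bins are half-open ``[lo, hi)`` over consecutive edge pairs.  TP/FP
    records without a depth annotation — or with a depth outside every bin —
    fall into a trailing "unknown" stratum.  FN records carry no caller
    depth and are not binned; the strata support precision only.
    """
    edges = list(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise InputError("bin edges must be strictly increasing, length >= 2")
    if comparison.tp_count + comparison.fp_count == 0:
        return []
    n = len(edges) - 1
    tp_counts = [0] * (n + 1)
    fp_counts = [0] * (n + 1)
    for recs, counts in ((comparison.tp, tp_counts),
                         (comparison.fp, fp_counts)):
        for r in recs:
            if r.depth is None or not edges[0] <= r.depth < edges[-1]:
                counts[n] += 1
                continue
            counts[int(np.searchsorted(edges, r.depth, side="right")) - 1] += 1
    strata = [DepthStratum(lo=edges[i], hi=edges[i + 1],
                           tp=tp_counts[i], fp=fp_counts[i])
              for i in range(n)]
    if tp_counts[n] or fp_counts[n]:
        strata.append(DepthStratum(lo=None, hi=None,
                                   tp=tp_counts[n], fp=fp_counts[n]))
    return strata


# ---------------------------------------------------------------------------
# VCF loading
# ---------------------------------------------------------------------------

_GT_MAP = {(0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}


def load_vcf(path: str, include_filtered: bool = False) -> list[CallRecord]:
    """Load a (possibly bgzipped) VCF into biallelic CallRecords.

    Multi-allelic sites are decomposed; alleles the sample genotype does not
    carry are kept only when the record has no genotype.  Records failing
    FILTER (anything other than PASS or '.') are dropped unless
    ``include_filtered``.  Depth comes from the first sample's DP, falling
    back to INFO/DP.
    """
    import pysam

    out: list[CallRecord] = []
    save = pysam.set_verbosity(0)
    try:
        with pysam.VariantFile(path) as vf:
            for rec in vf.fetch() if vf.index is not None else vf:
                filters = list(rec.filter.keys())
                if not include_filtered and filters and filters != ["PASS"]:
                    continue
                sample = rec.samples[0] if rec.samples else None
                gt = tuple(a for a in (sample["GT"] or ())
                           if a is not None) if sample and "GT" in sample else ()
                depth = None
                try:
                    if sample is not None and sample.get("DP") is not None:
                        depth = int(sample["DP"])
                    elif rec.info.get("DP") is not None:
                        dp = rec.info["DP"]
                        depth = int(dp[0] if isinstance(dp, tuple) else dp)
                except ValueError:
                    depth = None  # DP absent from the header entirely
                qual = float(rec.qual) if rec.qual is not None else None
                for ai, alt in enumerate(rec.alts or (), start=1):
                    if alt in ("*", "<NON_REF>") or alt.startswith("<"):
                        continue
                    genotype = None
                    if gt:
                        if ai not in gt:
                            continue
                        genotype = HOM_ALT if len(gt) > 1 \
                            and all(a == ai for a in gt) else HET
                    out.append(CallRecord(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        genotype=genotype, quality=qual, depth=depth))
    finally:
        pysam.set_verbosity(save)
    return out


def write_calls_vcf(records: Sequence[VariantLike], contigs: dict[str, int],
                    path: str, sample: str = "SAMPLE") -> None:
    """Write records (e.g. a comparison's TP/FP/FN lists) as a plain VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gcatbench-vareval\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
            gt = {HET: "0/1", HOM_ALT: "1/1"}.get(
                getattr(r, "genotype", None) or "", "./.")
            qual = getattr(r, "quality", None)
            depth = getattr(r, "depth", None)
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t"
                     f"{'.' if qual is None else round(qual, 2)}\tPASS\t.\t"
                     f"GT:DP\t{gt}:{'.' if depth is None else depth}\n")
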