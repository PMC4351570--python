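"""Score simulated-read alignments against their encoded true origins.

Given a SAM/BAM produced by any mapper from simulated reads, each primary
alignment is judged correct, incorrect or unmapped by comparing its reported
placement with the origin decoded from the read name.  From the per-read
judgments the module derives the benchmark outputs: summary counts, the
mapping-quality-sorted ROC-like curve (cumulative incorrect vs correct reads
as the MAPQ threshold decreases from the maximum), and a calibration
histogram of incorrectly mapped reads across normalized mapping-quality
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from scipy.stats import rankdata

from .errors import EvaluationError, ReadNameError
from .simkit import ReadOrigin, decode_read_name

CORRECT = "correct"
INCORRECT = "incorrect"
UNMAPPED = "unmapped"

DEFAULT_TOLERANCE = 20


@dataclass(frozen=True)
class AlignmentRecord:
    """A primary alignment (or unmapped record) reduced to judgment inputs."""

    name: str
    mate: int  # 1 or 2
    mapped: bool
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 1-based leftmost
    strand: Optional[str] = None
    mapq: int = 0

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignmentRecord":
        mapped = not aln.is_unmapped
        return cls(
            name=aln.query_name or "",
            mate=2 if aln.is_read2 else 1,
            mapped=mapped,
            chrom=aln.reference_name if mapped else None,
            pos=aln.reference_start + 1 if mapped else None,
            strand=("-" if aln.is_reverse else "+") if mapped else None,
            mapq=aln.mapping_quality if mapped else 0,
        )


@dataclass(frozen=True)
class AlignmentJudgment:
    verdict: str  # correct / incorrect / unmapped
    mapq: int = 0
    distance: Optional[int] = None  # |reported pos - true pos| when mapped


@dataclass(frozen=True)
class AlignmentSummary:
    total: int
    mapped: int
    correct: int
    incorrect: int
    unmapped: int

    def __post_init__(self) -> None:
        if self.correct + self.incorrect != self.mapped:
            raise EvaluationError("correct + incorrect must equal mapped")
        if self.mapped + self.unmapped != self.total:
            raise EvaluationError("mapped + unmapped must equal total")

    def _pct(self, n: int) -> float:
        return 100.0 * n / self.total if self.total else 0.0

    @property
    def mapped_pct(self) -> float:
        return self._pct(self.mapped)

    @property
    def correct_pct(self) -> float:
        return self._pct(self.correct)

    @property
    def incorrect_pct(self) -> float:
        return self._pct(self.incorrect)

    @property
    def unmapped_pct(self) -> float:
        return self._pct(self.unmapped)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "mapped": self.mapped, "mapped_pct": round(self.mapped_pct, 2),
            "correct": self.correct, "correct_pct": round(self.correct_pct, 2),
            "incorrect": self.incorrect,
            "incorrect_pct": round(self.incorrect_pct, 2),
            "unmapped": self.unmapped,
            "unmapped_pct": round(self.unmapped_pct, 2),
        }


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    correct: int
    incorrect: int


@dataclass(frozen=True)
class RocCurve:
    """Cumulative (correct, incorrect) counts at descending MAPQ thresholds."""

    points: tuple[RocPoint, ...]

    def __iter__(self):
        return iter(self.points)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class CalibrationHistogram:
    """Incorrect-read counts across normalized MAPQ percentile bins."""

    bin_edges: tuple[float, ...]  # len n_bins + 1, spanning [0, 100]
    counts: tuple[int, ...]

    @property
    def n_bins(self) -> int:
        return len(self.counts)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def judge_read(rec: AlignmentRecord, origin: ReadOrigin,
               tolerance: int = DEFAULT_TOLERANCE) -> AlignmentJudgment:
    """Judge one alignment against the read's true origin.

    A mapped read is correct when it sits on the true contig and strand with
    its leftmost coordinate within ``tolerance`` bases of the true leftmost
    coordinate (indels near the read end shift reported positions, so exact
    equality would be too strict); anything else mapped is incorrect.
    """
    if not rec.mapped:
        return AlignmentJudgment(verdict=UNMAPPED)
    true_pos, true_strand = origin.mate(rec.mate)
    distance = abs(int(rec.pos) - true_pos)  # type: ignore[arg-type]
    ok = (rec.chrom == origin.chrom and rec.strand == true_strand
          and distance <= tolerance)
    return AlignmentJudgment(verdict=CORRECT if ok else INCORRECT,
                             mapq=rec.mapq, distance=distance)


def summarize(judgments: Iterable[AlignmentJudgment]) -> AlignmentSummary:
    """Count verdicts; the partition identities hold by construction."""
    correct = incorrect = unmapped = 0
    for j in judgments:
        if j.verdict == CORRECT:
            correct += 1
        elif j.verdict == INCORRECT:
            incorrect += 1
        elif j.verdict == UNMAPPED:
            unmapped += 1
        else:
            raise EvaluationError(f"unknown verdict {j.verdict!r}")
    mapped = correct + incorrect
    return AlignmentSummary(total=mapped + unmapped, mapped=mapped,
                            correct=correct, incorrect=incorrect,
                            unmapped=unmapped)


def mapq_roc(judgments: Iterable[AlignmentJudgment]) -> RocCurve:
    """ROC-like curve over mapping quality.

    One point per distinct MAPQ among mapped reads, in descending threshold
    order; the point at threshold t counts correct and incorrect reads with
    MAPQ >= t, so both coordinates are non-decreasing along the curve and
    the last point holds the totals over all mapped reads.
    """
    mapped = sorted((j for j in judgments
                     if j.verdict in (CORRECT, INCORRECT)),
                    key=lambda j: -j.mapq)
    points: list[RocPoint] = []
    correct = incorrect = 0
    i = 0
    while i < len(mapped):
        q = mapped[i].mapq
        while i < len(mapped) and mapped[i].mapq == q:
            if mapped[i].verdict == CORRECT:
                correct += 1
            else:
                incorrect += 1
            i += 1
        points.append(RocPoint(float(q), correct, incorrect))
    return RocCurve(points=tuple(points))


def mapq_calibration(judgments: Sequence[AlignmentJudgment],
                     n_bins: int = 10) -> CalibrationHistogram:
    """Histogram of incorrect reads across normalized MAPQ percentiles.

    Every mapped read receives a percentile equal to the rank of its MAPQ
    among all mapped reads (ties take the mean rank) scaled to [0, 100];
    incorrect reads are then counted into ``n_bins`` equal-width percentile
    bins (the last bin is closed at 100).
    """
    mapped = [j for j in judgments if j.verdict in (CORRECT, INCORRECT)]
    if not mapped:
        raise EvaluationError("no mapped reads: percentiles are undefined")
    mapqs = np.array([j.mapq for j in mapped], dtype=float)
    pct = rankdata(mapqs, method="average") / len(mapqs) * 100.0
    width = 100.0 / n_bins
    counts = [0] * n_bins
    for j, p in zip(mapped, pct):
        if j.verdict == INCORRECT:
            counts[min(int(p / width), n_bins - 1)] += 1
    edges = tuple(i * width for i in range(n_bins + 1))
    return CalibrationHistogram(bin_edges=edges, counts=tuple(counts))


# ---------------------------------------------------------------------------
# SAM/BAM evaluation driver
# ---------------------------------------------------------------------------

def iter_primary(path: str) -> Iterable[pysam.AlignedSegment]:
    """Iterate primary, non-supplementary records of a SAM/BAM (auto-detected)."""
    save = pysam.set_verbosity(0)  # silence missing-index warnings
    try:
        with pysam.AlignmentFile(path, require_index=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_secondary or aln.is_supplementary:
                    continue
                yield aln
    finally:
        pysam.set_verbosity(save)


def evaluate_alignments(path: str,
                        origins: Optional[dict[str, ReadOrigin]] = None,
                        tolerance: int = DEFAULT_TOLERANCE,
                        ) -> list[AlignmentJudgment]:
    """Judge every primary record of a SAM/BAM.

    The truth channel is the origin decoded from each read name, or an
    explicit name -> origin mapping (e.g. the simulator's TSV sidecar).  A
    read whose name cannot be resolved aborts the evaluation — silently
    dropping reads would bias the reported percentages — as does a
    duplicated (name, mate) pair.
    """
    judgments: list[AlignmentJudgment] = []
    seen: set[tuple[str, int]] = set()
    for aln in iter_primary(path):
        rec = AlignmentRecord.from_pysam(aln)
        key = (rec.name, rec.mate)
        if key in seen:
            raise EvaluationError(
                f"duplicate primary record for read {rec.name!r} mate {rec.mate}")
        seen.add(key)
        if origins is not None:
            try:
                origin = origins[rec.name]
            except KeyError:
                raise EvaluationError(
                    f"read {rec.name!r} absent from origins table") from None
        else:
            try:
                origin = decode_read_name(rec.name)
            except ReadNameError as exc:
                raise EvaluationError(str(exc)) from None
        judgments.append(judge_read(rec, origin, tolerance=tolerance))
    return judgments


def write_perfect_sam(origins: Sequence[ReadOrigin], read_length: int,
                      contigs: dict[str, int], path: str,
                      mapq: int = 60) -> None:
    """Write a SAM placing every simulated read at its true origin.

    This truth-derived alignment closes the simulate -> align -> evaluate
    loop without an external mapper: scoring it must yield 100% correct.
    """
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    })
    tids = {name: i for i, name in enumerate(contigs)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        from .simkit import encode_read_name
        for o in origins:
            paired = o.start2 is not None
            mates = [(1, o.start1, o.strand1)]
            if paired:
                mates.append((2, o.start2, o.strand2))
            for mate, start, strand in mates:
                a = pysam.AlignedSegment(header)
                a.query_name = encode_read_name(o)
                a.reference_id = tids[o.chrom]
                a.reference_start = start - 1
                a.mapping_quality = mapq
                a.cigarstring = f"{read_length}M"
                flag = 0
                if strand == "-":
                    flag |= 0x10
                if paired:
                    other = mates[1 - (mate - 1)]
                    flag |= 0x1 | 0x2 | (0x40 if mate == 1 else 0x80)
                    if other[2] == "-":
                        flag |= 0x20
                    a.next_reference_id = tids[o.chrom]
                    a.next_reference_start = other[1] - 1
                a.flag = flag
                out.write(a)
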