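"""Score a SAM of simulated reads: correctness, MAPQ ROC, calibration.

Simulates reads, then fabricates an imperfect "mapper" output by perturbing
a slice of the truth-derived alignments (misplaced reads keep low-to-middling
MAPQ, a few keep high MAPQ — a calibration failure).  Scoring decodes each
read's true origin from its name and reports the summary, the ROC-like
curve over MAPQ thresholds and the calibration histogram.
"""

import numpy as np
import pysam

import gcatbench as gb

ref = gb.generate_reference(100_000, 0.41, seed=5)
genome = gb.mutate_diploid(ref, gb.MutationModel(), seed=5)
sim = gb.simulate_reads(genome, gb.LibraryModel(coverage=4.0), seed=5)

gb.write_perfect_sam(sim.origins, 100, {ref.name: ref.length}, "mapper.sam")

# Perturb 3% of records: shift far away; most get low MAPQ, some high.
rng = np.random.default_rng(5)
with pysam.AlignmentFile("mapper.sam") as fh:
    records = list(fh.fetch(until_eof=True))
    header = fh.header
for aln in records:
    aln.mapping_quality = int(rng.integers(40, 61))
    if rng.random() < 0.03:
        aln.reference_start = int(rng.integers(0, ref.length - 100))
        aln.mapping_quality = int(rng.integers(0, 20)) \
            if rng.random() < 0.9 else 60
with pysam.AlignmentFile("mapper.sam", "w", header=header) as out:
    for aln in records:
        out.write(aln)

judgments = gb.evaluate_alignments("mapper.sam", tolerance=20)
summary = gb.summarize(judgments)
print(f"reads: {summary.total:,}  mapped {summary.mapped_pct:.2f}%  "
      f"correct {summary.correct_pct:.2f}%  "
      f"incorrect {summary.incorrect_pct:.2f}%")

roc = gb.mapq_roc(judgments)
print("MAPQ ROC (threshold, cumulative correct, cumulative incorrect):")
for p in list(roc)[:3]:
    print(f"  q>={p.threshold:>4.0f}  correct={p.correct:>6}  "
          f"incorrect={p.incorrect}")
print(f"  ... {len(roc)} thresholds; the final point holds the totals")

hist = gb.mapq_calibration(judgments)
print("calibration (MAPQ percentile bin -> incorrect reads):")
for i, count in enumerate(hist.counts):
    lo, hi = hist.bin_edges[i], hist.bin_edges[i + 1]
    print(f"  [{lo:>3.0f},{hi:>3.0f}) {count}")
print("A well-calibrated mapper concentrates incorrect reads in the lowest "
      "percentile bins; counts in the top bins are confidently wrong calls.")
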