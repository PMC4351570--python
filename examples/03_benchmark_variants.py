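"""Benchmark a degraded call set against simulated truth.

Simulates a truth set, then fabricates a realistic "caller" output: 5% of
truth variants are dropped (missed calls), a handful of spurious low-quality
SNPs are added, and a few genotypes are flipped.  The comparison runs with
the standard protocol — normalization, high-confidence-region restriction,
complex-region exclusion — and reports precision/sensitivity/specificity,
the variant-quality ROC and precision stratified by read depth.
"""

import numpy as np

import gcatbench as gb
from gcatbench import vareval as vv

ref = gb.generate_reference(1_000_000, 0.41, seed=23)
genome = gb.mutate_diploid(ref, gb.MutationModel(), seed=23)
truth = vv.normalize_calls(genome.truth, ref)
regions = gb.IntervalSet([(ref.name, 0, ref.length)])
exclusions = gb.build_exclusions(truth, window=10)
print(f"truth: {len(truth)} variants; "
      f"{len(exclusions)} complex-region exclusion intervals")

rng = np.random.default_rng(23)
test = []
for t in truth:
    r = rng.random()
    if r < 0.05:
        continue  # missed call
    genotype = t.genotype
    if r > 0.98:  # genotype error
        genotype = "hom-alt" if genotype == "het" else "het"
    depth = max(1, int(rng.normal(30, 12)))
    quality = float(np.clip(rng.normal(28 + 1.2 * depth, 15), 1, 250))
    test.append(gb.CallRecord(t.chrom, t.pos, t.ref, t.alt,
                              genotype=genotype, quality=quality,
                              depth=depth))
for _ in range(10):  # spurious low-quality SNPs
    p = int(rng.integers(1, ref.length))
    a = ref.sequence[p - 1]
    test.append(gb.CallRecord(ref.name, p, a, "ACGT".replace(a, "")[0],
                              genotype="het",
                              quality=float(rng.uniform(1, 25)),
                              depth=int(rng.integers(1, 12))))
test = vv.normalize_calls(test, ref)

comparison = gb.compare(test, truth, regions, exclusions,
                        genotype_aware=True)
m = gb.metrics(comparison)
print(f"TP={comparison.tp_count} FP={comparison.fp_count} "
      f"FN={comparison.fn_count} TN={comparison.tn_count:,} bases "
      f"(excluded: {comparison.excluded_test_count} test, "
      f"{comparison.excluded_truth_count} truth)")
print(f"precision   TP/(TP+FP) = {100 * m.precision:.2f}%")
print(f"sensitivity TP/(TP+FN) = {100 * m.sensitivity:.2f}%")
print(f"specificity TN/(TN+FP) = {100 * m.specificity:.5f}%  "
      "(near-saturated: precision is the informative statistic)")

roc = gb.quality_roc(comparison)
print(f"quality ROC: {len(roc)} thresholds; e.g.")
for p in (roc.points[0], roc.points[len(roc) // 2], roc.points[-1]):
    print(f"  q>={p.threshold:>7.2f}  TPR={p.tpr:.3f}  FPR={p.fpr:.2e}")

print("precision by read depth (precision rises with depth, then plateaus):")
for s in gb.stratify_by_depth(comparison, [0, 10, 20, 30, 40, 1000]):
    label = f"[{s.lo},{s.hi})" if s.lo is not None else "unknown"
    prec = "n/a" if s.precision is None else f"{100 * s.precision:.2f}%"
    print(f"  depth {label:>10}: TP={s.tp:>4} FP={s.fp:>3} precision={prec}")
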