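import numpy as np
import pytest

import gcatbench as gb


@pytest.fixture(scope="session")
def small_ref():
    return gb.generate_reference(50_000, 0.45, seed=5)


@pytest.fixture(scope="session")
def small_genome(small_ref):
    return gb.mutate_diploid(small_ref, gb.MutationModel(), seed=9)


@pytest.fixture(scope="session")
def small_sim(small_genome):
    return gb.simulate_reads(small_genome, gb.LibraryModel(), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_truth_set(rng, ref, n, indel_prob=0.3, max_indel=8):
    """Random sorted, non-overlapping truth set over a Reference."""
    out = []
    pos0 = 0
    seq = ref.sequence
    while len(out) < n:
        pos0 += int(rng.integers(1, 40))
        if pos0 + max_indel + 1 >= ref.length:
            break
        anchor = seq[pos0]
        if rng.random() < indel_prob:
            ilen = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:
                ins = "".join(rng.choice(list("ACGT"), size=ilen))
                ref_a, alt_a = anchor, anchor + ins
            else:
                ref_a, alt_a = seq[pos0:pos0 + ilen + 1], anchor
        else:
            others = "ACGT".replace(anchor, "")
            ref_a, alt_a = anchor, others[int(rng.integers(0, 3))]
        genotype = gb.simkit.HET if rng.random() < 0.5 else gb.simkit.HOM_ALT
        hap = int(rng.integers(0, 2)) if genotype == gb.simkit.HET else None
        out.append(gb.TruthVariant(ref.name, pos0 + 1, ref_a, alt_a,
                                   genotype=genotype, haplotype=hap))
        pos0 += len(ref_a)
    return out
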