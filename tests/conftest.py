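import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from lucfam.seq import AlignedSet, GeneModel, NucSequence, classify_sites


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gene_model():
    # 30 columns: noncoding 1-6, exon 7-18 (4 codons), noncoding 19-30
    return GeneModel([(7, 18)], 0)


@pytest.fixture
def small_site_map(small_gene_model):
    return classify_sites(30, small_gene_model)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


@pytest.fixture
def random_alignment(rng):
    def make(n_seqs=5, length=60, mut=0.05):
        base = random_seq(rng, length)
        members = []
        for i in range(n_seqs):
            s = list(base)
            for c in range(length):
                if rng.random() < mut:
                    s[c] = "ACGT"[rng.integers(4)]
            members.append(NucSequence(f"s{i}", "".join(s)))
        return AlignedSet(members)

    return make
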