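import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ncranno import simulate as sim  # noqa: E402


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_seed():
    """A small hairpin seed alignment shared by model-level tests."""
    return sim.make_seed_family("toyfam", "snRNA", length=40, n_rows=8,
                                stem=6, seed=7)


@pytest.fixture(scope="session")
def family_setup():
    """Three realistic families, a 120 kb genome with planted copies and
    species-tagged queries; shared by pipeline-level tests."""
    lengths = {"snRNA": 100, "miRNA": 80, "snoRNA": 72}
    fams = []
    for i, rc in enumerate(["snRNA", "miRNA", "snoRNA"]):
        aln = sim.make_seed_family(f"fam{i + 1}", rc, length=lengths[rc],
                                   seed=10 + i)
        fams.append(sim.FamilySpec(aln, copies=6, target_identity=0.85,
                                   indel_rate=0.02, pseudogene_fraction=0.0))
    spec = sim.SyntheticSpec(genome_length=120_000, families=fams,
                             contaminant_contigs=3, seed=11)
    contigs, truth, cont = sim.build_genome(spec)
    queries = []
    for i, f in enumerate(fams):
        queries.extend(sim.make_queries(f.seed, seed=100 + i))
    return {"families": fams, "contigs": contigs, "truth": truth,
            "contaminants": cont, "queries": queries}
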