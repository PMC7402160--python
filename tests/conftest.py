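import numpy as np
import pytest

import combisort as cs
from combisort import ElementClass


def make_toy_parts(length: int = 10, seed: int = 7):
    """Five 10-bp parts, one per class, free of internal BsaI sites."""
    rng = np.random.default_rng(seed)

    def seq():
        while True:
            s = "".join(rng.choice(list("ACGT"), size=length))
            if not cs.has_internal_site(s):
                return s

    mk = lambda gene, cls: cs.RegulatoryPart(
        part_id=f"{gene}_{cls.value}", gene=gene, element_class=cls, sequence=seq()
    )
    return (
        mk("TDH3", ElementClass.ENHANCER),
        mk("TDH3", ElementClass.PROMOTER),
        mk("TDH3", ElementClass.UTR5),
        mk("mRuby2", ElementClass.REPORTER),
        mk("TDH3", ElementClass.UTR3),
    )


@pytest.fixture(scope="session")
def toy_parts():
    return make_toy_parts()


@pytest.fixture(scope="session")
def catalog():
    """The emulated 26-gene catalog with its structural exclusions."""
    return cs.default_catalog(seed=0)


@pytest.fixture(scope="session")
def gates():
    return cs.SortGates()


@pytest.fixture(scope="session")
def small_catalog():
    """Five genes, all parts usable: a 5x5x5x5-minus-nothing toy space."""
    return cs.default_catalog(
        seed=3,
        genes=("TDH3", "PGK1", "CYC1", "GAL1", "TEF1"),
        missing_promoters=(),
        bsai_blocked_enhancers=(),
    )


@pytest.fixture(scope="session")
def pipeline(catalog, gates):
    """One medium-scale synthetic Sort-seq run shared across tests."""
    truth = cs.draw_effects(catalog, seed=101)
    lib = cs.simulate_library(truth, 30_000, seed=102)
    pop = cs.simulate_sort(truth, lib, 50, gates=gates, seed=103)
    reads = cs.simulate_reads(pop, 300_000, dropout_rate=1 - 0.73**0.25, seed=104)
    counts, qc = cs.tally(
        reads, dict(zip(cs.BIN_LABELS, pop.cells_per_bin)), level="single_element"
    )
    return {
        "truth": truth,
        "library": lib,
        "population": pop,
        "reads": reads,
        "counts": counts,
        "qc": qc,
    }
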