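import numpy as np
import pytest

from ssrsurvey import CSSRPlan, PlantConfig, generate_genome


def random_sequence(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def small_planted():
    """A 100 kb two-contig genome with a mixed plant and a CDS track."""
    cfg = PlantConfig(
        genome_size=100_000,
        gc_content=0.58,
        seed=1234,
        genome_id="planted_small",
        n_contigs=2,
        ssr_plan=(("A", 7, 20), ("AC", 4, 15), ("AGC", 3, 12), ("ACGT", 3, 5),
                  ("AACGT", 3, 3), ("ACGAGC", 3, 3)),
        cssr_plan=(
            CSSRPlan(("A", "AC"), (6, 3), (5,), count=5),
            CSSRPlan(("AG", "AGC", "C"), (4, 3, 6), (2, 8), count=3),
        ),
        cds_fraction=0.8,
    )
    return cfg, generate_genome(cfg)
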