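import numpy as np
import pytest

from ervrip.simulate import (
    PlantSpec,
    choose_plant_positions,
    default_template,
    plant_insertions,
    random_genome,
)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def reference():
    return random_genome({"chr1": 60000}, seed=42)


@pytest.fixture(scope="session")
def planted_scenario(reference, template):
    """Five genomes, three carrying the element at two planted sites."""
    rng = np.random.default_rng(7)
    positions = choose_plant_positions(reference, "chr1", 2, rng)
    ids = [f"g{i}" for i in range(5)]
    specs = [
        PlantSpec(
            genome_id=g,
            chrom="chr1",
            position=p,
            tsd_len=6,
            ltr_divergence=0.0,
            seed=i * 10 + j,
        )
        for i, g in enumerate(ids[:3])
        for j, p in enumerate(positions)
    ]
    genomes, truth = plant_insertions(reference, specs, template, genome_ids=ids)
    return {
        "reference": reference,
        "genomes": genomes,
        "truth": truth,
        "positions": positions,
        "carrier_ids": ids[:3],
        "all_ids": ids,
    }
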