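import numpy as np
import pandas as pd
import pytest

from secretomapper.types import IntensityTable, Sample, SampleDesign


def make_design(groups=("astrocyte", "microglia", "neuron", "oligodendrocyte"),
                n_replicates=6):
    return SampleDesign(
        Sample(sample_id=f"{g}_{r}", group=g, replicate=r)
        for g in groups
        for r in range(1, n_replicates + 1)
    )


def make_table(values, design, protein_ids=None, scale="raw"):
    """IntensityTable from a 2-D array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i:03d}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"),
                        columns=design.sample_ids)
    return IntensityTable(data, design, scale=scale)


@pytest.fixture
def design_4x6():
    return make_design()


@pytest.fixture
def design_2x6():
    return make_design(groups=("control", "treated"))


@pytest.fixture(scope="session")
def sim_bundle():
    """One mid-sized simulation shared by read-only tests."""
    from secretomapper import synthetic_data as sim

    config = sim.SimConfig(n_proteins=400, seed=11)
    table, truth = sim.generate_secretome(config)
    annotations, sequences = sim.generate_annotations_topology(truth)
    return {"config": config, "table": table, "truth": truth,
            "annotations": annotations, "sequences": sequences}
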