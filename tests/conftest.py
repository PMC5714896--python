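import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polyqnet.datatypes import DonorExpression

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_donor(donor_id, probe_values: dict, structure="cortex", coords=None):
    """Build a DonorExpression from a {probe_id: values} dict."""
    first = next(iter(probe_values.values()))
    n = len(first)
    sample_ids = [f"{donor_id}_s{i}" for i in range(n)]
    if coords is None:
        coords = np.zeros((n, 3))
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": donor_id,
            "structure_label": structure,
            "mni_x": coords[:, 0],
            "mni_y": coords[:, 1],
            "mni_z": coords[:, 2],
        }
    )
    expr = pd.DataFrame(
        {s: [probe_values[p][i] for p in probe_values] for i, s in enumerate(sample_ids)},
        index=pd.Index(list(probe_values), name="probe_id"),
    )
    return DonorExpression(donor_id=donor_id, expression=expr, samples=samples)


@pytest.fixture
def donor_factory():
    return make_donor


@pytest.fixture(scope="session")
def small_planted():
    """A small planted dataset reused by several integration tests."""
    from polyqnet.synthetic import (
        BlockSpec,
        DEShiftSpec,
        RegionSpec,
        SyntheticSpec,
        generate_dataset,
        generate_genesets,
    )

    spec = SyntheticSpec(
        n_genes=250,
        regions=(
            RegionSpec("HD_region", (40, 40, 40, 40, 40, 40), in_mask=True),
            RegionSpec("striatum", (25, 25, 25, 25, 25, 25)),
            RegionSpec("rest_of_brain", (80, 80, 80, 80, 80, 80)),
        ),
        blocks=(
            BlockSpec("coexp_A", 25, 0.7, ("ATN1", "ATXN2", "HTT")),
            BlockSpec("coexp_B", 15, 0.6, ("ATXN1",)),
        ),
        de_shifts=(DEShiftSpec(15, 1.0, "up"), DEShiftSpec(30, 1.0, "down")),
    )
    dataset = generate_dataset(spec, seed=11)
    genesets = generate_genesets(dataset, seed=11)
    return spec, dataset, genesets
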