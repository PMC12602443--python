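import hypothesis
import numpy as np
import pandas as pd
import pytest

from ieireprog.io_formats import CountMatrix, SampleSheet
from ieireprog.synthetic_data import SimConfig, Spike, generate

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


def make_counts(values, genes=None, samples=None) -> CountMatrix:
    arr = np.asarray(values, dtype=np.int64)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=samples))


def make_sheet(conditions, organ="spleen") -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"s{j}" for j in range(len(conditions))],
                "condition": conditions,
                "organ": organ,
            }
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 2000-gene simulated dataset with a 60-gene panel and 12 spikes."""
    panel = tuple(f"Pnl{i:03d}" for i in range(60))
    spikes = tuple(
        Spike(panel[i], 4.0 if i % 2 == 0 else -4.0, -1.5 if i % 2 == 0 else 1.5)
        for i in range(12)
    )
    cfg = SimConfig(seed=7, n_genes=2000, panel_genes=panel, spike_table=spikes)
    cm, sheet, truth = generate(cfg)
    return cfg, cm, sheet, truth
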