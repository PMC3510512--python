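import numpy as np
import pandas as pd
import pytest

from apascreen import IntensityExperiment, PolyASite, SimConfig, simulate_dataset


def make_probes(starts, length=25, strand="+", chrom="chr17", probeset_id="PS_A"):
    """Probe alignment table with probes of one set at the given starts."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": list(starts),
            "end": [s + length for s in starts],
            "probe_id": [f"p{i:02d}" for i in range(len(starts))],
            "probeset_id": probeset_id,
            "strand": strand,
        }
    )


@pytest.fixture
def cdc6_like_probes():
    """Eleven tiled 25-mers; a site at 870 splits them 9 proximal / 2 distal."""
    return make_probes(range(0, 1100, 100))


@pytest.fixture
def cdc6_like_site():
    return PolyASite(
        site_id="PS_A@870", key="PS_A", chrom="chr17", strand="+", cleavage_pos=870
    )


def make_experiment(values: dict, sheet_rows: list[tuple]) -> IntensityExperiment:
    """Build an experiment from {probe_id: {array_id: value}} and
    (array_id, series_id, group) rows."""
    sheet = pd.DataFrame(
        sheet_rows, columns=["array_id", "series_id", "group"]
    ).set_index("array_id")
    return IntensityExperiment(
        values=pd.DataFrame(values).T, sample_sheet=sheet
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated dataset shared across tests."""
    cfg = SimConfig(seed=11)
    probes, sites, experiment, truth = simulate_dataset(cfg)
    return cfg, probes, sites, experiment, truth
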