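import numpy as np
import pandas as pd
import pytest

import regiontx as rx
from regiontx.synthetic import PlantedEffect, SimulationConfig, simulate_atlas


@pytest.fixture(scope="session")
def planted_atlas():
    """Default-scale atlas with 20 markers planted in region_00 (delta = 2)."""
    cfg = SimulationConfig(planted=(PlantedEffect("region_00", 20, 2.0),), seed=7)
    dataset, probes, samples, truth = simulate_atlas(cfg)
    return cfg, dataset, probes, samples, truth


@pytest.fixture(scope="session")
def planted_de(planted_atlas):
    """Full DE stage for the planted region of the shared atlas."""
    _, dataset, probes, samples, _ = planted_atlas
    return rx.region_differential_expression(dataset, probes, samples, "region_00")


@pytest.fixture(scope="session")
def all_region_rankings(planted_atlas):
    """Signed rankings for every region of the shared atlas."""
    _, dataset, probes, samples, _ = planted_atlas
    return {
        r: rx.region_differential_expression(dataset, probes, samples, r)["ranking"]
        for r in sorted(samples["region_name"].unique())
    }


@pytest.fixture()
def tiny_bundle(tmp_path):
    """A 3-probe, 4-sample bundle written to disk."""
    probes = pd.DataFrame(
        {"probe_id": ["p1", "p2", "p3"], "gene_symbol": ["GA", "GB", ""]}
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "donor_id": ["d1", "d1", "d2", "d2"],
            "region_name": ["R1", "R2", "R1", "R2"],
        }
    )
    values = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
        columns=samples["sample_id"].tolist(),
    )
    dataset = rx.ExpressionDataset(values)
    out = rx.write_atlas_bundle(tmp_path / "bundle", dataset, probes, samples)
    return out, dataset, probes, samples
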