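import numpy as np
import pandas as pd
import pytest

from springtail_metrics import AllometrySet, GeneratorConfig, generate_dataset
from springtail_metrics.allometry import Regression


@pytest.fixture(scope="session")
def default_dataset():
    """One medium synthetic dataset shared across read-only tests."""
    return generate_dataset(GeneratorConfig(n_sites=300, seed=42))


@pytest.fixture(scope="session")
def default_metrics(default_dataset):
    from springtail_metrics import compute_site_metrics

    ds = default_dataset
    m = compute_site_metrics(ds.samples, ds.sites, ds.traits)
    return m.merge(ds.sites[["site_id", "region"]], on="site_id")


@pytest.fixture
def simple_allometry():
    """One-regression-per-group set with easy hand-checkable coefficients."""
    return AllometrySet(
        regressions={
            "identity": [Regression(intercept=0.0, slope=3.0)],
            "pair": [
                Regression(intercept=np.log10(8.0), slope=2.0),
                Regression(intercept=np.log10(12.0), slope=2.0),
            ],
            "shifted": [
                Regression(
                    intercept=np.log10(2.0),
                    slope=2.5,
                    intercept_se=np.log10(2.5) - np.log10(2.0),
                )
            ],
        },
        dry_fresh={
            "identity": (10.0 / 3.0, 0.0),
            "pair": (10.0 / 3.0, 0.0),
            "shifted": (3.0, 0.2),
        },
    )


@pytest.fixture
def tiny_community():
    """Two samples, one site: hand-enumerable density and biomass."""
    samples = pd.DataFrame(
        {
            "site_id": ["s1"] * 3,
            "sample_id": ["a", "a", "b"],
            "taxon": ["Folsomia sp1", "Isotoma sp1", "Folsomia sp1"],
            "genus": ["Folsomia", "Isotoma", "Folsomia"],
            "abundance": [6, 4, 30],
            "sampling_area": [0.01, 0.01, 0.01],
        }
    )
    site = {"site_id": "s1", "soil_temperature": 10.0}
    traits = pd.DataFrame(
        {
            "genus": ["Folsomia", "Isotoma"],
            "body_length_mm": [1.0, 2.0],
            "morphogroup": ["identity", "identity"],
        }
    )
    return samples, site, traits
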