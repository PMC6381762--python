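import numpy as np
import pytest

from blockcoal.models import DemographyModel, panmictic
from blockcoal.simulate import SimConfig, simulate_genotype_fixture


@pytest.fixture(scope="session")
def pan_model():
    return panmictic()


@pytest.fixture(scope="session")
def div_model():
    """Strict divergence, single size class."""
    return DemographyModel("M1.1", t_split=1.0)


@pytest.fixture(scope="session")
def im_model():
    """Two-size-class IM with forward gene flow B -> V (the best-model class)."""
    return DemographyModel(
        "M3.3", flow="im", donor="B", deviating="B", t_split=1.0, c_x=0.4, m=0.5
    )


@pytest.fixture(scope="session")
def adm_model():
    return DemographyModel(
        "M5.3", flow="adm", donor="B", deviating="B",
        t_split=1.0, c_x=0.5, f=0.3, t_adm=0.4,
    )


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory, im_model):
    """A 400-block on-disk VCF/BED/FASTA fixture plus its true spectra."""
    from blockcoal.simulate import simulate_spectrum_counts

    d = tmp_path_factory.mktemp("fixture")
    cfg = SimConfig(model=im_model, theta_block=0.6, n_blocks=400, seed=42)
    summary = simulate_genotype_fixture(
        cfg, d / "f.vcf", d / "f.bed", d / "f.fasta"
    )
    return {
        "dir": d,
        "cfg": cfg,
        "summary": summary,
        "counts": simulate_spectrum_counts(cfg),
    }
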