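import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from transprs.io import DosagePanel
from transprs.simulate import SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation used across integration tests."""
    return SimulationConfig(n_variants=1_200, block_size=40,
                            n_discovery=400, n_cases=40, n_relatives=16,
                            n_controls=50, prevalence=0.1, seed=11)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    from transprs.simulate import generate_fixture_set
    outdir = tmp_path_factory.mktemp("fixtures")
    generate_fixture_set(small_config, outdir)
    return outdir


def toy_panel(dosages, chrom=None, pos=None, ref=None, alt=None, info=None,
              ids=None):
    """Hand-built DosagePanel from a samples x variants array."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    meta = pd.DataFrame({
        "variant_id": ids or [f"v{j}" for j in range(m)],
        "chromosome": chrom or ["1"] * m,
        "position": pos or list(range(100, 100 + m)),
        "ref": ref or ["A"] * m,
        "alt": alt or ["G"] * m,
        "info": info if info is not None else [1.0] * m,
    })
    return DosagePanel(meta, [f"s{i}" for i in range(n)], d)
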