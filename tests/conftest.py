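import numpy as np
import pytest

import ionsolv as iv


@pytest.fixture(scope="session")
def thermo():
    return iv.ThermoState(300.0)


@pytest.fixture(scope="session")
def harmonic_124(thermo):
    """Three-state harmonic ladder k = (1, 2, 4) with 50k samples/state."""
    spec = iv.HarmonicAlchemySpec(k=(1.0, 2.0, 4.0), n_samples=50_000, seed=11)
    matrix, analytic = iv.gen_harmonic_alchemy(spec, thermo)
    return matrix, analytic


@pytest.fixture(scope="session")
def enriched_profile():
    """Water-enriched inner shell (0.9 inside 1 nm) over a 0.5 bulk."""
    return iv.EnrichmentProfile(edges=(0.0, 1.0), x_w=(0.9,), x_w_bulk=0.5)


@pytest.fixture(scope="session")
def enriched_frames(enriched_profile):
    from ionsolv.synthetic import consistent_counts

    n_w, n_c = consistent_counts(enriched_profile, box=5.0, n_total=700)
    frames = iv.gen_mixture_trajectory(
        enriched_profile, n_w, n_c, box=5.0, n_frames=500, seed=21
    )
    return frames, n_w, n_c
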