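import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full synthetic study at default conditions, shared by the
    end-to-end tests (simulate -> FASTQ -> preprocess -> map -> classify)."""
    from pongclass import SimConfig, run_synthetic
    workdir = tmp_path_factory.mktemp("default_run")
    return run_synthetic(SimConfig(), workdir)


@pytest.fixture()
def tiny_panel():
    """Two short TEs with a planted plus/minus ping-pong pair on te_a."""
    import numpy as np
    from pongclass import TESequence
    rng = np.random.default_rng(42)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs = [bases[rng.integers(0, 4, 200)].tobytes().decode()
            for _ in range(2)]
    return [TESequence("te_a", seqs[0]), TESequence("te_b", seqs[1])]
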