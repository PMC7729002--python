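import dataclasses

import pytest

from homeosplice.pipeline import RunConfig, run_pipeline
from homeosplice.simulate import SimConfig, simulate_all, simulate_triads

# Standard recovery-study conditions: five triads (one per subfamily),
# mean FLNC depth 30, perfect alignment identity, low count dispersion
# (inside the regime where exact recovery of planted truth is expected).
RECOVERY_SIM = SimConfig(
    seed=42, n_triads=5, read_depth=30.0, read_identity=1.0, nb_dispersion=0.01
)


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory):
    """Full pipeline run on the standard recovery simulation, plus the
    matching in-memory simulation for truth comparisons."""
    outdir = tmp_path_factory.mktemp("recovery_run")
    cfg = RunConfig(outdir=outdir, seed=42, simulate=RECOVERY_SIM, dispersion=0.01)
    manifest = run_pipeline(cfg)
    sim = simulate_triads(RECOVERY_SIM)
    return sim, outdir, manifest


@pytest.fixture(scope="session")
def small_sim():
    """A two-triad simulation bundle (sim, reads, counts, design, support)."""
    cfg = dataclasses.replace(RECOVERY_SIM, n_triads=2, seed=11)
    return simulate_all(cfg)


@pytest.fixture(scope="session")
def aa_triad():
    from homeosplice.datasets import load_aa_triad

    return load_aa_triad()
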