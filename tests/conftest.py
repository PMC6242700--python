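import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from resmut.kstar import KStarRecord
from resmut.signatures import CLASS_LABELS, PSPMTable

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_record(
    ligand: str,
    role: str,
    run: str,
    score: float,
    pos: int = 0,
    wt: str = "X",
    mut: str = "WT",
    tag: str = "",
    target: str = "T1",
) -> KStarRecord:
    return KStarRecord(target, ligand, role, run, pos, wt, mut, tag, score)


@pytest.fixture
def uniform_pspm() -> PSPMTable:
    """pSPM table with every one of the 96 classes at probability 1/96."""
    return PSPMTable("uniform", pd.Series(1.0 / 96, index=list(CLASS_LABELS)))


@pytest.fixture
def random_pspm() -> PSPMTable:
    """A seeded non-uniform pSPM table (all classes strictly positive)."""
    rng = np.random.default_rng(42)
    values = rng.dirichlet(np.ones(96) * 2)
    return PSPMTable("random", pd.Series(values, index=list(CLASS_LABELS)))


@pytest.fixture
def fixture_bundle(tmp_path):
    """A written synthetic input bundle (seed 7) plus its truth."""
    from resmut.simulate import FixtureSpec, generate_fixture

    fx = generate_fixture(FixtureSpec(seed=7))
    outdir = tmp_path / "bundle"
    fx.write(outdir)
    return outdir, fx
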