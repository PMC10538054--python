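import numpy as np
import pytest

import maldilip as m


@pytest.fixture(scope="session")
def db():
    return m.load_default_db()


@pytest.fixture(scope="session")
def tissue_panel(db):
    return m.panel_from_db(db, +1, tier="tissue_specific", seed=1)


@pytest.fixture(scope="session")
def small_cohort(tissue_panel):
    """3+3 biological samples x 3 technical replicates, with drift."""
    design = m.SimulationDesign(groups=(("A", 3), ("B", 3)), replicates=3,
                                drift_ppm=100, seed=3)
    spectra, meta, truth = m.simulate_cohort(tissue_panel, design)
    return spectra, meta, truth


@pytest.fixture(scope="session")
def small_profiling(small_cohort, db):
    from maldilip.pipeline import run_profiling

    spectra, meta, _ = small_cohort
    return run_profiling(spectra, meta, db=db)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
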