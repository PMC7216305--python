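import pytest

from phasetps.pipeline import run_pipeline
from phasetps.synthetic_data import make_reference_panel

#: compact per-seed design used by robustness screens and shared fixtures
TINY_DESIGN = dict(n_fl_pairs=2, n_tandem_groups=1, n_fl_hemi=2,
                   n_dorf_pairs=1, n_dorf_hemi=1, n_partial=3)


@pytest.fixture(scope="session")
def panel2():
    """Two templates per subfamily (10 total)."""
    return make_reference_panel(2, seed=11)


@pytest.fixture(scope="session")
def panel4():
    """Four templates per subfamily — covers every TPS-a mechanism class."""
    return make_reference_panel(4, seed=7)


@pytest.fixture(scope="session")
def tiny_run():
    """One full noiseless pipeline run on a compact single-cultivar design."""
    return run_pipeline(seed=42, cultivars=("S1",), design_kwargs=TINY_DESIGN)
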