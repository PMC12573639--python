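import warnings

import numpy as np
import pytest

from ramanod import CohortDesign, simulate_cohort

# MCR-ALS routinely hits max_iter on low-noise denoised matrices while the
# residual keeps creeping; the non-convergence warning is expected there.
warnings.filterwarnings("ignore", message="MCR-ALS did not converge")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for fast structural tests (54 cells, full design axes)."""
    design = CohortDesign(nodules_per_phase=3, cells_per_nodule=(5, 7), seed=11)
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def small_cohort():
    """~200-cell cohort at the default noise level for recovery tests."""
    design = CohortDesign(nodules_per_phase=3, cells_per_nodule=(22, 23), seed=0)
    return simulate_cohort(design)
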