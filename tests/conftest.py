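import numpy as np
import pytest

from honeyscreen.cohort import (
    IDENTITY_DEVICE,
    ci_small_design,
    make_library,
    render_run,
)


@pytest.fixture(scope="session")
def small_design():
    return ci_small_design(seed=7)


@pytest.fixture(scope="session")
def small_library(small_design):
    return make_library(small_design)


@pytest.fixture(scope="session")
def noiseless_run(small_design, small_library):
    """One honey rendered with every stochastic contribution disabled."""
    profile = small_library.honey_profiles["H01"]
    return render_run(
        profile, "HILIC_neg", IDENTITY_DEVICE, small_design, small_library, noise=False
    )


def gaussian_roi(apex_rt=100.0, sd=3.0, apex=1e6, mz=300.0, span=30, interval=1.0):
    """A synthetic noiseless Gaussian elution trace as an ROI."""
    from honeyscreen.peaks import Roi

    rt = np.arange(apex_rt - span, apex_rt + span + interval, interval)
    inten = apex * np.exp(-((rt - apex_rt) ** 2) / (2 * sd**2))
    keep = inten >= 1.0
    return Roi(mz_center=mz, rt=rt[keep], mz=np.full(keep.sum(), mz), intensity=inten[keep])
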