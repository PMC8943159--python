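import numpy as np
import pytest

from lcpipe.basis import build_basis
from lcpipe.simulate import (GroundTruth, NoiseSpec, default_roi_masks,
                             make_task_design, simulate_bold_run)


@pytest.fixture(scope="session")
def designs():
    """The default six-run 245-s block paradigm on a TR = 2 s grid."""
    return make_task_design()


@pytest.fixture(scope="session")
def basis_default():
    """An order-2 basis with 24-s memory at TR = 2 s."""
    return build_basis(2, 12, alpha=1.0, tau=1.0, dt=2.0)


@pytest.fixture(scope="session")
def span_truth(basis_default):
    """Ground-truth HRF lying exactly in the default basis span."""
    coef = np.array([0.5, -0.2])
    return basis_default.B @ coef, coef


@pytest.fixture()
def quiet_noise():
    return NoiseSpec(white_sd=0.0, ar1=0.0, drift_slope=0.0,
                     physio_amps=(0.0,))


@pytest.fixture(scope="session")
def masks():
    return default_roi_masks()


def noiseless_runs(designs, h_nov, h_rep, beta_nov=1.0, beta_rep=0.5):
    gt = GroundTruth(hrf_nov=h_nov, hrf_rep=h_rep, beta_nov=beta_nov,
                     beta_rep=beta_rep,
                     noise=NoiseSpec(white_sd=0.0, ar1=0.0, drift_slope=0.0,
                                     physio_amps=(0.0,)))
    out = [simulate_bold_run(d, gt, seed=d.run_index) for d in designs]
    return [o[0] for o in out], out[0][2]
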