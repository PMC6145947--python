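import numpy as np
import pytest

from adaptdecorr import encoding_sim as enc
from adaptdecorr import shape_space as ss


@pytest.fixture(scope="session")
def prototypes():
    return ss.default_prototypes()


@pytest.fixture(scope="session")
def small_grid():
    return enc.VoxelGrid(shape=(6, 6, 6))


@pytest.fixture(scope="session")
def stimulus_set():
    return enc.make_stimulus_set(seed=0)


@pytest.fixture(scope="session")
def graded_cohort(small_grid, stimulus_set):
    """Default-mechanism cohort: 10 subjects x 8 runs on a 6^3 grid."""
    return enc.simulate_beta_cohort(
        n_subjects=10, n_runs=8, grid=small_grid, master_seed=11, stimuli=stimulus_set
    )


@pytest.fixture(scope="session")
def uniform_noiseless_cohort(small_grid, stimulus_set):
    """Uniform-gain adaptation with zero measurement noise (3 subjects)."""
    return enc.simulate_beta_cohort(
        n_subjects=3,
        n_runs=4,
        grid=small_grid,
        mode=enc.AdaptationMode("uniform_gain", 0.18),
        noise_sd=0.0,
        master_seed=5,
        stimuli=stimulus_set,
    )


def roi_delta_r(betas, localizers, k=100):
    """Per-subject whole-pipeline delta_r using each subject's top-k ROI."""
    from adaptdecorr import pattern_analysis as pa

    out = []
    parcel = np.ones(betas.n_voxels, dtype=bool)
    for s in range(betas.n_subjects):
        roi = pa.select_roi(localizers[s], parcel, k=min(k, betas.n_voxels))
        sub = enc.BetaPatterns(
            values=betas.values[s : s + 1],
            run_adaptor=betas.run_adaptor[s : s + 1],
            noise_sd=betas.noise_sd,
        )
        out.append(pa.decorrelation(sub, roi).per_subject["delta_r"].iloc[0])
    return np.asarray(out)
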