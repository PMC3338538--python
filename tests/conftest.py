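"""Shared synthetic-session builders and fixtures."""

import numpy as np
import pytest

import mazemvpa as mz
from mazemvpa.synthdata import AcquisitionParams, NoiseParams, required_scans


def build_exploration_samples(
    seed,
    effect=1.0,
    n_voxels=300,
    n_informative=20,
    n_repetitions=2,
    noise=None,
    isi=0.0,
    confound_regression=True,
):
    """Simulate a paced exploration session and extract event samples."""
    ev = mz.make_exploration_design(n_repetitions=n_repetitions, isi=isi, seed=seed)
    params = AcquisitionParams(
        tr=2.04, n_scans=required_scans(ev, 2.04), n_voxels=n_voxels
    )
    pat = mz.make_activation_patterns(
        n_voxels, n_informative, effect, 0.0, seed=seed + 1000
    )
    sim = mz.simulate_bold(ev, pat, params, noise=noise, seed=seed + 2000)
    if confound_regression:
        series = mz.regress_confounds(sim.data, sim.motion, params.tr)
    else:
        series = sim.data - 100.0
    samples = mz.extract_exploration_samples(series, ev, params.tr)
    return samples, ev, pat, sim


def build_imagery_samples(
    seed, effect=0.04, n_voxels=300, n_informative=20, n_tests=54, recall_prob=None
):
    """Simulate a self-paced imagery session and extract event samples."""
    kwargs = {} if recall_prob is None else {"recall_prob": recall_prob}
    ev = mz.make_imagery_design(n_tests=n_tests, seed=seed, **kwargs)
    params = AcquisitionParams(
        tr=2.04, n_scans=required_scans(ev, 2.04), n_voxels=n_voxels
    )
    pat = mz.make_activation_patterns(
        n_voxels, n_informative, effect, 0.0, seed=seed + 1000
    )
    sim = mz.simulate_bold(ev, pat, params, seed=seed + 2000)
    series = mz.regress_confounds(sim.data, sim.motion, params.tr)
    samples = mz.extract_imagery_samples(series, ev, params.tr)
    return samples, ev, pat, sim


def build_separable_samples(seed=7, n_voxels=150, n_informative=12, effect=2.0):
    """Noise-free slow-event session: classes exactly linearly separable."""
    silent = NoiseParams(white_sd=0.0, ar1_coef=0.0, drift_amp=0.0, motion_amp=0.0)
    samples, *_ = build_exploration_samples(
        seed,
        effect=effect,
        n_voxels=n_voxels,
        n_informative=n_informative,
        noise=silent,
        isi=9.0,
        confound_regression=False,
    )
    return samples


@pytest.fixture(scope="session")
def separable_samples():
    return build_separable_samples()


@pytest.fixture(scope="session")
def small_exploration():
    samples, ev, pat, sim = build_exploration_samples(3, effect=1.0)
    return {"samples": samples, "events": ev, "patterns": pat, "sim": sim}
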