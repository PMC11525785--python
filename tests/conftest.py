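import numpy as np
import pandas as pd
import pytest

from salnet.simulate import (LeadField, SimulationConfig,
                             default_coupling_spec, make_leadfield)


@pytest.fixture(scope="session")
def spherical_leadfield() -> LeadField:
    """Coarse spherical-head lead field shared across tests."""
    return make_leadfield(grid_spacing_mm=20.0)


@pytest.fixture()
def random_leadfield() -> LeadField:
    return make_leadfield(mode="random", n_voxels_random=40, seed=3)


@pytest.fixture()
def tiny_sim_config() -> SimulationConfig:
    """A desk-scale cohort: short recordings, few trials, tiny groups."""
    return SimulationConfig(
        n_subjects_per_group={"nrMDD": 3, "rMDD": 3, "HC": 2},
        resting_duration=10.0,
        n_oddball_trials=80,
        seed=7,
    )


def uniform_coupling_spec(kappa: float, lag_l: float = np.pi / 4,
                          lag_r: float = -np.pi / 4) -> dict:
    """Same coupling everywhere: isolates κ as the single dial."""
    spec = {}
    for group in ("nrMDD", "rMDD", "HC"):
        for cond in ("RS", "Std", "Dev"):
            for band in ("alpha", "low_beta", "high_beta", "gamma"):
                spec[(group, cond, band, ("dACC", "lIns"))] = (kappa, lag_l)
                spec[(group, cond, band, ("dACC", "rIns"))] = (kappa, lag_r)
    return spec


def quadrature_amplitude(y: np.ndarray, f_hz: float, fs: float) -> float:
    """Amplitude of the f_hz component by least-squares quadrature fit.

    Exact for a pure sinusoid of any phase regardless of window length, and
    insensitive to low-frequency filter transients, unlike a peak-to-peak
    measure.
    """
    t = np.arange(len(y)) / fs
    design = np.column_stack([np.sin(2 * np.pi * f_hz * t),
                              np.cos(2 * np.pi * f_hz * t)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(np.hypot(*coef))


def separable_feature_table(n1: int = 14, n2: int = 17, n_noise: int = 18,
                            seed: int = 0) -> pd.DataFrame:
    """Two well-separated Gaussian clusters plus pure-noise features."""
    rng = np.random.default_rng(seed)
    informative = np.vstack([rng.normal(3.0, 0.2, (n1, 5)),
                             rng.normal(0.0, 0.2, (n2, 5))])
    noise = rng.standard_normal((n1 + n2, n_noise))
    cols = [f"inf{i}" for i in range(5)] + [f"noise{i}" for i in range(n_noise)]
    df = pd.DataFrame(np.hstack([informative, noise]), columns=cols,
                      index=[f"s{i:02d}" for i in range(n1 + n2)])
    df["group"] = ["nrMDD"] * n1 + ["rMDD"] * n2
    return df


def null_feature_table(n1: int = 14, n2: int = 17, n_features: int = 23,
                       seed: int = 0) -> pd.DataFrame:
    """Features carrying no class information at all."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.standard_normal((n1 + n2, n_features)),
                      columns=[f"f{i}" for i in range(n_features)],
                      index=[f"s{i:02d}" for i in range(n1 + n2)])
    df["group"] = ["nrMDD"] * n1 + ["rMDD"] * n2
    return df
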