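import numpy as np
import pandas as pd
import pytest

from whitepox import ColonyRecord, Hyperparameters, ScenarioConfig, SurveyPanel


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_colonies():
    return [
        ColonyRecord("A", 0.0, 0.0, 1000.0),
        ColonyRecord("B", 3.0, 4.0, 2000.0),
        ColonyRecord("C", 10.0, 0.0, 500.0),
    ]


def make_panel(
    presence: np.ndarray,
    colonies=None,
    temperature=None,
    insolation=None,
    rng=None,
) -> SurveyPanel:
    """Small hand-assembled panel around a given presence matrix."""
    presence = np.asarray(presence, dtype=float)
    n, T = presence.shape
    if colonies is None:
        r = rng or np.random.default_rng(0)
        xy = r.uniform(0, 100, (n, 2))
        colonies = [
            ColonyRecord(f"c{i}", float(xy[i, 0]), float(xy[i, 1]), float(100 + 50 * i))
            for i in range(n)
        ]
    occasions = pd.date_range("2003-02-01", periods=T, freq="MS")
    t = np.arange(T)
    if temperature is None:
        temperature = 28.0 + 1.5 * np.cos(2 * np.pi * (t - 7) / 12)
    if insolation is None:
        insolation = 5.5 + 1.3 * np.cos(2 * np.pi * (t - 4) / 12)
    return SurveyPanel(
        colonies=colonies,
        occasions=occasions,
        presence=presence,
        temperature=np.asarray(temperature, dtype=float),
        insolation=np.asarray(insolation, dtype=float),
    )


@pytest.fixture
def small_panel(rng):
    presence = (rng.uniform(size=(6, 10)) < 0.3).astype(float)
    presence[2, 4] = np.nan
    return make_panel(presence, rng=rng)


@pytest.fixture
def small_scenario():
    """A reduced study-like scenario that fits in unit-test time."""
    return ScenarioConfig(
        n_colonies=20,
        n_occasions=24,
        hyper_true=Hyperparameters(
            spatial_range=150.0, sigma_xi=0.8, ar_coef=0.7, sigma_eps=0.2
        ),
        calibration_passes=6,
    )
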