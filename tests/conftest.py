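import dataclasses

import numpy as np
import pytest

import equivnoise as en
from equivnoise.observer import ConditionSimulator
from equivnoise.stimulus import Condition, SceneModels


@pytest.fixture(scope="session")
def surrogate_ensemble():
    """The default 632-spectrum surrogate reflectance ensemble."""
    return en.make_surrogate_dataset(en.SurrogateDatasetSpec(seed=1))


@pytest.fixture(scope="session")
def pca_model(surrogate_ensemble):
    model, _ = en.fit_reflectance_pca(surrogate_ensemble, n_components=6)
    return model


@pytest.fixture(scope="session")
def scene_models(pca_model):
    return SceneModels(pca_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_calibrated_observer(scene_models, condition: Condition,
                             surround: float, intrinsic_sd: float,
                             rng, n_calibration: int = 1000):
    """Observer with LRF-unit calibration under the given condition."""
    sim = ConditionSimulator(scene_models, condition)
    obs = en.LINRFObserver(en.ReceptiveField(sim.mask, surround), 0.0)
    obs = en.calibrate_rf_units(obs, sim, n_scenes=n_calibration, rng=rng)
    return dataclasses.replace(obs, intrinsic_sd=intrinsic_sd), sim


@pytest.fixture(scope="session")
def observer_factory(scene_models):
    def _make(condition=Condition(0.0, 0.0), surround=-0.05,
              intrinsic_sd=0.02, seed=7, n_calibration=1000):
        rng = np.random.default_rng(seed)
        return make_calibrated_observer(scene_models, condition, surround,
                                        intrinsic_sd, rng, n_calibration)
    return _make
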