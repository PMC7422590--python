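"""Shared fixtures: synthetic datasets at the standard study conditions."""

import numpy as np
import pytest

from egpest.data import DiurnalDataset, MealSegment
from egpest.model import LiverEGPModel, LiverParams
from egpest.simulate import GeneratorConfig, generate_dataset

#: a truth vector in the interior of the estimation box, used where the
#: dataset must identify all four parameters (A != 1 so breakfast matters)
RICH_THETA = (0.004, 0.008, 0.04, 1.1)


@pytest.fixture(scope="session")
def consistency_synth():
    """Noise-free consistency-mode dataset: the meal-invariance assumption
    holds exactly at the generating truth."""
    return generate_dataset(GeneratorConfig(consistency_mode=True, seed=11))


@pytest.fixture(scope="session")
def rich_synth():
    """Noise-free dataset with independent regressor deviations; all four
    parameters are identifiable from its EGP curves."""
    return generate_dataset(GeneratorConfig(theta=RICH_THETA, seed=7))


@pytest.fixture(scope="session")
def rich_model(rich_synth):
    return LiverEGPModel(rich_synth.dataset)


@pytest.fixture(scope="session")
def consistency_model(consistency_synth):
    return LiverEGPModel(consistency_synth.dataset)


@pytest.fixture(scope="session")
def constant_insulin_dataset():
    """Dataset whose insulin is flat in every segment, so the delayed-insulin
    deviation is identically zero and kp3 drops out of the EGP misfit."""
    base = generate_dataset(GeneratorConfig(theta=RICH_THETA, seed=19))
    t = base.dataset["breakfast"].times
    segments = [
        MealSegment(lab, t, base.dataset[lab].glucose,
                    np.full_like(t, 40.0), base.dataset[lab].isr, None)
        for lab in ("breakfast", "lunch", "dinner")
    ]
    interim = DiurnalDataset(tuple(segments),
                             {"breakfast": 2.0, "lunch": 1.9, "dinner": 1.8})
    model = LiverEGPModel(interim)
    egp = model.predict_egp(LiverParams.from_array(RICH_THETA))
    with_egp = [
        MealSegment(lab, t, interim[lab].glucose, interim[lab].insulin,
                    interim[lab].isr, egp[lab])
        for lab in ("breakfast", "lunch", "dinner")
    ]
    return DiurnalDataset.from_segments(with_egp)
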