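import numpy as np
import pytest

from popstate.data_model import SpikeSession, SpikeTrain, TrialEpochs
from popstate.synthetic import GeneratorConfig, UnitSpec, generate_session


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trials(n_per_condition=12, fix_dur=800.0, cue_dur=1600.0, gap=500.0):
    trials = []
    cursor = gap
    for i in range(2 * n_per_condition):
        condition = "attend_RF" if i % 2 == 0 else "attend_away"
        fixation = cursor
        cue = fixation + fix_dur
        dimming = cue + cue_dur
        trials.append(
            TrialEpochs(
                trial_id=f"tr{i:03d}",
                fixation_onset_ms=fixation,
                cue_onset_ms=cue,
                first_dimming_ms=dimming,
                condition=condition,
            )
        )
        cursor = dimming + gap
    return tuple(trials)


def make_session(rng=None, n_channels=4, n_per_condition=12, unit_rate_hz=20.0):
    """Small hand-rolled session: Poisson MUA plus one single unit."""
    if rng is None:
        rng = np.random.default_rng(0)
    trials = make_trials(n_per_condition)
    t_max = trials[-1].first_dimming_ms + 500.0
    trains = []
    for j in range(n_channels):
        n = rng.poisson(50.0 * t_max / 1000.0)
        trains.append(
            SpikeTrain(
                unit_id=f"mua{j:02d}",
                channel_index=j,
                kind="multi_unit",
                spike_times=np.sort(rng.uniform(0, t_max, n)),
            )
        )
    n = rng.poisson(unit_rate_hz * t_max / 1000.0)
    trains.append(
        SpikeTrain(
            unit_id="su00",
            channel_index=1,
            kind="single_unit",
            spike_times=np.sort(rng.uniform(0, t_max, n)),
        )
    )
    return SpikeSession(
        session_id="toy",
        monkey_profile="M1",
        spike_trains=tuple(trains),
        trials=trials,
        area_labels=tuple("V1" if j < n_channels // 2 else "V4" for j in range(n_channels)),
    )


@pytest.fixture()
def toy_session(rng):
    return make_session(rng)


@pytest.fixture()
def synthetic_session():
    """Structured two-state session with units on the soloist-chorister axis."""
    units = [
        UnitSpec(channel_index=0, base_rate_hz=15.0, rho=1.0, gain=0.2),
        UnitSpec(channel_index=2, base_rate_hz=15.0, rho=4.0, gain=0.2),
        UnitSpec(channel_index=4, base_rate_hz=15.0, rho=8.0, gain=0.2),
    ]
    config = GeneratorConfig(
        n_channels=8,
        n_trials=(12, 12),
        units=units,
        p_stay_off=0.9,
        p_stay_on={"attend_away": 0.9, "attend_RF": 0.97},
        seed=2024,
    )
    session, truth = generate_session(config)
    return session, truth, config
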