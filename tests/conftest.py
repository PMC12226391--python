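import numpy as np
import pandas as pd
import pytest

from ided_theta.data import Epochs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def make_epochs(data, fs=500.0, tmin=-1.25, conditions=None):
    """Helper: wrap an (n_ep, n_ch, n_t) array into Epochs."""
    n_ep, n_ch, n_t = data.shape
    times = np.arange(n_t) / fs + tmin
    info = pd.DataFrame({
        "trial": range(n_ep),
        "condition": conditions or ["ID"] * n_ep,
    })
    return Epochs(data=data.astype(np.float32), times=times, fs=fs,
                  ch_names=tuple(f"ch{i}" for i in range(n_ch)), info=info)


@pytest.fixture(scope="session")
def mini_young_subject():
    """One simulated young participant, processed through the full chain.

    Session-scoped: several tests reuse the (expensive) simulation.
    """
    from ided_theta import preprocess as pp
    from ided_theta import synth_eeg as se
    from ided_theta import tfr
    from ided_theta.data import MIDFRONTAL_ELECTRODES, MONTAGE_16
    from ided_theta.taskgen import generate_sequence

    profile = se.young_profile(seed=424)
    calibration = se.calibrate_profile(profile, montage=MONTAGE_16)
    sequence = generate_sequence(seed=31)
    rec, behaviour = se.simulate_subject(profile, sequence, fs=1000.0,
                                         montage=MONTAGE_16,
                                         calibration=calibration)
    epochs, report = pp.preprocess_recording(
        rec, behaviour, analysis_channels=MIDFRONTAL_ELECTRODES)
    t = tfr.morlet_power(epochs, freqs=np.arange(3.0, 10.0))
    return {
        "profile": profile,
        "calibration": calibration,
        "sequence": sequence,
        "recording": rec,
        "behaviour": behaviour,
        "epochs": epochs,
        "report": report,
        "tfr": t,
    }
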