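import numpy as np
import pytest

from squatcrf import SquatSignalParams, simulate_squat_signal, synthetic_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """Constructed synthetic subject table with the published models built in."""
    return synthetic_reference_cohort(seed=0)


@pytest.fixture()
def clean_signal():
    """Noiseless, decay-free, drift-free squat recording at 20 Hz."""
    return simulate_squat_signal(
        SquatSignalParams(amplitude_decay=0.0, tempo_drift=0.0, noise_sd=0.0, seed=0)
    )


def xcorr_bruteforce(fp, sp):
    """Independent double-loop cross-correlation oracle: R[n] = Σ_m fp[m]·sp[n+m].

    Indices outside the windows contribute zero.  Deliberately written as an
    explicit double loop; tests compare the fast implementation against it.
    """
    fp = np.asarray(fp, dtype=float)
    sp = np.asarray(sp, dtype=float)
    L = len(fp)
    lags = list(range(-(L - 1), L))
    values = []
    for n in lags:
        acc = 0.0
        for m in range(L):
            j = n + m
            if 0 <= j < L:
                acc += fp[m] * sp[j]
        values.append(acc)
    return np.array(lags), np.array(values)
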