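import numpy as np
import pytest

from sleeptf.stages import TARGET_FS


@pytest.fixture(scope="session")
def fs() -> float:
    return float(TARGET_FS)


@pytest.fixture(scope="session")
def epoch_t(fs) -> np.ndarray:
    """Time axis of one 30-s epoch at 256 Hz."""
    return np.arange(7680) / fs


def tone(t: np.ndarray, f0: float, amp: float = 1.0, phase: float = 0.0) -> np.ndarray:
    return amp * np.sin(2 * np.pi * f0 * t + phase)


@pytest.fixture(scope="session")
def small_recording():
    """A 60-epoch synthetic recording (all five stages present) shared by
    I/O and pipeline tests."""
    from sleeptf.synthdata import (
        DEFAULT_TARGET_PROPORTIONS,
        HypnogramSpec,
        synth_recording,
    )

    return synth_recording(
        HypnogramSpec(n_epochs=60, seed=13, target_proportions=DEFAULT_TARGET_PROPORTIONS)
    )
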