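"""The five-stage AASM sleep taxonomy and its fixed integer encoding."""

from __future__ import annotations

import enum


class Stage(enum.IntEnum):
    """AASM sleep stages with the package-wide integer encoding.

    The encoding (W=0, N1=1, N2=2, N3=3, REM=4) is stable everywhere:
    hypnograms, label files, confusion matrices and network outputs all use
    the same order.
    """

    W = 0
    N1 = 1
    N2 = 2
    N3 = 3
    REM = 4

    @classmethod
    def from_string(cls, s: str) -> "Stage":
        key = s.strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown sleep stage {s!r}; expected one of {STAGE_NAMES}") from None


STAGE_NAMES: tuple[str, ...] = tuple(s.name for s in Stage)
N_STAGES: int = len(Stage)

# Epoch geometry: AASM scores 30-s epochs; at the common 256 Hz rate each
# epoch is a vector of 7680 samples.
EPOCH_SECONDS: int = 30
TARGET_FS: int = 256
EPOCH_SAMPLES: int = EPOCH_SECONDS * TARGET_FS  # 7680
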