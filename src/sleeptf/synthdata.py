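"""Synthetic polysomnography: hypnograms and stage-conditional EEG.

Clinical sleep EEG is access-restricted, so this module generates surrogate
recordings with the statistical structure the staging pipeline assumes:

* a first-order Markov hypnogram over 30-s epochs that starts in Wake,
  meanders through N1/N2/N3 into REM in cycles of roughly 90-120 min, and
  reproduces a configurable (imbalanced) marginal stage distribution;
* stage-conditional waveforms whose dominant rhythms follow the textbook
  AASM signatures -- occipital alpha (8-12 Hz) in W, theta (4-7 Hz) in N1,
  theta with sleep spindles (11-16 Hz) and K-complexes in N2, high-amplitude
  delta (0.5-2 Hz) in N3, and low-amplitude mixed activity with 2-4 Hz
  sawtooth trains in REM -- on top of 1/f background noise.

The waveform model is artifact-defined: the stage signatures are not fitted
to any clinical data and carry no claim of physiological fidelity beyond
their band-power structure.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stages import Stage, N_STAGES, EPOCH_SECONDS, TARGET_FS
from .preprocess import EEGRecord

__all__ = [
    "CLINICAL_STAGE_COUNTS",
    "DEFAULT_TARGET_PROPORTIONS",
    "DEFAULT_TRANSITION_WEIGHTS",
    "HypnogramSpec",
    "StageSignalParams",
    "SyntheticRecording",
    "simulate_hypnogram",
    "stationary_distribution",
    "synth_stage_epoch",
    "synth_recording",
]

# Per-stage epoch counts of two clinical PSG cohorts (20 and 61 adult
# patients); their pooled proportions are the default class imbalance the
# generator emulates.  Order: W, N1, N2, N3, REM.
CLINICAL_STAGE_COUNTS: dict[str, tuple[int, ...]] = {
    "cohort-1": (4826, 5094, 4711, 1568, 1488),
    "cohort-2": (12983, 5818, 26091, 3621, 6296),
}

_pooled = np.sum(list(CLINICAL_STAGE_COUNTS.values()), axis=0)
DEFAULT_TARGET_PROPORTIONS: np.ndarray = _pooled / _pooled.sum()

# Row-stochastic after normalization; rows/cols ordered W, N1, N2, N3, REM.
# Dwell probabilities give multi-epoch stage bouts and the cyclic
# W -> N1 -> N2 <-> N3 -> REM -> W progression while keeping the chain
# well-mixed enough that empirical stage fractions of a night-scale
# simulation track the stationary distribution to a couple of percent.
DEFAULT_TRANSITION_WEIGHTS: np.ndarray = np.array(
    [
        [0.850, 0.150, 0.000, 0.000, 0.000],
        [0.050, 0.650, 0.300, 0.000, 0.000],
        [0.012, 0.018, 0.885, 0.050, 0.035],
        [0.000, 0.000, 0.090, 0.900, 0.010],
        [0.055, 0.035, 0.055, 0.000, 0.855],
    ]
)


@dataclass(frozen=True)
class HypnogramSpec:
    """Markov-chain specification of a night's stage sequence.

    Parameters
    ----------
    n_epochs
        Number of 30-s epochs to simulate.
    transition_weights
        5x5 nonnegative stage-transition propensities (rows renormalized).
    target_proportions
        Optional marginal stage fractions; when given, the transition matrix
        is rebalanced so its stationary distribution matches them.
    cycle_minutes
        Nominal sleep-cycle duration bounds (provenance metadata; the
        default transition weights were tuned for 90-120 min cycles).
    seed
        Seed for the simulation stream.
    """

    n_epochs: int
    transition_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_WEIGHTS.copy()
    )
    target_proportions: np.ndarray | None = None
    cycle_minutes: tuple[float, float] = (90.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")
        w = np.asarray(self.transition_weights, dtype=float)
        if w.shape != (N_STAGES, N_STAGES) or (w < 0).any():
            raise ValueError("transition_weights must be a nonnegative 5x5 matrix")
        if (w.sum(axis=1) <= 0).any():
            raise ValueError("every transition row must have positive sum")
        object.__setattr__(self, "transition_weights", w)
        if self.target_proportions is not None:
            p = np.asarray(self.target_proportions, dtype=float)
            if p.shape != (N_STAGES,) or (p < 0).any():
                raise ValueError("target_proportions must be a nonnegative 5-vector")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("target_proportions must sum to 1 (tolerance 1e-9)")
            object.__setattr__(self, "target_proportions", p)
        lo, hi = self.cycle_minutes
        if not (0 < lo < hi):
            raise ValueError("cycle_minutes must be an increasing positive pair")

    @property
    def transition_matrix(self) -> np.ndarray:
        """Row-normalized transition matrix (after proportion matching)."""
        P = self.transition_weights / self.transition_weights.sum(axis=1, keepdims=True)
        if self.target_proportions is not None:
            P = _match_proportions(P, self.target_proportions)
        return P


# Canonical scoring bands (Hz).  The per-stage `dominant` entry names the
# band whose power the stage's rhythm concentrates in.
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 2.0),
    "sawtooth": (2.0, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "spindle": (11.0, 16.0),
}


@dataclass(frozen=True)
class StageSignalParams:
    """Waveform parameters of the stage-conditional EEG model.

    Amplitudes are peak-to-peak microvolt ranges; rates are events per 30-s
    epoch.  All oscillation bands must lie inside the 0.3-35 Hz scoring
    band.  Defaults follow textbook AASM amplitude ranges.
    """

    bands: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {
            int(Stage.W): CANONICAL_BANDS["alpha"],
            int(Stage.N1): CANONICAL_BANDS["theta"],
            int(Stage.N2): CANONICAL_BANDS["theta"],
            int(Stage.N3): CANONICAL_BANDS["delta"],
            int(Stage.REM): CANONICAL_BANDS["sawtooth"],
        }
    )
    amplitudes_pp: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {
            int(Stage.W): (10.0, 40.0),
            int(Stage.N1): (10.0, 40.0),
            int(Stage.N2): (40.0, 60.0),
            int(Stage.N3): (75.0, 150.0),
            int(Stage.REM): (10.0, 40.0),
        }
    )
    spindle_rate: float = 3.0
    kcomplex_rate: float = 1.0
    spindle_band: tuple[float, float] = CANONICAL_BANDS["spindle"]
    spindle_amp_pp: tuple[float, float] = (20.0, 40.0)
    kcomplex_amp_pp: float = 120.0
    noise_exponent: float = 1.0
    noise_db: float = -10.0  # noise power relative to the stage rhythm
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in list(self.bands.values()) + [self.spindle_band]:
            if not (0.3 <= lo < hi <= 35.0):
                raise ValueError("oscillation bands must lie inside [0.3, 35] Hz")
        if self.spindle_rate < 0 or self.kcomplex_rate < 0:
            raise ValueError("event rates must be >= 0")
        for lo, hi in self.amplitudes_pp.values():
            if lo <= 0 or hi < lo:
                raise ValueError("amplitude ranges must be positive and increasing")


@dataclass(frozen=True)
class SyntheticRecording:
    """A generated record plus its hypnogram and generating specs."""

    record: EEGRecord
    hypnogram: np.ndarray  # int stage codes, one per epoch
    hyp_spec: HypnogramSpec
    sig_params: StageSignalParams

    def __post_init__(self) -> None:
        n = len(self.hypnogram)
        expected = n * EPOCH_SECONDS * int(self.record.fs)
        if self.record.samples.size != expected:
            raise ValueError(
                f"record length {self.record.samples.size} != n_epochs * 30 * fs = {expected}"
            )


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (eigen-analysis)."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _match_proportions(
    P: np.ndarray, target: np.ndarray, n_iter: int = 500, tol: float = 1e-10
) -> np.ndarray:
    """Rebalance ``P`` so its stationary distribution matches ``target``.

    Iterative column reweighting: scale column j by target_j / pi_j, then
    renormalize rows; repeat until the stationary distribution converges.
    Stages with zero target mass keep zero columns only if already zero.
    """
    Q = P.copy()
    target = np.maximum(target, 1e-12)
    target = target / target.sum()
    for _ in range(n_iter):
        pi = stationary_distribution(Q)
        ratio = target / np.maximum(pi, 1e-12)
        if np.max(np.abs(ratio - 1.0)) < tol:
            break
        Q = Q * ratio[None, :]
        Q = Q / Q.sum(axis=1, keepdims=True)
    return Q


def simulate_hypnogram(spec: HypnogramSpec) -> np.ndarray:
    """Simulate a night's stage sequence from the Markov specification.

    The sequence starts in Wake (a sleep cycle begins awake) and then
    follows the (possibly proportion-matched) transition matrix.  Returns
    integer stage codes of length ``spec.n_epochs``.
    """
    if spec.n_epochs == 0:
        return np.empty(0, dtype=np.int64)
    P = spec.transition_matrix
    rng = np.random.default_rng(spec.seed)
    out = np.empty(spec.n_epochs, dtype=np.int64)
    out[0] = int(Stage.W)
    # inverse-CDF sampling against a pre-drawn uniform stream
    cum = np.cumsum(P, axis=1)
    u = rng.random(spec.n_epochs - 1)
    for t in range(1, spec.n_epochs):
        out[t] = int(np.searchsorted(cum[out[t - 1]], u[t - 1], side="right"))
    return out


def _pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-power 1/f**exponent noise, high-pass limited at 0.3 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    valid = freqs >= 0.3
    shaping[valid] = freqs[valid] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    p = np.mean(x**2)
    return x / np.sqrt(p) if p > 0 else x


def _drifting_tone(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-amplitude oscillation with a slowly drifting in-band frequency."""
    t = np.arange(n) / fs
    lo, hi = band
    margin = 0.15 * (hi - lo)
    f0 = rng.uniform(lo + margin, hi - margin)
    # slow sinusoidal frequency drift within the band
    drift = 0.5 * margin * np.sin(2 * np.pi * rng.uniform(0.02, 0.05) * t + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f0 + drift) / fs
    am = 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t + rng.uniform(0, 2 * np.pi))
    return am * np.sin(phase + rng.uniform(0, 2 * np.pi))


def _sawtooth_train(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Bursts of triangular sawtooth-like waves covering about half the epoch."""
    from scipy.signal import sawtooth

    t = np.arange(n) / fs
    f0 = rng.uniform(band[0] + 0.5, band[1] - 0.5)
    wave = sawtooth(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi), width=0.5)
    # smooth on/off envelope: ~3 bursts of ~5 s
    env = np.zeros(n)
    for _ in range(3):
        c = rng.uniform(2.5, EPOCH_SECONDS - 2.5)
        env += np.exp(-0.5 * ((t - c) / 1.8) ** 2)
    env = np.clip(env, 0.0, 1.0)
    return wave * env


def _kcomplex(fs: float, rng: np.random.Generator) -> np.ndarray:
    """Biphasic K-complex transient, ~1.1 s, unit peak-to-peak."""
    dur = 1.1
    t = np.arange(int(dur * fs)) / fs - dur / 2
    # derivative-of-Gaussian shape: sharp negative then slower positive wave
    sigma = 0.18
    w = -t * np.exp(-0.5 * (t / sigma) ** 2)
    return w / (w.max() - w.min())


def synth_stage_epoch(
    stage: Stage | int,
    fs: float = TARGET_FS,
    params: StageSignalParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Generate one 30-s epoch of stage-conditional EEG, in microvolts.

    Deterministic given ``(stage, seed)``.  ``fs`` must be at least 128 Hz
    so all configured rhythms are below Nyquist.
    """
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    params = params or StageSignalParams()
    try:
        stage = Stage(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}") from None
    n = int(round(EPOCH_SECONDS * fs))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), params.seed, int(stage))))

    amp_lo, amp_hi = params.amplitudes_pp[int(stage)]
    amp = rng.uniform(amp_lo, amp_hi) / 2.0  # peak-to-peak -> amplitude
    band = params.bands[int(stage)]

    if stage == Stage.REM:
        rhythm = amp * _sawtooth_train(n, fs, band, rng)
        rhythm += 0.35 * amp * _drifting_tone(n, fs, CANONICAL_BANDS["theta"], rng)
    else:
        rhythm = amp * _drifting_tone(n, fs, band, rng)

    if stage == Stage.N2:
        t = np.arange(n) / fs
        n_spindles = rng.poisson(params.spindle_rate)
        for _ in range(n_spindles):
            f_sp = rng.uniform(*params.spindle_band)
            c = rng.uniform(1.0, EPOCH_SECONDS - 1.0)
            a_sp = rng.uniform(*params.spindle_amp_pp) / 2.0
            env = np.exp(-0.5 * ((t - c) / 0.35) ** 2)
            rhythm += a_sp * env * np.sin(2 * np.pi * f_sp * t + rng.uniform(0, 2 * np.pi))
        n_kc = rng.poisson(params.kcomplex_rate)
        kc = _kcomplex(fs, rng)
        for _ in range(n_kc):
            start = rng.integers(0, n - kc.size)
            rhythm[start : start + kc.size] += params.kcomplex_amp_pp * kc

    rhythm_power = float(np.mean(rhythm**2))
    noise_power = rhythm_power * 10.0 ** (params.noise_db / 10.0)
    noise = np.sqrt(noise_power) * _pink_noise(n, fs, params.noise_exponent, rng)
    return rhythm + noise


def synth_recording(
    hyp_spec: HypnogramSpec,
    sig_params: StageSignalParams | None = None,
    fs: float = TARGET_FS,
    channel: str = "C4-M1",
) -> SyntheticRecording:
    """Simulate a hypnogram and synthesize the matching continuous EEG."""
    sig_params = sig_params or StageSignalParams()
    hyp = simulate_hypnogram(hyp_spec)
    n_epoch = int(round(EPOCH_SECONDS * fs))
    samples = np.empty(hyp.size * n_epoch, dtype=float)
    # per-epoch seeds fanned out from the hypnogram seed
    for i, st in enumerate(hyp):
        samples[i * n_epoch : (i + 1) * n_epoch] = synth_stage_epoch(
            int(st), fs=fs, params=sig_params, seed=hyp_spec.seed * 1_000_003 + i
        )
    rec = EEGRecord(samples=samples, fs=float(fs), channel=channel)
    return SyntheticRecording(record=rec, hypnogram=hyp, hyp_spec=hyp_spec, sig_params=sig_params)


def write_labels_csv(path, hypnogram: np.ndarray) -> None:
    """Write per-epoch labels as (epoch_index, stage) with a header row."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["epoch_index", "stage"])
        for i, code in enumerate(hypnogram):
            w.writerow([i, Stage(int(code)).name])
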