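"""Time-frequency imaging of 30-s EEG epochs: FSST, Morse CWT, rendering.

Two transforms produce the images the classifiers consume:

* **FSST** (Fourier synchrosqueezing): a Gaussian-window STFT whose
  coefficients are reassigned along the frequency axis to the local
  instantaneous-frequency estimate, sharpening oscillatory ridges while
  preserving causality (time stays put).
* **CWT** with the exactly analytic generalized Morse wavelet, evaluated
  on a geometric scale grid (fixed voices per octave) covering the
  0.3-35 Hz scoring band.

``render_image`` maps either grid to the 224x224x3 unit-interval image
format the CNN expects: crop to the scoring band, log1p-compress the
magnitude, min-max normalize per image, bilinear-resize, and replicate to
three channels (or apply a named colormap).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from .stages import TARGET_FS

logger = logging.getLogger(__name__)

__all__ = [
    "ModeModel",
    "FSSTConfig",
    "STFTGrid",
    "FSSTGrid",
    "CWTConfig",
    "CWTGrid",
    "RenderConfig",
    "TFImage",
    "stft",
    "inst_freq",
    "fsst",
    "cwt_morse",
    "render_image",
    "spectral_entropy",
]


# --------------------------------------------------------------------------
# FSST
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeModel:
    """Multi-component AM-FM test signal y(t) = sum_k A_k(t) cos(2 pi phi_k(t)).

    Each component has a slowly varying amplitude around ``center_freqs[k]``
    with sinusoidal frequency modulation of depth ``fm_depth`` Hz.  The
    components' instantaneous frequencies must stay pairwise separated by at
    least ``min_separation`` (the synchrosqueezing resolvability condition
    d = 2 Delta for a given analysis window); violating it is a
    configuration error.
    """

    center_freqs: tuple[float, ...]
    am_depth: float = 0.3
    fm_depth: float = 0.5
    min_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.sort(np.asarray(self.center_freqs, dtype=float))
        if f.size == 0 or f[0] <= 0:
            raise ValueError("need at least one positive center frequency")
        if f.size > 1:
            gaps = np.diff(f) - 2 * self.fm_depth
            if self.min_separation and (gaps < self.min_separation).any():
                raise ValueError(
                    "instantaneous frequencies come closer than the required "
                    f"separation {self.min_separation:.2f} Hz"
                )

    def synthesize(self, n: int, fs: float) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        t = np.arange(n) / fs
        sig = np.zeros(n)
        for fc in self.center_freqs:
            am = 1.0 + self.am_depth * np.sin(
                2 * np.pi * rng.uniform(0.05, 0.2) * t + rng.uniform(0, 2 * np.pi)
            )
            inst_f = fc + self.fm_depth * np.sin(
                2 * np.pi * rng.uniform(0.02, 0.1) * t + rng.uniform(0, 2 * np.pi)
            )
            phase = 2 * np.pi * np.cumsum(inst_f) / fs
            sig += am * np.cos(phase + rng.uniform(0, 2 * np.pi))
        return sig


@dataclass(frozen=True)
class FSSTConfig:
    """Gaussian-window STFT / synchrosqueezing parameters.

    ``gamma_g`` is the Gaussian window scale (standard deviation) in
    seconds.  Its half-power frequency bandwidth is taken as
    Delta = sqrt(2 ln 2) / gamma_g, and two oscillatory components are
    resolvable when their instantaneous frequencies stay separated by
    d = 2 Delta.
    """

    window_length: int = 257          # samples, odd so the center is exact
    hop: int = 32                     # samples between frames
    n_fft: int = 512
    gamma_g: float = 0.25             # window scale, seconds
    fs: float = TARGET_FS
    mask_rel: float = 1e-6            # |V| threshold relative to max |V|

    def __post_init__(self) -> None:
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if self.hop < 1 or self.n_fft < self.window_length:
            raise ValueError("need hop >= 1 and n_fft >= window_length")
        if self.gamma_g <= 0:
            raise ValueError("gamma_g must be positive")

    @property
    def bandwidth(self) -> float:
        """Half-power bandwidth Delta of the Gaussian window, Hz."""
        return float(np.sqrt(2.0 * np.log(2.0)) / self.gamma_g)

    @property
    def separation(self) -> float:
        """Minimum resolvable component separation d = 2 Delta, Hz."""
        return 2.0 * self.bandwidth

    def window(self) -> np.ndarray:
        """Gaussian window g, peak value 1 at the center sample."""
        L = self.window_length
        m = np.arange(L) - L // 2
        sigma = self.gamma_g * self.fs
        return np.exp(-0.5 * (m / sigma) ** 2)

    def window_derivative(self) -> np.ndarray:
        """Analytic time-derivative g'(t) sampled on the window grid, 1/s."""
        L = self.window_length
        t = (np.arange(L) - L // 2) / self.fs  # seconds
        return -(t / self.gamma_g**2) * self.window()


@dataclass(frozen=True)
class STFTGrid:
    """Complex STFT V(eta, t): rows are frequency bins, columns frames.

    ``Vd`` is the companion STFT taken with the window's time derivative;
    it is what the instantaneous-frequency estimator consumes.
    """

    V: np.ndarray
    Vd: np.ndarray
    freqs: np.ndarray   # Hz, per row
    times: np.ndarray   # s, frame centers
    config: FSSTConfig

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.V)


@dataclass(frozen=True)
class FSSTGrid:
    """Synchrosqueezed grid T(omega, t) plus reassignment diagnostics.

    ``T`` accumulates the complex STFT coefficients (scaled by 1/g(0)) at
    their reassigned frequency rows.  ``energy`` accumulates |V|^2 along
    the same transport, so its column sums equal the unmasked per-frame
    STFT energy exactly; ``omega_hat`` is the instantaneous-frequency map
    with its validity mask.
    """

    T: np.ndarray
    energy: np.ndarray
    omega_hat: np.ma.MaskedArray
    freqs: np.ndarray
    times: np.ndarray
    config: FSSTConfig

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.T)


def stft(epoch: np.ndarray, cfg: FSSTConfig | None = None) -> STFTGrid:
    """Gaussian-window STFT of one epoch.

    Frames are demodulated at the window center, so a stationary tone has a
    frame-independent phase profile and the instantaneous-frequency
    estimator of :func:`inst_freq` is unbiased on the ridge.
    """
    cfg = cfg or FSSTConfig()
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be 1-D")
    L = cfg.window_length
    if L > x.size:
        raise ValueError(f"window ({L}) longer than signal ({x.size})")
    g = cfg.window()
    dg = cfg.window_derivative()
    starts = np.arange(0, x.size - L + 1, cfg.hop)
    frames = np.lib.stride_tricks.sliding_window_view(x, L)[starts]  # (T, L)
    spec = np.fft.rfft(frames * g, n=cfg.n_fft, axis=1)
    spec_d = np.fft.rfft(frames * dg, n=cfg.n_fft, axis=1)
    k = np.arange(spec.shape[1])
    # shift phase reference to the window center
    shift = np.exp(2j * np.pi * k * (L // 2) / cfg.n_fft)
    spec = spec * shift
    spec_d = spec_d * shift
    freqs = k * cfg.fs / cfg.n_fft
    times = (starts + L // 2) / cfg.fs
    return STFTGrid(V=spec.T, Vd=spec_d.T, freqs=freqs, times=times, config=cfg)


def inst_freq(grid: STFTGrid, threshold: float | None = None) -> np.ma.MaskedArray:
    """Instantaneous-frequency map omega^(eta, t) in Hz.

    Uses the derivative-window identity
    omega^ = f_eta - Im(V_g' / V) / (2 pi), defined where |V| exceeds the
    masking threshold (relative to the grid's maximum magnitude by
    default); masked elsewhere.
    """
    cfg = grid.config
    absV = np.abs(grid.V)
    thr = (cfg.mask_rel * absV.max()) if threshold is None else threshold
    mask = absV <= thr
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.imag(grid.Vd / grid.V) / (2.0 * np.pi)
    omega = grid.freqs[:, None] - corr
    omega = np.where(np.isfinite(omega), omega, 0.0)
    return np.ma.MaskedArray(omega, mask=mask)


def fsst(epoch: np.ndarray, cfg: FSSTConfig | None = None) -> FSSTGrid:
    """Fourier synchrosqueezing transform of one epoch.

    Each unmasked STFT coefficient V(eta, t) is moved along the frequency
    axis to the bin nearest its instantaneous-frequency estimate and
    accumulated into T (scaled by 1/g(0)); the coefficient's energy |V|^2
    rides along in the ``energy`` plane.  Only frequency is reassigned, so
    time localization (causality) is untouched.
    """
    cfg = cfg or FSSTConfig()
    grid = stft(epoch, cfg)
    omega = inst_freq(grid)
    g0 = cfg.window()[cfg.window_length // 2]  # = 1 for the Gaussian
    n_bins, n_frames = grid.V.shape
    df = cfg.fs / cfg.n_fft
    target = np.round(np.asarray(omega.data) / df).astype(np.int64)
    valid = (~omega.mask) & (target >= 0) & (target < n_bins)
    T = np.zeros_like(grid.V)
    E = np.zeros((n_bins, n_frames), dtype=float)
    rows, cols = np.nonzero(valid)
    tgt = target[rows, cols]
    np.add.at(T, (tgt, cols), grid.V[rows, cols] / g0)
    np.add.at(E, (tgt, cols), np.abs(grid.V[rows, cols]) ** 2)
    return FSSTGrid(
        T=T, energy=E, omega_hat=omega, freqs=grid.freqs, times=grid.times, config=cfg
    )


def spectral_entropy(power: np.ndarray) -> float:
    """Normalized Shannon entropy of a nonnegative distribution in [0, 1]."""
    p = np.asarray(power, dtype=float).ravel()
    total = p.sum()
    if total <= 0:
        return 0.0
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(p.size))


# --------------------------------------------------------------------------
# CWT (generalized Morse wavelet)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CWTConfig:
    """Analytic Morse wavelet scalogram parameters.

    ``gamma`` controls the wavelet's symmetry, ``beta`` its time-bandwidth
    product; the peak (center) angular frequency is (beta/gamma)^(1/gamma).
    Scales form a geometric grid with ``voices_per_octave`` steps per
    octave whose implied center frequencies span ``freq_range``.
    """

    gamma: float = 3.0
    beta: float = 20.0
    voices_per_octave: int = 12
    freq_range: tuple[float, float] = (0.3, 38.0)
    fs: float = TARGET_FS

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")
        lo, hi = self.freq_range
        if not (0 < lo < hi <= self.fs / 2):
            raise ValueError("freq_range must be increasing and below Nyquist")
        if lo > 0.3 or hi < 35.0:
            raise ValueError(
                "scale grid must cover the 0.3-35 Hz scoring band "
                f"(got freq_range={self.freq_range})"
            )
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    @property
    def peak_omega(self) -> float:
        """Peak angular frequency of the mother wavelet (rad/sample units)."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)

    def center_freqs(self) -> np.ndarray:
        """Geometric grid of scale center frequencies, Hz, ascending."""
        lo, hi = self.freq_range
        n = int(np.ceil(np.log2(hi / lo) * self.voices_per_octave)) + 1
        freqs = lo * 2.0 ** (np.arange(n) / self.voices_per_octave)
        return freqs[freqs < self.fs / 2]

    def scales(self) -> np.ndarray:
        """Scales (samples) for each center frequency, descending in s."""
        omega_c = 2.0 * np.pi * self.center_freqs() / self.fs  # rad/sample
        return self.peak_omega / omega_c


@dataclass(frozen=True)
class CWTGrid:
    """Complex coefficients W(s, tau): rows ascend in center frequency."""

    W: np.ndarray
    freqs: np.ndarray   # center frequency per row, Hz
    scales: np.ndarray  # scale per row, samples
    times: np.ndarray   # s
    config: CWTConfig

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.W)


def _morse_hat(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Frequency-domain Morse wavelet, peak value 2 (analytic, omega > 0)."""
    out = np.zeros_like(omega)
    pos = omega > 0
    w = omega[pos]
    log_amp = (beta / gamma) * (1.0 + np.log(gamma / beta))
    out[pos] = 2.0 * np.exp(log_amp + beta * np.log(w) - w**gamma)
    return out


def cwt_morse(epoch: np.ndarray, cfg: CWTConfig | None = None) -> CWTGrid:
    """Morse-wavelet CWT via frequency-domain (circular) convolution.

    The wavelet is analytic, so a real tone of amplitude A yields ridge
    magnitude ~A at the matching scale (peak-2 normalization).
    """
    cfg = cfg or CWTConfig()
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be 1-D")
    n = x.size
    X = np.fft.fft(x)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)  # rad/sample, signed
    scales = cfg.scales()
    freqs = cfg.center_freqs()
    W = np.empty((scales.size, n), dtype=complex)
    for i, s in enumerate(scales):
        psi = _morse_hat(s * omega, cfg.gamma, cfg.beta)
        W[i] = np.fft.ifft(X * np.conj(psi))
    times = np.arange(n) / cfg.fs
    return CWTGrid(W=W, freqs=freqs, scales=scales, times=times, config=cfg)


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderConfig:
    """How a TF grid becomes a 224x224x3 unit-interval image."""

    out_size: tuple[int, int] = (224, 224)
    freq_crop: tuple[float, float] = (0.3, 35.0)
    log_compress: bool = True
    colormap: str | None = None  # None = replicate grayscale

    def hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass(frozen=True)
class TFImage:
    """A rendered 224x224x3 image in [0, 1] with its provenance tag."""

    pixels: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.shape != (224, 224, 3):
            raise ValueError(f"TFImage must be 224x224x3, got {p.shape}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("TFImage pixels must lie in [0, 1]")


def render_image(grid, cfg: RenderConfig | None = None) -> TFImage:
    """Render an FSST/CWT grid (or raw magnitude array) to a TFImage.

    Pipeline: crop rows to the scoring band -> magnitude -> optional log1p
    -> per-image min-max to [0, 1] -> bilinear resize -> 3 channels.  An
    all-constant grid renders to the all-zero image with a warning.
    """
    from skimage.transform import resize

    cfg = cfg or RenderConfig()
    if hasattr(grid, "magnitude"):
        mag = np.asarray(grid.magnitude, dtype=float)
        freqs = grid.freqs
        lo, hi = cfg.freq_crop
        keep = (freqs >= lo) & (freqs <= hi)
        mag = mag[keep]
        kind = type(grid).__name__
        conf_repr = repr(grid.config)
    else:
        mag = np.abs(np.asarray(grid, dtype=float))
        kind = "array"
        conf_repr = ""
    if not np.all(np.isfinite(mag)):
        raise ValueError("grid contains non-finite values")
    if cfg.log_compress:
        mag = np.log1p(mag)
    lo_v, hi_v = float(mag.min()), float(mag.max())
    if hi_v - lo_v <= 0:
        logger.warning("all-constant grid; rendering all-zero image")
        norm = np.zeros_like(mag)
    else:
        norm = (mag - lo_v) / (hi_v - lo_v)
    # flip so the highest frequency is the top image row
    norm = norm[::-1]
    if norm.shape != cfg.out_size:
        out = resize(norm, cfg.out_size, order=1, mode="edge",
                     anti_aliasing=True, preserve_range=True)
    else:
        out = norm
    out = np.clip(out, 0.0, 1.0)
    if cfg.colormap is None:
        pixels = np.repeat(out[:, :, None], 3, axis=2)
    else:
        import matplotlib

        cmap = matplotlib.colormaps[cfg.colormap]
        pixels = cmap(out)[:, :, :3]
    tag = hashlib.sha1((kind + conf_repr + repr(cfg)).encode()).hexdigest()[:12]
    return TFImage(pixels=pixels.astype(np.float32), provenance=f"{kind}:{tag}")
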