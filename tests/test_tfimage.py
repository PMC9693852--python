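"""Time-frequency imaging: STFT, synchrosqueezing, Morse CWT, rendering."""

import numpy as np
import pytest

from sleeptf.tfimage import (
    CWTConfig,
    FSSTConfig,
    ModeModel,
    RenderConfig,
    TFImage,
    cwt_morse,
    fsst,
    inst_freq,
    render_image,
    spectral_entropy,
    stft,
)
from conftest import tone


class TestSTFT:
    def test_zero_signal(self, epoch_t):
        g = stft(np.zeros(7680))
        assert np.all(g.V == 0)

    def test_tone_peak_bin(self, epoch_t):
        g = stft(tone(epoch_t, 10.0))
        peak_rows = np.abs(g.V).argmax(axis=0)
        expect = np.argmin(np.abs(g.freqs - 10.0))
        assert np.all(peak_rows == expect)

    def test_parseval_per_frame(self, epoch_t):
        """FFT-domain frame energy equals windowed time-domain energy."""
        cfg = FSSTConfig()
        x = tone(epoch_t, 7.3) + 0.5 * tone(epoch_t, 19.1)
        g = stft(x, cfg)
        win = cfg.window()
        L, hop, nfft = cfg.window_length, cfg.hop, cfg.n_fft
        for frame in (0, 50, 117, 231):
            start = frame * hop
            seg = x[start : start + L] * win
            td = np.sum(seg**2)
            V = g.V[:, frame]
            fd = (np.abs(V[0]) ** 2 + 2 * np.sum(np.abs(V[1:-1]) ** 2) + np.abs(V[-1]) ** 2) / nfft
            assert fd == pytest.approx(td, rel=1e-2)

    def test_window_longer_than_signal(self):
        with pytest.raises(ValueError, match="longer than signal"):
            stft(np.zeros(100), FSSTConfig())


class TestInstFreq:
    def test_tone_ridge(self, epoch_t):
        g = stft(tone(epoch_t, 10.0))
        om = inst_freq(g, threshold=0.1 * np.abs(g.V).max())
        near = np.abs(g.freqs - 10.0) <= 1.0
        vals = np.asarray(om.data)[near][~om.mask[near]]
        assert vals.size > 0
        assert np.abs(vals - 10.0).max() < 0.2

    def test_linear_chirp_tracking(self, epoch_t):
        from scipy.signal import chirp

        x = chirp(epoch_t, f0=2, f1=20, t1=30, method="linear")
        g = stft(x)
        om = inst_freq(g, threshold=0.3 * np.abs(g.V).max())
        true_f = 2 + (20 - 2) * g.times / 30.0
        errs = []
        for j in range(10, om.shape[1] - 10):  # away from edges
            col = om[:, j]
            if col.mask.all():
                continue
            ridge = np.abs(g.V[:, j]).argmax()
            if not col.mask[ridge]:
                errs.append(col.data[ridge] - true_f[j])
        rms = np.sqrt(np.mean(np.square(errs)))
        assert rms < 0.5

    def test_zero_region_masked(self):
        g = stft(np.concatenate([np.zeros(4000), np.ones(3680)]))
        om = inst_freq(g)
        # frames fully inside the all-zero prefix must be fully masked
        zero_frames = g.times < 4000 / 256 - 1.0
        assert om.mask[:, zero_frames].all()


class TestFSST:
    def test_two_tone_ridge_capture(self, epoch_t):
        """Tones separated by more than d collapse onto their true rows."""
        cfg = FSSTConfig()
        assert 15.0 - 5.0 > cfg.separation
        F = fsst(tone(epoch_t, 5.0) + tone(epoch_t, 15.0), cfg)
        P = np.abs(F.T) ** 2
        cap = 0.0
        for f0 in (5.0, 15.0):
            b = np.argmin(np.abs(F.freqs - f0))
            cap += P[b - 2 : b + 3].sum()
        assert cap / P.sum() >= 0.90

    def test_energy_conservation_per_frame(self, epoch_t):
        """Reassignment transports, never creates or destroys, energy.

        Column sums of the transported |V|^2 mass equal the unmasked STFT
        frame energy; the complex coefficients likewise regroup exactly
        (scaled by 1/g(0)).
        """
        x = ModeModel(center_freqs=(6.0, 21.0), seed=3).synthesize(7680, 256.0)
        cfg = FSSTConfig()
        g = stft(x, cfg)
        F = fsst(x, cfg)
        df = cfg.fs / cfg.n_fft
        tgt = np.round(np.asarray(F.omega_hat.data) / df).astype(int)
        valid = (~F.omega_hat.mask) & (tgt >= 0) & (tgt < g.V.shape[0])
        # energy plane
        colE = F.energy.sum(axis=0)
        refE = np.where(valid, np.abs(g.V) ** 2, 0.0).sum(axis=0)
        assert np.abs(colE - refE).max() <= 1e-6 * refE.max()
        # complex marginal
        colT = F.T.sum(axis=0)
        refT = np.where(valid, g.V, 0.0).sum(axis=0)
        assert np.abs(colT - refT).max() <= 1e-6 * np.abs(refT).max()

    def test_entropy_sharpening_amfm(self):
        """Synchrosqueezing concentrates an AM-FM mode's distribution."""
        x = ModeModel(center_freqs=(8.0, 24.0), min_separation=FSSTConfig().separation,
                      seed=9).synthesize(7680, 256.0)
        g = stft(x)
        F = fsst(x)
        assert spectral_entropy(np.abs(F.T) ** 2) < spectral_entropy(np.abs(g.V) ** 2)

    def test_zero_signal(self):
        F = fsst(np.zeros(7680))
        assert np.all(F.T == 0)

    def test_mode_model_separation_enforced(self):
        with pytest.raises(ValueError, match="separation"):
            ModeModel(center_freqs=(10.0, 12.0), min_separation=9.0)


class TestCWT:
    @pytest.mark.parametrize("f0", [1.0, 4.0, 10.0, 20.0, 34.0])
    def test_tone_scale_mapping(self, epoch_t, f0):
        """The max-|W| row's center frequency is within one voice of the tone."""
        cfg = CWTConfig()
        G = cwt_morse(np.cos(2 * np.pi * f0 * epoch_t), cfg)
        fc = G.freqs[np.abs(G.W).mean(axis=1).argmax()]
        assert abs(np.log2(fc / f0)) <= 1.0 / cfg.voices_per_octave

    def test_homogeneity(self, epoch_t):
        y = np.sin(2 * np.pi * 9 * epoch_t)
        a = 3.7
        W1 = cwt_morse(a * y).W
        W2 = a * cwt_morse(y).W
        assert np.abs(W1 - W2).max() < 1e-10 * np.abs(W2).max()

    def test_translation_covariance(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(7680)
        m = 100
        W1 = cwt_morse(y).W
        W2 = cwt_morse(np.roll(y, m)).W
        interior = slice(1000, 6000)
        assert np.abs(np.roll(W1, m, axis=1)[:, interior] - W2[:, interior]).max() < 1e-6

    def test_scales_strictly_increasing_frequencies(self):
        cfg = CWTConfig()
        f = cfg.center_freqs()
        assert (np.diff(f) > 0).all()
        assert f[0] <= 0.3 and f[-1] >= 35.0
        s = cfg.scales()
        assert (np.diff(s) < 0).all()  # scale inversely related to frequency

    def test_band_not_covered_rejected(self):
        with pytest.raises(ValueError, match="scoring band"):
            CWTConfig(freq_range=(5.0, 10.0))


class TestRender:
    def test_shape_and_range(self, epoch_t):
        img = render_image(cwt_morse(tone(epoch_t, 10.0)))
        assert img.pixels.shape == (224, 224, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        # grayscale replication: channels identical
        assert np.array_equal(img.pixels[:, :, 0], img.pixels[:, :, 2])

    def test_zero_grid(self):
        img = render_image(np.zeros((50, 60)))
        assert np.all(img.pixels == 0)

    def test_monotone_toy_grid(self):
        """Cell magnitude ordering survives rendering on a 2x2 toy grid.

        Rows are flipped before resize (highest "frequency" row on top), so
        grid row 0 lands in the bottom image half.  The interior quarter of
        each quadrant is sampled to stay clear of interpolation seams.
        """
        grid = np.array([[4.0, 1.0], [2.0, 3.0]])
        img = render_image(grid, RenderConfig(log_compress=False)).pixels[:, :, 0]
        quad = {
            (0, 0): img[140:196, 28:84].mean(),   # grid row 0 -> bottom half
            (0, 1): img[140:196, 140:196].mean(),
            (1, 0): img[28:84, 28:84].mean(),     # grid row 1 -> top half
            (1, 1): img[28:84, 140:196].mean(),
        }
        ranked = sorted(quad, key=quad.get)
        assert ranked == [(0, 1), (1, 0), (1, 1), (0, 0)]  # 1 < 2 < 3 < 4

    def test_idempotent_normalization_core(self):
        """min-max + identity resize is idempotent on rendered [0,1] data
        (log compression intentionally breaks strict idempotence and is
        disabled here)."""
        rng = np.random.default_rng(4)
        base = rng.random((224, 224))
        base[0, 0], base[1, 1] = 0.0, 1.0  # pin the range
        cfg = RenderConfig(log_compress=False)
        once = render_image(base, cfg).pixels
        # undo the orientation flip so the second pass sees render output
        twice = render_image(once[::-1, :, 0], cfg).pixels
        assert np.allclose(once, twice, atol=1e-6)

    def test_named_colormap(self, epoch_t):
        img = render_image(cwt_morse(tone(epoch_t, 10.0)), RenderConfig(colormap="viridis"))
        assert img.pixels.shape == (224, 224, 3)
        # a real colormap produces distinct channels
        assert not np.array_equal(img.pixels[:, :, 0], img.pixels[:, :, 2])

    def test_tfimage_contract(self):
        with pytest.raises(ValueError, match="224"):
            TFImage(pixels=np.zeros((10, 10, 3)), provenance="x")
        with pytest.raises(ValueError, match="0, 1"):
            TFImage(pixels=np.full((224, 224, 3), 1.5), provenance="x")
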