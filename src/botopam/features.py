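"""Log-Mel spectrogram front-end: 5-s segment -> 512x128 classifier input.

The transform chain is: Hamming-windowed STFT (2048-sample window, 1112
samples of overlap, i.e. hop 936) -> one-sided power spectral density on
1024 linear bins spanning DC-48 kHz -> element-wise log10 with a floor ->
projection onto 128 Mel bands -> right-pad the 511 raw frames to 512 ->
per-band median equalization over time.

Median equalization subtracts, for every Mel band, its median over the 512
frames.  This cancels any time-constant additive component of the log
spectrum (stationary insect tones, electronic self-noise) while leaving
transients — clicks, rain drops, cavitation bursts — intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft

from botopam.audio_io import SEGMENT_SAMPLES, WORKING_RATE_HZ, Segment

WINDOW_SAMPLES = 2048
OVERLAP_SAMPLES = 1112
HOP_SAMPLES = WINDOW_SAMPLES - OVERLAP_SAMPLES  # 936
N_FREQ_BINS = WINDOW_SAMPLES // 2  # 1024 one-sided bins: DC kept, Nyquist dropped
N_MEL_BANDS = 128
N_TIME_FRAMES = 512  # raw 511 STFT frames right-padded by one floor frame
RAW_FRAMES = (SEGMENT_SAMPLES - WINDOW_SAMPLES) // HOP_SAMPLES + 1  # 511
LOG_FLOOR = 1e-12  # power floor relative to full scale before log10


@dataclass
class PsdMatrix:
    """Log10 power spectral density, frames x 1024 linear-frequency bins."""

    values: np.ndarray
    rate_hz: int = WORKING_RATE_HZ
    frame_hop_samples: int = HOP_SAMPLES

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_freqs_hz(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.rate_hz / WINDOW_SAMPLES


@dataclass
class MelMatrix:
    """512 time frames x 128 Mel bands of (optionally equalized) log power."""

    values: np.ndarray
    band_edges_hz: np.ndarray
    equalized: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (N_TIME_FRAMES, N_MEL_BANDS):
            raise ValueError(
                f"MelMatrix must be {N_TIME_FRAMES}x{N_MEL_BANDS}, "
                f"got {self.values.shape}"
            )


def hz_to_mel(f_hz: np.ndarray | float, variant: str = "htk") -> np.ndarray:
    """Mel scale: perceptual log warping of frequency."""
    f = np.asarray(f_hz, dtype=float)
    if variant == "htk":
        return 2595.0 * np.log10(1.0 + f / 700.0)
    if variant == "slaney":
        # linear below 1 kHz, logarithmic above
        mel = f / (200.0 / 3.0)
        log_region = f >= 1000.0
        mel = np.where(
            log_region,
            15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / (np.log(6.4) / 27.0),
            mel,
        )
        return mel
    raise ValueError(f"unknown mel variant {variant!r}")


def mel_to_hz(m: np.ndarray | float, variant: str = "htk") -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if variant == "htk":
        return 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    if variant == "slaney":
        f = m * (200.0 / 3.0)
        log_region = m >= 15.0
        f = np.where(log_region, 1000.0 * np.exp((m - 15.0) * np.log(6.4) / 27.0), f)
        return f
    raise ValueError(f"unknown mel variant {variant!r}")


def mel_filterbank(
    n_mels: int = N_MEL_BANDS,
    n_bins: int = N_FREQ_BINS,
    rate_hz: int = WORKING_RATE_HZ,
    fmin_hz: float = 0.0,
    fmax_hz: float | None = None,
    variant: str = "htk",
    norm: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular Mel filterbank mapping linear bins to Mel bands.

    Returns ``(weights, support_hz)`` with ``weights`` of shape
    ``(n_mels, n_bins)`` and ``support_hz`` the ``n_mels + 2`` triangle
    support points.  ``norm=None`` keeps unit-peak triangles (so a flat
    spectrum yields band outputs growing with bandwidth); ``norm="area"``
    scales each triangle to unit area.
    """
    if fmax_hz is None:
        fmax_hz = rate_hz / 2.0
    mel_pts = np.linspace(
        hz_to_mel(fmin_hz, variant), hz_to_mel(fmax_hz, variant), n_mels + 2
    )
    support_hz = mel_to_hz(mel_pts, variant)
    bin_freqs = np.arange(n_bins) * rate_hz / WINDOW_SAMPLES
    weights = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, mid, hi = support_hz[i], support_hz[i + 1], support_hz[i + 2]
        rising = (bin_freqs - lo) / max(mid - lo, 1e-9)
        falling = (hi - bin_freqs) / max(hi - mid, 1e-9)
        weights[i] = np.clip(np.minimum(rising, falling), 0.0, None)
        if norm == "area":
            area = weights[i].sum()
            if area > 0:
                weights[i] /= area
    return weights, support_hz


def compute_psd(seg: Segment | np.ndarray) -> PsdMatrix:
    """STFT power spectral density of one 5-s segment, log10 with floor.

    Frames use a 2048-sample Hamming window advanced by 936 samples (1112
    samples of overlap), giving 511 frames for a full segment; the one-sided
    spectrum keeps 1024 bins (DC retained, Nyquist dropped).
    """
    samples = seg.waveform.samples if isinstance(seg, Segment) else np.asarray(seg)
    if samples.size != SEGMENT_SAMPLES:
        raise ValueError(
            f"compute_psd expects a {SEGMENT_SAMPLES}-sample segment, "
            f"got {samples.size}"
        )
    window = np.hamming(WINDOW_SAMPLES)
    idx = np.arange(RAW_FRAMES)[:, None] * HOP_SAMPLES + np.arange(WINDOW_SAMPLES)
    frames = samples[idx] * window
    spectrum = rfft(frames, axis=1)[:, :N_FREQ_BINS]
    # per-bin power, normalized by window energy so levels are scale-stable
    power = (np.abs(spectrum) ** 2) / np.sum(window**2)
    values = np.log10(np.maximum(power, LOG_FLOOR))
    return PsdMatrix(values=values)


def mel_project(
    psd: PsdMatrix,
    filterbank: np.ndarray | None = None,
    support_hz: np.ndarray | None = None,
    variant: str = "htk",
    norm: str | None = None,
) -> MelMatrix:
    """Project 1024 linear bins onto 128 Mel bands and pad to 512 frames.

    The raw STFT of a 5-s segment yields 511 frames while the classifier
    contract is 512x128; the PSD is right-padded with one frame at the log
    floor before projection — the minimal repair that keeps the contract
    exact (and keeps an all-floor PSD mapping to a constant matrix).
    """
    if psd.n_bins != N_FREQ_BINS:
        raise ValueError(f"expected {N_FREQ_BINS} frequency bins, got {psd.n_bins}")
    if filterbank is None:
        filterbank, support_hz = mel_filterbank(variant=variant, norm=norm)
    values = psd.values
    if values.shape[0] < N_TIME_FRAMES:
        pad_value = float(np.log10(LOG_FLOOR))
        pad = np.full((N_TIME_FRAMES - values.shape[0], values.shape[1]), pad_value)
        values = np.vstack([values, pad])
    elif values.shape[0] > N_TIME_FRAMES:
        values = values[:N_TIME_FRAMES]
    mel = values @ filterbank.T
    edges = np.concatenate([support_hz[:N_MEL_BANDS], support_hz[-1:]])
    return MelMatrix(values=mel, band_edges_hz=edges, equalized=False)


def equalize(m: MelMatrix) -> MelMatrix:
    """Subtract each Mel band's median over time; output band medians are 0."""
    medians = np.median(m.values, axis=0, keepdims=True)
    return MelMatrix(
        values=m.values - medians, band_edges_hz=m.band_edges_hz, equalized=True
    )


@dataclass
class MelFrontEnd:
    """sklearn-style transformer: segments -> stacked 512x128 CNN inputs.

    Parameters mirror the STFT/Mel configuration; ``transform`` accepts a
    list of :class:`~botopam.audio_io.Segment` or an ``(n, 480000)`` array
    and returns an ``(n, 512, 128)`` float32 array of equalized log-Mel
    matrices.  The transform is stateless, so ``fit`` is a no-op kept for
    pipeline compatibility.
    """

    window_samples: int = WINDOW_SAMPLES
    overlap_samples: int = OVERLAP_SAMPLES
    n_mels: int = N_MEL_BANDS
    log_floor: float = LOG_FLOOR
    mel_variant: str = "htk"
    mel_norm: str | None = None
    _filterbank: np.ndarray = field(default=None, repr=False, compare=False)
    _support_hz: np.ndarray = field(default=None, repr=False, compare=False)

    def get_params(self, deep: bool = True) -> dict:
        return {
            "window_samples": self.window_samples,
            "overlap_samples": self.overlap_samples,
            "n_mels": self.n_mels,
            "log_floor": self.log_floor,
            "mel_variant": self.mel_variant,
            "mel_norm": self.mel_norm,
        }

    def set_params(self, **params) -> "MelFrontEnd":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        self._filterbank = None
        return self

    def _ensure_filterbank(self) -> None:
        if self._filterbank is None:
            self._filterbank, self._support_hz = mel_filterbank(
                n_mels=self.n_mels, variant=self.mel_variant, norm=self.mel_norm
            )

    def fit(self, X=None, y=None) -> "MelFrontEnd":
        self._ensure_filterbank()
        return self

    def transform_segment(self, seg: Segment | np.ndarray) -> MelMatrix:
        self._ensure_filterbank()
        psd = compute_psd(seg)
        mel = mel_project(psd, self._filterbank, self._support_hz)
        return equalize(mel)

    def transform(self, X) -> np.ndarray:
        mats = [self.transform_segment(seg).values for seg in X]
        return np.stack(mats).astype(np.float32)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit().transform(X)
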