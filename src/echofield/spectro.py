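"""From binaural time-domain echoes to the training representation.

The phase-less observation a bat-like receiver has access to is modeled as
the magnitude of the short-time Fourier transform of each ear signal,
restricted to the call band, stacked binaural (left block on top), dechirped
by the emitted sweep's time-frequency law (a semi-coherent matched filter:
pulse compression on magnitudes, phase discarded), and logarithmically
compressed to [0, 1].  Each time column maps to a one-way range
r = v_s * t / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .echosim import Call, EchoSignal

__all__ = [
    "CompressionConfig",
    "SpectroConfig",
    "BinauralSpectrogram",
    "stft_magnitude",
    "binaural_concat",
    "dechirp",
    "compress",
    "make_observation",
    "make_ensemble_observations",
]


@dataclass(frozen=True)
class CompressionConfig:
    """Logarithmic compression with linear rescaling to [0, 1].

    ``floor_db``/``ceiling_db`` are relative to the reference amplitude (the
    ensemble maximum, so every observation of a training set shares one
    scale).  ``epsilon`` guards log(0); the default places C(0) exactly at
    the floor, i.e. maps silence to 0.
    """

    floor_db: float = -60.0
    ceiling_db: float = 0.0
    epsilon: float | None = None

    def __post_init__(self):
        if self.ceiling_db <= self.floor_db:
            raise ValueError("ceiling_db must exceed floor_db")
        if self.epsilon is None:
            object.__setattr__(self, "epsilon", 10.0 ** (self.floor_db / 20.0))
        elif self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class SpectroConfig:
    """STFT and range-axis parameters.

    Defaults (Hann window of 64 samples, hop 3 at 400 kHz) give ~470 range
    columns over the default 0.6 m max range.
    """

    window_len: int = 64
    overlap: float = 1.0 - 3.0 / 64.0
    compression: CompressionConfig = dc_field(default_factory=CompressionConfig)

    def __post_init__(self):
        if self.window_len < 8:
            raise ValueError("window_len must be >= 8")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must be in [0, 1)")

    @property
    def hop(self) -> int:
        return max(1, round(self.window_len * (1.0 - self.overlap)))


@dataclass
class BinauralSpectrogram:
    """Compressed dechirped binaural magnitude spectrogram.

    ``values`` is [2*N_f x N_t] in [0, 1]; rows 0..N_f-1 are the left ear,
    N_f..2N_f-1 the right.  ``ranges`` are one-way ranges r = v_s * t / 2 for
    each column.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    ranges: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 2 * self.freqs.size:
            raise ValueError("values must have 2*N_f rows")
        if self.values.shape[1] != self.times.size or self.times.size != self.ranges.size:
            raise ValueError("time/range axes must match column count")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("compressed values must lie in [0, 1]")
        if np.any(np.diff(self.ranges) <= 0):
            raise ValueError("ranges must be strictly increasing")

    @property
    def n_f(self) -> int:
        return self.freqs.size

    @property
    def n_t(self) -> int:
        return self.times.size

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        return self.values[: self.n_f], self.values[self.n_f :]


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def stft_magnitude(signal, sample_rate: float, window_len: int, overlap: float,
                   band: tuple[float, float], n_bins: int):
    """Magnitude STFT restricted to ``n_bins`` uniform band-bin centers.

    Returns (mag [n_bins x N_t], band_freqs, times).  STFT rows are linearly
    interpolated onto the band grid.  Column times are window centers
    relative to signal start.
    """
    f_lo, f_hi = band
    if window_len < 8:
        raise ValueError("window_len must be >= 8")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    if not (0 < f_lo < f_hi):
        raise ValueError("band must satisfy 0 < f_lo < f_hi")
    if f_hi > sample_rate / 2:
        raise ValueError("band exceeds Nyquist frequency")
    signal = np.asarray(signal, dtype=float)
    hop = max(1, round(window_len * (1.0 - overlap)))
    sft = ShortTimeFFT(hann(window_len, sym=False), hop=hop, fs=sample_rate)
    z = sft.stft(signal)
    mag = np.abs(z)
    stft_freqs = sft.f
    times = sft.t(signal.size)
    band_freqs = np.linspace(f_lo, f_hi, n_bins)
    out = np.empty((n_bins, mag.shape[1]))
    for j in range(mag.shape[1]):
        out[:, j] = np.interp(band_freqs, stft_freqs, mag[:, j])
    return out, band_freqs, times


def binaural_concat(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Stack left over right into a [2*N_f x N_t] binaural block."""
    left = np.asarray(left)
    right = np.asarray(right)
    if left.shape != right.shape:
        raise ValueError(f"shape mismatch: {left.shape} vs {right.shape}")
    return np.vstack([left, right])


def dechirp(spec: np.ndarray, call: Call, col_dt: float) -> np.ndarray:
    """Shift each frequency row left by the sweep delay at that frequency.

    Delays are converted to whole columns (nearest rounding; magnitude data
    carries no sub-sample phase).  Works on single-ear [N_f x N_t] or
    binaural [2*N_f x N_t] blocks — both ear blocks shift identically.
    Vacated trailing columns are zero-filled.
    """
    spec = np.asarray(spec, dtype=float)
    band = call.band_freqs
    n_rows = spec.shape[0]
    if n_rows == band.size:
        row_freqs = band
    elif n_rows == 2 * band.size:
        row_freqs = np.concatenate([band, band])
    else:
        raise ValueError("spectrogram rows must be N_f or 2*N_f for the call band")
    shifts = np.rint(call.delta_t(row_freqs) / col_dt).astype(int)
    out = np.zeros_like(spec)
    n_t = spec.shape[1]
    for i, s in enumerate(shifts):
        if s <= 0:
            out[i] = spec[i]
        elif s < n_t:
            out[i, : n_t - s] = spec[i, s:]
    return out


def compress(x: np.ndarray, cfg: CompressionConfig, ref: float) -> np.ndarray:
    """C(x) = clip((20 log10(x/ref + eps) - floor) / (ceil - floor), 0, 1)."""
    if ref <= 0:
        raise ValueError("compression reference must be > 0")
    x = np.asarray(x, dtype=float)
    db = 20.0 * np.log10(x / ref + cfg.epsilon)
    return np.clip((db - cfg.floor_db) / (cfg.ceiling_db - cfg.floor_db), 0.0, 1.0)


def uncompress(y: np.ndarray, cfg: CompressionConfig, ref: float) -> np.ndarray:
    """Inverse of :func:`compress` where unclipped."""
    db = np.asarray(y, dtype=float) * (cfg.ceiling_db - cfg.floor_db) + cfg.floor_db
    return np.maximum(10.0 ** (db / 20.0) - cfg.epsilon, 0.0) * ref


# ---------------------------------------------------------------------------
# observation assembly
# ---------------------------------------------------------------------------

def _raw_observation(echo: EchoSignal, call: Call, cfg: SpectroConfig):
    """Uncompressed dechirped binaural magnitude plus axes."""
    band = (call.f_lo, call.f_hi)
    left, band_freqs, times = stft_magnitude(
        echo.left, echo.sample_rate, cfg.window_len, cfg.overlap, band, call.band_bins
    )
    right, _, _ = stft_magnitude(
        echo.right, echo.sample_rate, cfg.window_len, cfg.overlap, band, call.band_bins
    )
    both = binaural_concat(left, right)
    col_dt = float(times[1] - times[0]) if times.size > 1 else 1.0 / echo.sample_rate
    both = dechirp(both, call, col_dt)
    return both, band_freqs, times


def _finalize(both, band_freqs, times, call, cfg, ref, v_s, max_range):
    vals = compress(both, cfg.compression, ref)
    ranges = v_s * times / 2.0
    keep = ranges > 0
    if max_range is not None:
        keep &= ranges <= max_range
    meta = {
        "call": {
            "f_hi": call.f_hi, "f_lo": call.f_lo, "duration": call.duration,
            "law": call.law, "sample_rate": call.sample_rate,
            "band_bins": call.band_bins, "taper": call.taper,
        },
        "compression": {
            "floor_db": cfg.compression.floor_db,
            "ceiling_db": cfg.compression.ceiling_db,
            "epsilon": cfg.compression.epsilon,
            "ref": ref,
        },
        "stft": {"window_len": cfg.window_len, "overlap": cfg.overlap},
        "v_s": v_s,
    }
    return BinauralSpectrogram(
        vals[:, keep], band_freqs, times[keep], ranges[keep], meta
    )


def make_observation(echo: EchoSignal, call: Call, cfg: SpectroConfig | None = None,
                     ref: float | None = None, v_s: float = 343.0,
                     max_range: float | None = None) -> BinauralSpectrogram:
    """stft -> binaural concat -> dechirp -> compress, with range axis.

    ``ref`` is the compression reference amplitude (ensemble maximum); when
    None the observation's own peak magnitude is used (single-observation
    use).  Columns are cropped to (0, max_range] after dechirp; the time
    origin is emission start.
    """
    cfg = cfg or SpectroConfig()
    both, band_freqs, times = _raw_observation(echo, call, cfg)
    if ref is None:
        ref = float(both.max())
        if ref <= 0:
            ref = 1.0
    return _finalize(both, band_freqs, times, call, cfg, ref, v_s, max_range)


def make_ensemble_observations(echoes, call: Call, cfg: SpectroConfig | None = None,
                               v_s: float = 343.0,
                               max_range: float | None = None) -> list:
    """Process a set of echoes with one shared compression reference (the
    ensemble maximum raw magnitude), so all observations share a scale."""
    cfg = cfg or SpectroConfig()
    raws = [_raw_observation(e, call, cfg) for e in echoes]
    ref = max(float(r[0].max()) for r in raws)
    if ref <= 0:
        ref = 1.0
    return [_finalize(both, bf, t, call, cfg, ref, v_s, max_range)
            for both, bf, t in raws]
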