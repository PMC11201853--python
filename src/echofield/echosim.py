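"""Binaural echo synthesis for point-scatterer scenes.

The received signal at each ear is a linear sum over point reflectors: the
emitted FM call, filtered by the emitter directivity, the reflector's
reflection spectrum, the ear's head-related transfer function, delayed by the
full emitter->scatterer->ear path and (optionally) attenuated by geometric
spreading.  Synthesis is done in the frequency domain, where the per-path
filters multiply, then inverse-transformed to time.

Directivity: emitter and ears default to circular-piston models
(2 J1(ka sin t)/(ka sin t), normalized on-axis); a tabulated transfer
function over (azimuth, elevation, frequency) can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.signal.windows import tukey
from scipy.special import j1

from .scenes import Pose, Scene, body_to_world

__all__ = [
    "Call",
    "ErtfModel",
    "PistonErtf",
    "TableErtf",
    "SimConfig",
    "EchoSignal",
    "make_call",
    "ertf_gain",
    "simulate_echo",
    "write_wav",
]


# ---------------------------------------------------------------------------
# emitted call
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Call:
    """Broadband FM sweep descriptor plus its synthesized waveform.

    The dechirp delay law ``delta_t(f)`` gives, for each frequency in the
    band, the time after emission start at which the sweep passes through
    that frequency: 0 at ``f_hi`` and ``duration`` at ``f_lo`` for the
    descending sweeps used here.
    """

    f_hi: float
    f_lo: float
    duration: float
    law: str
    sample_rate: float
    band_bins: int
    waveform: np.ndarray
    taper: float = 0.2

    @property
    def band_freqs(self) -> np.ndarray:
        """Band bin centers, uniformly spanning [f_lo, f_hi] (ascending)."""
        return np.linspace(self.f_lo, self.f_hi, self.band_bins)

    @property
    def n_samples(self) -> int:
        return self.waveform.size

    def delta_t(self, freqs) -> np.ndarray:
        """Dechirp delay law: time at which the sweep crosses each frequency."""
        f = np.asarray(freqs, dtype=float)
        if self.law == "linear":
            dt = self.duration * (self.f_hi - f) / (self.f_hi - self.f_lo)
        elif self.law == "hyperbolic":
            # instantaneous frequency f(t) = f_hi*f_lo*T / (f_lo*T + (f_hi-f_lo)*t)
            dt = self.duration * self.f_lo * (self.f_hi - f) / (f * (self.f_hi - self.f_lo))
        else:
            raise ValueError(f"unknown sweep law: {self.law!r}")
        return np.clip(dt, 0.0, self.duration)


def make_call(
    f_hi: float = 100e3,
    f_lo: float = 40e3,
    duration: float = 1e-3,
    law: str = "linear",
    sample_rate: float = 400e3,
    band_bins: int = 47,
    taper: float = 0.2,
) -> Call:
    """Synthesize a descending FM sweep with a Tukey amplitude taper.

    The taper confines spectral leakage so nearly all call energy lies inside
    [f_lo, f_hi].  Duration is rounded to the nearest whole sample.
    """
    if not (f_hi > f_lo > 0):
        raise ValueError("need f_hi > f_lo > 0")
    if sample_rate <= 2 * f_hi:
        raise ValueError(
            f"sample_rate {sample_rate} violates Nyquist for f_hi {f_hi}"
        )
    if law not in ("linear", "hyperbolic"):
        raise ValueError(f"unknown sweep law: {law!r}")
    n = max(2, round(duration * sample_rate))
    duration = n / sample_rate
    t = np.arange(n) / sample_rate
    if law == "linear":
        k = (f_lo - f_hi) / duration
        phase = 2 * math.pi * (f_hi * t + 0.5 * k * t * t)
    else:
        # f(t) = f_hi / (1 + c*f_hi*t), descending hyperbolic sweep
        c = (f_hi - f_lo) / (f_hi * f_lo * duration)
        phase = 2 * math.pi * np.log1p(c * f_hi * t) / c
    w = tukey(n, taper)
    return Call(f_hi, f_lo, duration, law, sample_rate, band_bins, w * np.cos(phase), taper)


# ---------------------------------------------------------------------------
# directional transfer functions (emitter + ears -> ERTF)
# ---------------------------------------------------------------------------

def _piston_directivity(cos_angle: np.ndarray, radius: float, freqs: np.ndarray,
                        v_s: float) -> np.ndarray:
    """|2 J1(ka sin t)/(ka sin t)| piston directivity, 1 on-axis.

    ``cos_angle``: (...,) cosines of the off-axis angle; ``freqs``: (F,).
    Returns (..., F) real gains in [0, 1] (back hemisphere strongly
    attenuated by the same aperture law; the piston has no true back lobe, so
    rear gain is near zero but not exactly zero).
    """
    sin_t = np.sqrt(np.clip(1.0 - cos_angle**2, 0.0, 1.0))
    k = 2 * math.pi * np.asarray(freqs, dtype=float) / v_s
    x = k * radius * sin_t[..., None]
    out = np.ones_like(x)
    nz = x > 1e-12
    out[nz] = 2.0 * j1(x[nz]) / x[nz]
    # suppress rear hemisphere: taper by (1+cos)/2 so gain is continuous
    out = np.abs(out) * ((1.0 + cos_angle[..., None]) / 2.0)
    return out


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class ErtfModel:
    """Base class: combined emitter x ear directional gain per ear."""

    def gains(self, directions: np.ndarray, freqs: np.ndarray) -> np.ndarray:
        """Complex gains of shape (n_dir, n_freq, 2); [...,0]=left, [...,1]=right."""
        raise NotImplementedError

    ear_offsets = np.zeros((2, 3))  # body-frame ear positions (L, R)


@dataclass
class PistonErtf(ErtfModel):
    """Circular-piston emitter and two piston ears (parametric stand-in for a
    measured bat emission/hearing directivity).

    Ears sit at ``(0, +/-7 mm, +5 mm)`` in the body frame with their axes
    tilted ``+/-tilt`` in azimuth from forward; the model is left/right mirror
    symmetric.  On-axis gain is 1 at every frequency.
    """

    emitter_radius: float = 0.004
    ear_radius: float = 0.006
    ear_y: float = 0.007
    ear_z: float = 0.005
    tilt: float = math.radians(15.0)
    v_s: float = 343.0

    def __post_init__(self):
        self.ear_offsets = np.array(
            [[0.0, self.ear_y, self.ear_z], [0.0, -self.ear_y, self.ear_z]]
        )
        fwd = np.array([1.0, 0.0, 0.0])
        self._ear_axes = np.stack([_rot_z(self.tilt) @ fwd, _rot_z(-self.tilt) @ fwd])

    def gains(self, directions: np.ndarray, freqs: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        cos_e = d[:, 0]  # angle from forward axis
        he = _piston_directivity(cos_e, self.emitter_radius, freqs, self.v_s)
        out = np.empty((d.shape[0], freqs.size, 2))
        for ear in range(2):
            cos_r = d @ self._ear_axes[ear]
            hr = _piston_directivity(cos_r, self.ear_radius, freqs, self.v_s)
            out[:, :, ear] = he * hr
        # normalize so the on-axis combined gain is exactly 1 per frequency
        fwd = np.array([[1.0, 0.0, 0.0]])
        he0 = _piston_directivity(fwd[:, 0], self.emitter_radius, freqs, self.v_s)
        hr0 = _piston_directivity(
            fwd @ self._ear_axes[0], self.ear_radius, freqs, self.v_s
        )
        out /= (he0 * hr0)[..., None]
        return out.astype(complex)


class TableErtf(ErtfModel):
    """ERTF from a tabulated complex gain over (azimuth, elevation, frequency).

    ``table`` has shape (n_az, n_el, n_freq, 2).  Gains at query directions
    are linearly interpolated; azimuth/elevation follow the body frame
    (azimuth about +Z from forward, elevation toward +Z).
    """

    def __init__(self, azimuths, elevations, freqs, table, ear_offsets=None):
        self.azimuths = np.asarray(azimuths, dtype=float)
        self.elevations = np.asarray(elevations, dtype=float)
        self.freqs = np.asarray(freqs, dtype=float)
        table = np.asarray(table, dtype=complex)
        if table.shape != (self.azimuths.size, self.elevations.size, self.freqs.size, 2):
            raise ValueError("table shape must be (n_az, n_el, n_freq, 2)")
        self._interp_re = RegularGridInterpolator(
            (self.azimuths, self.elevations, self.freqs), table.real,
            bounds_error=False, fill_value=None)
        self._interp_im = RegularGridInterpolator(
            (self.azimuths, self.elevations, self.freqs), table.imag,
            bounds_error=False, fill_value=None)
        if ear_offsets is not None:
            self.ear_offsets = np.asarray(ear_offsets, dtype=float).reshape(2, 3)

    def gains(self, directions, freqs):
        d = np.atleast_2d(np.asarray(directions, dtype=float))
        norms = np.linalg.norm(d, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")
        freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
        az = np.arctan2(d[:, 1], d[:, 0])
        el = np.arcsin(np.clip(d[:, 2], -1, 1))
        nd, nf = d.shape[0], freqs.size
        pts = np.empty((nd * nf, 3))
        pts[:, 0] = np.repeat(az, nf)
        pts[:, 1] = np.repeat(el, nf)
        pts[:, 2] = np.tile(freqs, nd)
        g = self._interp_re(pts) + 1j * self._interp_im(pts)
        return g.reshape(nd, nf, 2)


def ertf_gain(model: ErtfModel, directions, freqs) -> np.ndarray:
    """Evaluate the combined emitter+ear gains E_L, E_R.

    Returns complex array (n_dir, n_freq, 2) with ear index 0 = left.
    """
    return model.gains(directions, freqs)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Simulation constants: speed of sound (m/s), additive noise floor
    (relative amplitude; 0 disables), max range (m, sets signal length),
    whether to apply 1/(d_out*d_back) round-trip spreading loss."""

    v_s: float = 343.0
    noise_floor: float = 0.0
    max_range: float = 0.6
    spreading_loss: bool = True
    noise_seed: int = 0

    def __post_init__(self):
        if self.v_s <= 0:
            raise ValueError("v_s must be > 0")
        if self.max_range <= 0:
            raise ValueError("max_range must be > 0")


@dataclass
class EchoSignal:
    """Binaural received pressure time series at a common sample rate."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right must have equal length")
        if not (np.all(np.isfinite(self.left)) and np.all(np.isfinite(self.right))):
            raise ValueError("echo signal must be finite")

    @property
    def n_samples(self) -> int:
        return self.left.size


def _signal_length(call: Call, cfg: SimConfig) -> int:
    n = math.ceil((2.0 * cfg.max_range / cfg.v_s) * call.sample_rate) + call.n_samples
    return n


def simulate_echo(scene: Scene, pose: Pose, call: Call, ertf: ErtfModel,
                  cfg: SimConfig | None = None) -> EchoSignal:
    """Synthesize the binaural echo of ``call`` from ``scene`` heard at ``pose``.

    Per scatterer i and ear: S_ear(w) += E_ear(psi_i, w) * H_p(eta_i, w)
    * spread_i * exp(-j w r_i / v_s) * S_e(w), where r_i is the full
    emitter->scatterer->ear path length.  The sum is inverse-transformed to a
    time series long enough to hold echoes out to ``cfg.max_range``.
    """
    cfg = cfg or SimConfig()
    if len(scene) < 1:
        raise ValueError("scene must be nonempty")
    import warnings

    if np.all(pose.position >= scene.bounds[0]) and np.all(pose.position <= scene.bounds[1]):
        warnings.warn("pose lies inside the scene bounds", stacklevel=2)

    n = _signal_length(call, cfg)
    freqs = np.fft.rfftfreq(n, d=1.0 / call.sample_rate)
    s_e = np.fft.rfft(call.waveform, n)

    positions = scene.positions  # (N, 3) world
    rel = positions - pose.position
    d_out = np.linalg.norm(rel, axis=1)
    if np.any(d_out <= 0):
        raise ValueError("scatterer coincides with the sensor position")
    # direction to each scatterer, in the body frame (for the ERTF)
    psi = (rel / d_out[:, None]) @ pose.rotation
    # incidence direction at the scatterer, world frame
    eta = rel / d_out[:, None]

    gains = ertf.gains(psi, freqs)  # (N, F, 2)

    # reflection spectra on the band bins, interpolated onto the FFT grid
    band = call.band_freqs
    refl = np.empty((len(scene), freqs.size), dtype=complex)
    for i, s in enumerate(scene.scatterers):
        h_band = s.reflectivity(eta[i], band)
        if s.spectrum is None and s.lobe_axis is None:
            refl[i] = h_band[0]
        else:
            refl[i] = np.interp(freqs, band, h_band.real) + 1j * np.interp(
                freqs, band, h_band.imag
            )

    ear_world = body_to_world(pose, ertf.ear_offsets)  # (2, 3)
    spec = np.zeros((2, freqs.size), dtype=complex)
    for ear in range(2):
        d_back = np.linalg.norm(positions - ear_world[ear], axis=1)
        r = d_out + d_back
        amp = 1.0 / (d_out * d_back) if cfg.spreading_loss else np.ones_like(r)
        phase = np.exp(-2j * math.pi * np.outer(r / cfg.v_s, freqs))
        spec[ear] = np.einsum(
            "s,sf,sf,sf->f", amp, gains[:, :, ear], refl, phase
        )
    spec *= s_e
    left = np.fft.irfft(spec[0], n)
    right = np.fft.irfft(spec[1], n)
    if cfg.noise_floor > 0:
        rng = np.random.default_rng(cfg.noise_seed)
        left = left + cfg.noise_floor * rng.standard_normal(n)
        right = right + cfg.noise_floor * rng.standard_normal(n)
    return EchoSignal(left, right, call.sample_rate)


def write_wav(echo: EchoSignal, path) -> None:
    """Export a binaural echo as a 2-channel 32-bit float WAV file."""
    from scipy.io import wavfile

    data = np.stack([echo.left, echo.right], axis=1).astype(np.float32)
    wavfile.write(str(path), int(echo.sample_rate), data)
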