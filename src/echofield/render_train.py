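"""Differentiable acoustic rendering and field training.

One dechirped spectrogram column at range r is predicted by integrating the
reflectivity field over a discretized constant-range hemisphere in front of
the sensor: per ear and frequency bin,

    S_ear(w) = sum_k  dOmega_k * F_Theta(P_k, v_k) * E_ear(psi_k, w) * e^{-j w 2r / v_s}

where P_k are hemisphere points at range r (world frame), v_k the unit
ensonification directions (sensor -> point), E_ear the combined
emitter-plus-ear directional gain evaluated in the body frame, and the
unimodular delay factor carries the round-trip travel phase (constant over
a hemisphere, hence inert under the magnitude — kept for fidelity).  The
magnitude of S is compressed exactly like the observations, so predicted and
measured range slices live on the same [0, 1] scale and a mean-squared-error
loss compares them directly.

The chain loss <- compression <- magnitude <- hemisphere sum <- MLP is
differentiated analytically; training is plain Adam over shuffled minibatches
of range slices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .echosim import Call, ErtfModel
from .field import (
    FieldConfig,
    FieldParams,
    decode_complex,
    field_backward,
    field_forward,
    init_field,
    normalize_positions,
)
from .scenes import Pose
from .spectro import BinauralSpectrogram, CompressionConfig

__all__ = [
    "HemisphereSamples",
    "RenderedSlice",
    "TrainConfig",
    "TrainingEnsemble",
    "hemisphere_samples",
    "render_slice",
    "render_spectrogram",
    "slice_loss",
    "train",
    "RenderContext",
]


# ---------------------------------------------------------------------------
# hemisphere discretization
# ---------------------------------------------------------------------------

def _hemisphere_dirs(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the forward (+X) hemisphere.

    Fibonacci lattice with the area coordinate mapped to [0, 1) so every
    point has a strictly positive forward component.
    """
    if n < 4:
        raise ValueError("need at least 4 hemisphere points")
    i = np.arange(n, dtype=float)
    x = 1.0 - (i + 0.5) / n  # cos(angle from +X), uniform in (0, 1)
    rho = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    th = math.pi * (3.0 - math.sqrt(5.0)) * i
    return np.column_stack([x, rho * np.cos(th), rho * np.sin(th)])


@dataclass
class HemisphereSamples:
    """Discretized constant-range hemisphere for one pose: world points,
    world ensonification directions, per-point solid-angle weights summing to
    2 pi."""

    points_world: np.ndarray
    directions: np.ndarray
    range: float
    weights: np.ndarray
    directions_body: np.ndarray


def hemisphere_samples(pose: Pose, r: float, n: int = 600) -> HemisphereSamples:
    """Sample the forward hemisphere of ``pose`` at range ``r``."""
    if r <= 0:
        raise ValueError("range must be > 0")
    db = _hemisphere_dirs(n)
    rot = pose.rotation
    dirs = db @ rot.T
    pts = pose.position + r * dirs
    w = np.full(n, 2.0 * math.pi / n)
    return HemisphereSamples(pts, dirs, float(r), w, db)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedSlice:
    """Predicted compressed binaural spectrum (94 values) at one range."""

    spectrum: np.ndarray
    range: float


class RenderContext:
    """Pose-independent precomputation for rendering: the body-frame
    hemisphere lattice and the ERTF gains on it (identical for every pose and
    range because the hemisphere is defined in the body frame)."""

    def __init__(self, call: Call, ertf: ErtfModel, n_hemisphere: int = 600,
                 compression: CompressionConfig | None = None,
                 ref: float = 1.0, v_s: float = 343.0):
        self.call = call
        self.ertf = ertf
        self.n = int(n_hemisphere)
        self.compression = compression or CompressionConfig()
        self.ref = float(ref)
        self.v_s = float(v_s)
        self.dirs_body = _hemisphere_dirs(self.n)
        self.weights = np.full(self.n, 2.0 * math.pi / self.n)
        self.band = call.band_freqs
        # E[k, w, ear], complex (K, 47, 2)
        self.ertf_gains = ertf.gains(self.dirs_body, self.band)
        # A[k, w, ear] = weight_k * E (delay factored in per slice)
        self.A = self.weights[:, None, None] * self.ertf_gains

    def delay(self, r) -> np.ndarray:
        """Unimodular round-trip delay factor per (slice, band bin)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        return np.exp(-2j * math.pi * np.outer(2.0 * r / self.v_s, self.band))


def _forward_slices(params: FieldParams, ctx: RenderContext,
                    rotations: np.ndarray, positions: np.ndarray,
                    ranges: np.ndarray, want_cache: bool = False):
    """Render a batch of B slices.

    rotations (B,3,3), positions (B,3), ranges (B,).  Returns compressed
    spectra (B, 94) and, when requested, the cache for the backward pass.
    """
    B = ranges.size
    K = ctx.n
    nf = ctx.band.size
    dirs_w = np.einsum("bij,kj->bki", rotations, ctx.dirs_body)  # (B,K,3)
    pts_w = positions[:, None, :] + ranges[:, None, None] * dirs_w
    cache = None
    if isinstance(params, FieldParams):
        pn = normalize_positions(pts_w.reshape(-1, 3), params.scene_bounds)
        x6 = np.concatenate([pn, dirs_w.reshape(-1, 3)], axis=1)
        if want_cache:
            y, cache = field_forward(params, x6, want_cache=True)
        else:
            y = field_forward(params, x6)
        F = decode_complex(y, nf).reshape(B, K, nf)
    else:
        # any callable (world positions, world directions) -> complex spectra,
        # e.g. analytic oracle fields
        if want_cache:
            raise TypeError("gradients require FieldParams, not a callable field")
        F = np.asarray(
            params(pts_w.reshape(-1, 3), dirs_w.reshape(-1, 3)), dtype=complex
        ).reshape(B, K, nf)
    delay = ctx.delay(ranges)  # (B, nf)
    # S[b, w, ear] = sum_k A[k, w, ear] F[b, k, w] * delay[b, w]
    S = np.einsum("kfe,bkf->bfe", ctx.A, F) * delay[:, :, None]
    M = np.abs(S)  # (B, nf, 2)
    cc = ctx.compression
    lin = M / ctx.ref + cc.epsilon
    db = 20.0 * np.log10(lin)
    raw = (db - cc.floor_db) / (cc.ceiling_db - cc.floor_db)
    psi = np.clip(raw, 0.0, 1.0)
    # pack per ear: left 47 then right 47
    spectra = np.concatenate([psi[:, :, 0], psi[:, :, 1]], axis=1)  # (B, 94)
    if not want_cache:
        return spectra
    fwd = {
        "cache": cache, "F": F, "S": S, "M": M, "lin": lin, "raw": raw,
        "delay": delay, "B": B, "K": K, "nf": nf,
    }
    return spectra, fwd


def _backward_slices(params: FieldParams, ctx: RenderContext, fwd: dict,
                     dpsi: np.ndarray):
    """Gradients of a scalar loss w.r.t. field parameters, given dL/dspectra
    (B, 94)."""
    B, K, nf = fwd["B"], fwd["K"], fwd["nf"]
    cc = ctx.compression
    dpsi3 = np.stack([dpsi[:, :nf], dpsi[:, nf:]], axis=2)  # (B, nf, 2)
    active = (fwd["raw"] > 0.0) & (fwd["raw"] < 1.0)
    dM = dpsi3 * active * (
        20.0 / (math.log(10.0) * fwd["lin"] * ctx.ref * (cc.ceiling_db - cc.floor_db))
    )
    M_safe = np.maximum(fwd["M"], 1e-300)
    g = dM * (fwd["S"] / M_safe)  # dL/dS, complex-packed (B, nf, 2)
    g = g * np.conj(fwd["delay"])[:, :, None]
    # dL/dF[b,k,w] = sum_e conj(A[k,w,e]) g[b,w,e]
    dF = np.einsum("kfe,bfe->bkf", np.conj(ctx.A), g)
    dy = np.concatenate(
        [np.real(dF).reshape(B * K, nf), np.imag(dF).reshape(B * K, nf)], axis=1
    )
    return field_backward(params, fwd["cache"], dy)


def render_slice(params: FieldParams, pose: Pose, r: float, ertf: ErtfModel,
                 call: Call, compression: CompressionConfig | None = None,
                 ref: float = 1.0, v_s: float = 343.0,
                 n_hemisphere: int = 600,
                 ctx: RenderContext | None = None) -> RenderedSlice:
    """Render the compressed binaural spectrum for one range slice."""
    if ctx is None:
        ctx = RenderContext(call, ertf, n_hemisphere, compression, ref, v_s)
    spectra = _forward_slices(
        params, ctx,
        pose.rotation[None], pose.position[None], np.array([float(r)]),
    )
    return RenderedSlice(spectra[0], float(r))


def render_spectrogram(params: FieldParams, pose: Pose, ranges, ertf: ErtfModel,
                       call: Call, compression: CompressionConfig | None = None,
                       ref: float = 1.0, v_s: float = 343.0,
                       n_hemisphere: int = 600, times=None,
                       batch: int = 64) -> BinauralSpectrogram:
    """Render a full spectrogram column-by-column along ``ranges``."""
    ranges = np.asarray(ranges, dtype=float)
    ctx = RenderContext(call, ertf, n_hemisphere, compression, ref, v_s)
    cols = []
    rot = pose.rotation[None]
    pos = pose.position[None]
    for start in range(0, ranges.size, batch):
        rs = ranges[start : start + batch]
        B = rs.size
        spectra = _forward_slices(
            params, ctx, np.repeat(rot, B, axis=0), np.repeat(pos, B, axis=0), rs
        )
        cols.append(spectra)
    values = np.concatenate(cols, axis=0).T  # (94, N_t)
    if times is None:
        times = 2.0 * ranges / v_s
    return BinauralSpectrogram(
        values, ctx.band, np.asarray(times, dtype=float), ranges,
        meta={"rendered": True, "compression": {
            "floor_db": ctx.compression.floor_db,
            "ceiling_db": ctx.compression.ceiling_db,
            "epsilon": ctx.compression.epsilon,
            "ref": ref,
        }, "v_s": v_s},
    )


def slice_loss(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Mean squared error between predicted and measured 94-vectors."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    measured = np.asarray(measured, dtype=float).ravel()
    if predicted.size != measured.size:
        raise ValueError("predicted/measured length mismatch")
    d = predicted - measured
    return float(np.mean(d * d))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and sampling settings: Adam with per-epoch multiplicative
    learning-rate decay; each training sample is one (pose, range-slice)
    pair."""

    batch_size: int = 512
    lr: float = 0.01
    lr_drop: float = 0.97
    epochs: int = 100
    seed: int = 0
    n_hemisphere: int = 600
    loss: str = "mse"

    def __post_init__(self):
        if not (0.0 < self.lr_drop <= 1.0):
            raise ValueError("lr_drop must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss != "mse":
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainingEnsemble:
    """Aligned (pose, spectrogram) pairs plus the shared acquisition
    metadata (call, compression reference, speed of sound)."""

    poses: list
    spectrograms: list
    call: Call
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if len(self.poses) != len(self.spectrograms):
            raise ValueError("poses and spectrograms must pair up")
        if len(self.poses) == 0:
            raise ValueError("ensemble must be nonempty")
        s0 = self.spectrograms[0]
        for s in self.spectrograms[1:]:
            if s.values.shape != s0.values.shape or not np.allclose(s.ranges, s0.ranges):
                raise ValueError("all spectrograms must share axes")

    @property
    def n_slices(self) -> int:
        return len(self.poses) * self.spectrograms[0].n_t

    def compression_config(self) -> CompressionConfig:
        c = self.spectrograms[0].meta.get("compression", {})
        return CompressionConfig(
            floor_db=c.get("floor_db", -60.0),
            ceiling_db=c.get("ceiling_db", 0.0),
            epsilon=c.get("epsilon", None),
        )

    @property
    def ref(self) -> float:
        return float(self.spectrograms[0].meta["compression"]["ref"])

    @property
    def v_s(self) -> float:
        return float(self.spectrograms[0].meta.get("v_s", 343.0))


class _Adam:
    def __init__(self, shapes, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, tensors, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(tensors, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state(self) -> dict:
        out = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state(self, state: dict):
        self.t = int(state["t"])
        for i in range(len(self.m)):
            self.m[i] = np.asarray(state[f"m{i}"], dtype=float)
            self.v[i] = np.asarray(state[f"v{i}"], dtype=float)


def train(ensemble: TrainingEnsemble, field_cfg: FieldConfig,
          train_cfg: TrainConfig, scene_bounds=None,
          init: FieldParams | None = None, optimizer_state: dict | None = None,
          start_epoch: int = 0, callback=None) -> FieldParams:
    """Fit the reflectivity field to a training ensemble.

    Every (pose, range-slice) pair is one sample, including empty slices
    (they supervise free space toward zero reflectivity).  Epochs shuffle
    the slice order with a seed derived from (train seed, epoch), so a run
    resumed from a checkpoint at epoch k reproduces the un-resumed run.
    Returns trained parameters; the per-epoch mean loss history lives in
    ``params.meta['loss_curve']``.
    """
    spects = ensemble.spectrograms
    poses = ensemble.poses
    n_poses = len(poses)
    n_t = spects[0].n_t
    ranges_axis = spects[0].ranges

    if scene_bounds is None and init is not None:
        scene_bounds = init.scene_bounds
    if scene_bounds is None:
        # fall back to the volume swept by the observation ranges around poses
        pts = np.array([p.position for p in poses])
        c = pts.mean(axis=0)
        r = float(ranges_axis.max())
        scene_bounds = np.stack([c - r, c + r])

    params = init.copy() if init is not None else init_field(field_cfg, scene_bounds)
    if params.scene_bounds is None:
        params.scene_bounds = np.asarray(scene_bounds, dtype=float).reshape(2, 3)

    ctx = RenderContext(
        ensemble.call, ensemble.meta["ertf"], train_cfg.n_hemisphere,
        ensemble.compression_config(), ensemble.ref, ensemble.v_s,
    )

    rotations = np.stack([p.rotation for p in poses])
    positions = np.stack([p.position for p in poses])
    targets = np.stack([s.values for s in spects])  # (P, 94, N_t)

    pose_idx, col_idx = np.meshgrid(
        np.arange(n_poses), np.arange(n_t), indexing="ij"
    )
    pose_idx = pose_idx.ravel()
    col_idx = col_idx.ravel()
    n_samples = pose_idx.size

    tensors = params.weights + params.biases
    opt = _Adam([t.shape for t in tensors])
    if optimizer_state is not None:
        opt.load_state(optimizer_state)

    loss_curve = list(params.meta.get("loss_curve", []))
    out_dim = 2 * field_cfg.n_freq_bins
    for epoch in range(start_epoch, train_cfg.epochs):
        lr = train_cfg.lr * (train_cfg.lr_drop ** epoch)
        order = np.random.default_rng((train_cfg.seed, epoch)).permutation(n_samples)
        epoch_loss = 0.0
        for start in range(0, n_samples, train_cfg.batch_size):
            sel = order[start : start + train_cfg.batch_size]
            pi = pose_idx[sel]
            ci = col_idx[sel]
            rs = ranges_axis[ci]
            meas = targets[pi, :, ci]  # (B, 94)
            spectra, fwd = _forward_slices(
                params, ctx, rotations[pi], positions[pi], rs, want_cache=True
            )
            diff = spectra - meas
            batch_loss = float(np.mean(diff * diff))
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (batch starting {start}); "
                    f"lr={lr:.3g}, |params|max="
                    f"{max(np.abs(t).max() for t in tensors):.3g}"
                )
            epoch_loss += batch_loss * sel.size
            dpsi = (2.0 / (sel.size * out_dim)) * diff
            gw, gb = _backward_slices(params, ctx, fwd, dpsi)
            opt.step(tensors, gw + gb, lr)
        epoch_loss /= n_samples
        loss_curve.append(epoch_loss)
        if callback is not None:
            callback(epoch, epoch_loss, lr, params, opt)
    params.meta["loss_curve"] = loss_curve
    params.meta["epochs"] = train_cfg.epochs
    params.meta["train_seed"] = train_cfg.seed
    params.meta["n_hemisphere"] = train_cfg.n_hemisphere
    params.meta["compression_ref"] = ensemble.ref
    return params
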