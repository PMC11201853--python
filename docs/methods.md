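# Methods

This note documents the model implemented in `echofield`, the choices made
where the design was genuinely open, and what the synthetic data does and
does not establish.

## Echo formation model

Scenes are collections of point-like reflectors (Huygens approximation);
extended surfaces are dense point samplings (Fibonacci lattices on spheres,
sunflower lattices on discs, area-weighted sampling of STL meshes). For a
sensor pose with body→world rotation R (intrinsic yaw–pitch–roll, forward =
+X, left = +Y, up = +Z — the convention is ours; any fixed right-handed one
would do), the received spectrum per ear is a linear sum over reflectors:

    S_ear(ω) = Σ_i E_ear(ψ_i, ω) · H_p(η_i, ω) · a_i · e^{-jω r_i / v_s} · S_e(ω)

* ψ_i — direction to reflector i in the body frame; η_i — incidence
  direction at the reflector (world frame).
* E_ear = H_emitter · H_ear, the per-ear ERTF. The default is a parametric
  stand-in: a circular-piston emitter (radius 4 mm) and two piston ears
  (radius 6 mm) at (0, ±7 mm, +5 mm), tilted ±15° in azimuth, each
  normalized to unit on-axis gain, with a smooth (1+cosθ)/2 rear-hemisphere
  taper (a piston has no meaningful back lobe). Measured directivity tables
  over (azimuth, elevation, frequency) can be supplied instead.
* H_p — the reflector's complex spectrum: flat `gain`, a per-band-bin
  table, and/or a cosine-power lobe in the incidence direction.
* r_i — the full emitter→reflector→ear path length; the phase term is
  implemented as a causal delay e^{-jωr/v_s}. Delays are always round-trip.
* a_i — geometric spreading 1/(d_out · d_back), on by default;
  `SimConfig(spreading_loss=False)` gives the strict constant-amplitude
  variant of the formation equations. Atmospheric absorption is
  deliberately omitted. No multi-path, occlusion or Doppler (see
  Limitations).

The emitted call is a single-harmonic descending FM sweep (default 100→40
kHz, 1 ms, linear; hyperbolic available) with a Tukey(0.2) amplitude taper
confining spectral leakage. Multi-harmonic calls are out of scope; the
dechirp law below is only unambiguous for one harmonic.

## Observation pipeline

Each ear signal goes through: Hann STFT magnitude (64-sample window; hop 3,
i.e. ~95% overlap, chosen so the default 0.6 m max range yields ~470 range
columns) → linear interpolation of the STFT rows onto 47 uniform band bins
spanning [f_lo, f_hi] → vertical binaural stack (left on top, 94 rows) →
dechirping: each frequency row is advanced by the sweep's delay law
Δt(ω) rounded to whole columns (magnitude data carries no sub-sample
phase) → logarithmic compression

    C(x) = clip( (20·log10(x/ref + ε) − floor) / (ceil − floor), 0, 1 )

with floor −60 dB, ceiling 0 dB, and ε = 10^(floor/20) so that C(0) = 0
exactly and the map stays differentiable near silence. The reference
amplitude `ref` is the maximum over a training ensemble, so all
observations of a set share one scale; it is stored in metadata and reused
when rendering. Columns map to one-way range r = v_s·t/2 with the time
origin at emission start.

## Reflectivity field

F_Θ is an MLP with leaky-ReLU (slope 0.01) hidden layers. Inputs are 6
scalars — voxel position normalized to [−1,1] by the scene bounding box,
plus the unit direction from which the voxel is ensonified (sensor →
voxel). Each scalar is lifted to 30 Fourier features (15 octave-spaced
sin/cos pairs, 180 features total). The frequency band is π·2⁻⁷ … π·2⁷:
the top of the band resolves sub-centimeter structure at the scenes' scale
while still interpolating between training poses — extending the band
upward makes the network oscillate freely in the angular gaps between
poses and held-out prediction collapses, which is why the band is deliberately
capped. The output is 94 values decoded as 47 real + 47 imaginary parts of
the complex reflection spectrum.

The default hidden profile [256, 256, 256, 256, 280, 256], with the
embedding depth-concatenated into the input of layer 4, gives 462,166
learnable parameters (the architecture is specified only up to its ~5·10⁵
total; the profile is config-overridable). Initialization is seeded He
(leaky-ReLU gain) with the output layer scaled down (σ = 0.01/√fan_in) so
the untrained field predicts near-silence — this keeps the compressed
rendering off its clipped plateaus, where gradients vanish, at the start
of training.

## Rendering and training

One spectrogram column at range r is rendered by summing the field over a
600-point (default) Fibonacci lattice on the forward hemisphere, weighted
ΔΩ = 2π/n, multiplied by the ERTF at the body-frame lattice directions and
the unimodular round-trip delay factor, then magnitude and compression.
The delay factor is constant over a hemisphere and therefore inert under
the magnitude; it is kept for structural fidelity and tested to be inert.
Because the hemisphere lattice is fixed in the body frame, the ERTF factor
is precomputed once per configuration.

Training data is every (pose, range column) pair — empty columns included:
they supervise free space toward zero reflectivity. The loss is mean
squared error on compressed 94-vectors (the photometric-loss analog; the
method does not prescribe a particular loss). The optimizer is Adam,
batch 512, learning rate 0.01 with a ×0.97 drop applied once per epoch
(the drop period is our reading), 100 epochs at full scale. All data is
used for fitting; held-out poses are generated separately for evaluation
only. Forward and backward passes through the full chain (MLP → hemisphere
sum → magnitude → compression → loss) are explicit numpy; the backward
pass treats clipped compression outputs as zero-gradient and is verified
against central finite differences to ~10⁻⁶ relative. Epoch shuffling is
seeded per (seed, epoch), so a run resumed from a checkpoint (which stores
the Adam moments) reproduces the uninterrupted run exactly.

## Reconstruction

The trained field is queried on a cubic voxel grid × a full-sphere
Fibonacci direction set (default 100 directions); per (voxel, direction)
the stored value is the band energy Σ_ω |F_Θ|² ("reflectivity value" is
not given a norm by the method; band energy matches the energy-difference
analysis). Summing over directions gives Rs; geometry is the
marching-cubes isosurface at 0.5×max (the threshold is unspecified
upstream and configurable), visualization is maximum-intensity projection,
and paired scenes are compared by the signed difference of their Rs
volumes normalized to the joint maximum. The reference 0.5 mm voxel at
0.3–0.6 m scene scale is not CPU-feasible with 100 directions; the desk
default is 5 mm and the grid refuses to allocate past a configurable
memory budget instead of thrashing.

## Synthetic data and what the tests show

All experiments are simulation: the point-scatterer synthesizer generates
the training ensembles (the study conditions: poses quasi-uniform on a
sphere of 0.3–0.6 m radius about the scene; 100 poses per scene at full
scale, 400 supported; three-sphere L, 19-sphere "UA", and leaf ± insect
scenes — letter and L dimensions are plausible reconstructions, not
reference values). The simulator shares the formation equations with the
renderer but not the code path: the renderer-vs-simulator agreement is
checked through an analytic delta field at a lone scatterer (2.2% relative
after matched normalization, flat-envelope probe). What passing tests do
not show: behavior under multi-path echoes between scene elements, surface
shadowing, atmospheric absorption, sensor noise (available but off by
default), or measured bat directivities — real echoes contain all of
these, and the clean simulator is an easier world than any experiment.

Desk-scale study sizes (chosen for single-CPU runtimes, stated here as the
package's reference configuration): one 3 cm sphere / leaf scenes, 24
training poses at 0.3 m, 2×64 field, 128-point hemispheres, hop-8 STFT
(~122 range columns at 0.42 m max range), batch 64, 20 epochs. Under these
conditions: final training loss ≈ 8% of the first epoch's, held-out
Pearson r ≈ 0.94–0.96, energy-peak error < 1 cm, isosurface bounding
radius ≈ 3.7–4.0 cm (inflation, expected from semi-coherent compression),
and the leaf±insect difference volume peaks within 0.5–2 cm of the insect
across seeds.

## Numerical notes and degenerate inputs

* Compression clip boundaries carry zero gradient; |S| = 0 is guarded.
* Dechirp uses nearest-column shifts; double rounding (STFT grid + shift)
  makes a ±1-column jitter of per-row ridge positions unavoidable.
* Flat energy volumes yield an empty mesh plus a warning; thresholds at or
  above the maximum yield an empty mesh.
* A pose inside the scene bounds is allowed but warned about; scatterers
  behind the sensor contribute through the (near-zero) ERTF rear taper.
* Non-finite training loss aborts with the epoch/batch and parameter-scale
  diagnostics rather than continuing.

## Limitations

No multi-path rendering term (the rendering equation is single-bounce by
construction), no occlusion, no cochlear filter bank (uniform, not
logarithmic, frequency spacing), no measured ERTFs shipped, no trained
weights shipped, and no real-world measurements — the package is a
simulation testbed for the reconstruction-through-prediction hypothesis,
not a validated sensor pipeline.
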