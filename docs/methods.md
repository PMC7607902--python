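# Methods

## Physical model

The slow-wave (ECA) source is idealised as an annular depolarization band on
the wall of a tubular organ, represented by a surface double layer of
electric dipoles. The volume conductor is unbounded and homogeneous with
permittivity ε; abdominal-wall heterogeneity, skin–electrode coupling and
spike (ERA) activity are outside the model. Under these assumptions the
potential at a point E from a dipole of moment **P** at position **c** is
(1/4πε) **P**·ρ/|ρ|³ with ρ = E − **c**, and the band potential is the plain
superposition over its dipoles. The simulator therefore guarantees exact
linearity in |P| and 1/ε, superposition over disjoint band segments, and
rigid-motion invariance of the differential signal — all of which are tested.

## Surface construction

The organ is described only by its centerline: N ordered 3D points C_n with
per-point radii r_n (all lengths in centimetres internally; builders accept
metre-valued inputs and log the conversion). At each C_n a circle of M
vertices is placed in the plane perpendicular to the segment C_n → C_{n+1};
the final circle reuses the last segment's direction. Orientation uses the
elevation/azimuth two-angle rotation R_z(β)·R_y(γ) built from the
full-quadrant arctangent; for vertical segments, where the azimuth is
undefined, the previous circle's azimuth is reused so the circumferential
parameterisation does not flip along the tube. The construction is validated
by its geometric postconditions — every vertex at distance r_n from C_n, the
circle plane perpendicular to the segment to ≤ 1e−9·r_n, rotations
orthonormal and proper to 1e−12 — rather than by any particular formula
transcription, because the commonly printed two-rotation recipe does not map
the circle normal onto the segment direction even for a pure +z segment.

One consequence of anchoring the azimuth to the global x-axis is that vertex
labelling is equivariant only under translations and rotations about z;
under a general rotation the swept *surface* is equivariant (each ring maps
onto the rotated ring as a circle) but individual vertices shift phase. The
potential of a built mesh is rigid-motion invariant regardless, and all
three properties are tested separately.

Adjoining circles are joined into M quads per ring (the circumferential
index wraps). Each quad's area vector is the cross product of its two edges
leaving corner (m, n) — a one-sided parallelogram estimate, first order in
the ring width, whose summed magnitude converges to the lateral frustum area
as both directions refine (≤ 0.1% at M = 100 on the cylinder fixture's ring
geometry). The dipole sits at the midpoint of the quad's diagonal corners,
directed along the quad normal with a configurable inward/outward sign, with
moment magnitude |P| × the circumferential chord, so a full ring at radius r
carries total moment |P|·2πr (matching the conventional cylinder model's
surface density |D| = |P|/δ for band width δ). Degenerate (zero-area) quads
from pinched meshes carry no dipole and emit a warning rather than failing.

## Polarity convention

The sign of the published waveforms is not recoverable, and the classical
formulations are internally inconsistent about it (a leading minus combined
with an inward-dipole numerator). `eggsim` fixes one convention everywhere:
inward dipoles with a positive 1/4πε prefactor, under which a single
electrode sees a positive excursion as the band passes, and the differential
V = V1 − V0 of the cylinder benchmark dips at the reference station and
crests at the measurement station — the described approach/recede behaviour.
Both analytic reference models are implemented in the same convention so
that cross-model comparisons are meaningful. The `orientation` flag flips
the sign globally if the opposite convention is preferred.

## Band motion

The band occupies the rings whose axial midpoint falls in [s(t), s(t) + w);
with the default band width of one ring width, the nearest ring is used when
the window straddles midpoints, so an on-tube band is never empty and a fine
time sweep visits every ring exactly once per cycle. Two closed-form motion
laws are provided: constant-speed periodic traversal (position l·(f/60)·t
mod l; f in cycles/min) and the exponentially saturating conoidal law
v(t) = 0.00825 − 0.00575·e^(−0.362 t), integrated in closed form and checked
against numerical quadrature to 1e−8. The conoidal law is dimensionally
interpreted as metres/second and scaled ×100 to the centimetre mesh (the
`unit_scale` parameter); its cycle period is the root of l(T) = path length,
and the next cycle restarts immediately (configurable dwell, default 0).
Band states are evaluated exactly at the sample instants (default SR 10 Hz);
no sub-step integration is needed since the laws are closed-form.

## Analytic reference models

*Mathematical cylinder model.* The band is a thin ring of radial dipoles on
an upright cylinder; the potential is a double integral over the band angle
Θ and axial extent [z(t), z(t)+δ], evaluated by periodic trapezoid (Θ,
default 720 points — spectrally accurate for periodic integrands) × Simpson
(z, default 64 intervals). The classical integrand carries an extra slant
weight z/√(R0²+z²) beyond what plain dipole superposition gives for a
cylinder; it is kept, as it is part of the model being reproduced. At the
cylinder benchmark's electrode station (z ≈ 4 cm, R0 = 1.25 cm) this weight
is ≈ 0.954, which bounds the achievable amplitude agreement with the meshed
model to ~5% while leaving the waveform correlation above 0.999; values very
near the origin (z ≈ 0), where the weight collapses, trigger a warning.

*Conoidal dipole model.* The band center sits at distance R from the origin
at elevation α(t) = l(t)/R in the yz-plane; the band circle of radius r(t)
lies in the plane spanned by the origin direction and the x-axis, which
reproduces the model's sub-expressions exactly: the chord
OL = √(R² + r² − 2Rr cos θ), the azimuth φ = arcsin(r sin θ / OL) (argument
clamped within 1e−12; beyond that a numeric error is raised), and the
electrode distance ρ² = OL² + OQ² − 2·OL·OQ·cos(φ−φ_c)cos(α_c−α) — exact for
electrodes in the yz-plane (φ_c = 0), the benchmark case. The potential is a
single periodic-trapezoid θ-integral of the inward band-radial dipole term
with the model's prefactor |P|·δ·r(t)·α(t)·tan α_c; the widely reproduced
closed form of this integral is typographically corrupted, so the
implementation is built from the sub-expressions above and cross-checked
against the meshed model rather than against the unreadable layout (a stray
θ sometimes shown under the denominator is treated as a typesetting
artifact). Electrodes at elevation α_c = ±π/2 are rejected as singular. The
`update_rate` option refreshes the band angles at a coarser cadence
(zero-order hold) to expose the conventional method's sensitivity to the
"centerline sampling rate"; reproducing its divergence artifact
quantitatively is not a goal.

Cartesian electrode positions are converted to each model's native
coordinates — cylindrical (z_p, h, θ) and conoid (OQ, φ_c, α_c) — with
round-trip-tested conversions.

## Benchmark scenarios

All three generators are deterministic (no randomness anywhere in the
package) and validated so that both electrodes keep at least 1e−3 cm from
every microregion center.

*Cylinder.* l = 0.10 m → 10 cm along +z, constant radius 1.25 cm, N = 910
circles (ring width 10/909 cm = 0.00011 m), M = 100, |P| = 0.45e−7 C/cm,
ε = 2.65e−8 C²/(N·cm²), constant-speed motion at f = 5.4 cycles/min,
electrodes on the axis at z = 4.0 (reference) and 4.2 cm (measurement) — the
printed coordinates interpreted in the geometry's converted unit; on-axis
interior points are legitimate in a homogeneous medium.

*Conoid.* Arc of radius R = 10 cm in the yz-plane starting on the y-axis,
span 1.5 rad (path 15 cm), N = 201, M = 100, tube radius tapering 3.0 → 1.0
cm (taper endpoints are not part of the classical parameter set; these keep
the printed electrodes (0, 4.8, 10.9)/(0, 3.8, 11.1) clear of the surface by
≈ 0.4 cm), |P| = 2.2e−6 C/cm, ε = 2.21e−8 C²/(N·cm²), exponential motion.
The 1.5 rad span makes one traversal ≈ 20.1 s, so successive cycle turns —
where the conventional model's trace is discontinuous — fall near 20/40/60 s.

*Pseudocolon.* A parametric spline emulation of a colon silhouette:
ascending, transverse and descending limbs, two sharp flexures, out-of-plane
y-displacement; the 81-point polyline is rescaled to exactly 15 cm. The tube
radius oscillates sinusoidally between 1.5 and 2.5 cm with 4 full periods,
chosen (a) so the 81-sample grid hits both extrema exactly and (b) because
the haustra-like waviness tilts the microregion normals back and forth,
which is what makes the simulated potential alternate in sign several times
per cycle near the electrodes — with a nearly smooth tube the trace is
merely biphasic. No motion law is part of this geometry's definition; the
band moves at a constant 5.4 cycles/min (one ECA cycle per traversal).
Electrodes sit above the hepatic-flexure region at (3.19, 0.25, 7.36) and
(2.62, 0.25, 7.33) cm. Users can substitute any `x,y,z,r` CSV centerline.

## Numerical choices and limitations

- Singularity guard: electrodes closer than 1e−6 cm to an active dipole
  raise an error naming the ring and sample.
- Quadrature resolutions (720 angular / 64 axial) leave the reference models
  self-consistent to < 1e−6 relative under halving; doubling the mesh's M
  changes the band potential by < 0.5% on the cylinder benchmark.
- Problem sizes in the test-suite and acceptance runs are the benchmark
  sizes themselves (N up to 910, M = 100, tens of seconds of signal at
  10 Hz); each run completes in seconds.
- The synthetic scenarios emulate the *geometry and kinematics* of the
  benchmarks, not tissue electrophysiology: amplitudes are in model units
  (the absolute scale of published waveforms is not recoverable), no noise,
  electrode contact, or conductive heterogeneity is modelled, and passing
  tests demonstrate correctness of the forward dipole computation — not
  clinical fidelity of simulated EGG.
- The tube is smooth: teniae coli, appendix and true sacculation geometry
  are not represented (the radius modulation of the pseudocolon is a
  caliber change, not a surface feature).
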