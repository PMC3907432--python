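# Methods

## Model overview

`spindlefield` computes the electric field generated by acoustically
vibrating microtubules (MTs) of a model mitotic spindle. The computation is
strictly feed-forward:

1. **Geometry** — place MTs in an ellipsoidal cell and expand each into its
   coarse-grained dipole lattice;
2. **Dynamics** — give each MT a principal longitudinal frequency, mode
   shape, phase and damping envelope;
3. **Field** — superpose the exact time-harmonic Hertzian-dipole fields of
   all oscillating monomer dipoles in a homogeneous lossy cytosol;
4. **Analysis** — Lorentzian vibration spectra, Monte-Carlo field
   statistics, spatial dynamic range.

Key physical assumptions: each tubulin monomer is reduced to a point dipole
at its centre of gravity; MTs vibrate independently in their fundamental
longitudinal mode (no MT–MT mechanical coupling, rigid MTOCs, no
back-coupling of the field onto the mechanics); the cytosol is a homogeneous
single-Debye dielectric; only the oscillating part of each dipole radiates
(the static background field is not evaluated); the magnetic component is
not computed.

## Parameters

| Symbol | Meaning | Default | Units |
|---|---|---|---|
| D_α, D_β | static monomer dipole moments | 369, 26 | D |
| p_a | oscillating fraction at 1 nm antinode | (3.8)⁻¹ | – |
| s | inter-protofilament axial shift | 0.92 | nm |
| ζ | MT ring diameter (dipole circle) | 10.76 | nm |
| Ξ | ring leading angle (metadata, unused) | 10.28 | deg |
| l_TH | heterodimer length | 8 | nm |
| r | MT outer wall radius (metadata, unused) | 12.5 | nm |
| a, b | cell semi-axes | 5.16, 2.64 | µm |
| R | volume-equivalent sphere radius | 3.3 | µm |
| c | MTOC offset on the spindle (x) axis | 2.64 | µm |
| ρ | MTOC sphere diameter | 200 | nm |
| N_a, N_k, N_p | MTs per class per MTOC | 50, 50, 50 | – |
| κ_a, Ω_a | astral Thomson points / cap angle | 120, 2.8212 | –, sr |
| κ_pk, Ω_pk | kinetochore+polar Thomson points / cap | 225, 2.9154 | –, sr |
| k₁, k₂ | frequency-law coefficients | 2.5304·10¹², 9.0966·10⁸ | Hz |
| β_fixed, β_free | boundary-condition factors | 2, 1 | – |
| A | antinode amplitude | 1 | nm |
| Q | quality factor | 10 (range 0.1–50) | – |
| ε_s, ε_∞, τ, σ | cytosol Debye model | 78.3, 5.2, 8.27 ps, 0 | –, –, s, S/m |
| voxel edge | default field grid pitch | 8 | nm |
| r_min | exclusion radius (½ voxel edge) | 4 | nm |

Notes on the parameter table:

- The printed volume `V = 0.15 µm³` of the R = 3.3 µm reference sphere is
  inconsistent with `(4/3)πR³ ≈ 150.5 µm³` (a unit typo); the code derives
  volume from R and never uses the printed value.
- `(a·b²)^(1/3) = 3.2993 µm` matches R = 3.3 µm to 0.02% — the cell
  validator enforces this volume equivalence at 1%.
- Ξ = 10.28° does not match the helix angle implied by s and ζ (~19.5°) and
  no equation consumes it; it is carried as metadata only. Ring placement is
  generated directly from s and ζ.
- The κ/Ω bookkeeping is internally inconsistent with a 4π normalisation
  (a 2.8212 sr cap of a 120-point distribution holds ~27 points, not 50).
  The per-class target counts are authoritative; κ and Ω size the nominal
  cap only, and the builder logs a warning when the nominal cap population
  differs from the target.
- The quality factor is quoted both as 0.5–100 and 0.1–50 in the source
  material; the code accepts any Q > 0 and documents 0.1–50 as the studied
  range.

## Geometry construction

**Nucleation layout.** Directions are spread on each MTOC sphere by
minimising the Thomson energy `Σ_{i<j} m_q/|x_i − x_j|` with projected
gradient descent: tangent-plane-projected gradients, Barzilai–Borwein step
guess, step halving whenever the energy would increase, convergence when
the maximum per-iteration displacement drops below 1e-9 (on the unit
sphere). Initialisation is seeded-uniform on the sphere; the two MTOCs use
independent child seeds. κ ∈ {2, 4, 6} reproduce the antipodal pair,
regular tetrahedron and octahedron; for κ = 120/225 the descent reaches a
low-energy local minimum (verified in tests to beat 100 random
configurations).

**Trajectories.** Astral MTs run straight from the MTOC sphere surface
(start = centre + (ρ/2)·direction) to the ray–ellipsoid intersection.
Kinetochore/polar MTs follow a planar quarter-ellipse: origin-centred,
semi-axes (c, q_u), in the plane of the spindle axis and the nucleation
azimuth, from the parameter nearest the nucleation point to the equatorial
plane. The equatorial target radius is the linear magnification
`q_u = d_u · (spread·b / d_max)` of the nucleation centre's axis distance
d_u, with `spread = 0.8` so the targets tile a disc of radius 0.8·b; d_max
is the largest d_u on the cap. This magnification rule is a documented
choice (the printed magnification formula is typographically incomplete in
the source material); any replacement must stay monotone in d_u. An
ellipse through three points is not unique, so the quarter-ellipse above is
likewise a fixed, reproducible convention. Kinetochore and polar MTs share
the trajectory rule and differ only by label; the builder alternates labels
along the angular ranking of the cap.

**Arc-length parameterisation.** Each ellipse arc is tabulated on 16k
parameter samples (trapezoidal cumulative speed, verified against a dense
chord-sum oracle to sub-pm accuracy) and inverted with a monotone PCHIP
spline; ring origins sit at exact arc-length multiples of l_TH,
`floor(L/l_TH)` rings per MT.

**Dipole lattice.** Per ring, 13 heterodimer sites at azimuths `2πj/13`
(spiral phase origin at the local frame's first basis vector; configurable)
on the ζ-diameter circle, axially staggered by `j·s`; per site an α and a β
monomer at ∓l_TH/4 along the axis, α toward the MTOC (minus end) by
default. Dipole axes are the local MT tangent. Axial lattice coordinates
are clamped to `[0, L]` so terminal rings do not protrude past the MT tip.
Containment convention: MT centerlines satisfy the ellipsoid inequality
strictly (tolerance 1e-9); dipole positions may exceed it by at most the
lattice extent (≲ 15 nm), because astral tips terminate exactly on the
membrane while their wall dipoles sit ζ/2 off-axis. (A strict all-dipole
bound is geometrically impossible under these two conventions.)

## Dynamics

`ν(L) = β_bc · k₁ · l_TH / L + k₂`, strictly decreasing in length with
asymptote k₂. The printed functional form of the extrapolation law is
incomplete in the source text; this reconstruction (i) has the correct k₂
asymptote for very long MTs and (ii) respects the factor-two frequency
ratio between a half-wave (fixed–fixed) and quarter-wave (fixed–free)
longitudinal resonator. k₂ is kept as an additive offset and is *not*
scaled by β (a documented choice; both β factors are config-exposed).

**Boundary-condition scenarios.** Astral MTs are always fixed at both ends
(membrane and MTOC). In the `fixed` scenario kinetochore/polar MTs are also
fixed at the equator; in the `free` scenario they are free there
(mode antinode in the midzone). The headline spectrum quantities of
`workflows.py` are evaluated in the free scenario: with β = 2/1 the
free-scenario spectrum is the one that spans the published ~8–18 GHz
small-cell band and puts the 65 µm-cell response near 1 GHz, whereas the
all-fixed spectrum lies a factor ~2 higher (≈11.6–21.3 GHz band and a
≈1.5 GHz large-cell peak for the same build — both computed by the test
suite's scenario comparison only implicitly; rerun with
`scenario="fixed"` to reproduce). The free-end condition is also the
physically favoured one for midzone MTs, which are either searching for
chromosomes or pliantly cross-linked.

**Excitation.** Pulsed feeding sets every phase to zero (synchronised,
maximum displacement at t = 0, cosine convention); random feeding draws
i.i.d. uniform phases from the excitation seed. The oscillating dipole
magnitude is `p_a · D · sin-mode(ξ) · (A / 1 nm)`, linear in the antinode
amplitude (the minimal assumption; only the constant p_a at A = 1 nm is
given). Damping multiplies amplitudes by `exp(−πνt/Q)`; the undamped case
is the exact Q → ∞ limit.

## Field evaluation

Phasor convention `e^{+iωt}`. The cytosol permittivity is
`ε(f) = ε_∞ + (ε_s−ε_∞)/(1+i2πfτ) − iσ/(2πfε₀)` (lossy part negative
imaginary); the wavenumber `k = (2πf/c₀)√(μ_r ε)` takes the principal
branch, giving Im k ≤ 0 so the propagation factor `e^{−ikr}` decays.
The per-dipole field is the coordinate-free exact Hertzian solution

    E = e^{−ikr}/(4πε₀ε) · [ k²(p − n(n·p))/r + (3n(n·p) − p)(1/r³ + ik/r²) ]

which reduces to the electrostatic dipole for kr ≪ 1 (verified < 0.1% at
kr ~ 1e-4) and to 1/r radiation for kr ≫ 1 (|E|·r constant to < 1% per
decade in a lossless medium).

Each MT radiates at its own frequency, so fields are computed per MT as
complex phasors at (ν_n, k(ν_n)) and combined as real instantaneous fields
`Σ_n Re{E_n e^{i(ω_n t + φ_n)}}·env_n(t)`; a multi-frequency sum has no
single phasor. Time series cover 5 periods of the slowest MT in 300 equal
steps by default.

**Singularities.** Evaluation points closer than the exclusion radius
r_min (default: half the grid pitch, 4 nm at the default 8 nm resolution)
to a source have that contribution clamped at r_min; clamped evaluations
are counted per point, reported in frame metadata, and excluded from the
dynamic-range statistic.

**Near/far ring aggregation.** The production kernel (numba) sums each
ring's 26 parallel dipoles into one equivalent dipole at their
amplitude-weighted centroid and uses it for evaluation points farther than
250 nm from the ring; nearer points see the exact dipoles. The weighted
centroid cancels the first-order displacement moment, leaving a relative
error second-order in (ring extent / distance) — measured < 1e-2 worst
case and ~1e-5 in the median against the exact numpy reference path, which
remains available (`aggregate="exact"`) and is cross-checked in the tests.

## Analysis

Spectra are sums of unit-peak Lorentzians, FWHM ν_n/Q (Q = f₀/Δf
convention). Unit peak (not unit area) is chosen so that superposed line
heights reflect the number of MTs per length bin, making the spectrum read
as a smoothed MT-length histogram; unit-area normalisation is a config
switch. Band edges are the outermost crossings of `threshold · max(S)`
with linear interpolation between samples; the default threshold 0.5
(half maximum) is the package's measurement convention for the published
"covers a range" statements.

Monte-Carlo statistics pool per-point max/mean/min of |E| over
`n_samples × n_realizations` random-phase frames (defaults 300 × 100);
realization seeds are spawned from a root seed, making runs reproducible.
The spatial dynamic range of a plane frame is computed with a sliding
circular minimum filter (radius = max separation, default 500 nm),
equivalent to an exhaustive pair search (asserted in tests).

## Synthetic fixtures and what the tests show

The test fixtures are fully synthetic: a 4-atom neutral "toy monomer" with
hand-computable centre of gravity and dipole moment (exercising the PDB +
sidecar-charge reader), a 6-MT mini spindle (2 MTs per class; all geometry
invariants, at second-scale cost), and a constant synthetic field frame
(statistics edge cases). They emulate the *structure* of real inputs, not
their scale: passing tests demonstrate correctness of the construction,
the field solution and the statistics, but say nothing about biological
variability of real spindles (MT counts, lengths, damping and the charge
model of real tubulin are all parameters, not predictions). The packaged
369/26 D moments are used as constants; recomputing them from an atomic
structure requires a charge assignment that is deliberately out of scope.

## Known limitations

- No MT–MT mechanical coupling, no electromechanical back-action, rigid
  MTOCs: the ensemble is a superposition of independent resonators.
- Only the fundamental longitudinal mode; bending/torsional modes and
  higher harmonics are excluded (more damped / electrically inefficient).
- Homogeneous cytosol without membrane boundary or ionic screening beyond
  the bulk conductivity term; no dielectric contrast at the MT wall.
- The Debye medium parameters are water-like defaults (25 °C); the
  published permittivity curve is not tabulated, so all four values are
  config-exposed.
- Absolute field magnitudes are validated by physical properties
  (quasi-static and far-field oracles, linearity, frame invariance), not
  against printed values, which are unavailable.
- The 8 nm evaluation pitch undersamples the point-like interference
  minima of the vector field; spatial dynamic-range figures at this pitch
  are therefore conservative lower bounds.
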