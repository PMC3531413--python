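# Methods

## The system being modeled

A ring-shaped engineered tissue construct (ETC) — fibroblasts in a collagen
gel, compacted over days of culture — is stretched rapidly (~60%/s) and held
isometrically for 30 minutes while a fraction of cells expressing an F-actin
reporter is imaged every 5 minutes.  Three ingredients of that experiment
are modeled here: the strain field cells actually feel, the remodeling
dynamics of their stress fibers, and the image statistic used to read
remodeling out of the micrographs.

## Strain kinematics

Because the compacted construct is strongly anisotropic (collagen fibrils
align circumferentially), most of the grip displacement is absorbed by local
radial compression at the loading bars.  The nominal→local map is a
piecewise-linear interpolation through the measured knots
(0, 0), (10%, 5%), (30%, 10%); outside the calibrated range the map refuses
to extrapolate, since only two non-trivial points were measured.

A fiber at angle θ to the stretch axis feels the uniaxial strain
transformation

    ε(θ) = ε₀ (cos²θ − ν sin²θ),

with the construct's effective Poisson ratio ν ≈ 1, giving ε₀·cos 2θ:
compression transverse to the stretch equal in magnitude to the axial
tension, and zero strain at ±45°.  Strain extraction from bead tracks uses a
least-squares affine fit (after = F·before + t) and small-strain extraction
diag(F) − 1, consistent with the ≤10% local strains involved.  The
first-order passive area change (1 + ε)(1 − νε) − 1 collapses to −ε² at
ν = 1, which is why passive geometry contributes negligibly to fibrosity
changes.

## The sector model

A cell is a set of angular sectors (default 36, i.e. 5° resolution; spindle
cells concentrate orientations about a natural axis), each with

* an orientation θ and width w,
* a pre-stretch λ_pre drawn i.i.d. from a normal with mean μ and spread σ,
  truncated to the allowable stretch window [λ_min, λ_max] — fibers outside
  the window cannot exist,
* a stress-fiber density ρ (arbitrary units, initial ρ₀ = 1).

One stretch event multiplies each sector's stretch by 1 + ε(θ).  Two rules
then act:

**Rupture/buckling (instantaneous, irreversible).**  Sectors whose total
stretch leaves the window depolymerize: density goes to zero and the
released F-actin is credited to a reservoir pool.  Rupture is confined to
the stretch event; nothing re-nucleates a dead sector within a run.

**Stress-gated polymerization.**  The adhesion-site stress of an intact
sector is s = k_fiber · ρ · max(λ − 1, 0) · S, where S is a load-sharing
factor (below).  Sectors with s in the intermediate band [s_low, s_high]
grow by forward-Euler relaxation ρ ← ρ + dt·k_poly·(ρ_max − ρ) (closed-form
exponential saturation is the accuracy oracle for the stepper).  The
ROCK-inhibitor switch disables growth entirely; the optional finite
reservoir caps total density gain by the pool content.

**Load sharing.**  Rupture of fibers loaded in tension releases stress in
the surrounding matrix.  S is computed once, at the stretch event, as the
ratio of tension carried by surviving stretch-tensioned sectors
(Σ ρ·w·(λ−1) over sectors whose stretch increased) to the same quantity
immediately after stretch but before rupture, clipped to [0, 1].  Three
modeling choices matter and are deliberate:

* *stress weighting* — a ruptured fiber releases matrix stress in proportion
  to the tension it carried, not its mass alone (a density-weighted variant
  is available via `share_mode="density"`, but it never collapses far enough
  to arrest growth, because rupture removes at most the top slice of the
  pre-stretch distribution);
* *frozen at the event* — newly polymerized fibers assemble at rest length
  and cannot re-tension the matrix during an isometric hold; letting S
  recover with regrowth creates a positive feedback loop with no physical
  counterpart here;
* *pool restricted to stretch-tensioned sectors* — the release happens
  around the parts of the cell loaded in tension by the stretch.  With no
  stretch the pool is empty, S = 0, and an unstretched cell stays in
  homeostasis (flat trace), as it should.

The model fibrosity is Σ ρ·w normalized to its pre-stretch value.

### Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| λ_min, λ_max | 0.96, 1.28 | allowable fiber stretch window |
| μ_pre | 1.12 | mean pre-stretch |
| σ_pre | config | pre-stretch spread; the sweep variable |
| ρ₀, ρ_max | 1.0, 1.8 | initial and saturating density |
| k_poly | 0.15 /min | polymerization rate (e-fold ~7 min, near-saturation in 30 min) |
| s_low, s_high | 0.14, 1.0 | growth band on adhesion stress (k_fiber = 1 sets the stress unit) |
| dt, duration | 0.1 min, 30 min | forward-Euler stepping over the imaging window |

No measured values exist for the window, rates or thresholds at the cell
scale; all are config-exposed placeholders chosen so the model occupies the
regime the experiments describe.  The geometry of the choice matters more
than the numbers: with ε₀ = 0.10 and μ_pre = 1.12, the mean fiber sits
0.048 inside both window edges after stretch (μ(1+ε) = 1.232 vs 1.28;
μ(1−ε) = 1.008 vs 0.96).  Those staggered margins produce the three regimes
as σ grows:

* σ = 0.02 — essentially no ruptures; axis-aligned sectors sit in the
  growth band; **monotonic reinforcement** with polarization (the rare
  ruptures cluster within ~15° of the axis or its perpendicular, because
  only there does the strain reach either window edge);
* σ = 0.08 — buckling losses near the perpendicular and some tensile
  ruptures drop the trace below threshold, but the load share stays high
  enough for survivors to regrow; **retraction then reinforcement**;
* σ = 0.25 — the upper tail of the pre-stretch distribution ruptures in
  tension, the stress-weighted load share falls to ~0.55–0.65, and no
  survivor reaches s_low; **monotonic retraction**.

These three spreads are frozen as `SWEEP_SIGMAS`; the sweep demonstrates
class dominance at 50 seeds per level.  Reinforcement-followed-by-retraction
cannot occur: losses happen only at the stretch event and growth is
monotone afterwards, so a trace that rises by more than the classification
margin can never fall back by more than it.  The trace classifier treats
that pattern as an anomaly and raises.

A structural consequence of ν = 1 worth knowing: sectors at ±45° feel no
strain, and because pre-stretch is sampled inside the allowable window they
can never leave it.  The orientation histogram of depolymerized sectors
therefore keeps troughs at ±45° at every σ — direction-dependence weakens
with σ but never becomes uniform.  Orientation histograms are computed at
720 sectors (0.25°) so the low-σ histogram is well populated.

## Fibrosity

The statistic is the band-pass power of the 2D periodogram of the
luminosity-normalized image: scale to unit mean (so z-motion and expression
level drop out), demean, Hann-window (edge-leakage suppression), FFT, and
sum power over the annulus of radial frequencies [1/(2w_max), 1/(2w_min)]
— a fiber of width w concentrates power near the half-period frequency
1/(2w).  The sum is divided by window energy × pixel count so the value is
image-size independent.  Defaults: w ∈ [0.3, 1.0] µm (typical stress-fiber
thickness).  Note the Nyquist constraint: the 0.3 µm band edge requires
pixels finer than 0.3 µm, hence the renderer's 0.25 µm/px default.

For non-overlapping fibers of fixed width, band power adds incoherently and
the statistic is proportional to total contour length (an intensity-
*fraction* normalization would cancel that proportionality, which is why
the denominator is the image's luminosity, not its total spectral power).
Two caveats set what the passing tests do and do not show: overlapping or
bundled fibers merge into thicker features and leave the band, and the Hann
taper weights content by image position, so length comparisons are exact
only between equally-tapered placements.  Traces are normalized to a
reference frame (default: the pre-stretch frame).

## Synthetic data

Generators are pure functions of (spec, seed) and carry recoverable ground
truth; the round-trip suite (length → fibrosity, deformation gradient →
affine fit, force decrement → active-force estimate, densities → rendered
series → trace class) is the core evidence that each stage measures what it
claims.  Rendering emulates collapsed confocal stacks at 20× scale: fibers
are Gaussian-profile segments (0.5 µm FWHM) laterally scattered within each
sector so added fibers add length rather than thickness, reservoirs are
2 µm Gaussian blobs whose intensity tracks F-actin lost from sectors, and
frames share fiber placements so only density-driven counts change over
time.  Intensities default to a 40-unit fiber peak over a 50-unit diffuse
background with σ = 1 Gaussian noise — the regime where the cell's diffuse
fluorescence dominates the image mean, keeping the statistic linear in
length.  It is not an optical model: no PSF, no photobleaching, no 3D.

Bead fields are uniform in a 200 µm field of view with Gaussian
localization noise (default study: 50 beads, 0.1 µm noise).  Force traces
are baseline + step × (plateau + decaying exponentials) with an optional
first-order step-down at drug onset; the defaults (µN-scale forces,
~30 min relaxation) match isometric-hold recordings.

## Statistics

Pearson's chi-square (no continuity correction by default; Yates behind a
flag) and the two-sided Fisher exact test are implemented from first
principles — expected counts from margins; hypergeometric enumeration with
the standard "as or less probable" tie rule — and are cross-checked in the
tests against scipy, an explicit factorial-enumeration oracle (exhaustively
for all 2×2 tables with N ≤ 40), and permutation nulls.  The chi-square
tail is asymptotic: at small expected counts it deviates from the exact
permutation null by far more than Monte-Carlo error (observed up to ~0.07
at cell counts of 2–15), so agreement with a sampled permutation null is
asserted only at large counts.

The active-contraction estimate is the drop in steady isometric force after
ROCK inhibition, divided by the number of load-bearing cells; the optional
active-stress estimate ΔF·L/(n_cells·V_cell) (bar spacing L, cell volume
V_cell) is a coarse order-of-magnitude quantity kept behind an explicit
opt-in.

## Known limitations

* The sector model has no spatially resolved matrix mechanics, no focal
  adhesion kinetics, no re-nucleation of ruptured sectors, and no feedback
  from cell contraction onto construct force; matrix stiffening is not
  distinguished from stress.
* Model parameters are placeholders in physically sensible units; the model
  demonstrates mechanisms and class structure, not fitted magnitudes —
  per-cell experimental fibrosity excursions are not reproduced by design.
* The fibrosity statistic is a spectral proxy, not a tracing method; it
  saturates when fibers bundle and is blind to features outside its band.
* Classification thresholds (δ = 0.10) are tuned to trace excursions well
  above noise; traces hovering at the threshold can land in adjacent
  classes.
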