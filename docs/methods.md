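# Methods

This note documents the models implemented in `filoguide`, the parameters
that matter, the choices made where the design was open, and what the
synthetic experiments do and do not show about real cells.

## 1. Substrate geometry and contact classification

All simulation happens in the 2-D substrate plane.  A grating is a
periodic band pattern (ridge width `r_w`, groove width `g_w`, period
`r_w + g_w`); the ridge depth `r_d` never produces out-of-plane motion —
it only modulates the guidance strength (§2).  A swallowtail substrate is
a trunk grating that bifurcates at a branch point into two branch
gratings rotated by ±φ; the local principal direction is piecewise
constant, and points exactly on the dividing line are assigned to the
positive-rotation branch so the map is deterministic.

The growth cone is a virtual disk of radius `r_bar = 1.14 um` (mean
equivalent radius of non-spread PC12 growth cones) centred on the neurite
tip.  Contact with the pattern falls into three cases:

* **case 1** — centre in a groove, disk overlapping the neighbouring
  ridge(s).  The candidate limit angles are `±arcsin(d/r_bar)` toward the
  facing ridge edges at lateral offsets `d`; with only one ridge in reach
  both candidates point toward it.
* **case 2** — centre within a ridge or on a border.  The limit angle is
  taken toward the nearer ridge edge (exact-midpoint ties resolved toward
  the positive side); if no edge lies within one radius (very wide
  ridges) the locally unpatterned substrate prefers no deviation and the
  angle is 0.
* **no contact** — grooves wider than the disk diameter; the tip then
  performs an unbiased random walk, since with no ridge under the cone
  there is no stress anisotropy to exploit.

Disks overlapping more than two ridges are reduced to the nearest ones:
the main ridge acts as a filter that dominates the global orientation.

## 2. Analytic mean-alignment model

A ridge edge at lateral offset `d` meets the disk boundary at height
`h = sqrt(r_bar**2 - d**2)`.  The stable on-ridge filopodium reaches
laterally a fraction `a` of the ridge width, so its direction subtends
`beta_geom = arctan(a*r_w / h_tilde)` with the grating axis, where
`h_tilde` is the median K-point height over uniform disk placements.  The
influence of ridge depth is decoupled through

    f(r_w, r_d) = exp(-eps * r_d / r_w)          (dimensionless)

interpreted as the surviving fraction of unguided behaviour: `f = 1` on
flat substrates, decaying as ridges get deep relative to their width.
The mean unsigned alignment angle is the mixture

    beta_mean = 90 deg * f + beta_geom * (1 - f).

Properties (all grid-verified in the test suite): `beta_mean` is monotone
non-decreasing in `r_w`, non-increasing in `r_d`; the flat substrate is
the unguided limit of 90 deg, approached as a vertical asymptote when
`r_w` grows without bound — which is why the inverse design problem
("width for a target alignment") diverges near the flat limit; narrow
deep ridges drive the angle toward zero.  On the reference period-1
grating (`r_w = g_w = 0.5 um`, `r_d = 0.25 um`) the model gives
`beta_mean = 14.1 deg`, consistent with the simulated alignment
distribution concentrated within 10-20 deg.

`h_tilde` is approximated once per grating by pooling the K-point heights
of 1e5 uniform disk placements drawn from a fixed internal stream, so it
is a reproducible function of geometry alone (1.112 um on the period-1
grating).  `a` defaults to 0.5 — the symmetric-ridge configuration, with
the stable filopodium reaching the ridge half-width; it is exposed in
`GuidanceParams`.

`eps` is the model's only fitted parameter.  `fit_epsilon` estimates it
by bounded 1-D least squares on (width, depth, angle) observations
(bracket [1e-4, 1e4], three log-spaced restarts) and reports R^2 as the
squared correlation of observed and predicted angles; on noiseless
synthetic observations the generating value is recovered to 1e-6
relative error.  The shipped default `eps = 8.0` was set by the same
period-1 calibration as the simulator noise (§3), since the biological
mean-alignment points behind the published fits exist only as figure
glyphs and cannot be re-fitted from a desk.

## 3. Stochastic outgrowth simulator

Tip headings (degrees, in the local grating frame) follow the biased
persistent random walk

    theta[t+dt] = theta[t] + omega_t + lambda * (beta*_t - theta[t])
    lambda      = (1 - f) * (1 - exp(-xi * dt)),   xi = 75 / h

with `omega_t ~ N(0, sigma_omega**2)` and `beta*_t` the contact-derived
limit angle of §1 (case 1 chooses uniformly at random between the two
candidates — the symmetric left/right possibility; the choice is
mirror-equivariant under antithetic coupling of the uniform draw).  On a
flat substrate `lambda = 0` and the heading is a pure Gaussian random
walk, the unguided null model.

Growth dynamics: neurites appear at 11.38 um (the flat-substrate initial
length) with a heading drawn from a zero-mode Laplacian truncated to
`laplace_interval`; the tip advances at `v_ext = 20 um/h` in
`dt = 0.05 h` steps (1 um per step).  When the length crosses the current
target — drawn from N(18.98, 2.65) um — the phase flips and the neurite
retracts along its stored path at `v_ret = v_ext` until it crosses a
freshly drawn target, and so on; `cycle_counter` (default 240 steps)
caps a phase that never meets its target.  Retraction speed, and whether
retraction re-randomises the heading, are not constrained by published
values; we retract along the stored path and resume extension in the
direction of the surviving distal segment.

Randomness: one root seed; per-neurite streams are spawned from it, so
enlarging a population never perturbs existing trajectories, and identical
configurations reproduce output files byte for byte.

### Calibrated defaults

Three constants of the heading model have no published values and were
calibrated once against the reference period-1 observables (mean
tortuosity 1.012, ≈65% of chords within 10 deg, >90% within 20 deg,
≈69% within 10 deg at 12 h) and the swallowtail turning fractions; the
calibrated values ship as the defaults:

| parameter | default | meaning |
|---|---|---|
| `sigma_omega` | 5 deg / step | intrinsic turning noise |
| `laplace_scale` | 25 deg | initial-heading Laplacian scale |
| `laplace_interval` | (−30, 30) deg | truncation of the initial heading |
| `TurningRule.alpha50` | 61 deg | half-turn approach angle (§4) |
| `TurningRule.width` | 16 deg | logistic width of the turning rule |

The truncation at ±30 deg reflects the observation that simulated and
biological orientation distributions on period-1 gratings are essentially
empty beyond 30 deg; with a much wider interval the Laplacian tail would
put ≈10% of chords beyond 20 deg, contradicting the >90%-within-20-deg
observable at any scale that keeps 65% within 10 deg.

### Cell-cell interactions

`run_population` advances all neurites in lockstep and optionally applies
the minimal interaction model: hard-core repulsion displaces tip pairs
closer than a contact distance back to exactly that distance (prevents
overlap), and fasciculation attraction turns the headings of nearby,
roughly parallel tips toward each other, bounded per step (adhesion
between neighbouring processes).  CX3D-style force physics is
intentionally not reproduced; with interactions disabled, population runs
are exactly the independent single-neurite runs.

## 4. Swallowtail beam splitting

Axons grow on the trunk toward the branch line (somata 22 um upstream,
scattered laterally over 20 periods).  When a tip first enters a branch
region it is assigned to that branch (by its lateral position), and its
approach angle `alpha` — between the tip heading and the branch ridge
border direction — decides the outcome: the axon turns with probability
`1 / (1 + exp((alpha - alpha50) / width))`, otherwise it stalls in place
near the corner.  The mechanism (approach angle) is fixed by the
experimental literature; the logistic form and its two constants are the
package's calibrated choice (§3).  The turning fraction is reported over
axons that reach the branch; it decreases strictly with the tail angle
(≈90/75/51/25% at φ = 20/40/60/80 deg, n = 1000).

## 5. Finite-element growth-cone mechanics

Geometry: a quarter ball of radius `r_bar` resting on the substrate with
its flat vertical face (the neurite contact area) at the back, plus 1-3
half-cylindrical filopodia (shaft radius 0.1 um, configurable) lying on
the substrate and radiating outward.  Meshing is a parametric
structured-to-tet decomposition (spherical / cylindrical grids, Kuhn
subdivision, degenerate cells dropped) — reproducible with no geometry
kernel; meshes agree with the closed-form solid volume to within 2%.

The filopodium blocks are joined to the cone by master-slave ties: every
proximal-cap node's displacement component *along the filopodium axis*
follows a Gaussian-weighted average of the nearby cone-surface nodes,
while transverse components remain free.  The axial-only coupling
reflects adhesion-mediated load transfer along the shaft and keeps the
interface stress orientation-independent (a full vector tie would inject
a spurious bending moment that grows with orientation); the shared
smooth window makes the coupling insensitive to where the filopodium
lands on the cone's surface grid.

Boundary conditions: filopodial tip ending lines fully fixed (tip
adhesions); filopodial shaft bottoms and the cone bottom restricted to
slide along their longitudinal axes (implemented as zero displacement in
the two transverse directions); an imposed shortening (default 5% of
`r_bar`) along the neurite axis at the contact area represents
cytoskeletal contraction.  Material: isotropic linear elasticity,
`E = 1e6 Pa`, `nu = 0.47` (nearly incompressible).  The printed source
value "E = 106 Pa" is typographically ambiguous; every reported quantity
is normalized, so E cancels and the choice is immaterial.  Plain
displacement tet4 is used despite the locking risk at `nu = 0.47`
because all claims are qualitative and normalized; the patch test is
exact and solutions are linear in the load to solver precision.

Post-processing: the standard Von Mises invariant per element; the
interface stress of a filopodium is the maximum over its elements
adjacent to the proximal cap.  Reproduced behaviour: the shortest of
several filopodia carries the interface maximum; the normalized
interface stress is constant within ~1.5% over orientations ±10 deg and
monotone, markedly non-linear in length over [0.001, 2]·`r_bar`
(normalization cell ≡ 1).  Successive uniform refinements change the
single-filopodium interface maximum by <10%.

## 6. Metrics and statistics

Tortuosity = path length / chord length (≥1, exactly 1 for straight
paths; undefined and signalled for coincident endpoints).  Alignment =
unsigned angle in [0, 90] deg between the start-to-end chord and the
grating axis (axis, not vector, so 170 deg folds to 10 deg); the chord
definition is used rather than mean local heading.  Angular histograms
use half-open bins [lo, hi) with the final bin closed at 90 and sum to
100.  Group comparisons: Welch's two-sided t test preceded by per-sample
Shapiro-Wilk normality reports, or the two-sided Wilcoxon rank-sum
(Mann-Whitney) test, exact for small untied samples; observation times
are parameters, not constants, since alignment and tortuosity cohorts
were sampled at different times in the source experiments.

## 7. Synthetic data and what it shows

The generator produces (a) alignment observations from the analytic model
at a known `eps` with optional Gaussian noise — used to demonstrate exact
fit recovery, not to claim biological validity of `eps`; and (b)
canonical trajectories with closed-form metric values.  Simulated cohorts
emulate the *statistical* structure of the reference experiments (sample
sizes 61/117/500+, observation times, printed speeds and length
distributions) but not cell individuality, substrate defects, branching,
somal migration, 3-D growth or chemical cues.  Passing tests therefore
show internal consistency with the published summary statistics, not that
the model generalises beyond the calibration conditions.

## 8. Problem sizes and numerical choices

Default experiment sizes (117 neurites x 72 h; 1000-2000 x 60 h; 4x1000
swallowtail axons x 24 h; FE sweeps of ~25 solves at ~6e3 tets) run in
about a minute each on one CPU, chosen so the full study reruns
comfortably in a single sitting.  Tolerances: inversion round trips to
1e-6 deg (Brent); fit recovery to 1e-6 relative; FE equilibrium residual
below 1e-8 relative (direct sparse solve); degenerate inputs (flat
substrates, zero-length chords, empty samples, unconstrained systems)
raise explicit errors rather than returning silent defaults.
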