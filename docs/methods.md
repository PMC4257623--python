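# Methods

This note documents the models, conventions, numerical choices and known
limitations of `stillframe`.  Units: lengths in ångströms (reciprocal space
in Å⁻¹), detector coordinates in millimetres, angles in degrees at every
public interface and radians internally.

## Geometry and conventions

The laboratory frame is right-handed with the incident beam along −z; the
flat detector occupies the plane z = −distance with fast/slow axes parallel
to lab x/y, and spot coordinates are millimetres relative to the direct-beam
intercept.  Beam-centre handedness is therefore fixed by the lab frame: a
spot at positive x lies along +x as seen from the sample.  The crystal is
carried by the reciprocal orientation matrix **A** whose *columns* are
**a***, **b***, **c*** in the lab frame, so **q** = **A h**.  The reference
(unrotated) setting of the reciprocal basis **B** is the Busing–Levy
convention (a* along x, b* in the x–y plane); only **A** = **R B** is
observable, so any fixed convention is equivalent.  The direct cell is
recovered from **A** through the reciprocal metric **G*** = **AᵀA**.

## The signed off-sphere angle Δψ

For a lattice point **q** (0 < |q| < 2/λ, not collinear with the beam), all
points of radius |q| on the Ewald sphere make the fixed polar angle
θ_r = arccos(|q| λ/2) with ê_a = −ŝ₀.  The reflecting position **r** is the
one in the plane spanned by **q** and the beam on **q**'s side; Δψ is the
in-plane angle from **q** to **r**, evaluated as an arctangent of the
projections of **r** on **q̂** and on ê₁ × **q̂** so that the sign and the
behaviour near zero are exact (no arccos cancellation).  The rotation axis
ê₁ = ê_a × ê_b is perpendicular to **q** and to the plane through the
sphere centre, the origin and **q**; rotating **q** by the *signed* Δψ about
ê₁ lands exactly on the sphere (tested to 1e-10).  The sign is physical:
negative when the point lies outside the sphere, positive inside.  Three
degenerate configurations are flagged and excluded from all fits: the
origin, points at or beyond the limiting sphere, and beam-collinear points
(undefined axis).  Derivatives of Δψ with respect to orientation angles,
cell parameters and wavelength are central finite differences (step 1e-6 in
natural units); they are validated against an independent stencil, and
∂Δψ/∂R_z vanishes identically because a beam-axis rotation preserves both
|q| and the polar angle.

## Refinement targets and the transverse-angle model

The positional target sums squared centroid residuals in mm²; the hybrid
target adds (Δψ/2π)² per spot.  The fixed unit convention (mm and
radians/2π) is deliberate — no inverse-variance weighting — so both residual
classes are numerically of order one and the objective is exactly the sum of
the two blocks.

Calculated centroids are the detector projections of reflecting positions.
In the still-shot model the transverse misorientations R_x, R_y do not move
calculated centroids — they only exchange which reflections diffract — so
the refinement Jacobian treats the positional residual block as independent
of R_x and R_y; those two angles draw their information exclusively from
the Δψ block.  Exact ray geometry would give the positional block a small
transverse lever (~4–6 mm/rad versus ~36 mm/rad for R_z, measured on the
default scene).  Keeping it has a large practical consequence: detector
noise then leaks into R_x/R_y at ~0.017° per image and the positional-only
protocol silently *recovers* the transverse angles instead of leaving them
unconstrained, erasing the qualitative distinction between the targets that
motivates the hybrid method.  The model choice (zero transverse positional
derivative) preserves that distinction; target *values* are always computed
from the exact geometry.

Minimisation is damped Gauss–Newton: a numerically differenced Jacobian
(central steps 1e-5 rad, 1e-3 Å, 1e-3°), a minimum-norm `lstsq` solve of the
normal equations (which leaves genuinely unconstrained directions — e.g.
R_x/R_y under the positional target — untouched), and multiplicative
step-halving (up to 25 halvings) so accepted steps never increase the
target.  Convergence: relative target decrease < 1e-10, parameter step
< 1e-8, or a vanishing model-predicted decrease; at most 100 iterations.
Because the masked-Jacobian fixed point is not exactly a stationary point of
the full target, the damping search can stall with every trial step higher
by a rounding-level margin; a stall within 1e-6 relative is classified as
convergence (measured stall excesses are below 5e-7), while larger excursions
are flagged as divergence and abort the two-stage protocol.

Parameterisation: a small-rotation update (R_x, R_y, R_z about the lab
axes) re-linearised onto the current orientation each iteration (no Euler
gimbal issues), plus the cell parameters of the active constraint class —
all six for triclinic, (a, c) for hexagonal 622 (a = b, 90/90/120).  The
two-stage protocol refines triclinic, projects the metric onto the Bravais
family (hexagonal a = mean of refined a, b), re-derives the orientation as
the Procrustes-closest rotation to the refined **A**, and re-refines under
constraints.  Miller indices are not reassigned inside refinement; an
optional flag enables one reassignment pass between stages.

## Symmetry-reduced misorientation

Lattice point-group rotations (triclinic: identity; hexagonal 622: twelve
rotations generated by the sixfold about **c** and a twofold about **a**,
closed by multiplication) are expressed in the reference crystal frame, so
the equivalents of orientation **R** are {**R C**}.  The misorientation
between two models is the minimum rotation angle of **R**_m(**R**_t**C**)ᵀ
over the group — using the shared reference frame makes the measure
symmetric — together with its rotation-vector decomposition along the lab
axes.

## Mosaic envelope estimation

Half-width model: w(d) = η/2 + d/D_eff, with η ≥ 0 the full-width effective
mosaicity and D_eff > 0 the effective block size (D_eff = ∞ encodes a
vanishing size term; α = 2/D_eff).

**Binned least squares.** Spots sorted by d, contiguous bins of 25, a final
partial bin merged into its predecessor; each bin contributes
(mean d, max |Δψ|).  The straight-line normal equations give (η/2, 1/D_eff);
a negative estimate is clamped to zero and the remaining parameter refitted.
Only 1/25 of the data (the bin extremes) informs this fit.

**Smoothed top-hat maximum likelihood.** Per-spot likelihood is the hard
top-hat density 1/(2w(dᵢ)) with logistic edges: log P = log σ(ε(1+t)) +
log σ(ε(1−t)) − log 2w, t = Δψᵢ/w(dᵢ), ε = 10.  Normalising by the hard
width and scaling the sigmoid argument by the *local* half-width makes ε a
single dimensionless steepness for all resolutions; the smoothing distorts
the total mass by under 1% (tested).  The likelihood diverges to −∞ when the
envelope excludes data and decays as it grows, so an interior maximum
exists; it is found by L-BFGS-B on (log η̃/2, log α̃) (offsets of 1e-8 keep
the domain open, bounds [1e-10, 1]), initialised from the least-squares fit.
On optimizer failure the least-squares envelope is returned flagged not
converged.  Because the soft edges let the envelope sit just inside the
extreme observations, the ML mosaicity is generally at or below the
least-squares value and the fitted block size overshoots the truth by a few
percent on finite samples.  One caveat found in recovery studies: when the
true resolution-independent spread is zero, the two estimators differ at the
1e-5 rad level and their per-replicate ordering is essentially a coin flip
(the LS intercept clamps to exactly zero while ML keeps an arbitrarily small
positive one); the ordering is clear in medians and on data with genuine
spread or heavy tails.

## Prediction and scoring

A reflection is predicted observable iff |Δψ| ≤ w(d); its centroid is the
projection of the reflecting position (where the partial reflection is
centred), and off-detector predictions are dropped and counted.  Candidate
indices are enumerated over a box bounded per axis by ‖aᵢ‖/d_min (no
qualifying index can escape), with |A h| evaluated through the reciprocal
metric by broadcasting, which keeps the ~2.5 × 10⁶-point search box cheap.
Agreement with a reference set is scored by exact Miller-index matching,
pooled over images, as falsely-predicted and unmodeled fractions, overall
and in shells of equal reciprocal-space volume (equal increments of 1/d³).

## The simulator

A scene draws a uniform random orientation (normalised Gaussian quaternion),
accepts exactly the lattice points inside the true envelope over 15–3.5 Å,
projects their reflecting positions, and optionally adds Gaussian centroid
jitter and/or quantisation to 0.11 mm pixel centres.  Defaults emulate a
photosystem-I experiment: hexagonal a = b = 281 Å, c = 165.2 Å; λ = 1.32 Å,
zero divergence; 129 mm detector distance; zero mosaic spread with
D_eff = 4850 Å, the effective size of a ~17 × 17 × 30-cell crystallite
(≈1100 accepted spots per image on a 1000² panel chosen to hold the 3.5 Å
ring).  The default centroid noise for recovery studies is σ = 0.03 mm
(about a quarter pixel), standing in for spot-finding centroid error.
Start-model perturbations apply rotations up to a stated magnitude per lab
axis and independent relative errors to all six cell parameters, as a
freshly indexed triclinic cell would carry.  Everything is bit-reproducible
from (seed, parameters).

What the simulator does *not* model — and hence what passing recovery tests
do not show about real data: diffraction intensities and intensity-dependent
detection, solvent background and false spots, shape-transform fringes,
finite bandpass and divergence, multi-lattice images, detector tilt or
multi-panel geometry.  In particular the hard envelope acceptance makes the
Δψ scatter exactly uniform within w(d), which is cleaner than real bright
spot lists.

## Recovery-study scales

The bundled studies run 200 scenes for orientation/mosaicity recovery and
100 paired scenes per protocol for the target-ordering comparison, sizes at
which the aggregate statistics are stable to well within the margins being
tested (a 200-scene batch completes in about two minutes on one CPU).
Under these conditions two-stage hybrid refinement recovers orientations to
~0.003° r.m.s.; the positional-only protocol stalls near its starting
transverse error (~0.26° r.m.s. for 0.5° starts), and the mixed protocol
(hybrid then positional) lands in between — the ordering that motivates
applying the Δψ term in both stages.
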