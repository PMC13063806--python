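# Methods

This note records the models, conventions and numerical choices behind
memraft, and what the synthetic-data experiments do and do not
demonstrate about real membrane data.

## Containers and units

Internal units are nm for length, ns for time, amu for mass; lateral
diffusion coefficients are reported in cm²/s (1 nm²/ns = 10⁻⁵ cm²/s).
A `Trajectory` stacks frames as an (F, N, 3) array with per-frame
rectangular boxes; triclinic cells are rejected at the I/O layer because
all systems of interest are planar, semi-isotropically coupled bilayers.
The topology is a per-atom table (species, subregion tag, element, mass,
vdW radius, H-bond roles, and a `donor_of` link from each hydrogen to its
bonded heavy atom). Subregion tags are restricted to {choline, phosphate,
glycerol, tails, sterol, ligand, other}; "headgroup" in SASA and density
work means {choline, phosphate, glycerol, sterol}.

GRO (fixed-width, nm, box on each frame's final line) is the canonical
trajectory dialect; XYZ is read as Å and converted. Binary formats are
out of scope — the analyses here never need them and text keeps the
package dependency-free.

## Synthetic membranes

`build_bilayer_config` places coarse pseudo-lipids (4–8 beads: one
reference atom — phosphorus "P" for phospholipids, hydroxyl oxygen "O3"
for sterols — plus one bead per subregion and 2–4 tail beads) on
jittered square lattices, one per leaflet. Bead masses sum to the parent
lipid's molecular weight so density profiles carry realistic mass; bead
radii are generic (0.20 nm heavy, 0.12 nm hydrogen). Hydrogen-bond roles
follow the underlying chemistry: POPC-like species are acceptor-only,
PSM-like species carry a backbone donor, and the sterol hydroxyl is both
donor and acceptor. The projected box area equals lipids-per-leaflet ×
APL target exactly, and the two reference planes sit the target
thickness apart. Defaults: Ld = 40 POPC per leaflet at 0.651 nm² and
3.90 nm; Lo = 40 PSM + 80 CHOL per leaflet (CHOL:PSM = 2) at 0.45 nm²
and 4.4 nm.

Lateral dynamics are free 2-D Brownian motion: each lipid moves rigidly
with independent per-axis Gaussian steps of variance 2·D·dt. There are
no inter-lipid forces, so collective flows, correlated diffusion and
subdiffusive short-time behavior of real membranes are absent; passing
recovery tests therefore demonstrates the correctness of the estimator
chain (unwrap → MSD → fit), not robustness to anomalous transport.
Box-area fluctuations are stationary iid Gaussian draws; when a target
modulus K_A is given the variance is k_B·T·⟨A⟩/K_A, and all lateral
coordinates are rescaled affinely with the box. Real area fluctuations
are temporally correlated; using iid draws makes the fluctuation
estimator's sampling error smaller than it would be for an MD series of
equal length.

Binding kinetics are a two-state Markov chain with per-frame switching
probabilities 1 − exp(−k·dt), emitting contact counts as
round(level + Gaussian noise) floored at zero. Defaults (bound level
1000, unbound 10, noise sd 50, k_on = 0.01/ns, k_off = 0.005/ns) keep the
two levels ≈ 4σ away from the 800-count threshold, so threshold crossing
errors are rare but not impossible — matching the regime in which the
strong-binding-time statistic is meaningful at all.

Planted hydrogen-bond triplets draw the donor–acceptor distance and
donor–H–acceptor angle either inside (0.26–0.295 nm, 152–178°) or
outside (0.305–0.35 nm, or 100–148°) the acceptance box, with a 0.005 nm
/ 2° guard band so floating-point rounding cannot flip a label. Triplets
sit 1.5 nm apart on a grid, far beyond the cutoff, so no cross-triplet
bonds exist and the construction is its own oracle.

Isotherms are piecewise: zero pressure in the gas phase, a linear
condensed branch π = m·(A₀ − A), and a flat plateau at the collapse
pressure; an additive at mole fraction x shifts the area scale by
(mixing slope)·x. Real isotherms have curved lift-off regions and
rounded collapse; the generator's sharp kinks are intentionally the
hardest case for the slope-based collapse detector's windowed smoothing.

All generators take explicit seeds; there is no global random state, and
identical seeds give byte-identical outputs.

## Analysis conventions

**Leaflets and structure.** Lipids are assigned to leaflets by the sign
of their reference atom's z minus the mean reference z; an atom exactly
at the midplane goes to the upper leaflet (logged warning). APL is
projected box area / lipids-per-leaflet, averaged over leaflets — for
the homogeneous or well-mixed leaflets modeled here this equals the
Voronoi-cell mean; per-lipid tessellation is left as an extension.
Thickness is the reference-plane (phosphate-level) separation.
K_A uses the standard equilibrium estimator k_B·T·⟨A⟩/var(A) with the
unbiased variance; it requires ≥ 100 frames and refuses degenerate
series.

**Density regions.** Profiles are per-frame mass histograms along z,
re-centered on the instantaneous midplane and converted to kg/m³ with
the frame's bin volume. The five-region scheme is derived from folded
(|z|) profiles: the 4|5 boundary at the tail density's half-rise out of
its central trough, 3|4 at the headgroup/tail crossover, 2|3 at the
outer headgroup half-maximum, and 1|2 at the water crossover (or the 2 %
headgroup decay level when no water profile exists — the generator
represents solvent implicitly). Folded profiles are Gaussian-smoothed
(σ = 0.15 nm by default) so that coarse-bead delta-like profiles form
contiguous bands; atomistic profiles can set σ = 0. Boundaries are also
directly settable to honor any externally published z-ranges.

**Diffusion.** Unwrapping accumulates nearest-image steps; because a
true displacement ≥ half a box edge is aliased and unobservable, any
apparent step above 90 % of the half-box raises an undersampling error.
Per-leaflet center-of-mass drift removal is on by default but off in the
recovery experiments (free Brownian motion has no collective drift, and
subtracting the mean of n molecules biases each D by (1 − 1/n)). The
MSD averages over molecules and strided time origins; fits are OLS over
a configurable lag window (default 10–200 ns), report r² and warn below
0.98, and per-molecule fits retain negative slopes so distribution tails
are honest. D_xy = slope/4.

**Interactions.** Boundary conventions are fixed and documented: H-bond
criteria are inclusive (distance ≤ 3.0 Å, angle ≥ 150°), contact cutoffs
are strict (<), and "exceeds threshold" for the binding time is strict
(>). All distances are minimum-image; the neighbor-grid (periodic
k-d tree) counting path is required to agree exactly with the all-pairs
brute-force path, which stays in the package as the oracle. The 0.16 nm
tight-contact cutoff with the 800-pair threshold is bond-length-scale
tight; both are parameters, and a 0.45 nm heavy-atom profile is the
sensible alternative for coarse synthetic data. Contact cutoffs larger
than half the smallest box edge are rejected.

**SASA.** Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, probe 1.4 Å): a point on an inflated sphere is
exposed iff inside no other inflated sphere. Each exposed point is
attributed to "headgroup" or "tail" when the nearest non-ligand inflated
surface lies within one probe diameter (2.8 Å) — the concrete rendering
of "surface in contact with" — otherwise to solvent, so the three
components sum to the total identically. The attribution tolerance is a
parameter.

**Isotherms.** Collapse detection: the condensed-branch slope is fitted
by OLS over the rising section between 40 % and 90 % of the maximum
smoothed pressure; collapse is the first later point where the smoothed
running slope magnitude falls below 10 % of it, with the method tag
recorded and the global maximum (flagged "no-collapse-plateau") as the
fallback for monotone curves. The limiting-area extrapolation band
defaults to 60–95 % of the collapse pressure. C_s⁻¹ uses
Savitzky–Golay-smoothed finite differences (window 5, order 2 — exact on
linear branches); at the branch/plateau kink the windowed estimate
bleeds over ~half a window, which is inherent to local smoothing.
Mixing slopes interpolate A(π) on each curve's pre-collapse branch,
average replicates per mole fraction, and regress on fraction (≥ 3
fractions including the pure film); curves whose collapse lies below the
target π are excluded with a warning.

**Statistics.** Standard deviations are unbiased (n − 1). The overall
group test is the classical one-way ANOVA F; versus-control comparisons
are two-sided Welch t tests, uncorrected by default (matching common
reporting practice in this literature) with Bonferroni correction by
flag, and the choice is recorded in the result object. Fold changes are
ratios of replicate means, not means of per-replicate ratios, because
that is the arithmetic consistent with the reference tables; the
published reference values themselves live in `memraft.refdata` as
worked-example inputs and are never recomputed.

## Validation experiment sizes

The experiments in `memraft.validation` (shared by the acceptance tests
and `scripts/acceptance.py`) use: 20 seeds × 20,000 frames at dt = 0.1 ns
for diffusion recovery on a 48 + 48 lipid two-species bilayer (the
10–200 ns window then spans lags 100–2000); 10,000-frame fluctuation
series for K_A; 20 seeds of 60 true + 60 near-miss H-bond triplets; 100
random 500-atom frames at cutoffs 0.16/0.45/0.5 nm for contact
equivalence; 20,000-frame binding traces; 20 seeds of noisy isotherms
(σ = 0.5 mN/m); and 10,000 null datasets (3 groups × 3) for the ANOVA
calibration. These sizes give the recovery targets (≤ 10 % median D
error, ≤ 1 Å² limiting-area bias, type-I rate in [0.04, 0.06])
comfortable statistical headroom while completing in about half a minute
on one CPU.

## Known limitations

* Free Brownian lipids cannot probe finite-size hydrodynamics, leaflet
  coupling or anomalous diffusion; recovery tests validate estimators,
  not membrane physics.
* The box-APL estimator and the reference-plane thickness are exact only
  for flat, homogeneous leaflets; curved or phase-separated membranes
  need tessellation-based methods.
* The five-region boundary recipe is this package's concrete rendering
  of a depth-scheme idea that is often cited without numeric boundaries;
  when published z-ranges exist they should be set explicitly.
* SASA attribution ("covering") has no unique definition; the
  probe-diameter tolerance is a documented choice, and totals (not the
  partition) are what the independent cross-check validates.
* Whether the 0.16 nm tight-contact cutoff in the binding-time
  definition reflects a typographical slip in its source cannot be
  resolved here; it is implemented as printed and fully parameterized.
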