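# Methods

`permeakit` re-implements, as a desk-scale and fully testable pipeline, the
post-simulation analysis stack used in computational studies of ion
permeation through narrow channels (the motivating system is the plant
vacuolar two-pore channel TPC1): biased-sampling free-energy profiles,
pore-geometry profiling, hydration counting, field-driven permeation
counting, and Goldman–Hodgkin–Katz (GHK) relative-permeability analysis.
Every analysis stage can be exercised end-to-end against synthetic inputs
with exactly known ground truth, so correctness never depends on access to
cluster-scale all-atom trajectories.

## The Brownian surrogate sampler (`synth.langevin`)

Umbrella-sampling inputs are generated by overdamped Langevin
(Euler–Maruyama) dynamics on an analytic 1D landscape `U(ξ)` (a sum of
Gaussian wells and barriers, `synth.landscape.PotentialSpec`):

    ξ_{t+1} = ξ_t − (Δt/γ) d(U+W)/dξ + sqrt(2 kT Δt / γ) η_t,  η ~ N(0,1),

with `W` the sum of restraints: the harmonic umbrella bias ½k(ξ−ξ₀)², a
flat-bottom restraint (zero inside a radius, harmonic outside), and a
lower-bound exclusion restraint (harmonic inside a floor distance, zero
beyond). Only configurational sampling matters for the downstream
estimators, so the friction γ and timestep are free numerical parameters,
not physical ones:

| parameter | default | rationale |
|---|---|---|
| kT | 0.5962 kcal/mol | 300 K with k_B = 0.0019872041 kcal/(mol·K) |
| γ (friction) | 0.5 kcal·mol⁻¹·Å⁻²·ns | a 10 ns-equivalent window is 10⁵ steps |
| Δt | 1e-4 ns | bias of the restrained variance, Δt·k/γ, stays ≤ 0.2% at k = 10 |
| bound | 10⁴ Å | runs that leave this range raise a diagnostic naming the step |

Statistical validation (`validation`) accounts for autocorrelation: the
χ²-against-Boltzmann check thins the series by three integrated
autocorrelation times before comparing the histogram to the quadrature
Boltzmann density, since raw per-step samples are far from independent and
would otherwise invalidate the χ² reference distribution. For validation
runs the tests use γ = 0.05–0.1, which shortens the correlation time so a
10⁶-step trajectory carries hundreds of effectively independent samples.

Steered pulls reuse the integrator with a harmonic restraint following a
monotone schedule; the steady-state lag of the particle behind the moving
center is γv/k, which the tests verify against that closed form.

## WHAM (`wham`)

Umbrella windows (default plan: centers every 0.5 Å along a 50 Å pull,
i.e. 100 windows, with the terminal 15 Å — 30 windows in the gated region —
droppable after planning) are combined by the weighted histogram analysis
method, iterating

    P(ξ_b) = Σ_j n_j(ξ_b) / Σ_j N_j exp[(f_j − w_j(ξ_b))/kT]
    f_j    = −kT ln Σ_b P(ξ_b) exp(−w_j(ξ_b)/kT)

until max_j |Δf_j| < tolerance (default 10⁻⁷ kcal/mol, 300 bins). The
gauge freedom is fixed by f₁ = 0; the profile G(ξ) = −kT ln P(ξ) is
anchored by shifting the mean of its first and last 10 bins (designated
bulk) to zero. Each window discards leading equilibration frames (the
source protocol's convention: 3 of 10 ns) before binning.

Numerical choices: biases enter as precomputed Boltzmann factors (underflow
to zero is harmless); bins never visited by any window carry +inf and are
excluded from shifting and features; an internal run of empty bins longer
than 5% of the grid aborts with a disconnected-coverage error naming the
gap. With a single zero-force window the equations degenerate to direct
Boltzmann inversion of the histogram, which the tests verify bin-wise.

Uncertainties follow the block convention: the retained samples of every
window are split into 7 contiguous blocks (one simulated nanosecond each),
WHAM + shift is re-solved per block, and the per-bin SEM across blocks
(n−1 denominator) is reported, matching the "mean ± SEM (n = 7)"
convention of replica-blocked free-energy figures.

Feature extraction reads three scalars off a shifted profile: the maximum
inside a user-supplied selectivity-filter interval (defaulting to the 10%
of the coordinate nearest the luminal end, since no numeric bounds are
universal), the global minimum, and the luminal→cytosolic barrier — the
maximum past the minimum (toward increasing ξ) minus the minimum. A
profile with a −4.1 kcal/mol minimum before a 2.8 kcal/mol barrier thus
yields a 6.9 kcal/mol climb.

## Pore profiling (`pore`)

The pore radius at slice z is the largest-inscribed-sphere clearance
r(z) = max_{x,y} min_i(|p − a_i| − r_i), maximized per slice by multi-start
Nelder–Mead continued from the previous slice's center. Because the
clearance is unbounded outside the channel wall, the search is softly
confined to a disc (default 3 Å) around the continuation center and the
initial center must lie inside the pore — the same convention as HOLE's
seed point. Slices whose clearance exceeds a cap (default 15 Å) are set to
the cap and flagged. Van der Waals radii come from a Bondi element table,
or per-atom from the PDB occupancy column (the synthetic fixtures' way of
carrying exact radii); waters and common ions are excluded by default.

The synthetic fixtures are stacked rings of spheres whose centers sit at
`profile(z) + vdw` from the axis. For steep profiles the true inscribed
radius at z is set by *neighboring* rings,

    r(z) = min_{z_r} sqrt((profile(z_r)+vdw)² + (z−z_r)²) − vdw,

which `synth.analytic_inscribed_radius` provides as the exact oracle; the
profiler reproduces it to ~1e-7 Å on cylinder and hourglass fixtures (the
angular ripple of a 72-atom ring stays below 0.01 Å for wall radii ≤ 7 Å).
Replica profiles are averaged with per-z SEM (n−1); the Kabsch
superposition utility (proper rotation enforced via the SVD determinant
correction) supplies RMSD between conformations.

## Hydration counting (`hydration`)

First-shell hydration numbers are counts of water *oxygens* (standard
practice; whole-molecule counting would only rescale by one) within a
species-specific cutoff of the ion, minimum-image under an orthorhombic box
when given. Default cutoffs sit at the first minimum of the ion–oxygen
RDF: K⁺ 3.5 Å, Na⁺ 3.2 Å, Ca²⁺ 3.2 Å; the cutoff used is recorded in every
output. Per-window count series are aggregated as block means ± SEM with
the same 7-block convention as the free-energy errors.

## Permeation counting (`permeation`)

Complete crossings of a selectivity-filter slab are registered by a
two-plane hysteresis state machine: an ion last seen strictly below the
lower plane must later be seen strictly above the upper plane (or vice
versa); rattling between or across a single plane counts nothing, and after
an event the ion must fully exit on the far side before an
opposite-direction event can begin. Periodic z series are unwrapped by
minimum-image increments first, and the planes are replicated every box
length, so a recirculating ion is counted once per full passage; an
increment of ≈ box/2 is flagged as an ambiguous unwrap. The net count
equals the band displacement (winding number) of the unwrapped coordinate,
which the tests verify against an independent midplane tracker on 100
random scripted fixtures. The slab bounds are required input (with a
helper convention of filter-residue center ± margin when a structure is
available); which side is the cytosol is explicit, fixing the sign mapping
between upward events and the cytosol→lumen direction.

Replica summaries report mean ± SD (n−1), the min–max range and the median
per direction and in total. Two conversions connect counting to
electrophysiology: a uniform applied field E (kcal·mol⁻¹·Å⁻¹·e⁻¹) across a
box of length L_z corresponds to ΔV = E·L_z·0.0433641 V (0.180 across
128.1 Å ≈ 1 V), and a channel of conductance G at voltage ΔV for time Δt
passes N = G·ΔV·Δt/(|z|e) ions — 80 pS × 1 V × 500 ns ≈ 250 monovalent
ions.

## GHK analysis (`ghk`)

For species X (valence z, permeability P, concentrations in mM) the
charge-weighted GHK flux at voltage V (convention V = φ_cyt − φ_lum;
positive flux = cations moving cytosol→lumen) is

    Φ_X(V) = P z u ([X]_cyt − [X]_lum e^{−u}) / (1 − e^{−u}),  u = zFV/RT,

the constant-field current equation up to a common factor. It is evaluated
through expm1 and takes its analytic V→0 limit P z ([X]_cyt − [X]_lum)
exactly at V = 0, so the function is numerically continuous through the
origin. The full expression is used for divalents too (rather than the
bi-ionic Fatt–Ginsborg shortcut), so arbitrary mixtures solve uniformly;
the V = 0 closed form z_A[A]_cyt/(z_B[B]_lum) is retained as an internal
cross-check of the bi-ionic solver. Total current (∝ Σ_X Φ_X) is strictly
monotone in V, and its unique zero — the reversal potential — is found by
Brent's method on [−0.5, 0.5] V. Under bi-ionic conditions the measured
reversal potential fixes the permeability ratio: 150 mM K⁺ (cytosolic)
against 15 mM Ca²⁺ (luminal) reversing at 0 mV gives P_Ca/P_K = 5 exactly.
Temperature defaults to 298.15 K; activities equal concentrations.

The GHK model's defining assumption — independent ion movement — is exactly
what a single-file pore violates. The lattice model
(`synth.lattice`) makes this contrast quantitative: two species enter an
8-site single-file pore from opposite ends (illustrative rates, 100 ns⁻¹
entry at the driven ends, 50 ns⁻¹ symmetric hopping; no kinetic claims
about any real channel) and hop with or without site exclusion. Without
exclusion both species sustain opposing net fluxes (the GHK picture); with
exclusion at high load (mean occupancy ≥ 0.8) the opposing fluxes block
each other and drop by far more than 50% — the mechanism by which a small
opposing gradient can null a large flux in a single-file pore without any
actual counter-permeation, and hence why GHK-derived "relative
permeabilities" of such pores mislead.

## What the synthetic data does and does not show

The generators emulate the statistical structure the estimators assume:
Boltzmann-distributed biased sampling on a known landscape, scheduled slab
crossings with sub-margin noise, axisymmetric pore walls with exact radii,
scheduled hydration shells, and Markovian lattice transport. They do not
emulate a protein: no 3D conformational coupling, no anisotropic or
position-dependent diffusion, no correlated multi-ion electrostatics, no
water structure. Passing tests therefore certify the *estimators*
(planning, reweighting, anchoring, error blocks, geometry optimization,
event counting, root solving) at the study's stated protocol parameters;
they say nothing about force fields or sampling adequacy of any real MD
system, which is precisely the division of labor intended.

Problem sizes used by the test suite and the acceptance script — 20
windows × ~2×10⁴ retained samples for WHAM recovery (RMSE ≈ 0.1–0.2
kcal/mol vs the 0.3 acceptance bound), 10⁶-step sampler checks, 100 random
crossing fixtures, 400 ns lattice runs — were chosen as the smallest sizes
at which the expected statistical resolution cleanly separates pass from
fail.

## Known limitations

- WHAM error bars are block SEMs; no autocorrelation-corrected or MBAR
  estimator is provided (by design, matching the source protocol).
- The 1D bias is the only term entering WHAM weights; flat-bottom and
  exclusion restraints shape sampling but are excluded from w_j(ξ), as in
  protocols where they act on coordinates orthogonal to ξ.
- The pore profiler assumes a pore roughly aligned with z and a seed point
  inside it; it does not trace arbitrary curved channels.
- The lattice model is a qualitative mechanism demonstration; its rates are
  not calibrated to any measured conductance.
- A second literature ionic condition reported to give P_Ca:P_K ≈ 1:10
  cannot be reproduced here because its concentrations are not specified in
  the source; the bi-ionic solver handles any fully specified condition.
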