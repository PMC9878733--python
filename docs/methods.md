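# Methods

## Model and inverse problem

The package solves the structure-based coarse-graining problem: find
pair potentials `u_ab(r)` between bead types `a, b` whose equilibrium
radial distribution functions match given targets `g_tgt,ab(r)`.  All
potentials are stacked into one vector `u` (lexicographic in the sorted
type names, AA before AB before BB; each interaction tabulated on a
uniform grid `r_i = i·Δr` up to `n_cut` points), and likewise the RDFs
up to `n_res ≥ n_cut` points.  An update scheme produces `Δu_k` from
the residual `g_tgt − g_k`:

* **IBI** — `Δu = kT ln(g_k/g_tgt)`, the diagonal logarithmic update.
  It is the exact one-step solution when `g = exp(−u/kT)·q(r)` with a
  potential-independent `q`, which is precisely the situation in the
  RDF onset region; this is why IBI is so stable there.
* **Newton (HNCN, IMC)** — `Δu = J⁻¹(g_tgt − g_k)` with a square
  Jacobian on the cutoff range.
* **Gauss–Newton (HNCGN, IMCGN)** — minimise
  `‖W(g_tgt − g_k − J Δu)‖₂` subject to optional linear constraints
  `K Δu = d`, over potential columns up to `n_cut` and residual rows up
  to `n_res`.

### The HNC route

The hypernetted-chain closure `g = exp(−u/kT + h − c)` (with
`h = g − 1` and the direct correlation function `c`) inverts to
`u = kT (h − c − ln g)`, used both as the initial guess and,
differentiated, as the Jacobian inverse

    (du/dg)_{Ii,Jj} = kT [ δ_IJ δ_ij (1 − 1/ḡ_i) − (dc/dh)_{Ii,Jj} ],

where the diagonal uses `ḡ = (g_tgt + g_k)/2` — the "a-Newton"
stabilisation.  Because `|g_tgt − g_k| ≤ 2ḡ` identically, every onset
update stays bounded by about `2 kT` no matter how many orders of
magnitude the two RDFs differ there.

`c` follows from `h` through the RISM equation.  For molecules with
`n_a` indistinguishable sites of type `a`, the site-site equation
collapses under a block-orthonormal similarity transformation to
bead-type matrices per wave vector: with

    H_ab = sqrt(n_a n_b) ĥ_ab,
    W_ab = (n_a n_b)^(−1/2) Σ_{site pairs} ŵ_ss'   (ŵ = sin(kb)/(kb)),
    ρ_a  = N_a / (n_a V)     (molecule number density per site),

the reduced equation reads `H = W C W + W C ρ H`, solved as
`C = W⁻¹ H (W + ρH)⁻¹`.  These conversion factors are pinned by a test
against an explicit full-site-matrix solve of the rigid A–B–A trimer
(agreement ~1e-12 relative).  Differentiating the same map and
vectorising gives the per-k operator
`dC/dH = (Z⁻¹)ᵀ ⊗ [W⁻¹(I − H Z⁻¹ ρ)]`, `Z = W + ρH`; conjugation with
the discrete radial Fourier matrix produces the real-space `dc/dh`
matrix, with the ab/ba duplicates merged (rows averaged, columns
summed).  Verified element-wise against central finite differences of
the direct-correlation map for mixtures and for the bonded trimer.

### The IMC route

The pair-count vector `S_ab,i = g_ab(r_i)·4π r_i² Δr N_a N_b/((1+δ_ab)V)`
has the exact response `dS/du = −(1/kT)·cov(S, S)` in the canonical
ensemble; dividing rows by the `S↔g` factor gives `dg/du`.  Statistics
must come from constant-volume sampling (a barostat biases the count
correlations; NpT input is rejected).  The estimated Jacobian is noisy
where sampling is poor, so rows whose reference RDF value
(`min(g_tgt, g_k)` per element, configurable) lies below `t₂ = 0.1`
are blended toward the diagonal low-density row `−ḡ/kT` with weight
`w = sqrt((g − t₁)/(t₂ − t₁))`, becoming the pure diagonal below
`t₁ = 0.001`.  The square root compensates the exponential growth of
the RDF through its onset.

### Constraints

For any observable φ(r, g, u), linearising around the current iterate
yields one row `K Δu = d` with `d = φ_k − φ_tgt`; `d = 0` exactly at
satisfaction.  Implemented: the virial pressure (ideal term
`Σ ρ_a kT` plus the discrete pair-virial over half-shifted grid points,
forces by centred differences, the `2 − δ_ab` factor from the
unrestricted double species sum), the Kirkwood–Buff integrals
`G_ab = Σ_i 4π r_i²(g−1)Δr` up to `n_res` (one row per constrained
interaction, routed through the step's own Jacobian via
`Δg ≈ J Δu`), and the intermolecular potential energy per bead
(intensive by construction; valid for molecules without intramolecular
pair potentials).  Pressure and energy are linear in `u` at fixed `g`,
so their rows are exact; their `g`-response is neglected, a good
approximation once RDF changes per iteration are small.  The
constrained least-squares problem is solved by direct elimination (QR
of `Kᵀ`, null-space method); feasibility `‖KΔu − d‖∞ ≲ 1e-16` is logged
at every step.  Rank-deficient or inconsistent constraint sets raise,
naming the offending rows.

### Onset extrapolation

Atomistic RDFs vanish at short range and their onset is poorly
sampled.  Before any update, `−ln g` is fitted with `a·e^{−br} + c`
over the window of RDF values `[0.001, 0.1]` (both thresholds
configurable; the fit needs at least 4 points, else the window must be
widened) and values below the threshold are replaced by `e^{−f}`.
The replaced region is floored at 1e-250 so that exponent underflow can
never reintroduce exact zeros into the closure logarithms.  On fit
failure a log-linear fallback (c = 0) is used.

## Surrogate forward model

The paper-of-record workflow evaluates `g(u)` by molecular dynamics;
here a deterministic self-consistent solver stands in: Picard iteration
alternating the reduced RISM equation (h from c) with the HNC closure,
mixing factor 0.2, tolerance 1e-10 on `max|Δg|`, with early abort on
divergence.  Two consequences worth stating plainly:

* The surrogate *is* the HNC model, so the HNC Jacobian is the exact
  derivative of the forward map (finite-difference agreement ~1e-9)
  and the HNC initial guess is essentially exact.  Closed-loop tests
  therefore start from the PMF guess, which is genuinely wrong at
  finite density, so the iteration has real work to do.  Against MD
  data the HNC machinery is approximate and convergence is slower;
  passing tests here demonstrate the correctness of the machinery, not
  HNC's physical accuracy.
* Warm starting: the driver's forward adapter reuses the previous
  solution's direct correlation functions as the starting point,
  keeping the solved branch continuous along the iteration the way an
  MD engine carries its configuration.  Cold-started Picard can land
  on a different branch or fail to converge even where a solution
  exists.

Synthetic-data generators emulate two statistical features of real
trajectory analysis: multiplicative RDF noise with per-bin standard
deviation `sqrt(g/(4π r² Δr ρ N n_frames))` (Poisson counting in a
histogram shell; clipped at zero, seeded) and pair-count ensembles
drawn from a multivariate normal whose covariance is the solver's own
exact response matrix `−kT·diag(factors)·dg/du`, symmetrised and
projected onto the positive-semidefinite cone.  They reproduce the
`N^{−1/2}` scaling of estimator noise but not its non-Gaussian tails,
bin-to-bin correlation structure from finite box size, or equilibration
transients.

## Study conditions (toy systems)

* `lj_fluid` — single-bead Lennard-Jones fluid with the argon
  parameters (σ = 0.3401 nm, ε = 0.978628 kJ/mol), 2250 beads in
  125 nm³ (ρ = 18 nm⁻³) at 100 K; a dense supercritical fluid.
  Grid Δr = 0.004 nm, tables to 2.048 nm, cutoff 1.0 nm.
* `ne_ar` — the 1:1 neon–argon mixture (σ_Ne = 0.278 nm,
  ε_Ne = 0.28869 kJ/mol; geometric combination for the cross pair) at
  100 K on the production grid Δr = 0.002 nm, tables to 2.4 nm, cutoff
  0.9 nm.  Density 250 + 250 beads in 250 nm³ (ρ_tot = 2 nm⁻³), the
  dilute branch: at 100 K this mixture is close to its plait point over
  a broad band of intermediate densities, where intermediate potentials
  of an iteration can have no homogeneous solution at all; the dilute
  branch keeps the full closed loop well posed, which is the property
  the toy must have.  (The reference workflow chose its MD settings by
  the same criterion — conservatively, so that every iteration is
  stable.)
* `trimer` — rigid symmetric A–B–A molecule (bond 0.25 nm, collinear),
  multiplicities n_A = 2, n_B = 1, 500 molecules in 160 nm³ at 300 K;
  exercises the symmetry-reduced RISM path with 2×2 reduced versus 3×3
  site matrices.

## Numerical choices

* Units: nm, kJ/mol, K; `k_B = 0.00831446 kJ/(mol·K)`; pressures
  reported in bar; KBIs in nm³ (×10³ for Å³).
* Radial transforms by type-I discrete sine quadrature with
  `Δk = π/(nΔr)`; the pair is an exact round trip on all bins `r > 0`;
  the `k = 0` element uses the analytic limit `4π Σ r² f Δr`.  The
  `r = 0` bin has zero quadrature weight and carries no information.
* The intramolecular matrix of a rigid molecule is exactly singular at
  `k = 0`; all per-k matrix algebra skips that wave vector and
  continues its slice from `k = Δk` (affects only the weightless
  `r = 0` bin).
* Residual sign convention repository-wide: `r = g_tgt − g_k`, updates
  solve `J Δu ≈ r`.  Constraint rows store `K = −∂φ/∂u − (∂φ/∂g)J`,
  `d = φ_k − φ_tgt`.
* Gauss–Newton least squares via LAPACK `gelsd` with a relative
  singular-value cutoff of 1e-10; the default row weights are
  `r²/(g_tgt + 1e-30)` (onset and tail emphasis).  The weights and the
  Jacobian rows scale inversely in the onset, so the weighted system
  stays bounded even where `g_tgt` underflows.
* Update scaling (`scale=0.67`) damps overshooting updates; with
  scaling, the logged constraint feasibility refers to the equally
  scaled right-hand side.
* The one-time (`t-`) closure derivative should be computed from
  curves at least twice the residuum range; shorter input produces a
  truncation warning.
* The divergence detector aborts after three consecutive growths of
  `chi(g)` (ignoring plateau wiggles below 1e-10) and suggests update
  scaling.
* Potentials are cut at `r_cut` and shifted to zero beyond after every
  update; the grid point at the cutoff is pinned to zero and excluded
  from the update variables, as is the `r = 0` bin.

## Known limitations

* The RISM intramolecular input is static (fixed distances or fixed
  distributions); the true Jacobian's bending of cross-block
  structures when molecules approach is not modelled.
* Percus–Yevick closure, charged/long-range splitting, and a
  surface-tension constraint are out of scope.
* Combined KBI + pressure constraints can oscillate on the mixture toy
  even with damping (each constraint individually converges); the
  driver aborts with the divergence detector rather than masking it.
* The Picard solver handles dilute and moderately dense states; deep
  in the liquid branch the basin of convergence for off-optimal
  potentials narrows, which limits closed-loop experiments to state
  points chosen as described above.
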