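# Methods

## Model

The engine treats one elementary reaction step as a two-state empirical
valence bond (EVB) system. Two diabatic states with energies ε₁ and ε₂
(kcal/mol) represent the reactant-like and product-like bonding patterns on a
common geometry; a gas shift α (added to ε₂ throughout: mapping, eigenvalue
and gap operations alike) and an off-diagonal coupling H₁₂ complete the 2×2
Hamiltonian whose lowest eigenvalue is the adiabatic ground state. The
coupling is either a constant or the exponential form A·e^(−μ(r_DA−r₀)) in
the donor–acceptor distance; only evaluation of the exponential form is
supported, not fitting of (A, μ).

The reaction coordinate is the energy gap x = ε₁ − (ε₂+α). Its sign
convention puts the reactant basin at negative x (⟨x⟩ = −(λ+ΔG₀) in the
reactant window under linear response). The gap — not a geometric
coordinate — carries the environment's electrostatic reorganization, which is
what changes between sequence variants.

## Estimators

**Window accumulation.** Sampling runs on the mapping potential
ε_m = (1−θ)ε₁ + θ(ε₂+α) over a window schedule θ: 0 → 1. Mapping free
energies ΔG_m come from Zwanzig exponential averaging between adjacent
windows, forward (window-m frames) by default; a reverse and a
forward/reverse-averaged estimator are available as hysteresis checks.
Per-increment standard errors use batch means (10 contiguous batches), which
absorbs the autocorrelation left after frame thinning; increment variances
add along the accumulation.

**Profile reweighting.** Every frame of every window is binned on x and
reweighted from ε_m onto the target surface (ground state or one diabat):
Δg_m(x′) = ΔG_m − β⁻¹ln⟨1_{x∈x′}e^{−β(E_t−ε_m)}⟩_m, evaluated with
log-sum-exp shifting for overflow safety. Default binning is 50 equal-width
bins over the observed gap range; per-(window, bin) contributions with fewer
than 10 frames are dropped, and surviving contributions are merged by
count-weighted averaging after the ΔG_m offsets. The profile is gauge-fixed
to zero at the reactant-side minimum.

**Stationary points.** Basin minima are located on a 3-bin moving-average
copy of the profile and must clear a prominence of 0.5 kcal/mol — without
that filter, statistical dips on a rising flank occasionally masquerade as a
product basin and corrupt ΔG₀ by ~1 kcal/mol. The reactant state is the
leftmost basin, the product state the rightmost, the transition state the
maximum between them. Values are refined on the raw bins: quadratic fits
over ±3 bins at smooth extrema; at H₁₂ = 0 the ground surface has a genuine
cusp at the diabatic crossing, where a quadratic fit biases the barrier low
by several tenths of a kcal/mol, so the barrier top is instead taken as the
intersection of straight-line fits to the two branches (apex bin excluded).
Raw bin-level values are retained in the result for audit.

**Bin-width resolution.** A binned free energy is an exponential average over
the bin, which sits below the point value on a slope a by roughly
k_BT·(βaw)²/24 (w = bin width) and more at a cusp apex. At the default
problem sizes (2×10⁴ steps/window, 100 bins for quantitative work) this
plateaus near 0.1 kcal/mol; accuracy-sensitive checks therefore treat
0.15 kcal/mol as a floor on profile standard errors rather than trusting a
lucky replicate spread. 50 bins remain the API default for quick-look
profiles.

**Reorganization energy.** λ̂ = |⟨x⟩_{θ=1} − ⟨x⟩_{θ=0}|/2 from the endpoint
windows (the absolute half-difference; the sign convention of the printed
form is absorbed by the modulus, which matches the surrogate's analytic λ).
The gas shift cancels in the difference. The profile-level estimate
(x_PS−x_RS)/2 is reported when endpoint windows are absent.

**Marcus barrier.** ΔG‡ = w_r + (ΔG₀+λ)²/4λ − H₁₂(TS) + H₁₂(RS)²/(ΔG₀+λ),
classical limit: the nuclear quantum correction Γ is fixed at 1 and the work
term w_r defaults to 0 (pre-assembled reactants); both are overridable.
ΔG₀ + λ ≤ 0 (inverted region) is rejected rather than extrapolated.

## Calibration

The reference-state fit adjusts (α, H₁₂-constant) until the full FEP/US
pipeline reproduces a reference reaction's (ΔG‡, ΔG₀) within a tolerance
(default 0.1 kcal/mol). The solver alternates two one-dimensional solves
inside an outer loop (max 20 iterations): secant iteration on α targeting
ΔG₀ — under linear response ΔG₀ responds with unit slope to a uniform shift
of diabat 2, so the first step is a unit-slope Newton step — then bisection
on H₁₂ ∈ [0, barrier at H₁₂=0] targeting ΔG‡, which is monotone in the
coupling. Fresh frames are sampled whenever α changes (α enters the mapping
potential); the same frames are reused across the H₁₂ bisection because the
mapping ensemble is independent of the off-diagonal coupling — an exact
reuse, not an approximation. Convergence is declared only after both targets
are met on a freshly seeded verification sample; every sampling is logged in
an iteration trace carried by the result (and by the failure exception).

## Surrogate sampler

The sampler that stands in for the MD engine uses two harmonic,
equal-curvature diabats on one scalar coordinate: ε_i(s) = ½k(s−s_i)² + c_i.
This is the linear-response picture in which every quantity the pipeline
estimates has a closed form — λ = ½k(s₂−s₁)², ΔG₀ = c₂−c₁, diabatic barrier
(λ+ΔG₀)²/4λ, mapping free energy ΔG(θ) = θ(ΔG₀+α) + λθ(1−θ), and Gaussian
gap statistics giving parabolic diabatic free-energy functions with
curvature 1/4λ. Defaults: k = 20 kcal/mol/unit², 300 K, an optional harmonic
restraint on the coordinate (the analogue of the weak positional restraint
kept on reacting atoms in a real setup).

Sampling is Metropolis on the mapping potential: uniform proposals of
half-width 2.5·√(k_BT/k_eff) (≈ 40–50% acceptance on a harmonic well),
chains started at the potential minimum, frames retained every 5 steps
counting back from the final step so that at least the first 20% of the
chain is discarded as burn-in — max(1, ⌊0.8n/5⌋) frames per window, at least
one even for a single-step chain. All random numbers are drawn from a
PCG64 generator seeded outside the (numba-compiled) kernel, so identical
seeds give bit-identical frame tables; window, task and calibration seeds
all derive from a master seed by a stable 64-bit hash of the structural
identity.

**Variant effects.** A synthetic mutant library is defined by
per-substitution shifts (δΔG₀, δλ): listed substitutions use their listed
values, unlisted ones draw both deterministically from the master seed via a
normal law (sd 1.5 kcal/mol by default — a fixture choice of plausible
single-mutation magnitude, not a claim about any enzyme). Shifts compose
additively; sorted position pairs can carry explicit epistasis terms on ΔG₀,
which is how cooperative multi-mutants are planted. λ shifts rescale the
minima separation at fixed curvature and are floored at 1 kcal/mol with a
warning rather than allowed through zero.

**What the surrogate does and does not emulate.** It reproduces the
statistics that the estimators actually consume — Gaussian gap fluctuations,
window overlap, burn-in and autocorrelation, seed-dependent noise, variant-
and epistasis-dependent energetics. It has no explicit atoms, no
multidimensional solvent coordinate, no non-linear response, no sampling
traps or slow conformational changes. Passing tests therefore validate the
estimators, the calibration logic and the campaign machinery; they say
nothing about force-field quality or conformational sampling adequacy in a
real protein, which remain the dominant error sources with an MD engine
behind the same frame-table interface.

## Campaign layer

The default window schedule is the 26-θ list
(0, 0.05, 0.075, …, 0.45, 0.55, …, 0.95, 1) of 20 ps windows, with θ = 0.5
deliberately absent: frames there come from the preceding equilibration
stream, run at the midpoint mapping potential, and join the accumulation as
a pseudo-window between 0.45 and 0.55. One EVB run is 26 × 20 = 520 ps.
The default plan — 4 replicas, 8 ns of MD, snapshots at the end of every
1 ns, the first 2 ns discarded as equilibration — yields 6 snapshots per
replica, 24 tasks per variant and 12.48 ns of EVB time per variant.
Snapshot indexing is end-of-interval; "discard the first 2 ns" removes
snapshots at t ≤ 2 ns, the only reading consistent with 24 tasks. Heating
schedule, restraint scheme, thermostat coupling and time step are carried as
plan metadata for external-engine manifests and never interpreted
internally.

Execution is a work-queue contract: tasks are independent, at most
`workers` run concurrently (threads; the sampling kernel releases the GIL),
every completion is persisted by atomic write-rename, failures are recorded
per task without aborting the campaign, and re-invocation skips completed
tasks. The result store is rewritten in canonical manifest order on every
update, so its bytes depend only on *which* tasks have completed — an
interrupted-and-resumed campaign ends byte-identical to an uninterrupted
one.

Alanine scans skip positions whose wild type is already Ala or Gly (a no-op
or a backbone change) with a notice. Profiles without a barrier are data,
not failures: they are excluded from replicate moments, counted into a
no-barrier fraction, and flagged when that fraction exceeds 25%. Ranking is
by point estimate (mean by default; median available, and every report
states which was used) with ties broken by smaller sd then label; no
multiple-testing correction is applied — sd is reported, not tested. The
"too good to be true" flag marks variants more than 5 kcal/mol below the
wild-type barrier (a qualitative artifact guard made concrete; the value is
a package choice) and hotspot selection skips flagged variants with a
notice.

## Structure bookkeeping

PDB I/O is delegated to gemmi. Alternate locations are resolved on read
(highest occupancy, ties to label 'A'); residue numbering and insertion
codes are preserved exactly. Built-in mutagenesis is truncation: ALA keeps
{N, CA, C, O, CB}, GLY the backbone, each plus hydrogens riding on kept
heavy atoms (riders of removed atoms are removed; the hydrogen→parent map
uses the standard remoteness-letter naming convention). Prolines are
declared unsupported rather than guessed, and crystallographic waters in
the mutated residue's volume are left untouched. Every other target residue
is dispatched to an external rotamer-placement adapter together with an
exclusion set of reacting-region atoms that must not move; wild-type
identity at every site is verified before any change. Region assignment
follows the multi-layer spherical scheme: mobile within 17 Å of the center,
10 kcal/mol/Å² positional restraint to 20 Å, 200 kcal/mol/Å² beyond.

## Problem sizes and numerical defaults

Quantitative runs use 2×10⁴ Metropolis steps per window (3200 frames/window,
~86k frames per run) and 100 bins; campaign screening uses 4×10³ steps and
the 50-bin default, which resolves ~0.5 kcal/mol variant differences with
4–6 replicates. Calibration tolerance 0.1 kcal/mol; temperature 300 K
everywhere unless overridden; k_B = 0.0019872041 kcal/mol/K. Statistical
checks in the test suite compare against closed forms within 3 standard
errors (replicate spread combined in quadrature with the 0.15 kcal/mol
resolution floor above).

## Known limitations

Two states only — no intermediates, no three-state mechanisms. No force
field, MD integrator or boundary model: real sampling enters through the
frame-table contract. Distance-dependent coupling is evaluated, never
fitted. The Γ = 1 classical limit ignores nuclear quantum effects (relevant
for proton transfers at low temperature). Count-weighted merging of window
contributions is simple and slightly suboptimal compared to a full
multistate reweighting solve; it is accurate here because adjacent windows
overlap generously.
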