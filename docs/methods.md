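# Methods

## The mechanical end-state estimator

The package quantifies lipid-packing-defect sensing as the change in the
work of stretching a membrane when a peptide is bound to it. The chain of
assumptions is:

1. **Tension from the pressure tensor.** At fixed box area the lateral
   tension is σ = L_z(P_zz − (P_xx + P_yy)/2), evaluated per frame with
   the per-frame box height inside the time average (the product of two
   fluctuating observables; at constant area with z-only pressure coupling
   the difference from ⟨L_z⟩·⟨ΔP⟩ is tiny, but the per-frame product is
   the defensible ensemble-average estimator). σ is the full bilayer
   tension — no division by two for the two monolayers — so values are a
   factor two above monolayer conventions.
2. **Hookean elasticity.** For small relative strains ε = (A − A₀)/A₀ the
   tension is linear, σ = K_A·ε. Linearity is what licenses the
   trapezoidal rule with only two simulated areas: ΔF_s =
   (σ(A)+σ(A₀))/2·(A−A₀). The multi-point composite-trapezoid mode exists
   to verify this on data; for exactly linear curves the two modes agree
   to machine precision.
3. **End-state sensing formula.** ΔΔF_sensing = ΔF′_s − ΔF_s collapses to
   four tensions. The identity between "difference of works" and the
   four-tension formula is algebraic and is enforced by a property test on
   random curves.
4. **CHAOS.** Dividing by the peptide-free tension drop Δσ = σ(A₀) − σ(A)
   removes the arbitrary end-state choice. With the Hookean generating
   model (below) CHAOS = (1−s)·ΔA/2 + s·ΔA_p: the injected excess area
   plus a softening term, reducing to ΔA_p exactly for a pure area shift.

Units: tensions in mN/m (1 bar·nm = 0.1 mN/m), energies in kJ/mol with
1 mN/m·nm² = 0.60221408 kJ/mol (Avogadro scaling), CHAOS in nm² per
molecule.

## Error model

Tension uncertainties come from contiguous block averaging (default 5
blocks; remainder frames are dropped from the *front*, the least
equilibrated end). Block averaging rather than autocorrelation fitting is
a deliberate simplicity/reproducibility choice; the SEM is exactly zero
for a single block or noiseless data. When independent replica runs are
available, `combine_replicas` supersedes block SEMs with the replica
spread. All downstream errors are first-order quadrature assuming
independent tension estimates (each area is an independent simulation);
the correlation between ΔΔF and Δσ through the shared reference tensions
is ignored in the CHAOS error, consistent with that assumption. The K_A
fit is anchored at the measured σ(A₀) with only the slope free; its
standard error propagates both the per-point SEMs and the anchor SEM —
the anchor term dominates and omitting it understates the error by a
factor ≈ 2 at the default noise level.

Equilibration discards default to 50 ns (coarse-grained profile) or
500 ns (atomistic profile), selectable in the YAML config; time is ps
internally, with `"50ns"`-style durations accepted at the CLI.

## Thermodynamic-integration cross-check

The alchemical route integrates ⟨∂V/∂λ⟩ over λ ∈ [0, 1] (λ = 0 fully
coupled, λ = 1 peptide in vacuo) separately for the van der Waals and
Coulomb legs, by composite trapezoid (default; exact for affine profiles)
or Simpson (odd grids). The leg error is the quadrature of per-λ SEMs
with trapezoid weights; a max-second-difference diagnostic flags profiles
too rough for the grid. Consistency between the mechanical and alchemical
ΔΔF is judged by a two-tailed Welch's t test on replicate means with the
Welch–Satterthwaite degrees of freedom; "closed" means p > 0.05. Equal
means with zero variance count as closed; unequal means with zero
variance are non-closed with p undefined.

## Synthetic data

The generator emulates the *reduced observables* of constant-area runs,
not the simulations themselves. A Hookean membrane+peptide model
(defaults: A₀ = 42.4 nm², K_A = 240 mN/m, L_z = 10 nm — a small
coarse-grained POPC patch; area grid 42.4–49.4 nm² in 1.4 nm² steps, six
areas, up to 16.5 % strain) emits per-frame tensions as its mean tension
plus AR(1) noise (default sd 50 mN/m, correlation time 100 ps, frames
every 10 ps — fluctuation scales typical of a ~40 nm² patch), decomposed
into diagonal pressures with P_zz pinned at 1 bar (z-only barostat).
Recomputing the tension from the emitted pressures recovers the injected
series exactly, so the generator is its own oracle. The matching λ-legs
use a fixed degree-4 profile shape g(λ) = 1 + 10·λ²(1−λ)²; only its
integral is contractual, and since g′(0) = g′(1) = 0 the leading
trapezoid error term vanishes, closing the thermodynamic cycle to
< 10⁻³ kJ/mol on a 37-point grid by construction. The solvation baseline
(−300 kJ/mol) is peptide-state-independent and cancels between tension
states.

What the generator does **not** emulate: force-field-specific values,
peptide unbinding/refolding events, slow conformational drift,
non-Hookean response at large strain, or finite-size pressure-tensor
artifacts. Passing tests therefore validate the estimators and their
calibration under the stated statistical model, not the behavior of any
particular force field.

## Geometry

Buckled-membrane curvature κ = z″/(1+z′²)^{3/2} is differentiated on a
periodic FITPACK smoothing spline (smoothing parameter exposed;
interpolating by default), with a finite-difference mode as cross-check —
raw second differences on noisy neutral-plane data are unusable. A buckle
is cylindrical, so vesicle mean curvature is half the cylindrical value.
The strain↔vesicle-size map uses the thin-shell form ε = 2d/R with the
leaflet neutral-plane offset d defaulting to 1.03 nm, calibrated so that
16.5 % strain corresponds to a 25 nm diameter vesicle; d is exposed
because it is a model choice, not a measured constant.

## Evolutionary optimizer

Fixed-length sequences over the 20 canonical amino acids evolve by
rank-based selection (top n_parents), single-point crossover at a
uniformly chosen cut, per-residue point mutation, and elitism (defaults:
population 32, parents 8, crossover 0.9, mutation 0.02/residue, elites 2,
24 residues). Fitness is minimized; with at least one elite the best
fitness is monotone non-increasing. The built-in surrogate fitness is the
negative sum of per-residue scores (Kyte–Doolittle hydropathy plus
aromatic bonuses of +8 for W and +4 for F, making poly-tryptophan the
strict optimum) — a fast toy encoding of the aromatic-enrichment
signature of strong defect sensors, with no claim of matching any
simulation-derived fitness. Simulation-backed fitness functions plug in
as callables returning a ΔΔF_sensing per sequence.

Convergence is flagged when the best fitness is *unchanged* for a stall
window of 5 consecutive generations, a standard early-stopping patience.
On the 24-residue surrogate landscape this flag typically does **not**
trip within 25 generations: with ~14 point mutations per generation
across the offspring, strictly improving mutations keep arriving nearly
every generation until far more of the sequence is optimal than 25
generations can reach, so observed best-fitness plateaus in the first 25
generations are ≤ 4 generations long. A shorter window (1–2 generations)
would trip early but would label transient plateaus as convergence, which
we consider misleading; on small enumerable spaces (e.g. a two-letter,
four-residue toy) the optimizer reaches the brute-force optimum and the
flag behaves as intended.

## Problem sizes

Stochastic checks use 4 000-frame traces per area (six areas per curve),
100 000-frame traces for single-tension recovery, 100 seeds for the
end-state/multi-point agreement rate, 20 replica sets (3 mechanical + 3
alchemical replicas each) for the closure fraction, and 10 seeds for the
optimizer benchmarks; these sizes make the full suite and the acceptance
script run in seconds while leaving the statistical assertions
well-resolved.

## Known limitations

- Strain is always box-area based; in peptide-bound systems the peptide
  occupies leaflet area, so leaflet strain and box strain differ by the
  (unknown) occupied fraction.
- No constant-tension (NPγT) ensemble corrections.
- No MBAR/BAR estimators; TI only.
- The bound/partial/unbound classification thresholds (|z| < 1.5 nm,
  fraction cutoffs 0.9/0.5) are package conventions, not literature
  standards.
- Binary GROMACS energy files (.edr) are not read; plain-text XVG/CSV is
  the reference path.
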