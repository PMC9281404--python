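# chaoscalc

Mechanical end-state estimation of lipid-packing-defect sensing free
energies, and the CHAOS parameter, from constant-area membrane-simulation
time series.

## The problem

Amphipathic helices and other peripheral peptides bind the transient
hydrophobic patches ("lipid packing defects") that appear when a membrane
is stretched or bent. A natural way to quantify this is the relative
binding free energy between a stretched and a tensionless membrane,
ΔΔF_sensing = ΔF′_b − ΔF_b, but computing both binding terms alchemically
(thermodynamic integration over a λ coupling parameter, separately for van
der Waals and Coulomb interactions) costs of order 37 × 2 × 2 = 148
simulations per peptide.

A thermodynamic cycle converts this into a mechanical problem. Because a
membrane is Hookean for small relative strains ε = (A − A₀)/A₀,

    σ(A) = K_A · ε,

the work of stretching between two constant-area states follows from the
trapezoidal rule, and the sensing free energy reduces to four measured
surface tensions:

    ΔΔF_sensing = (A − A₀)/2 · [(σ′(A) + σ′(A₀)) − (σ(A) + σ(A₀))],

where primes mark the peptide-bound system. Each tension comes from the
diagonal pressure tensor of a constant-area run,

    σ = L_z · (P_zz − (P_xx + P_yy)/2).

ΔΔF_sensing < 0 means the peptide senses defects. Because its magnitude
depends on the arbitrary choice of end states, the package also computes
the end-state-invariant **CHAOS** parameter (characteristic area of
sensing),

    CHAOS = ΔΔF_sensing / Δσ(A),   Δσ(A) = σ(A₀) − σ(A)  (peptide-free),

which has units of area per molecule (nm²) and can be read, in part, as
the leaflet area the bound peptide injects.

The package implements this pipeline end to end: XVG/CSV ingestion,
block-averaged tension estimation, stretch-curve fitting (K_A), end-state
and multi-point sensing free energies with propagated errors, the
CHAOS invariance profile, a TI module with a Welch's-t cycle-closure test,
geometry mappings (strain ↔ vesicle radius, buckle curvature profiles), a
cycle-consistent synthetic-data generator with closed-form ground truth,
and a genetic-algorithm peptide optimizer with a pluggable fitness.

## Worked example

```python
import chaoscalc as cc

# a Hookean membrane (K_A = 240 mN/m, A0 = 42.4 nm^2) plus a peptide that
# injects 0.5 nm^2 of leaflet area and softens the membrane by 10%
ref_model = cc.HookeanMembraneModel(noise_amp=0.0)
pep_model = cc.HookeanMembraneModel(dA_p=0.5, softening=0.9, noise_amp=0.0)

ref, pep = cc.generate_stretch_curves(ref_model, pep_model, n_frames=10, seed=0)
result = cc.SensingModel(ref, pep).fit(mode="end_state")
print(result.summary())
```

prints

```
Packing-defect sensing summary — peptide
==============================================
mode             end_state
end states       A0 = 42.400 nm^2, A = 49.400 nm^2
ddF_sensing        -19.0890 +/- 0.0000 kJ/mol
delta_sigma(ref)   -39.6226 mN/m
CHAOS                0.8000 +/- 0.0000 nm^2
verdict          sensor (ddF < 0)
```

The negative ΔΔF says stretching the membrane is 19.1 kJ/mol cheaper with
the peptide bound, i.e. the peptide is a packing-defect sensor; the CHAOS
value of 0.80 nm² decomposes exactly (for this Hookean model) into
s·ΔA_p = 0.45 nm² of injected area plus (1−s)·ΔA/2 = 0.35 nm² from the
softening, and the pipeline recovers it to machine precision.

The same analyses run from the shell on real reduced time series:

```sh
chaoscalc tension --xvg run.xvg --area 42.4 --discard 50ns --blocks 5
chaoscalc sense --ref ref_curve.csv --pep pep_curve.csv --mode end_state
chaoscalc geometry strain2radius --eps 0.165
```

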