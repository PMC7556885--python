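# hydrosub

Analysis of anomalous sub-diffusion of hydration water around biomolecules,
for people working with quasi-elastic neutron scattering (QENS) spectra
and/or particle trajectories of interfacial water: spectroscopists fitting
backscattering data, and simulators connecting molecular trajectories to a
coarse-grained picture of heterogeneous mobility.

## The science

Water at a biomolecular surface does not diffuse normally: its
mean-squared displacement grows as ⟨x²(t)⟩ ∼ t^β with β < 1. The package
implements the full chain of analysis that quantifies this and traces it
back to mobility heterogeneity:

1. **Susceptibility conversion.** A measured dynamic structure factor
   S(q, ν) is converted to the imaginary susceptibility
   χ″(q, ν) = S(q, ν) / n_B(ν), with the Bose occupation
   n_B(ν) = 1/(exp(hν/k_BT) − 1). Relaxations appear as peaks at
   ν_peak = 1/(2πτ).
2. **Cole–Cole fitting.** Each q-slice is fitted with

   χ″(ν) = χ₀ (2πντ)^(1−α) cos(πα/2) / [1 + 2(2πντ)^(1−α) sin(πα/2) + (2πντ)^(2(1−α))]

   where τ is the relaxation time (ps), χ₀ the relaxation strength and
   α ∈ [0, 1) the symmetric broadening: α = 0 is the single-timescale
   Debye lineshape, larger α means a broader distribution of underlying
   relaxation times (more heterogeneous water mobility).
3. **q-scaling.** τ(q) follows a power law τ ∼ q⁻ⁿ; since τ is the time
   to diffuse a distance ∼ 2π/q, the MSD exponent is β = 2/n (n = 2 is
   Fickian diffusion; n > 2 means sub-diffusion).
4. **Residence times.** From trajectories, the mobility of a single
   molecule is its residence time τ_res — the first-passage time to move
   3.5 Å (one coordination-shell radius), extracted sequentially with
   reset. P(τ_res) and its second moment ⟨(τ_res − ⟨τ_res⟩)²⟩ quantify
   heterogeneity, optionally resolved by 3.5 Å hydration layers above a
   planar surface.
5. **Random-jump (CTRW) simulator.** An event-driven one-dimensional
   walk with constant jump length l₀ and waiting times drawn from a
   parametric law or directly from an extracted P(τ_res). Heavy-tailed
   waits produce sub-diffusion; driving the simulator with a measured
   P(τ_res) and comparing its MSD exponent with the trajectory's own
   tests whether mobility heterogeneity explains the sub-diffusion.
6. **Bulk-like water budget.** With the first two hydration layers
   binding ≈ 1.2 g water/g protein, the bulk-like fraction at hydration
   level h is (h − 1.2)/h.

A synthetic-data module generates Cole–Cole spectra (optionally in raw
Bose-weighted form, with multiplicative noise) and CTRW/layered-slab
trajectories with known ground truth, so every stage is testable without
beamtime or molecular-dynamics runs.

## Worked example

`examples/05_full_pipeline.py` runs a configured end-to-end analysis
(synthetic spectra at n = 2.3, α = 0.23 plus a three-layer water slab
whose surface layer is 16× slower than bulk) and prints:

```
tau(q) exponent n         = 2.297   (generator truth 2.3)
beta = 2/n                = 0.871
alpha averaged over band  = 0.230   (generator truth 0.23)
bulk-like water at h=2.0  = 0.40
beta from trajectory MSD  = 0.833
beta from residence-driven RJ = 0.817
residence: mean 7.46 ps over 59662 samples
```

Reading the numbers: the Cole–Cole fits recover the generator's τ(q)
power law (n ≈ 2.3 > 2, sub-diffusive) and heterogeneity (ᾱ ≈ 0.23) from
the noisy spectra; 40% of the water at h = 2.0 is bulk-like; and the two
independent MSD-exponent routes — directly from the trajectories, and
from the random-jump model driven only by the extracted residence-time
distribution — agree (0.833 vs 0.817), showing that the heterogeneity of
P(τ_res) accounts for the sub-diffusion. The other examples isolate one
capability each (fitting, q-scaling, RJ asymptotics, layer-resolved
residence analysis).

The same pipeline is available from a shell:

```sh
hydrosub run-all --config my_run.yaml --outdir out
```

writing delimited tables plus a single `report.json`.

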