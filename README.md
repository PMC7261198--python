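# h1ntd

Helix–coil modelling and enhanced-sampling analysis of the linker-histone H1
N-terminal domain (NTD).

The H1 NTD is a short, Lys/Arg-rich intrinsically disordered tail. Its basic
subregion — the segment between the first and last Arg/Lys residue, adjoining
the globular domain — mediates DNA binding, and different human subtypes
(H1.0, H1.1, H1.2) differ in charge density and in their content of
helix-breaking Pro/Gly residues. When the Lys charges are screened or
neutralized, charge-dense, breaker-poor subtypes can undergo a
disorder-to-order transition into an amphipathic helix whose basic face
(K14/K17/K20/K21 in H1.0) matches the DNA phosphate spacing. `h1ntd`
provides the complete computational toolbox for studying this transition at
desk scale:

* **sequence analysis** — basic-subregion extraction, composition statistics,
  helical-wheel projection (3.6 residues/turn, 100°/residue) with automatic
  basic-face detection;
* **a coarse-grained helix–coil peptide model** — per-residue helix/coil
  micro-states with Zimm–Bragg-type cooperativity (`E = -kT [Σ_h ln w_i +
  n_runs ln v]`), screened Debye–Hückel sidechain electrostatics with a
  charge-neutralization switch, an optional rigid 20-bp B-DNA rod field, a
  Metropolis Monte-Carlo sampler and an *exact* transfer-matrix oracle;
* **collective variables** — helical content `S_α = Σ_w (1-(ΔRMSD/R₀)⁸) /
  (1-(ΔRMSD/R₀)¹²)` over all six-residue windows (R₀ = 0.08 nm), radius of
  gyration `S_rg`, protein–DNA contacts `S_cont` (R₀ = 0.2 nm, n = 8,
  m = 10) and the in-plane radial binding distance;
* **enhanced sampling** — (well-tempered) metadynamics, the well-tempered
  ensemble (WTE) stage on the potential energy, geometric temperature
  ladders `T_i = T_min (T_max/T_min)^((i-1)/(N-1))`, T-REMD and two-stage
  PTMetaD-WTE with the bias-aware exchange rule
  `P = min{1, exp[(β_i-β_j)(U_i-U_j) + β_i(V_i(S_i)-V_i(S_j)) +
  β_j(V_j(S_j)-V_j(S_i))]}`, and harmonic umbrella sampling;
* **reweighting** — time-dependent bias offsets
  `c(t) = β⁻¹ ln [∫e^{-βF(s)}ds / ∫e^{-β(F(s)+V(s,t))}ds]`, frame weights
  `w(t) ∝ exp(β[V(s,t) - c(t)])` and weighted ensemble averages;
* **ensemble analytics** — helicity assignment (α-like and 3₁₀-like runs
  both count), Rg distributions against the globular (2.2·N^0.38 Å) and
  random-coil (2.02·N^0.60 Å) baselines, single-linkage Cα-RMSD clustering
  (2.5 Å cutoff), per-residue DNA-contact fractions (3.2 Å), free-energy
  surfaces and block-convergence checks;
* **WHAM** — self-consistent weighted-histogram PMF estimation from umbrella
  windows with Bayesian-bootstrap uncertainties and a large-distance zero
  convention.

## Worked example

The subtype report reproduces the basic-subregion composition table and the
helical-wheel faces of the three bundled NTDs:

```sh
$ h1ntd report
subtype  subregion_start  subregion_end  length  n_basic  pct_basic  n_breaker  ntd_length  ntd_n_basic  ntd_pct_basic  face_members
H1.0     12               21             10      6        60.0       1          26          6            23.1           K14,K17,K20,K21
H1.1     17               37             21      9        42.8       3          37          9            24.3           K22,K23,K25,K26,K29,K36,K37
H1.2     17               34             18      8        44.4       4          36          8            22.2           K22,K23,K26,K27,R33,K34
```

Reading the H1.0 row: its basic subregion spans residues 12–21 (10 residues),
6 of which are Lys/Arg (60.0%) with a single Pro/Gly breaker; the full
26-residue NTD is 23.1% basic; and the helical wheel concentrates K14, K17,
K20 and K21 on one face — the amphipathic geometry that favours DNA binding
once the helix forms.

A well-tempered metadynamics run on the bundled analytic double well
(barrier 8 kJ/mol) reconstructs the potential from the deposited bias:

```python
import numpy as np
from h1ntd import MetadParams, run_metad, free_energy_estimate
from h1ntd.toys import DoubleWell1D

dw = DoubleWell1D()
run = run_metad(dw, MetadParams(height=1.2, sigma=(0.12,), stride=25,
                                bias_factor=10.0), n_steps=60_000, seed=1,
                record_stride=20)
grid = np.linspace(-1.4, 1.4, 141)
diff = free_energy_estimate(run.bias, grid) - dw.free_energy_reference(grid)
diff = diff[np.abs(grid) <= 1.3]
print(run.bias.n_kernels)                                   # 2400
print(round(float(np.sqrt(np.mean((diff - diff.mean())**2))), 3))  # 0.398
```

2400 Gaussians were deposited and the recovered profile agrees with the
exact double well to 0.4 kJ/mol RMS (well under thermal noise,
k_BT ≈ 2.5 kJ/mol at 300 K).

Unbiased Monte-Carlo runs of the basic subregions with the shipped model
defaults reproduce the central qualitative result: upon charge
neutralization the per-window helicity ⟨S_α⟩/(L−5) orders
H1.0 > H1.2 > H1.1, and neutralization never reduces helicity
(`h1ntd simulate --subtype H1.0 --neutralized ...`, or see
`scripts/acceptance.py`).

## File formats

FASTA for sequences (Biopython), multi-model PDB for Cα traces, PLUMED-style
whitespace tables with `#! FIELDS` headers for CV time series (COLVAR-like)
and deposited kernels (HILLS-like), and YAML for run configuration. Every
run-producing CLI subcommand (`wheel`, `report`, `simulate`, `metad`,
`remd`, `ptmetad-wte`, `umbrella`, `reweight`, `analyze`, `wham`) takes
`--seed` and writes a provenance log.

See `docs/methods.md` for the model definition, parameter choices,
numerical conventions and limitations.
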