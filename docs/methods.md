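# Methods

This note defines the models and estimators implemented in `h1ntd`, the
conventions and defaults they use, and what the desk-scale synthetic systems
do and do not establish about real peptides.

## Units and conventions

Energies are kJ/mol, lengths nm, temperatures K, with
k_B = 0.0083145 kJ mol⁻¹ K⁻¹. Two quantities follow the Å conventions of
the structural literature and are converted explicitly at their call sites:
the clustering and DNA-contact cutoffs (2.5 Å and 3.2 Å) and the
radius-of-gyration baselines. Residue numbering is 1-based and inclusive
throughout (a span written 16–22 contains seven residues). His is treated
as neutral everywhere.

## Sequence fixtures

The bundled FASTA records are the N-terminal domains of human H1.0 (26 aa),
H1.1 (37 aa) and H1.2 (36 aa), UniProt-derived, with numbering anchored so
that the package's reference features are internally consistent: the H1.0
helix motif ¹⁶AKASKKS²², the H1.2 motifs ¹⁹PVKKKAAKKAGG³⁰ and ³³RKAS³⁶ with
the G29/G30 double-glycine breaker, and the H1.1 motifs ¹⁷KPLA²⁰,
²¹GKKAKKPA²⁸ and ²⁹KAAAA³³. One deliberate deviation from the canonical
H1.1 entry: position 34 is Lys here (canonical Gly), which keeps the basic
subregion at 21 residues with 9 Arg/Lys and 3 Pro/Gly — the composition the
rest of the package treats as ground truth. Published residue numbering for
H1.2 is internally inconsistent (the face members K22/K23/K26/K27 match the
¹⁹PVKKKAAKKAGG³⁰ numbering but not the ¹⁹PVKKKA²⁴ helix label); the
fixtures resolve nothing — they simply adopt the numbering that matches the
motif spans above.

Two basic-subregion definitions coexist and both are implemented:
`span-first-to-last-basic` (the default; used for all composition tables)
and `three-before-first-lys` (start one helical turn before the first
Lys/Arg, run to the NTD's end; the convention used to carve simulation
constructs). Composition percentages in the subtype table are *truncated*
to one decimal (9/21 → 42.8); the full-NTD percentage in the report is
*rounded* (6/26 → 23.1). Both conventions are in circulation for these
quantities, so the package exposes both explicitly rather than silently
picking one.

## The coarse-grained helix–coil model

Each residue is in a helix (h) or coil (c) micro-state. The Hamiltonian is

  E = −k_B·T_ref · [ Σ_{i∈h} ln w_i + n_runs · ln v ]
      + Σ_{pairs} q_i q_j · A · exp(−r_ij/λ_D)/r_ij
      + (optional DNA term),

with T_ref = 300 K fixed so the Hamiltonian is temperature-independent and
replica ladders temper it in the usual way (at T → ∞ all states become
equally likely).

*Residue classes.* Four propagation-weight classes: Pro (w = 0.05), Gly
(w = 0.10), basic Lys/Arg (w = 3.5) and all others (w = 0.5), with
nucleation weight v = 0.05 paid once per contiguous helical run. A
three-class model (Pro/Gly/other) cannot reproduce the observed subtype
behaviour: the H1.1 subregion contains the *longest* Pro/Gly-free run of
the three subtypes (residues 28–37), so any Hamiltonian keyed only on
breaker content ranks H1.1 most helical — the opposite of what is seen.
Giving neutralized Lys/Arg a high propagation weight encodes the
charge-density argument directly: folding propensity concentrates where
basic residues cluster, and H1.1's Lys cluster (22–26) is fenced by G21 and
P27 so it cannot host a six-residue helical window. The numerical values
were fixed by an exact transfer-matrix scan (`scripts/calibrate_model.py`)
choosing the candidate that maximizes the separation of the neutralized
per-window helicity ordering H1.0 > H1.2 > H1.1 while keeping all three
systems clearly disordered (H1.0 fraction ≪ 1); at the shipped defaults the
exact fractions are 0.169 / 0.084 / 0.041.

*Electrostatics.* Charges: Lys/Arg +1 (0 when `neutralized`), Asp/Glu −1,
all else 0. One pseudo-atom per charged residue sits 0.35 nm from its Cα
along the local outward direction. Pair energy is Debye–Hückel with
prefactor A = 138.935/80 ≈ 1.74 kJ mol⁻¹ nm (Coulomb constant over the
water dielectric; equivalently the Bjerrum length 0.70 nm at 300 K) and
screening length λ_D = 0.78 nm (0.15 M monovalent salt). Sites closer than
0.01 nm return a hard-core rejection energy of 10⁶ kJ/mol.

*Geometry.* Helical residues take ideal dihedrals (φ, ψ) = (−57°, −47°);
coil residues draw uniformly from a broad extended basin
φ ∈ [−150°, −60°], ψ ∈ [60°, 180°]. Backbones are built by standard
internal-coordinate (NeRF) placement with trans peptide geometry, giving
consecutive Cα distances of 0.3804 nm and a helical rise of 0.155
nm/residue; maximal h-runs therefore reproduce the ideal helix template
exactly (runs ≥ 4 are full helical turns). Only statistical realism of the
coil (its Rg scale) is intended — no Ramachandran fidelity is claimed.

*DNA rod.* A rigid straight 20-bp B-DNA surrogate: one phosphate site per
bp per strand at radius 0.89 nm, 36°/bp twist, 0.34 nm rise, the second
strand offset 154°; the central 11 bp are flagged as the contact-CV
acceptor set. The rod supports the contact CV and radial-distance PMFs
only; groove geometry and docking are out of scope.

*Sampling.* Metropolis Monte Carlo; one sweep is L elementary moves, each
either a single-residue h/c flip or a redraw of a coil residue's dihedrals
(both proposals symmetric, so detailed balance holds by construction; it is
also verified exhaustively on the 64-state six-residue system). With
charges off the energy is a pure function of the state vector and the
sampler uses O(1) local updates; with charges on, coordinates are rebuilt
per move.

*Exact oracle.* For charge-free parameters the model is solved exactly by
a forward–backward transfer-matrix recursion over (coil, helix) pair
states, giving per-residue helix probabilities, the probability that any
six-residue window is fully helical, and hence the exact expected
per-window helicity. The oracle refuses charged parameter sets. It is
cross-checked against brute-force enumeration for L ≤ 16 and against the
Monte-Carlo sampler within statistical error.

## Collective variables

`S_α` sums the rational switch (1−x⁸)/(1−x¹²), x = ΔRMSD/0.08 nm, over all
L−5 contiguous six-residue windows (stride 1); ΔRMSD is the best-fit
(Kabsch, proper rotations) Cα RMSD to the ideal six-residue helix template.
The removable x = 1 singularity is evaluated as n/m inside a |x−1| < 10⁻⁹
guard band. The template is Cα-only for model conformations (the CG model
has no backbone N/C/O or Cβ atoms); dihedral-based assignment handles
atomistic input instead (below). An ideal L-residue helix scores exactly
L−5.

`S_rg` is the mass-weighted RMS distance of the Cα atoms from their centre
of mass. `S_cont` applies the (1−x⁸)/(1−x¹⁰) switch with R₀ = 0.2 nm to
all donor–acceptor distances, donors being the Lys/Arg charge pseudo-atoms
and acceptors the central-11-bp phosphate sites; because this switch decays
only as x⁻², contributions are stretched to reach exactly zero at a 2.0 nm
cutoff (the raw switch would still count 0.01 per pair at 2 nm). The
radial distance is the in-plane (normal to the rod axis) distance between
the central base pair and the Cα centroid.

## Enhanced sampling

*Metadynamics.* Gaussians of height W and width σ are deposited every τ_G
steps along the chosen CVs; the bias at (S, t) is the exact kernel sum over
deposits with t′ ≤ t. Well-tempered deposition decays heights as
W·exp(−V(S,t)/(k_B ΔT)) with ΔT = (γ−1)T; γ = ∞ reproduces plain
fixed-height deposition. Free energies follow from F(s) =
−γ/(γ−1)·V(s,t) (γ = ∞ → F = −V), shifted to min F = 0. On the analytic
double well, a 1.2·10⁵-step well-tempered run (γ = 10, W = 1.2 kJ/mol,
σ = 0.12, τ_G = 25) recovers the potential to < 0.5 kJ/mol RMS.

*WTE.* The preliminary stage runs per-replica well-tempered metadynamics on
the potential energy itself (defaults: height 2.5 kJ/mol, deposition every
250 steps, bias factor 50 — the protocol values; kernel width is
system-dependent and must be set near the unbiased σ_U). The frozen stage
bias is then carried into production as part of each replica's effective
bias V_i. Folding it into V_i rather than U is algebraically identical in
the exchange rule and keeps U a replica-independent function of
configuration. The desk-scale demonstration of the WTE effect uses a
32-dimensional harmonic system with γ = 10, where the stage genuinely
converges: the potential-energy variance grows by ≈ γ and the mean
exchange acceptance of a sparse 300/550 K pair rises from ≈ 0.08 to
≈ 0.4–0.7. At γ = 50 over this toy's energy range the stage does not
converge in desk-scale time — the exploration frontier leaves underfilled
wells that trap replicas — so the protocol default is kept for peptide runs
but the diagnostic uses the converging setting.

*Replica exchange.* Temperature ladders are exactly geometric. Exchange
attempts alternate even and odd adjacent pairs each cycle; swaps exchange
configurations (and their energies/CVs) between temperature slots, so the
pooled configuration set is conserved and each bias stays attached to its
temperature. RNG streams are spawned per replica from a master seed, with
a separate stream for exchange decisions. The "ps"-denominated schedule
language of MD maps to MC steps via a declared constant (1 ps ≡ 10 steps).

*Umbrella sampling.* Harmonic restraints ½k(s−s₀)² on any CV; windows run
independently with per-window spawned seeds; the first 25% of each series
is discarded as equilibration by default (windows retaining < 100 samples
warn). The bundled protocol is 20 windows at 0.1 nm spacing with
k = 750 kJ mol⁻¹ nm⁻².

## Reweighting

The biased density factorizes as P(R,t) = P₀(R)·exp(−β[V(s(R),t) − c(t)]).
F(s) in the offset integrals is taken from the final deposited bias via the
well-tempered relation (the standard realization of this protocol), V(s,t)
is evaluated from the kernels with t′ ≤ t, and c(t) is computed by
trapezoidal quadrature on a fixed CV grid (default 400 points padded 10%
beyond the sampled range, 200 time points, linear interpolation in t).
Frame weights are max-shifted before exponentiation and normalized; a
time-independent "final-bias" weighting (w ∝ exp(βV(s, t_final))) is
provided as a cross-check mode. On the enumerable six-residue system the
reweighted helix-count distribution from a 2·10⁵-step biased run matches
the exact Boltzmann probabilities within ≈ 2 block-estimate standard
errors (max |error| ≈ 0.01–0.02).

## Ensemble analysis

Helicity assignment does not call an external secondary-structure binary:
in state mode a residue is helical iff it sits in a run of ≥ 3 consecutive
h residues (runs of 3 are 3₁₀-like, ≥ 4 α-like; both count toward
helicity); in dihedral mode the criterion is (φ, ψ) within ±30° of
(−57°, −47°) over ≥ 3 consecutive residues. Rg baselines are
R_g^glob = 2.2·N^0.38 Å and R_g^coil = 2.02·N^0.60 Å. Single-linkage
clustering links frames with best-fit Cα RMSD < 2.5 Å and takes connected
components (scipy); frame sets above 2000 are strided with the stride
recorded; cluster populations are normalized summed frame weights and the
representative is the highest-weight member. Free-energy surfaces come
either from the bias (−γ/(γ−1)·V) or from −kT·ln of the weighted CV
histogram with empty bins masked as undefined — never imputed — and ΔE
reported between the two lowest minima only when both lie on the sampled
region. Convergence checks compare block means of an observable after an
initial discard.

## WHAM

Standard self-consistent iteration over the per-window free-energy
constants (tolerance 10⁻⁶ kJ/mol on the constants, at most 10⁵
iterations). Histogram bins span the range of window *centres*: bins
beyond the terminal centres are visited only by restraint-tail samples and
carry large, systematically biased errors. Adjacent windows sharing no
sampled bins raise an error naming the gap; sharing fewer than 10 samples
warns. Profiles are shifted so the mean of the two outermost sampled bins
is zero (the large-distance zero convention; the estimator of "large
distance" is the outer-bin mean). Bayesian bootstrapping draws unit-mean
Dirichlet weights over complete windows — the trajectory, not the sample,
is the resampling unit — and re-solves WHAM per replicate (default 100;
minimum 2). Well depths are reported in kJ/mol and in k_B T (20 kJ/mol →
8 k_B T, 15 kJ/mol → 6 k_B T at 300 K); a profile whose minimum sits on
the boundary is reported as having no bound state.

## What the synthetic systems do and do not show

The generator emulates: sequence-dependent helix propensity with Pro/Gly as
breakers, screened repulsion between basic sidechains switchable off
(neutralization), an optional DNA attraction, and trajectory ensembles with
realistic Rg scales. It does not emulate: atomistic packing, specific
hydrogen bonding, groove geometry, water or ions, or any quantitative
mapping from coarse-grained helicity to atomistic helicity. Passing tests
therefore establish that the *machinery* (CVs, biasing, reweighting, WHAM,
analytics) is correct against exact oracles and that the *qualitative*
subtype ordering emerges from charge density and breaker placement — not
that the model predicts real free-energy values. Microsecond-scale
atomistic observables (absolute S_α minima positions, ΔE values of a few
kJ/mol, PMF depths of ~20/15 kJ/mol) are outside what a desk-scale CG model
can or should reproduce; the package reports its own PMFs with the same
conventions instead.

The subtype-ordering observable is the per-window mean helicity
⟨S_α⟩/(L−5): the three constructs differ in length (10/21/18 residues,
i.e. 5/16/13 windows), so an absolute ⟨S_α⟩ comparison would be dominated
by chain length rather than folding propensity.

## Problem sizes

Default test/diagnostic sizes, chosen as the package's own desk-scale
conditions: 1.2·10⁵ steps for the double-well metadynamics recovery,
2·10⁵ steps for the six-residue reweighting oracle, 6·10⁴-step WTE stage
with 150 exchange cycles for the replica diagnostics, 21 umbrella windows
× 8·10³ steps (doubled for the bootstrap-shrinkage check) for WHAM, and
3·10³ MC sweeps per subtype and charge state (20% burn-in discard) for the
helicity ordering. All stochastic stages take explicit seeds and are
exactly reproducible.

## Known limitations

* The coil dihedral basin is a single rectangle; real coils populate
  several basins. Rg scales are reasonable, local geometry is not.
* Charge pseudo-atoms are rigid offsets from Cα; sidechain flexibility and
  salt-bridge geometry are absent.
* Well-tempered convergence at large bias factors is slow; the frozen-WTE
  diagnostic documents this explicitly rather than hiding it.
* The transfer-matrix oracle covers only the charge-free Hamiltonian;
  charged-state results are validated statistically (neutralized ≥ charged
  helicity), not exactly.
* Single-linkage clustering is O(n²) in frames; large ensembles are strided.
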