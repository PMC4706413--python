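# Methods

This note documents the models, algorithms, numerical conventions and
design choices behind `curlimc`, in the order a simulation flows through
the package: chain representation → energy → Monte Carlo moves →
generalized-ensemble sampling → canonical reweighting → structural
analysis → synthetic fixtures. It states what the implementation does and
why; every empirical number quoted here is computed by the test suite or
by `scripts/acceptance.py`.

## Chain representation

Peptides are represented in internal coordinates with fixed covalent
geometry: bond lengths and bond angles are held at standard Engh–Huber-like
values (`curlimc.constants`), leaving as degrees of freedom

- backbone torsions φ, ψ per residue (ω is trans-locked by default; the
  builder accepts per-residue ω values, so cis/ω-flexible studies are
  possible but are not sampled by the default move set),
- one coarse side-chain torsion χ1 for every residue except Gly/Ala, and
- a rigid-body pose (translation + unit quaternion) per chain inside a
  periodic cubic box (default edge 100 Å).

The atom model per residue is N, CA, C, O, the amide H (residues 2..n),
CB (all but Gly), and a single side-chain pseudo-bead SC placed by χ1 at a
per-residue-type distance from CB (1.2–3.4 Å, a coarse stand-in for the
full side chain). Chains are rebuilt from torsions by natural-extension
reference frames (NeRF); the rebuild is deterministic and bitwise
reproducible. Dihedral angles follow the standard IUPAC sign convention
(verified against RDKit geometry); CB chirality is fixed L by the improper
torsion C-N-CA-CB = −122.6°. Ideal (−57°, −47°) torsions produce
i → i+4 O···N distances of 3.09 Å, i.e. a correctly hydrogen-bonded
right-handed α-helix.

Conventions worth knowing:

- φ of residue 1 has no preceding carbonyl; it is stored but not counted
  as a degree of freedom and never moved. ψ of the last residue is free
  (it orients the terminal carbonyl).
- `degrees_of_freedom` = (n−1) φ + n ψ + χ1 count per chain, plus 6
  rigid-body coordinates for every chain beyond the first. One Monte Carlo
  *sweep* is that many elementary move attempts. Chain 1 is anchored:
  rigid-body moves act on subsequent chains only (with periodic boundaries
  only relative poses matter).
- Center-of-mass distances and all inter-chain pair interactions use the
  minimal-image convention; intra-chain geometry is never wrapped (an
  extended 19-mer is longer than half the default box).

## Energy model

The potential follows the four-term implicit-solvent decomposition
`E = E_loc + E_ev + E_hb + E_sc` (kcal/mol, k_B = 0.0019872 kcal/(mol·K)).
The functional forms are deliberately simple and fully specified here —
they preserve the term structure and qualitative physics of published
implicit-solvent peptide potentials without reproducing any particular
parameterization:

- **E_loc** (local/torsional): per residue with both φ and ψ defined, two
  Gaussian wells of depth `eps_helix` = `eps_strand` = 1.2 kcal/mol and
  width σ = 30° centred on the canonical helix (−57°, −47°) and strand
  (−139°, 135°) regions, with wrapped angular distances. This is the
  torsional/neighbour-dipole term; it makes both basins thermally
  accessible at 300 K.
- **E_ev** (excluded volume): pairwise `0.5·[(σ_ij/r)¹² − 1]` for
  r < σ_ij, truncated and shifted to zero at the pair contact diameter
  σ_ij = (σ_i + σ_j)/2. Pairs within three covalent bonds are excluded
  (1–2 and 1–3 distances are fixed by geometry; 1–4 torsional strain is
  E_loc's job). Contact diameters are calibrated once so that ideal helix
  and strand geometries are essentially clash-free; O (2.6 Å) and amide H
  (1.4 Å) are small because their close approach *is* the hydrogen bond,
  which E_hb scores. Any non-bonded pair closer than 0.1 Å makes the total
  energy +∞ (a sentinel, never NaN), which the sampler auto-rejects.
- **E_hb** (backbone hydrogen bonds): for donor N–H (residues 2..n) and
  acceptor C=O pairs with H···O distance r < 4.5 Å,
  `eps_hb · [5(σ/r)¹² − 6(σ/r)¹⁰]` with eps_hb = 3.0 kcal/mol and
  σ = 2.0 Å, scaled by the alignment factor cos²(N-H···O) and zero unless
  the alignment cosine exceeds 0.5. The radial profile is clamped to ≤ 0
  (attractive only): steric repulsion between donor and acceptor atoms is
  delegated to E_ev. Same-residue and sequence-adjacent backbone pairs are
  skipped.
- **E_sc** (side-chain charges): between charged SC beads (Asp/Glu −1,
  Lys/Arg +1), a screened-Coulomb-like signed contact
  `q_i q_j · 4.15 kcal·Å/mol · (1/r − 1/10 Å)` truncated at 10 Å.
- An optional fifth hydrophobic contact term between apolar SC beads
  exists but is **off by default** (`eps_hydrophobic = 0`).

The `EnergyModel` contract (deterministic `evaluate(state) →
EnergyBreakdown`, total = sum of terms, invariant under global rigid
motion) is all the samplers see; the exactly enumerable toy systems
implement the same sampling interface and run unmodified in every
ensemble routine.

## Monte Carlo moves

Five update kinds, selected with weights pivot 0.25 / semilocal 0.25 /
sidechain 0.30 / rigid rotation 0.10 / rigid translation 0.10
(inapplicable kinds — no χ torsions, single chain — are dropped and the
weights renormalized; applicability depends only on topology, keeping
selection probabilities state-independent):

- **Pivot**: one backbone torsion perturbed by a Gaussian step (σ = 25°);
  only downstream atoms move; symmetric.
- **Semilocal (biased Gaussian step)**: a window of ≤ 8 consecutive
  backbone torsions receives a correlated Gaussian perturbation with
  covariance σ²(I + b G Gᵀ)⁻¹, where G is the Jacobian of the chain-end CA
  position with respect to the window torsions — biasing toward small
  displacement of downstream atoms. Forward and reverse proposal densities
  are evaluated explicitly and their log-ratio enters the
  Metropolis–Hastings acceptance; at b = 0 the move reduces to independent
  Gaussian steps with ratio 1. Any proposal with computable two-way
  densities satisfies the contract; this construction was chosen for
  simplicity and testability.
- **Sidechain**: one χ1 perturbed (σ = 45°); symmetric.
- **Rigid rotation / translation** (chains beyond the first): rotation
  about the chain COM by a Gaussian angle about a uniform axis;
  translation by a Gaussian vector wrapped into the box; symmetric.

Acceptance is `min(1, [w(E_new)/w(E_old)] · q_rev/q_fwd)` for an arbitrary
weight function w(E); the canonical weight recovers standard Metropolis.
Empirical flow-balance tests (per move kind, on 3-residue systems under a
non-flat tabulated weight) and long-run uniformity tests back the
correctness of the Hastings ratios. All randomness flows through numpy's
PCG64 generator; identical seeds give bitwise-identical trajectories.

## Generalized-ensemble machinery

Histograms live on a uniform `EnergyGrid`. For a trajectory sampled every
Δt sweeps:

- `Z_H(E)` = counts per bin / ΔE; `Z_C(E)` = half the number of strictly
  crossing consecutive pairs at each bin-center cut (samples exactly on a
  cut count as non-crossing).
- `D(E) = (π/Δt)(Z_C/Z_H)²`. The source expression for D is typeset
  ambiguously in the literature this follows; this form is fixed by
  dimensional analysis (D must scale as energy²/time) and is
  self-consistent with the rest of the scheme: with it, P_opt ∝ 1/√D =
  Z_H/Z_C, so the feedback update below is exactly the reweighting from
  the currently sampled P ∝ Z_H to P_opt.
- `P_opt ∝ 1/√D`, normalized over covered bins; mean first-passage
  τ = Σ ΔE/(D·P) over covered bins (∞ if D or P vanish inside the range).
- Multicanonical weights: ln w = −ln g per bin from an exact or estimated
  density of states; bins without states inherit the nearest defined value.
- Feedback: `ln wⁿ = ln wⁿ⁻¹ − ln Z_C`, bins with Z_C = 0 inherit the
  nearest updated value. `learn_weights` starts from **flat** weights (the
  uninformed state) and warm-starts each iteration from the previous run's
  final configuration. Exact Markov-chain analysis on the double-well toy
  (building the transition matrix and stationary crossing fluxes) showed
  why these defaults matter: from a flat start the iteration lands on the
  optimum immediately and is stationary, whereas iterating from the
  multicanonical table can diverge on landscapes whose level-set geometry
  makes Z_C impossible to flatten — the update then amplifies the residual
  spread each round. Weight tables are bin-constant with nearest-edge
  extrapolation outside the grid (no hard rejections while weights are
  still being learned) and are serialized as two-column text with a
  provenance header (kind, iteration, grid).
- Round trips: completed one-way traversals alternating between E_low and
  E_high, by default the 2 % / 98 % points of the *covered* energy range
  (grid bins actually visited); the first partial leg is not counted.
- Parallel tempering baseline: geometric ladder
  `T_k = T_lo (T_hi/T_lo)^(k/(n−1))` (defaults 16 rungs, 279–367 K),
  neighbour swaps every 10 sweeps (alternating parity) accepted with
  `min(1, exp[(β_i − β_j)(E_i − E_j)])`, trajectories recorded per rung.

## Canonical reweighting and thermodynamics

Samples drawn under w(E) are reweighted to temperature T with
`r_i ∝ exp(−E_i/k_B T)/w(E_i)` (log-domain, `logsumexp`). Multiple
independent runs are pooled with per-run normalization (each run's factors
sum to the same total), a deliberately simple alternative to
multi-histogram estimators that suffices at the problem sizes used here.
Every ensemble reports its effective sample size (Σr)²/Σr² and flags
ESS < 10.

Derived quantities:

- Free-energy surfaces `F = −ln P` in k_B T units over one or two
  observables, anchored so the minimum visited bin is 0; unvisited bins
  masked. Marginalizing the 2-D surface reproduces the 1-D surface.
- Dimer population: weighted fraction with D < 15 Å (alternative 10 Å),
  optionally requiring β-content > 0.5 computed over all residues of both
  chains (a per-chain variant is available).
- Melting curve: population(T) on a temperature grid; Tm is the 0.5
  crossing by linear interpolation (first crossing if several; NaN if
  none). Monotonicity of the curve is reported, not assumed.
- Binding: with c0 = 1/(N_A V_box) — one molecule per box; 1/602 mol/L for
  the 100 Å box, printed as 1/600 at the precision commonly quoted —
  `[AB] = p·c0`, `[A] = [B] = (1−p)·c0`, `K_a = p/((1−p)² c0)`, and
  `ΔG = −k_B T ln(K_a·V_ref)` with V_ref the reciprocal of a 1 mol/L
  reference concentration by default (the box concentration itself can be
  passed instead). p = 1 yields an infinite-K_a sentinel.
- Jackknife: delete-1 over independent runs; bias-corrected mean
  `n·θ̂ − (n−1)·mean(θ_(i))` and the standard error
  `sqrt[(n−1)/n Σ(θ_(i) − θ̄)²]`.

## Structural analysis

Secondary structure is assigned from backbone torsions alone — a
documented divergence from hydrogen-bond-aware assigners (STRIDE/DSSP),
matching a Ramachandran-based workflow. Boxes: H = φ∈[−100°,−30°] ∧
ψ∈[−80°,−5°]; E = φ∈[−180°,−80°] ∧ ψ∈[80°,180°]∪[−180°,−170°]; singleton
E runs are demoted to C. Terminal residues lacking φ or ψ are excluded
from content denominators (a 19-mer has 17 assignable residues). The boxes
are a declared convention of this package, not a reconstruction of any
particular assigner's internals.

Contact maps count CA–CA distances below 8 Å as contacts, with intra-chain
pairs closer than 5 in sequence excluded and no separation filter between
chains. The published layout convention is kept: intra-chain probabilities
below the main diagonal (averaged over the two chains), inter-chain above
(symmetrized over chain labels, so a contact present in only one
chain-assignment reads 0.5). Frames with non-finite coordinates are
skipped and counted.

Dimer topology classification: each chain's *interface strand* is the
strand segment with the most inter-chain CA contacts (ties toward the
longer strand; at least two strand segments per chain and ≥ 3 interface
contacts required, else `unclassified`). The label letters record whether
each interface strand is the N- or C-proximal strand of its hairpin
(ordered N-before-C: NN, NC, CC); orientation is the sign of the dot
product of the two interface strands' sequence-direction end-to-end
vectors. The turn is the contiguous non-E segment between the two longest
strand segments, reported 1-based inclusive. Representative structures
come from Daura-style neighbour-count clustering on pairwise CA RMSD after
optimal superposition (default cutoff 2.5 Å; deterministic, ties toward
the lower frame index).

## Synthetic fixtures and what they do (not) show

- **Double-well chain** (default 61 states): two degenerate minima at the
  chain ends, broad gently-tilted basins, and a narrow Gaussian barrier of
  height exactly h = 5 (reduced units, k_B = 1) at the centre. The shape
  is chosen so the landscape has what makes round-trip optimization
  meaningful: high-entropy end states and a low-entropy transition region,
  the discrete analogue of an association/dissociation equilibrium. A
  smooth quartic well was rejected during design because its diffusivity
  profile is nearly flat — multicanonical sampling is then already
  near-optimal and the benchmark measures nothing.
- **2-D self-avoiding lattice chain** (length ≤ 12): nearest-neighbour
  contact energy −1; all walks enumerable exactly (length 3 → 12 walks,
  length 10 → 16268), giving exact g(E), ⟨E⟩(T) and C_v(T) as oracles for
  the full multicanonical + reweighting chain. MC runs start from a random
  self-avoiding walk per seed: dispersed starts turn any residual
  equilibration bias into run-to-run scatter that the jackknife error
  honestly reflects (identical extended starts produced a shared bias
  invisible to it).
- **Two-level system**: ground state plus a degenerate excited level;
  closed-form occupancies for acceptance-rule and PT checks.
- **Repeat sequences**: 19–23-mers matching the conserved repeat motif
  (Ser at 1, Gln at 7 and 18, Gly at 9 and 11, Asn at 12, Ala at 14) with
  seed-deterministic random X positions drawn from a polar-biased
  alphabet. The shipped FASTA defaults are *synthetic* and user-replaceable.
- **Ideal conformations and dimer poses**: helix/strand/hairpin torsion
  sets, and two-hairpin poses realizing each of the six topology classes
  by rigid placement of the designated interface strands at 4.8 Å CA–CA
  spacing in the designated orientation (no energy minimization — analysis
  operators must not require physical energies).
- **Stochastic trajectories**: two-component D/β mixtures with stated
  weight (dimer component below the 15 Å cutoff, monomer above), and
  two-state melting runs whose macrostate energies/degeneracies put the
  canonical 50/50 point exactly at the designed Tm, sampled flat with the
  matching multicanonical weight table returned alongside.

Passing tests on these fixtures demonstrates that the machinery —
sampling, reweighting, estimators, classifiers — is correct on systems
with known answers. It does **not** demonstrate that the simplified
four-term potential reproduces experimental thermodynamics of real
peptides: binding free energies, melting temperatures and class
populations of the repeat peptides are force-field-dependent and require
far larger budgets than the desk-scale defaults used throughout
(10³–10⁵-sweep runs here, against ~10⁸ sweeps per system in cluster-scale
studies of this kind; the `paper_scale` config flag raises the budgets but
is not exercised by the test suite).

## Numerical choices and degenerate inputs

- Reweighting is done in log space; weight tables are normalized to
  max ln w = 0; tabulated weights are bin-constant with nearest-edge
  extrapolation.
- Non-finite proposal energies are auto-rejected and counted; overlapping
  atoms give +∞, never NaN.
- Empty trajectories, inverted round-trip thresholds, all-zero transition
  histograms, monomer input to dimer analyses, and sub-2-run jackknives
  raise named errors; melting curves without a 0.5 crossing return NaN;
  p = 1 binding returns an infinite-K_a sentinel.
- Sampling every elementary proposal is avoided in estimates that assume
  weak correlation; tests thin or use batch-means effective sample sizes
  where it matters.
- `run_sweeps` with a sample interval longer than the run returns an empty
  table without error; zero-sweep budgets count zero round trips.

## Known limitations

- The potential is a teaching-grade simplification: one pseudo-bead side
  chain (single χ1, no rotamer statistics beyond it), no hydrogen-bond
  directionality at the acceptor beyond one alignment factor, no
  hydrophobic driving force by default, no salt/pH dependence. Absolute
  ΔG/Tm values for real sequences should not be taken quantitatively.
- ω sampling and proline-specific backbone restrictions are not
  implemented (ω trans-locked; Pro φ is treated like any other residue).
- Multi-run pooling uses per-run normalization, not WHAM/MBAR; fine at
  these scales, suboptimal for strongly non-overlapping runs.
- The semilocal move biases the chain-end CA rather than reproducing any
  specific published biased-Gaussian construction; it satisfies the same
  contract (computable two-way densities).
- Trimer and larger assemblies are untested territory; the machinery
  accepts more than two chains for energy/moves, but all dimer analyses
  require exactly two.
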