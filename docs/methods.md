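# Methods

This note documents the models implemented in `rnadock`, the parameter
choices that matter, what the synthetic data does and does not emulate,
and the numerical decisions a maintainer should know about.

## Structural model

A complex is strictly binary: one protein partner, one RNA partner.
Residues are assigned to partners by residue name (the 20 standard
amino acids; ribonucleotides A, C, G, U). DNA residue names are
rejected, HETATM records, waters and ions are ignored, and unknown
residue names (e.g. modified nucleotides in tRNAs) are skipped with a
warning — a file in which more than half the residues are unrecognized
is rejected rather than silently truncated. Alternate locations resolve
to the highest-occupancy conformer; only the first model of multi-model
files is read. All parsing and record formatting goes through `gemmi`.

Backbone definitions: protein N, CA, C, O; RNA phosphate group plus the
full sugar ring (P, OP1/OP2, O5′, C5′, C4′, O4′, C3′, O3′, C2′, O2′,
C1′). Every other heavy atom of a nucleotide is base ("side chain").

## Coarse-grained stage

One centroid per unit: the unweighted geometric centre of the
side-chain (protein) or base (RNA) heavy atoms. A mass-weighted variant
is available (`mass_weighted=True`) but differs negligibly for C/N/O
groups. Glycine, having no side-chain heavy atom, uses its CA position.
Protein centroids are computed per structure rather than from a
database-average library: per-structure centres are deterministic,
data-free, and at least as faithful to the actual conformation.

Low-resolution terms and defaults:

| term | definition | parameters |
|---|---|---|
| contact | # units with centroid < cutoff of other partner | cutoff 6.0 Å |
| bump | Σ (d_clash − d)² over coarse-atom pairs with d < d_clash | d_clash 3.0 Å |
| env | Σ −log P(type \| environment class) | see below |
| pair | Σ −log odds(protein type, nucleotide type \| contact) | cutoff 6.0 Å |

The bump functional form (quadratic below a single global clash
distance) keeps the term parameter-free with respect to atom typing.
Environment classes are interface/non-interface × buried/exposed;
burial is operationalized as ≥ 8 same-partner centroids within 10 Å
(both config-exposed — no standard operational definition exists at
centroid resolution). Tables are estimated by counting with add-one
pseudocounts over the 24 types (environment) and an ε = 10⁻⁶
pseudo-probability floor (pair), so small reference sets always yield
finite, complete tables. The four term weights default to 1.0: these
are counting statistics and are not optimized further. An
alignment-pattern term used in antibody docking has no protein–RNA
counterpart and is omitted.

## All-atom stage

Ten term slots (`fa_atr`, `fa_rep`, `fa_sol`, `fa_pair`, `fa_dun`,
`hack_elec`, `hbond_lr_bb`, `hbond_sr_bb`, `hbond_lr_sc`,
`hbond_sr_sc`) combined linearly by a weight vector boxed to [0, 1].
Only inter-partner pairs are scored: under rigid-body moves the
intra-partner energy is constant and cancels in ranking. `fa_dun`
(rotamer internal energy) is identically zero — no repacking is
performed for rigid RNA docking — but the slot is kept so weight
vectors retain the standard ten components. A solvent-accessible
surface area term, often omitted in this scheme, is not implemented.

Functional forms and constants (all config-exposed in
`HighResConfig`):

* **Lennard-Jones**: 12-6 with r_min = r_i + r_j, ε = √(ε_i ε_j),
  6 Å cutoff; contributions with E ≤ 0 accumulate into `fa_atr`, E > 0
  into `fa_rep`; the repulsive wall is linearized below 0.6·r_min so a
  deeply clashed decoy gets a large finite penalty rather than a
  numeric overflow.
* **Electrostatics**: Coulomb q_iq_j·332.0637/(ε(d)·d) with
  distance-dependent dielectric ε(d) = d (hence 1/d²), distances
  clamped at 1.45 Å, 5.5 Å cutoff.
* **Solvation**: Lazaridis–Karplus Gaussian exclusion,
  −ΔG_i/(2π^{3/2}λ_i d²)·exp(−x_i²)·V_j symmetrized, x_i = (d−r_i)/λ_i,
  6 Å cutoff.
* **Hydrogen bonds**: 10–12 potential ε_hb·[5(r₀/d)¹² − 6(r₀/d)¹⁰] for
  donor–acceptor heavy-atom distances in [2.2, 3.6] Å, r₀ = 2.9 Å,
  ε_hb = 2.0 kcal/mol, modulated by cos²θ of the D–H⋯A angle when a
  covalent hydrogen is resolved (zero beyond 90° bend) and by 1.0
  otherwise, so hydrogen-free structures remain scorable. Bonds are
  binned backbone/side-chain by whether *both* heavy atoms are
  backbone; since only inter-partner bonds are scored, all bonds are
  long-range and the short-range slots stay zero (kept for weight-slot
  compatibility).
* **Pair**: the centroid-level contact log-odds table applied at
  residue–nucleotide granularity, triggered by any inter-partner
  heavy-atom pair under 5 Å.

Atom parameters (LJ radius/depth, LK ΔG_free/λ/volume, partial charge,
donor/acceptor flags) come from a compact bundled table of ~16
element-and-context types (`src/rnadock/data/atom_types.tsv`); RNA
atoms map onto the same protein-derived types by element and polarity
(anionic phosphate oxygens share the carboxylate-oxygen type, sugar
ester/ring oxygens an ester type, base rings the aromatic types). The
values are a plausible molecular-mechanics-style set; the package's
contract is the functional forms and the learning machinery, not any
specific upstream parameterization.

## Perturbation decoys and labelling

A pose is three intrinsic ZYX Euler angles plus a translation, applied
to the RNA (the protein stays fixed) about the RNA's geometric centre —
the pivot choice keeps rotation and translation amplitudes
approximately independent. Amplitudes follow Normal(mean, 1) in the
unit of each quantity, clamped at zero (the clamp bias is < 0.001 for
every regime mean); translation direction is uniform on the sphere and
each angle takes a random sign — the directional law is a design
choice, made isotropic for lack of a reason to prefer any axis.

Regimes: small (1 Å, 4°), regular (3 Å, 8°), large (9 Å, 27°). Per
complex the smallest regime whose ensemble contains at least the
required number (default 30) of near-natives (Irmsd < 5 Å) *and*
decoys (Irmsd > 8 Å) is selected by regeneration, not rejection
sampling; if none qualifies the per-regime counts are surfaced in the
error. The 5–8 Å band is labelled `test` and never enters a learning
set. Balanced learning sets draw, uniformly without replacement, 30
near-natives and 30 decoys per complex (120 complexes × 60 rows = 7,200
rows at full scale).

## Interface RMSD

The native interface is every unit with a heavy atom within 10 Å of the
other partner (the conventional interface cutoff; config-exposed). The
fit/measure atom set is protein N/CA/C/O plus RNA P of interface units;
superposition is least-squares (via `scipy`'s rotation alignment) over
that same set on both partners, and the RMSD is measured over it.
Fitting on both partners is a deliberate choice — the alternative
(fitting on the receptor only) systematically enlarges Irmsd for the
same pose.

A consequence worth knowing: with few interface phosphates the fit set
is protein-dominated, so a pure RNA translation t yields an Irmsd of
roughly √(n_p·n_r)/(n_p+n_r)·t, well below t. Large perturbations of
small fixtures therefore produce near-native labels at surprisingly
large physical displacements.

## Weight optimization

Fitness of a weight vector is the tie-aware ROC-AUC (Mann–Whitney form,
ties ½) of the energy s = −Σ w_k f_k against near-native/decoy labels.
The logistic link being strictly monotone, the AUC of the logistic
output equals the AUC of s, so the search optimizes s directly; a
logistic intercept is fitted afterwards by 1-D maximum likelihood and
only calibrates reported probabilities.

The optimizer is a (μ + λ) evolution strategy: μ = 10 parents, λ = 80
offspring per generation, uniform crossover (rate 0.5) of two
tournament-selected (size 2) parents, Gaussian mutation (σ = 0.05)
clipped to the box, survivors the best μ of parents ∪ offspring, and a
budget of 100,000 fitness evaluations by default — "iterations" are
counted as evaluations, the conservative reading when the generation
size is ambiguous. The best-ever individual is returned, so the
reported fitness is non-decreasing in the budget. Everything is
deterministic per seed. Signed weight boxes ([−1, 1], [−1, 0]) are
selectable via `GAConfig.box` but are known to train less stably and
are not exercised by default.

Cross-validation is leave-one-pdb-out: every row derived from the
held-out complex is excluded from the balanced learning sample, the
weights are refitted, and the held-out complex's *full* ensemble is
evaluated with assessment labels (near-native < 5 Å vs non-native
≥ 5 Å — note these differ from the learning labels, which exclude the
5–8 Å band). Fitted scorers record the group ids they saw, and the
pipeline asserts the held-out group is never among them.

## Assessment statistics

ROC/AUC is computed tie-aware; ES = |E_top ∩ R_top|/(f²N) at f = 0.10
with ⌊fN⌋-element top sets (boundary ties broken by stable input
order) — the unique normalization for which random ordering gives 1 in
expectation and perfect agreement gives 1/f; top-k counts near-natives
among the k best energies (stable tie-break) and reports the chance
expectation k·n_nn/N alongside. One reference threshold note: the
learning decoy boundary (> 8 Å) and the assessment near-native boundary
(< 5 Å) are both interface-RMSD thresholds throughout; no
ligand-RMSD-based variant is used.

## Synthetic data

The fixture generator builds parametric, deterministic complexes: a
helical protein backbone with schematic side chains (including
glycine's bare backbone, charged, polar and aromatic types) and a
single-strand RNA with full phosphate/sugar/base nomenclature, bases
facing the protein, placed so the minimum inter-partner heavy-atom
distance equals a requested gap (solved by bracketing to ~0.01 Å). It
emulates realistic atom densities, standard PDB nomenclature, and
interface distances down to hydrogen-bond range. It does *not* emulate
real A-form/α-helical geometry, sequence-dependent structure,
conformational flexibility, ions or waters — so passing tests
demonstrate the correctness of the scoring/learning machinery, not
predictive power on real complexes.

Two consequences at fixture scale: (i) pipeline fixtures use a small
protein and a long RNA so the strand's rotation lever lets the large
perturbation regime reach the > 8 Å decoy band; (ii) most mid-Irmsd
decoys of a tiny rigid fixture have no inter-partner atoms within any
interaction cutoff, so their feature rows are identically zero and
AUC gains from learning are modest even when top-k/ES gains are large —
on real structures near-natives retain contacts far more often. The
controlled-balance ensemble generator mixes a tight channel (0.6 Å, 2°)
with a far channel (60 Å, 10°); the far channel's rotation is kept
modest because very large rotations can, rarely, map the nearly
colinear interface-phosphate line back onto itself and produce an
accidental near-native.

The feature-matrix generator draws class-conditional isotropic
Gaussians separated by one unit along the true weight direction, so the
Bayes-optimal linear discriminant is exactly the specified weight
vector, perfect separation occurs at zero noise, and the discriminating
power decays as 1/noise_sd.

## Problem sizes and defaults

Default study-scale constants: 10,000 decoys per complex, 30 + 30
learning rows per complex, GA budget 100,000 evaluations. The bundled
smoke configuration (3 complexes × 500 decoys, budget 2,000) exercises
every stage end-to-end in seconds and is the scale used by the test
suite; statistical anchors (amplitude means, random-scoring ES) are
verified at their full sizes (10,000 samples, 200 replicates) since
they are cheap.

## Known limitations

* Ion- or water-mediated interfaces and RNA conformational flexibility
  are out of scope; scoring is strictly rigid-body and unmediated.
* The atom-type parameter table is deliberately compact; absolute
  energies are not comparable to any published force field — only
  rankings within an ensemble are meaningful.
* Modified nucleotides are skipped rather than modelled.
* The short-range hydrogen-bond slots are structurally zero under
  inter-partner-only scoring; they exist for weight-vector
  compatibility.
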