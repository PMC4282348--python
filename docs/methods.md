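# Methods

This note documents the models, conventions and numerical choices behind
`refassess`, the points where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Structures and residue correspondence

Structures are read from PDB files through gemmi. HETATM records, waters
and hydrogens are dropped; alternate locations resolve to the
highest-occupancy conformer, first listed on ties. All chains are read and
concatenated in file order — refinement targets are single-domain, so this
is a no-op in practice. Author residue numbering is preserved verbatim.

Model↔target correspondence pairs residues by identical
(chain, residue number, insertion code). Refinement submissions inherit the
target numbering, which makes key-based pairing equivalent to a
sequence-dependent alignment while staying deterministic; a residue-name
mismatch at a shared key is flagged but kept, and residues absent from
either side are simply excluded. A submission is discarded outright when it
carries fewer heavy atoms than the starting model (missing residues or a
non-all-atom model); the rule is one-sided — extra atoms are accepted.

## The GDT superposition search

GDT-style fractions ask, per distance cutoff d, for the superposition that
maximizes the number of paired Cα atoms within d Å. The search used here:

1. **Seeds.** Contiguous sequence windows of lengths 3, 5 and 7 at every
   position, plus the full pairing. For n ≤ 12 paired atoms, *every* subset
   of size ≥ 3 is used as a seed instead, which makes the search provably
   exact over subset-seeded superpositions (each evaluated superposition is
   a Kabsch fit on some subset, so the search can neither exceed nor, with
   exhaustive seeds, fall short of the subset-fit optimum).
2. **Cross-cutoff scoring.** Every superposition evaluated anywhere in the
   search is scored against *all* requested cutoffs. Reported fractions are
   therefore non-decreasing in the cutoff by construction, and a
   trajectory that helps one cutoff automatically helps the others.
3. **Refit trajectories.** Per cutoff, the 8 best seed-pass inlier sets are
   iteratively refitted — superpose on the inliers, reselect inliers —
   until a fixed point, at most 20 iterations, with a seen-set preventing
   any inlier set from being refitted twice (this also breaks 2-cycles).
   Ties on inlier count are broken toward the lower inlier RMSD.

All seeds and trajectories are processed as one batched weighted-Kabsch
problem (batched 3×3 SVDs), which is what makes whole-round assessment
cheap. Because the multi-cutoff search shares trajectories across cutoffs,
it can find slightly better superpositions than four independent
single-cutoff searches; GDT-HA and GDC-SC are computed from the joint
search.

Superpositions are proper rotations only (reflections are repaired by
flipping the smallest singular direction).

## Quality measures

* **GDT-HA**: mean of the search fractions at 0.5, 1, 2, 4 Å, on paired Cα.
  A masked variant drops a caller-supplied residue set (e.g. residues
  flagged as flexible or forming crystal contacts) before scoring.
* **Cα RMSD**: Kabsch RMSD over paired Cα.
* **GDC-SC**: the search fractions on one characteristic side-chain atom
  per residue (the distal functional atom; `data/characteristic_atoms.tsv`,
  19 non-glycine residue types) at thresholds 0.5·i Å, i = 1..10, combined
  with linearly decreasing weights w_i = (11 − i)/55 (they sum to 1).
  When the distal atom is missing on either side the residue falls back to
  CB; glycine does not contribute. Both the table and the weights are
  configuration, since conventions differ between published variants.
* **SphereGrinder**: sphere membership (6 Å around each residue's Cα,
  boundary inclusive) is decided on the *target* only; model counterparts
  are matched by residue key + atom name. Atoms the model lacks count as
  outside 2 Å (penalized, not skipped). Spheres with fewer than 3 atoms are
  skipped; a sphere with fewer than 3 atoms present in the model cannot be
  aligned and scores 0. Alignment uses all member atoms.
* **MolProbity score and LLG** are external scalars supplied as 2-column
  TSV tables. A model missing from the table is flagged absent and excluded
  from statistics based on that score — never imputed.

## Ranking

Δ_Q(p) = Q(p) − Q(s) against the starting model s. Per target and measure,
robust Z = (Δ − median)/MAD over all assessed model-1 submissions, with the
plain MAD (no 1.4826 normal-consistency constant — configurable, and the
replicated experiments confirm the top of the ranking is insensitive to
it). Degenerate targets are handled deterministically: MAD = 0 falls back
to the sample standard deviation (ddof = 1, still centred on the median);
if that is also 0 every Z is 0.

Clipping zeroes negative Z for higher-better measures (GDT-HA, GDC-SC,
SphGr) and positive Z for lower-better ones (RMSD, MP), so adventurous
failures cost nothing; S_p sums the clipped terms with metric-appropriate
signs and is ≥ 0 by construction. An absent MP term contributes 0 and is
flagged. Groups are ranked by median S_p over predicted targets with a
default eligibility threshold of 23 targets; a mean/SD variant of the
standardization is available as configuration. The naive baseline (the
starting model resubmitted, all Δ = 0) is Z-scored against the
participants' per-target statistics without ever entering them.

The cherry-pick analysis re-scores *all* assessed submissions of a target
(every group, every model index) in one pooled population, then takes each
group's highest-S_p entry, ties going to the lowest model index. By
construction the pick's pooled S_p is never below the same group's model 1.

## Statistical comparisons

One-tailed Wilcoxon signed-rank tests on paired Δ_Q values, α = 0.01, no
multiple-testing correction. Zero differences are dropped (Wilcoxon's
original treatment; the Pratt variant was considered and rejected to keep
one deterministic convention) and tied magnitudes receive average ranks.
For n ≤ 25 non-zero differences the p-value comes from the exact null
distribution, computed by generating-function convolution on a
doubled-rank integer lattice so tied average ranks stay exact; above that,
a continuity-corrected normal approximation with the tie-adjusted rank
variance. The suite checks the implementation against scipy's exact mode
on tie-free fixtures and verifies the empirical size at α = 0.01 over
2,000 null pairs.

## Elastic-network deformation energy

A Hookean pairwise elastic network on the reference structure's Cα trace:
springs connect all pairs within 12 Å at their reference distance, with a
uniform force constant of 1 kcal/mol/Å². The deformation energy of another
conformation is Σ ½·k·(d − d₀)² — internal distances only, hence invariant
to rigid motion and superposition-free. All three parameters are exposed.

The absolute scale of this energy is **not calibrated** against any
published deformation-energy implementation; the module's contract is
ordinal: filtering conformations within the thermal ensemble of a
reference (per-residue energy ≤ 0.89 kcal/mol/residue, boundary inclusive)
and ranking how adventurous refinement moves are (per-group mean/max
energy versus the starting model, restricted to models whose GDT-HA
improved).

## Hydrogen bonds

Neither predicted nor experimental structures carry hydrogens, so bonds
are assigned from heavy-atom geometry: donor–acceptor distance ≤ 3.5 Å and
antecedent–donor–acceptor angle ≥ 90°, with the antecedent taken as the
donor's nearest heavy atom in the same residue. Donors are backbone N
(except proline) and a fixed side-chain table; acceptors are backbone
O/OXT and a side-chain table. Same-residue pairs are excluded, as are
main-chain pairs of sequence-adjacent residues (covalently too close, e.g.
N(i+1)–O(i)). Bond identity for model-vs-target comparison is (donor
residue key, donor atom, acceptor residue key, acceptor atom); precision,
recall and F1 are reported for all-atom and main-chain-only scopes, with 0
on empty denominators. These criteria are deliberately simple and applied
identically to model and target; the contract is ordinal group comparison,
not bond-set identity with any particular assignment program. No
solvent-accessibility weighting is applied — surface side chains competing
with solvent are a known confounder left as future work.

## Synthetic rounds

The generator emulates the *structure* of a refinement round, not protein
physics:

* **Natives** are backbone+CB chains built by NeRF from ideal internal
  coordinates with fold-dependent φ/ψ (α-helix −57/−47; extended strands;
  turns), giving 3.8 Å Cα spacing and genuine i→i+4 helical hydrogen
  bonds. Sequences are drawn from 15 CB-bearing residue types, so GDC-SC
  always operates through the CB fallback.
* **Starting models** add per-atom zero-mean Gaussian noise (default
  σ = 1.0 Å, which lands starting GDT-HA values in the 50–70 range typical
  of real rounds) plus one rigid 6-residue segment rotation.
* **Submissions** interpolate starting → native by a fraction drawn from
  Normal(skill, consistency), clamped to [−0.5, 1], plus a smooth
  sinusoidal "adventurousness" perturbation. With probability 0.02 a
  terminal residue is deleted, exercising the discard rule. The truly best
  of the five candidates is labelled model 1 with probability
  `ranking_acumen`, otherwise buried uniformly among indices 2–5, so the
  model-1 identification rate of a profile equals its acumen.
* **External score tables** are fabricated as deterministic monotone
  functions of each model's mean distance to native (MolProbity-like
  increasing, LLG-like decaying), clearly marked synthetic in their
  headers. Determinism matters: identical models must receive identical
  scores so that noiseless profiles tie cleanly.

The default round has 27 targets, 10 groups and 5 models per group,
mirroring the scale of a real refinement round; synthetic chains are
32–48 residues, a size chosen to keep replicated whole-round experiments
fast while leaving every metric non-trivial. The default group profiles
span skills from +1.0 (perfect refiner) through 0 (naive-equivalent) to
−0.3, symmetric about zero so that the per-target median Δ sits near zero
and the naive baseline lands near S_p = 0.

**What passing experiments show**: that the ranking machinery recovers
planted ordinal skill (Spearman ≥ 0.9 against median S_p, averaged over 20
seeded rounds), that clipping protects rather than rewards damage, that
cherry-picking is internally consistent, and that the plumbing — discard
rule, external scores, naive baseline — behaves. **What they do not
show**: anything about real refinement pipelines, force-field quality,
rotamer realism, or the absolute values of any score on experimental
structures.

## Numerical conventions and degenerate inputs

* Percentages are of n_common, the paired residues.
* Kabsch requires ≥ 3 non-collinear points; correspondences below 3
  residues (including after masking) are errors.
* Zero common residues, zero-ATOM files, duplicated score-table ids and
  duplicate group ids are errors; empty hydrogen-bond sets are not.
* MR viability is strict (LLG > 60); the thermal-ensemble filter is
  inclusive (≤ 0.89 kcal/mol/residue).
* All randomness flows from explicit integer seeds; reports are written
  with fixed float formatting so reruns are byte-identical.

## Known limitations

* The GDT search is a documented heuristic above n = 12; its exactness
  guarantee is over subset-seeded superpositions, verified against an
  exhaustive oracle at small n.
* The elastic-network energy and hydrogen-bond criteria are ordinal
  stand-ins, not calibrated reproductions of any external program.
* Correspondence by author numbering assumes submissions keep target
  numbering — true for refinement rounds, not for arbitrary model sets.
* mmCIF input, ligands, nucleic acids and symmetry-mate generation are out
  of scope; exclusion masks are an input, not computed.
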