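# refassess

Assessment toolkit for **protein model refinement** experiments, in the style
of the CASP refinement category: given a native target structure, the starting
model released for refinement, and each group's up-to-five refined
submissions, it measures whether refinement actually moved models closer to
the native structure, ranks the participating groups, and runs the
surrounding statistical and structural analyses.

It is written for assessors and method developers who want a reproducible,
scriptable version of this evaluation that can be exercised end-to-end on
synthetic data — no structure archive, no external scoring programs.

## What it computes

For every submission *p* and quality measure
*Q* ∈ {GDT-HA, RMSD, GDC-SC, SphGr, MP}:

* **GDT-HA** — mean percentage of paired Cα atoms superposable within 0.5,
  1, 2 and 4 Å, each cutoff under its own best superposition (found by a
  seed-and-extend superposition search, exhaustive over seed subsets for
  small chains).
* **Cα RMSD** after optimal (Kabsch) superposition.
* **GDC-SC** — threshold-weighted mean of the same superposition-search
  percentages computed on one characteristic side-chain atom per residue at
  0.5–5.0 Å (weights decrease linearly and sum to 1).
* **SphereGrinder** — for each residue, all atoms within 6 Å of its Cα are
  aligned independently and the fraction within 2 Å retained; the score is
  the mean over residues.
* **MP** — MolProbity score, consumed as an external scalar (never computed
  here); lower is better.

Scores enter the ranking as differences from the starting model *s*,
Δ_Q(p) = Q(p) − Q(s), standardized per target into robust Z-scores
Z = (Δ − median)/MAD, clipped to zero on the unrewarded side, and combined:

    S_p = Z_GDT-HA + Z_GDC-SC + Z_SphGr − Z_RMSD − Z_MP  ≥ 0

Groups are ranked by median S_p over predicted targets (eligibility
threshold on the number of targets attempted), against a naive baseline that
resubmits the starting model unchanged. On top of this sit:

* one-tailed **Wilcoxon signed-rank** head-to-head comparisons on paired
  Δ_Q values (exact null distribution up to n = 25, α = 0.01, no
  multiple-testing correction);
* **cherry-picking**: re-scoring all submissions of a target in one pooled
  population to find each group's a-posteriori best entry, and the rate at
  which that entry was actually labelled model 1;
* **hydrogen-bond network** comparison (geometric assignment, heavy atoms
  only; precision/recall/F1 of the model's bond set against the target's);
* **elastic-network deformation energy** of each model relative to the
  starting model (Hookean Cα network, 12 Å cutoff), used to filter
  near-native starting models and to gauge how adventurous refinement moves
  are;
* **molecular-replacement viability** from externally computed Phaser LLG
  scores (a model with LLG > 60 almost always yields an automated MR
  solution).

A synthetic-data generator (`refassess.synthdata`) builds complete rounds —
ideal-geometry natives, noisy starting models, and group submissions with
planted skill levels — so the whole pipeline is testable and its ranking
demonstrably recovers planted group quality.

## Worked example

```bash
# generate a synthetic 4-group round on disk and assess it
refassess simulate --seed 4 --n-targets 27 --out-dir round
refassess all --round-dir round --out-dir reports --min-targets 23
```

or in Python:

```python
from refassess import synthdata, cli

manifest = synthdata.generate_round(seed=7, n_targets=27)
result = cli.assess_round(manifest, min_targets=23)
print(result.ranking_df.head())
```

prints (ten planted groups; skills from +1.0 down to −0.3):

```
         group     type  n_targets  median_sp
0      perfect  unknown         26  35.642424
1  strong-plus  unknown         27  11.264312
2     mid-plus  unknown         27   5.515593
3    weak-plus  unknown         25   2.413634
4  marginal-plus unknown        27   0.830794
```

The planted perfect refiner (every model equals the native) tops the table
with a large median S_p; groups that move models toward the native in
proportion to their planted skill follow in order; groups that damage the
starting model, and the naive baseline, score ≈ 0 because their negative
Z-scores are clipped. The `reports/` bundle adds per-model metrics, Δ/Z
records, the pairwise significance matrix, cherry-pick, hydrogen-bond,
deformation-energy and MR-viability tables, plus a JSON run log listing any
submission discarded for carrying fewer atoms than the starting model.

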