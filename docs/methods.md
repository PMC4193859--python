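# Methods

This note records the model, the numerical choices and the deliberate
design decisions behind the package, in the spirit of a statistical
software methods appendix.

## The prioritization model

The workflow ranks a list of zoonotic diseases against a small set of
criteria agreed by a multi-sectoral group, in two stages.

**Stage 1 — criterion weights from pairwise comparisons.** Each of the
*K* participants supplies a complete set of pairwise judgments over the
*n* criteria on Saaty's fundamental scale (admissible values 1/9 … 9; a
ratio of 3 means "moderately more important"). A participant's judgments
form a positive reciprocal matrix *A* (diagonal 1, `A[j,i] = 1/A[i,j]`,
enforced at construction). Criterion priorities are the normalized
principal right eigenvector of *A*; for a perfectly consistent matrix
(`A[i,j] = v_i/v_j`) this recovers *v* exactly. Consistency is measured by
`CI = (λ_max − n)/(n − 1)` and `CR = CI/RI(n)`; `CR = 0` for `n ≤ 2`
because 1×1 and 2×2 reciprocal matrices are always consistent.

Group merging defaults to aggregation of individual judgments (AIJ): the
element-wise geometric mean of the matrices, which is itself reciprocal,
followed by one eigenvector extraction, so a group-level CR is defined.
Aggregation of individual priorities (AIP, arithmetic mean of the
per-participant priority vectors, renormalized) is available; for AIP no
group CR exists and the field is `None`. AIJ is the default because it
merges the evidence rather than the conclusions and keeps the consistency
diagnostic meaningful.

The continuous group priorities are then deliberately discretised:
criteria sorted by descending priority receive sequential integer weights
*n*, *n − 1*, …, 1. This is the weighting rule of the workflow the package
implements; the continuous priorities remain available (CLI flag
`--weights raw-priorities`) for sensitivity analyses.

**Stage 2 — decision-tree scoring.** Each criterion carries exactly one
categorical question. Binomial scales score the designated full-score
answer 1 and the other 0 — which answer scores 1 is a per-question
configuration choice, not a global convention. Ordinal multinomial scales
with *m* categories score the answer at 1-based position *k* as *k/m*.
Note the deliberate discontinuity: a binomial question scores {0, 1},
not the {1/2, 1} that the *k/m* rule would give for *m* = 2. That is the
scoring rule of the published workflow and is preserved as such; a
harmonised variant is a possible future option but is not offered now.

Each disease's total is `T = Σ w·s` over all criteria, normalized as
`N = T/T_max` against the maximum observed total (option: against the
maximum possible total `Σ w`). The "decision tree" is evaluated as this
weighted sum — every disease passes through every node, so node order
affects only the order of the per-question trace entries, never a score;
the test suite asserts this equivalence. Final ranking uses competition
ranking (tied totals share a rank, the next rank is skipped) with ties
presented in configured disease order, which makes output deterministic.

## Tunable parameters

| parameter | default | notes |
| --- | --- | --- |
| priority derivation | eigenvector | power iteration, L1 tolerance 1e-12, max 10,000 iterations; `geometric_mean` (row geometric means) offered — the two agree to 1e-9 on consistent matrices |
| group aggregation | `aij` | `aip` as option |
| weight rule | sequential integers n…1 | `raw-priorities` for sensitivity work |
| normalization | max observed total | `max-possible` divides by Σ weights |
| CR threshold | 0.1 (warn only) | the workflow never rejects judgments for inconsistency |
| tie tolerance | 1e-9 on priorities and totals | ties broken by configured order, recorded in `tie_notes` |
| missing answers | hard error | `--missing-as-lowest` maps a missing cell to the lowest-scoring category, logged per cell |

Guidance bands — 5–9 criteria, 6–12 participants, 15–30 diseases, at most
5 ordinal categories — are soft: violations warn (error under `--strict`).
Hard rules: at least 2 criteria, unique ids/labels/diseases, exactly one
question per criterion, complete positive pairwise sets, labels within
scales. Judgment ratios outside [1/9, 9] warn but are accepted, since
elicitation scales vary in practice.

## Random index

`RI(n)` is defined as the expected consistency index of a random
reciprocal matrix whose upper-triangle entries are drawn uniformly from
the 17-value Saaty scale. The packaged constants
(n = 3 … 9: 0.52, 0.89, 1.11, 1.25, 1.35, 1.40, 1.45) are the
large-sample simulation estimates reported in the AHP literature, and the
test suite re-estimates each one by an independent Monte-Carlo oracle
(10,000 matrices per size). Published RI tables differ in the second
decimal (notably 0.58 vs 0.52 for n = 3, depending on the generating
simulation); the simulation-consistent values are used here so that the
packaged table and its stated definition agree. Since CR only ever drives
a warning, this choice has no effect on rankings. For n > 9 — beyond the
recommended criteria range — RI is estimated on demand by a deterministic
seeded Monte-Carlo run rather than shipping unverifiable constants.

## Synthetic data generator

`SynthSpec` emulates a facilitated exercise: a latent importance vector
*v* over the criteria shared by all participants, distorted per judgment
as `A[i,j] = (v_i/v_j)·exp(ε)`, `ε ~ N(0, σ²)` i.i.d. over upper-triangle
cells, reciprocals enforced and values clamped to [1/9, 9] (clamp counts
are logged). Log-normal multiplicative noise is the standard judgment
error model in AHP simulation studies; σ = 0 yields perfectly consistent
matrices and exact recovery of the latent order. Answers are drawn from
per-criterion category probabilities attached to disease archetypes
(default: a single uniform archetype). Defaults mirror the packaged
worked example: 5 criteria with latent importances (5, 4, 3, 2, 1),
10 participants, 20 diseases, σ = 0.1 as a moderate-noise condition.

What the generator does *not* emulate: systematic inter-sector
disagreement (all participants share one latent *v*), correlated answers
across criteria, data-source error in answering the questions, or
real-world disease data. Passing rank-recovery tests therefore show the
pipeline's statistical machinery is correct under the stated noise model,
not that any particular real prioritization is robust.

The packaged `fixture_country_x` exercise is constructed, not elicited:
its 10 judgment matrices are identical consistent matrices from
v = (5, 4, 3, 2, 1) (any consistent set with the same aggregate ordering
would do); rabies carries the answer vector whose weighted scores are
5, 0, 0, 2, 1 (total 8); the other 19 diseases' answers are synthetic
fixed-seed draws.

## Numerical and degenerate-case choices

- Power iteration starts from the uniform vector; for a positive matrix
  the Perron vector is unique, so convergence is guaranteed; failure to
  reach the 1e-12 tolerance within 10,000 iterations raises an error
  carrying the residual.
- λ_max is computed as the mean Rayleigh quotient `mean((A p)/p)` at the
  converged vector.
- AIJ geometric means are rebuilt from the upper triangle so reciprocity
  is exact in floating point.
- All-zero disease totals: normalized scores are defined as 0 with a
  warning (division by `T_max = 0` is never performed).
- CSV output rounds to 6 decimals for diffability; JSON keeps full
  precision. Reports are byte-stable given identical inputs.
- The leave-one-criterion-out sensitivity scan re-assigns sequential
  weights (n−1 … 1) over the remaining criteria in their original rank
  order, re-scores everything, and counts rank changes against the
  baseline.

## Experiment sizes

The rank-recovery acceptance experiment uses 500 replicate panels per
noise level over the grid σ ∈ {0, 0.1, 0.3, 0.8}, and the random-index
cross-check uses 10,000 matrices per size; both sizes give Monte-Carlo
standard errors comfortably below the assertion tolerances (≈0.02 for a
recovery proportion, ≈0.01 for RI) while keeping the default test run
fast.

## Known limitations

- Single-level AHP only: no criterion hierarchies or sub-criteria, no
  incomplete-matrix completion.
- Scoring offers no partial credit between categories and no imputation
  beyond the lowest-category fallback.
- Disease entries are opaque names (diseases, pathogens or groups); no
  taxonomy validation is attempted.
- File dialects are YAML/CSV/JSON/Markdown; there is no spreadsheet
  reader/writer and no facilitation/meeting support.
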