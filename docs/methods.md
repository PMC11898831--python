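# Methods

## Data model

A panel is a complete cases × raters grid. Every cell is an ordered,
duplicate-free list of management-option codes from an 11-category nominal
vocabulary, written in slash notation (`"1/2/4"`). Order matters only for
the *primary* option, defined as the first-listed code; all set-overlap
metrics use the unordered option set. Raters are partitioned into a
candidate roster (systems under evaluation) and a reference roster (the
expert standard). Completeness is enforced at construction: a missing or
blank cell is a load error naming the case and rater, not a silent NA.

The packaged dataset is a 22-case panel of Dupuytren's-disease management
recommendations: five AI chat systems (candidates) and three hand surgeons
(references), transcribed cell-for-cell from the study's coded table.
Two-digit codes ("10", "11") are parsed as integers, never split by
character. Two transcription caveats are documented in
`multirater.datasets`: the Copilot cells of cases 9 and 13 look swapped
relative to the study's free-text narrative, and Surgeon II's conditional
case-4 advice is coded flatly as `2/6/8`. The coded grid is followed
verbatim in both instances because it is the dataset the quantitative
analysis was defined on; the free-text vignettes ship only as optional
per-case metadata that no metric consumes.

## Concordance metrics

For candidate set `S_A`, reference sets `S_R1..S_Rm` per case:

- **Union accuracy**: fraction of cases with `S_A ∩ (S_R1 ∪ … ∪ S_Rm) ≠ ∅`.
- **Reference agreement**: per single reference, fraction of cases with
  `S_A ∩ S_Rj ≠ ∅`. This *intersection* rule is the default because it is
  the only rule that reproduces the published Surgeon I values exactly;
  two stricter variants are exposed for sensitivity analysis
  (`equality`: identical option sets; `primary`: the candidate's set
  contains the reference's primary option). The per-candidate average over
  references is the unweighted arithmetic mean.
- **Precision/recall/F1** per case against the reference union:
  `P = |S_A ∩ U| / |S_A|`, `R = |S_A ∩ U| / |U|`, F1 the harmonic mean with
  the 0/0 case defined as 0 (a disjoint pair scores (0, 0, 0), never NaN).
  Macro averaging (unweighted per-case mean) is the default; micro
  averaging (pooled counts) is available. Macro was chosen because the
  single "average" value per system that panels of this kind report is
  most naturally a per-case mean, and micro/macro coincide on singleton
  cells.
- **Consensus stratification** partitions cases by reference unanimity and
  recomputes union-hit accuracy per stratum. The unanimity definition is a
  genuine modelling choice with materially different strata, so the CLI
  makes it a mandatory explicit flag (library default: `strict_set`,
  identical option sets; alternatives: identical primaries, or all pairs
  overlapping). An empty stratum yields `None`, not 0/0.
- **Overlap agreement matrix**: for each unordered rater pair, the
  fraction of cases whose option sets intersect; symmetric with unit
  diagonal.

Every proportion is an exact rational with the case count (or stratum
size) as denominator; floats and one-decimal percentage strings are
derived views. This makes union dominance — union accuracy ≥ every
single-reference agreement, because the union is a superset — an exact
invariant, tested on the fixture and on 200 random synthetic panels.

## Reliability

Cohen's and Fleiss' kappa operate on one label per rater and case.
Set-valued cells are reduced to the primary option by default. The
reduction rule is inferred, not stated by the original study; it is the
default here because it reproduces all four published kappas exactly
(0.224 / 0.081 / 0.169 pairwise, 0.122 Fleiss) with components
po = 8/22, pe = 87/484 (Surgeon I–II) and P̄o = 10/33, P̄e = 25/121.
A seeded uniform-over-cell `random` reduction is exposed for sensitivity;
reductions that would redefine the statistic on sets (e.g. weighting by
set expansion) are deliberately out of scope.

The category space is the set of labels observed after reduction;
unobserved codes carry zero marginal mass either way, so this only affects
the reported proportion vectors, never kappa. When expected agreement
equals 1 (all raters constant on one label) kappa is undefined and is
returned as a flagged degenerate result with κ = NaN rather than an
exception. No bias/prevalence correction and no weighting are applied —
the codes are nominal — and no confidence intervals are computed.

Both statistics keep exact rational observed/expected components, so the
defining identity κ = (po − pe)/(1 − pe) holds to 1e-12 by construction.
Implementation is verified three ways: an independent brute-force
contingency-table oracle over every 2-rater panel with ≤ 4 cases and
≤ 3 labels (7,371 panels, exhaustive), an exhaustive 3-rater Fleiss check
at ≤ 3 cases × 2 labels, and spot cross-checks against statsmodels'
`fleiss_kappa` and scikit-learn's `cohen_kappa_score`. The set-valued
overlap matrix is checked against a literal double-loop oracle
exhaustively over every 2-case, 2-rater panel of non-empty subsets of a
3-code vocabulary (2,401 panels) and on 40 random 5-case panels (full
enumeration of set-valued grids at 4 cases is combinatorially infeasible,
millions of panels; the algebraic invariants cover the remaining ground).

## Synthetic panel generator

Each case draws a latent consensus option `c` from
`consensus_distribution` (uniform by default). Each rater's primary equals
`c` with that rater's adherence probability θ, otherwise is uniform over
the rest of the vocabulary. After the primary, distractor options are
appended one at a time, each with probability λ (`extra_rate`), drawn
uniformly without replacement from the unused vocabulary — a truncated
geometric tail that can never duplicate the primary, so generated cells
satisfy the recommendation invariants by construction. One rng stream,
seeded from `config.seed`, drives the whole panel (cases outer, raters in
roster order inner), so identical configs give byte-identical panels.

Defaults mirror the study conditions: 22 cases, the 11-code vocabulary,
3 references + 5 candidates. θ = 0.5 and λ = 0.3 were fixed once as a
mid-range agreement regime whose mean cell size (≈ 1.4 options) falls
inside the 1.0–1.9 options-per-case range the real raters produced.

In the singleton regime (λ = 0) the union-hit probability has a closed
form: conditioning on `c` and on the candidate's label `x`, each reference
covers `x` independently with probability θ_r (if `x = c`) or
(1 − θ_r)/(V − 1), so `P(hit) = Σ_c π_c Σ_x P(x) (1 − Π_r (1 − P_r(x)))`.
The generator is validated against its own law: Monte-Carlo union accuracy
at 10,000 cases per point matches this closed form within 3 binomial
standard errors across θ ∈ {0, 0.25, 0.5, 0.75, 1}, Fleiss' kappa is
empirically monotone in common θ (200 replicates per grid point), and
setting θ = 1/V makes labels exactly iid uniform, under which the mean
pairwise kappa over 1,000 replicates is statistically indistinguishable
from 0.

What the generator does *not* emulate: case-difficulty covariates
(contracture angles, comorbidities), rater-specific option preferences,
or correlated errors between candidate systems. Passing tests therefore
demonstrate correctness of the metrics under an exchangeable noise model,
not fidelity of any conclusion about real raters.

## Reproduction policy

The analysis pipeline recomputes every published headline statistic from
the coded panel and, in `reproduction.csv`, marks each as `match` or
`differs` at its printed precision. Exactly reproducible: the five union
accuracies, four of five Surgeon I agreements, and all four kappas.
Not reproducible from the coded grid under any rule implemented here
(intersection, equality, primary coverage; macro or micro averaging):
the published Surgeon II/III agreements, mean options counts,
precision/recall/F1 averages, inter-AI agreement percentages (which are
not even multiples of 1/22), and the consensus-stratified accuracies
(whose implied denominators exceed any observable stratum size). For
these, the package reports its own exactly derived values alongside the
published ones rather than hiding either; no attempt is made to
reverse-engineer the unpublished conventions.

## Numerical and scale choices

Percentages display at one decimal, kappa at three, matching the field's
reporting convention; all arithmetic is exact until display. Test-suite
problem sizes — 200 panels for dominance, 7,371 exhaustive kappa panels,
10,000 Monte-Carlo cases per θ, 1,000 null replicates — were sized to keep
the full suite around ten seconds while leaving every statistical
tolerance at 3 standard errors.
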