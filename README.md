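# multirater

Set-valued multi-rater concordance metrics and chance-corrected inter-rater
reliability for coded clinical recommendation panels.

## The problem

When several raters each recommend *one or more* management options per
clinical case — for example, five AI chat systems and three hand surgeons
each advising on 22 Dupuytren's-disease vignettes — standard single-label
agreement statistics do not apply directly. This package implements the
set-overlap metrics used to evaluate such panels, together with Cohen's and
Fleiss' kappa on primary-option labels, and ships the 22-case × 8-rater
Dupuytren's-disease panel as a built-in dataset.

For a panel of cases \(i = 1..n\), candidate rater \(A\) with option set
\(S_{A,i}\) per case, and reference raters \(R_1..R_m\):

- **Union accuracy** = \( \frac{1}{n} \sum_i \mathbf{1}\!\left[\, S_{A,i}
  \cap \bigcup_j S_{R_j,i} \neq \emptyset \,\right] \) — how often the
  candidate names at least one option some reference also named.
- **Reference agreement** (per reference \(j\)) = \( \frac{1}{n} \sum_i
  \mathbf{1}[\, S_{A,i} \cap S_{R_j,i} \neq \emptyset \,] \), averaged
  arithmetically across references.
- **Precision / recall / F1** of \(S_{A,i}\) against the reference union,
  macro-averaged over cases.
- **Consensus stratification**: union-hit accuracy computed separately for
  cases where the references were unanimous vs not, under an explicit
  unanimity definition (`strict_set`, `primary_match`, `any_pairwise_overlap`).
- **Cohen's κ** \( = (p_o - p_e)/(1 - p_e) \) and **Fleiss' κ**
  \( = (\bar P_o - \bar P_e)/(1 - \bar P_e) \) after reducing each
  set-valued cell to its primary (first-listed) option.

All proportions are carried as exact rationals (`9/22`, not `0.40909…`)
and rounded only for display.

## Worked example

```python
>>> import multirater as mr
>>> panel = mr.builtin_study_panel()          # 22 cases, 5 AI + 3 surgeons
>>> res = mr.ConcordanceModel(panel).fit()
>>> ua = res.candidate("copilot").union_accuracy
>>> print(ua, ua.display())
9/22 40.9
>>> rel = mr.ReliabilityModel(panel).fit()    # kappas among the surgeons
>>> print(rel.pair("surgeon1", "surgeon2").display, rel.fleiss.display)
0.224 0.122
>>> print(rel.summary())
Inter-rater reliability
  reduction: primary; raters: Surgeon I, Surgeon II, Surgeon III

  pair                            kappa         po           pe
  Surgeon I – Surgeon II          0.224       4/11       87/484
  Surgeon I – Surgeon III         0.081       5/22         7/44
  Surgeon II – Surgeon III        0.169       7/22       87/484

  Fleiss' kappa: 0.122   (P̄o = 10/33, P̄e = 25/121)
```

Copilot overlapped the surgeons' pooled recommendations in 9 of 22 cases
(40.9%); the surgeons themselves agree only slightly better than chance
(κ ≈ 0.08–0.22, Fleiss 0.122), which is the key caveat when reading any
accuracy against their union.

The same analysis from the shell:

```sh
multirater analyze --builtin --consensus strict_set --out-dir out/
multirater simulate --adherence 0.8 --seed 17 --out-dir sim/
```

`analyze --builtin` also writes `out/reproduction.csv`, a side-by-side
table marking which of the originally published statistics the coded panel
supports exactly (union accuracies, Surgeon I agreements, all four kappas)
and which it contradicts (Surgeon II/III agreements, mean option counts,
precision/recall/F1 averages, inter-AI percentages, consensus-stratified
accuracies) — for those, the package reports its own exactly derived
values instead.

## Synthetic panels

`SyntheticPanelConfig` / `generate_panel` draw panels with a latent
per-case consensus option, per-rater adherence θ (probability the rater's
primary equals the consensus) and a distractor-appending rate λ, so every
metric is testable at known agreement strength;
`expected_union_accuracy` gives the generator's closed-form hit
probability in the singleton (λ = 0) regime.

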