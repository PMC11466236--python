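# clpnet — cross-lagged panel networks for NSSI, depression and anxiety

`clpnet` estimates **cross-lagged panel networks (CLPN)**: directed
symptom-level networks from two-wave panel data, built for studying how
non-suicidal self-injury (NSSI) behaviours, depression symptoms and
anxiety symptoms predict one another over time — and how those dynamics
differ between groups (here: adolescent boys vs girls).  It is aimed at
researchers in psychiatric epidemiology and network psychometrics who
have wide-format ordinal questionnaire panels (12 NSSI items, 6
depression and 6 anxiety items of the BSI-18, each scored 0–4 at two
waves) and want a reproducible, scriptable pipeline instead of an ad-hoc
R session.

## The model

For each of the *p* = 24 symptoms, the wave-2 score is regressed on all
24 wave-1 scores plus covariates with an L1 (lasso) penalty:

    z2_j = sum_i  beta_ij * z1_i  +  gamma_j * sex  +  e_j ,

where every symptom column is z-scored within wave.  The coefficient
matrix `W[i, j] = beta_ij` is a directed network: the diagonal holds
**autoregressive** edges (a symptom predicting itself six months later),
the 552 off-diagonal entries are **cross-lagged** edges.  The penalty
for each regression is chosen by K-fold cross-validation over a
log-spaced grid descending from λ_max (the smallest penalty that zeroes
every coefficient); weak edges shrink exactly to zero.

On top of the fitted network the package computes:

* **Expected influence** — out-EI(i) = Σ_{j≠i} W[i, j] and
  in-EI(j) = Σ_{i≠j} W[i, j], the signed sums of a node's outgoing and
  incoming cross-lagged weights;
* **Bridge edges** — the strongest cross-community edges (e.g.
  NSSI → {depression, anxiety}), the candidate comorbidity pathways;
* **Bootstrap accuracy** — non-parametric subject resampling
  (1,000 iterations by default) with 95% percentile confidence
  intervals around every edge weight;
* **Network comparison** — Pearson correlation of edge weights, mutual
  overlap percentages of nonzero edges, and the Jaccard similarity
  index (shared signed directed edges / union) between two networks.

Because raw cohort data of this kind are rarely shareable, the package
ships a **synthetic panel generator** whose default ground truth encodes
the study design it emulates: n = 884 adolescents (403 boys / 481
girls), two waves six months apart, zero-inflated NSSI items calibrated
to a 23.3% any-NSSI prevalence, and gender-specific cross-lagged weight
matrices, so every stage of the pipeline can be exercised against known
truth.

## Worked example

```bash
clpn simulate --n-subjects 884 --seed 5 --out demo
clpn analyze demo/panel.csv --out demo_analysis
```

The `analyze` command fits the gender-adjusted whole-sample network and
the two gender-specific networks, then prints this summary (verbatim
output of the commands above):

```
Whole sample (n=884): mean |autoregressive| = 0.09, mean |cross-lagged| = 0.00; 552 assessed cross-lagged edges, 93 nonzero.
Boys (n=399): mean |autoregressive| = 0.01, mean |cross-lagged| = 0.00.
  highest out-EI: A4 (+0.15)
  NSSI -> affect bridges: N9->D2 (-0.12), N6->D2 (+0.08), N9->D1 (-0.08)
  anxiety -> depression bridges: A4->D2 (+0.15), A2->D2 (+0.08), A6->D2 (+0.04)
Girls (n=485): mean |autoregressive| = 0.10, mean |cross-lagged| = 0.00.
  highest out-EI: A4 (+0.28)
  NSSI -> affect bridges: N11->D1 (-0.07), N10->A6 (+0.07), N12->D1 (-0.07)
  anxiety -> depression bridges: A4->D1 (+0.14), A4->D6 (+0.13), A3->D1 (-0.03)
Boys vs girls: edge correlation 0.01, overlap girls-in-boys 6.67%, Jaccard 0.03.
```

Reading it: the autoregressive edges outweigh the cross-lagged ones (as
expected in symptom panels); in the boys' network self-cutting (N9)
negatively predicts later feeling blue (D2) and indifference (D1) — the
bridge pattern seeded in the simulator's ground truth — while in the
girls' network skin-rubbing (N11) and carving (N12) predict later
indifference, and feeling scared (A4) bridges anxiety to depression in
both groups.  The comparison line quantifies how different the two
gender networks are.  Note the recovered edge magnitudes are much
smaller than the generating coefficients: a bounded 0–4 ordinal outcome
scale compresses large effects from rare (zero-inflated) NSSI
predictors (see `docs/methods.md`).

Other commands: `clpn fit` (one network, JSON + edge list),
`clpn centrality`, `clpn bootstrap` (edge-weight CIs), `clpn compare`.
Every run writes a `manifest.json` with inputs, seeds and a config hash.

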