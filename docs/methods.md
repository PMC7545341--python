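# Methods

This document describes the statistical and biophysical models implemented
in `ceraxis`, the default parameter values, and the reasoning behind the
less obvious design decisions.

## 1. Synthetic cohorts (`ceraxis.synthetic`)

Expression is simulated on the log2 scale. Each feature has a baseline drawn
from U(6, 12) and i.i.d. Gaussian measurement noise (default
`noise_sd = 0.02`, chosen so that a planted standardized effect of
`axis_effect = 2` is detectable at n = 3 per group while leaving the null
features genuinely noisy).

A planted axis (lncRNA, miRNA, mRNA) receives:

- a **group effect** with the sponge sign pattern — the miRNA is shifted up
  by `axis_effect`·sd in responders, the lncRNA and mRNA down by the same
  amount (all shifts are applied to the *group-centered* values, so the
  realized per-feature effect equals the planted one exactly);
- a **shared latent factor** within each group with loading `axis_corr`
  (default 0.9), signed so the miRNA anticorrelates with the other two.
  The factor is group-centered, so it alters correlations without touching
  the between-group effect.

Sequences are random RNA with engineered binding sites: the lncRNA carries a
site pairing miRNA positions 2–16 and the mRNA a site pairing positions
2–11, so the lncRNA site is the stronger one by construction. Decoy
sequences are rejection-sampled until they contain no 6mer seed core for any
simulated miRNA. Because random flanks can still form incidental pairings
inside the alignment window, each planted axis is additionally
rejection-sampled until the package's own duplex scorer confirms the
documented invariant: the lncRNA site strictly outcompetes the mRNA site in
both alignment score and ΔG. This enforces the generator's contract with its
own scoring model; it does not tune any threshold.

qPCR tables are derived as Ct = 40 − log2(expression), with three
group-independent control genes (GAPDH, 18S, U6).

## 2. Moderated differential expression (`ceraxis.diffexpr`)

With 3 samples per group, per-feature variance estimates are extremely
unstable. We therefore model the inverse variances as Gamma-distributed
across features: 1/σ² ~ Gamma(a, scale b). Under this prior the pooled
sample variance satisfies s²·a·b ~ F(m, 2a) with m pooled degrees of
freedom, which yields a closed-form marginal likelihood for (a, b). The
hyperparameters are estimated by maximum likelihood with **type-II right
censoring** of the largest 5 % of variances (`trim = 0.05`), which makes the
fit robust to variance outliers that violate the Gamma assumption;
multi-start Nelder–Mead avoids local optima.

The moderated variance is the posterior mean

σ̃² = (m·s² + 2/b) / (m + 2a),

and the moderated t statistic uses m + 2a degrees of freedom. Acceptance
tests verify that on data simulated from the model itself the test is
calibrated (type-I error within [0.04, 0.06] at α = 0.05) and that (a, b)
are recovered within 20 %.

**Thresholds.** A feature is dysregulated when fold change > 1.2 or < 0.83
and p < 0.05. Two FDR modes exist because the conventional q < 0.05
requirement is statistically unattainable in the intended design: with
n = 3 + 3 and a realistic effect size, Benjamini–Hochberg q-values across
170 features essentially never fall below 0.05, so requiring it would make
the screen vacuous. `fdr_mode = "q_lt"` (the module default, the
statistically orthodox choice) applies q < 0.05; `fdr_mode =
"paper_literal"` (the pipeline default) applies no q cutoff, matching
common practice in small-cohort screens where the FDR column is reported
but not used as a filter. The fold-change dead zone [0.83, 1.2] is a hard
exclusion regardless of p (verified exhaustively in the tests).

## 3. Coexpression networks and core nodes (`ceraxis.coexnet`)

For each group separately, a bipartite lncRNA–mRNA graph connects pairs with
|Pearson r| ≥ 0.99 (an intentionally extreme cutoff: with n = 3 per group
almost any pair can reach moderate correlation by chance, so only
near-deterministic coexpression is meaningful). Each node's **relative
degree** is its degree divided by the maximum degree in that group's
network; a node absent from a network has relative degree 0. Nodes are
ranked per RNA class by |rd_responder − rd_nonresponder| (ties broken by
maximum degree, then name), and the top-5 per class are the **core nodes** —
the features whose network role changes most between responders and
non-responders.

## 4. Target prediction (`ceraxis.targets`)

Three layers, all computed from sequence alone:

1. **Seed match.** For every 6mer core occurrence (complement of miRNA
   positions 2–7), the most specific canonical class is assigned: 8mer,
   7mer-m8, 7mer-A1 or 6mer (target position 1 is checked for A in the
   A1-classes).
2. **Duplex alignment.** A Gotoh local alignment of the miRNA against the
   reversed target window around the site (window spans from
   `site.start − (len(miRNA) − 6)` to the site end, i.e. enough target
   sequence for full-length pairing). Scoring: Watson–Crick +5, G:U wobble
   +1, mismatch −3, gap open −9, gap extend −4; seed positions 2–8 of the
   miRNA are double-weighted. A perfect 22-mer Watson–Crick duplex scores
   145. The retention cutoff `s_min = 80` corresponds to roughly 55 % of the
   perfect score — extensive complementarity well beyond the seed.
3. **Stacking free energy.** Nearest-neighbor ΔG over consecutive paired
   positions, using the Watson–Crick stack table of Xia et al. (1998) and
   wobble stacks filled in by a composition rule that keeps all stacks
   negative; duplex initiation +4.09 kcal/mol and a +0.45 terminal penalty
   per helix end closed by an A:U or G:U pair. A run consisting of a single
   pair is charged the terminal penalty **once** (its two "ends" are the
   same pair). Retention requires ΔG ≤ −7 kcal/mol.

   Note: because initiation alone costs +4.09, very short pairings have
   positive ΔG; a negative total is only guaranteed for the extensively
   paired duplexes that survive the score cutoff, and the `dG ≤ dg_max`
   filter is what enforces thermodynamic plausibility.

One site per (miRNA, target) pair is retained: the best by alignment score,
then ΔG, then position.

## 5. ceRNA screen (`ceraxis.cerna`)

For every (lncRNA, miRNA, mRNA) triple in which the miRNA has a retained
site on both the lncRNA and the mRNA:

1. **Shared MRE** — both sites exist (by construction of the triple set).
2. **Anticorrelation** — Pearson r ≤ −0.99 for miRNA–lncRNA *and*
   miRNA–mRNA across all discovery samples.
3. **Competition** — the lncRNA site strictly outcompetes the mRNA site:
   align_score_lnc > align_score_mrna **and** ΔG_lnc < ΔG_mrna.

Triples passing all three are **candidates**; candidates whose lncRNA and
mRNA are both core nodes are **nominated**. The output table keeps the full
audit trail (each criterion's truth value and the underlying numbers), and
candidates are ranked by core status, summed relative-degree change,
anticorrelation strength, then lexicographically — the ranking is fully
deterministic.

## 6. Response model (`ceraxis.response`)

Relative expression is 2^−ΔΔCt against a control gene and a reference
sample. A partial-least-squares discriminant (responder = 1) is fit on the
axis members' expression; X is standardized internally and the PLS is run
unscaled, so coefficients are comparable across features. The operating
point is the Youden-J threshold on the training scores. Evaluation on an
independent cohort reports Mann–Whitney AUC (ties counted ½), sensitivity/
specificity at the trained threshold, and DeLong tests comparing the
panel's ROC against each single marker (identical score vectors are defined
to give p = 1). Acceptance tests show mean validation AUC ≥ 0.9 for the
planted-axis panel on 3+3 training / 27+18 validation, with a
label-permutation null mean AUC near 0.5.

## 7. Determinism and provenance

Every run is a pure function of (configuration, seed): all randomness flows
through `numpy.random.default_rng` seeded from the configuration, no
timestamps are written, and output bundles are byte-identical across
re-runs. Every table carries a 3-line provenance header (package version,
SHA-256 of the canonicalized configuration JSON, seed).

## 8. Limitations and open decisions

- The |r| ≥ 0.99 and r ≤ −0.99 cutoffs are appropriate only for very small
  cohorts with strong planted structure; on larger real cohorts they should
  be relaxed (both are configurable).
- The FDR-mode ambiguity (§2) is deliberately exposed rather than resolved:
  the pipeline defaults to the permissive mode because the strict mode is
  powerless at n = 3 + 3, but users analyzing larger cohorts should switch
  to `q_lt`.
- The energy model covers stacking of contiguous pairs only; internal
  loops and bulges contribute no explicit penalty beyond ending the stack
  run. This is adequate for ranking the extensively paired duplexes the
  screen retains, not for absolute ΔG prediction.
- The synthetic generator plants a single dominant axis per cohort by
  default; it is a test harness for the screen's operating characteristics,
  not a generative model of real transcriptomes.
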