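# ceraxis

Discovery of competing-endogenous-RNA (ceRNA) axes and treatment-response
prediction from small two-group transcriptomic cohorts.

A ceRNA axis is a triple (lncRNA, miRNA, mRNA) in which the lncRNA and the
mRNA carry binding sites for the same miRNA. When the lncRNA is abundant it
sponges the miRNA, de-repressing the mRNA; the signature of an active axis is
therefore a shared miRNA-response element, strong anticorrelation of the
miRNA with both the lncRNA and the mRNA, and a lncRNA site that outcompetes
the mRNA site for the miRNA. `ceraxis` screens expression profiles and
sequences for exactly this signature and then asks whether the axis members,
measured by qPCR-style relative expression, predict which patients respond
to a treatment.

## Pipeline stages

1. **`synthetic`** — generates cohorts with a planted, fully specified ceRNA
   axis (expression matrices, RNA sequences with engineered binding sites,
   Ct tables) so that every downstream claim can be checked against ground
   truth.
2. **`diffexpr`** — moderated t-test under a random-variance model (inverse
   variances are Gamma-distributed across features; the hyperparameters are
   fit by censored maximum likelihood). Dysregulation requires fold change
   > 1.2 or < 0.83 **and** p < 0.05; a BH q-value cutoff is applied according
   to `fdr_mode`.
3. **`coexnet`** — group-specific lncRNA–mRNA coexpression networks at
   |Pearson r| ≥ 0.99; nodes are ranked by the between-group change of their
   relative degree (degree divided by the maximum degree of the network) and
   the top-5 per RNA class become *core* nodes.
4. **`targets`** — miRNA binding-site prediction: canonical seed matches
   (8mer, 7mer-m8, 7mer-A1, 6mer), a Gotoh local alignment score with
   double-weighted seed positions, and a nearest-neighbor stacking free
   energy. Sites are retained when score ≥ 80 and ΔG ≤ −7 kcal/mol.
5. **`cerna`** — the three-criterion axis screen: shared site, r ≤ −0.99 for
   both miRNA pairings, and strict competition (lncRNA site scores higher
   *and* binds more stably than the mRNA site). Candidates whose lncRNA and
   mRNA are both core nodes are *nominated*.
6. **`response`** — 2^−ΔΔCt relative expression, a PLS discriminant trained
   on the axis members, Youden-J operating point, Mann–Whitney AUC and
   DeLong tests of the panel against each single marker.

## Worked example

Run the full pipeline on a simulated cohort (50 lncRNAs, 20 miRNAs,
100 mRNAs, 3+3 discovery samples, 27+18 validation samples, one planted
axis):

```console
$ ceraxis run --simulate --seed 0 --outdir demo
simulate: 170 features, 6 discovery + 45 validation samples
diffexpr: 170 features in, 3 dysregulated
coexnet: edges responder=1 nonresponder=1, core lnc=1 mrna=1
target_predict: 2 retained miRNA-target pairs
cerna_screen: 1 triples, 1 candidates, 1 nominated
response_model: axis ('LNC0001', 'MIR0001', 'MRNA0001'), validation AUC=0.949 accuracy=0.600
```

The bundle contains every intermediate table with a provenance header
(package version, SHA-256 of the configuration, seed). The nominated axis is
the planted one:

```console
$ grep -v '^#' demo/nominated.tsv | cut -f1-3,16-17
lnc     mirna   mrna    candidate  nominated
LNC0001 MIR0001 MRNA0001 True      True
```

and `demo/summary.json` reports the validation ROC:

```json
"validation_auc": 0.948559670781893,
"roc_comparison_p": {
  "LNC0001": 4.95e-59,
  "MIR0001": 0.914,
  "MRNA0001": 4.95e-59
}
```

Each stage is also available as its own subcommand (`ceraxis simulate`,
`de`, `coexnet`, `targets`, `screen`, `predict-response`) operating on plain
TSV/FASTA files, so the pipeline can be run piecewise on real data.

## Reproduction

All results are deterministic: identical configuration and seed produce
byte-identical output bundles. The headline calibration and recovery numbers
(type-I error of the moderated t-test, hyperparameter recovery,
planted-axis recovery and null nomination rates, validation AUC and its
permutation null) are recomputed from scratch by

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which writes one `{"value": ..., "n": ...}` entry per quantity. The same
criteria are enforced as tests in `tests/test_acceptance.py`, alongside
brute-force oracle checks for every numeric primitive (alignment DP, stacking
energies, BH FDR, relative degree, AUC).

See `docs/methods.md` for the statistical model, parameter defaults and
design decisions.
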