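# attnrank

Gated-attention ranking and selection of discriminative contrasts in
multi-contrast 3D MRI.

Quantitative MRI studies routinely reconstruct many voxel-wise measures of
the same tissue — for example a dozen diffusion-microstructure maps from
several biophysical models — that are strongly intercorrelated.  Which of
them is most sensitive to focal pathology, and is a combination more
informative than any single one?  `attnrank` answers this with a
patch-classification network: for each subject the co-registered contrast
volumes, a lesion label map and a tissue mask yield small 5×5×5 patches of
lesion and perilesional tissue; a convolutional network with one encoder per
contrast and a *gated attention* head across contrasts learns to classify
the patches, and its attention weights

&nbsp;&nbsp;a = softmax_c( w·( γ · tanh(V h_c) ⊙ σ(U h_c) ) ),&nbsp;&nbsp;
fused feature = Σ_c a_c h_c,

(γ = 2 the enhancement factor, h_c the 16-d hidden feature of contrast c)
quantify each contrast's importance.  Because the weights of correlated
contrasts differ only slightly and their order fluctuates across
cross-validation folds, a **rank-consensus** rule escalates a depth k and
selects the first set of contrasts ranked in the top k of *every* fold whose
cumulative mean attention exceeds 0.5.  The selection is then validated
clinically: per-patient lesion means of the selected measures (and of every
combination of them, formed as unweighted sums) are rank-correlated with a
disability score and a serum biomarker using two-sided 20,000-permutation
Spearman tests under Benjamini–Hochberg FDR control at q = 0.05.

Patient imaging of this kind is not shareable, so the package ships a
synthetic-cohort generator with known ground truth — equicorrelated Gaussian
contrast fields, ellipsoid lesions, intensity shifts confined to a chosen
informative subset, and covariates linked to lesion intensity through a
Gaussian copula — and every stage is exercised and benchmarked end to end on
such cohorts.  The intended audience is methods researchers in quantitative
neuroimaging who want a reproducible, dependency-light reference
implementation of attention-based contrast selection.

The network, training loop and backpropagation are implemented directly in
NumPy (im2col convolutions, batch norm, AdamW, plateau scheduling) and
verified against finite differences; everything runs on one CPU.

## Worked example

A complete five-stage run (simulate → sample → train → select → correlate)
on a deliberately tiny cohort — 10 subjects, 6 contrasts of which #0 and #3
carry a −1.5 sd lesion effect, 2 folds, 6 epochs:

```bash
attnrank run --config examples/quickstart.yaml --seed 7 --outdir run
```

prints

```
simulate: 10 subjects, 18 lesions -> run/cohort
sample: 35 lesion / 95 perilesional patches from 10 subjects
train: fold 0 AUC 0.982 (57 train / 73 val)
train: fold 1 AUC 0.997 (73 train / 57 val)
select: contrasts [0, 3, 5] at depth 4, cumulative attention 0.565
correlate: disability: 9 tests, 0 significant
correlate: biomarker: 9 tests, 5 significant
```

and `run/selection.txt` shows the per-fold attention ranks behind the
consensus:

```
contrast  mean_weight  rank_f0  rank_f1
* m00         0.2092        2        1
  m01         0.1462        6        3
  m02         0.1447        4        6
* m03         0.2060        1        2
  m04         0.1444        5        5
* m05         0.1494        3        4
```

Reading: the two truly informative contrasts dominate the attention
(weights ≈ 0.21 vs ≈ 0.145 for the rest) and are ranked first or second in
both folds; at this toy scale one uninformative contrast (m05) slips into
the consensus set before the cumulative weight crosses 0.5.  At the
package's standard benchmark scale (40 subjects, 12 contrasts, 5 folds) the
selected set matches the informative set exactly in the large majority of
replicates — that experiment is run by the test suite and the acceptance
script below.  `run/correlations_disability.tsv` holds the Spearman ρ,
permutation p and FDR flag for each lesion-load metric and measure
combination.

Every stage is individually re-runnable (`attnrank simulate|sample|train|
select|correlate`), reads/writes NIfTI volumes, TSV manifests and JSON
results, and records provenance (config hash, derived seed) per stage.  The
same functionality is available as a library: `attnrank.synthetic`,
`attnrank.patches`, `attnrank.network`, `attnrank.training`,
`attnrank.selection`, `attnrank.correlation`, `attnrank.experiments`.

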