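# survclustae

Survival- and cluster-supervised autoencoders for prognostic subgroup
discovery in multi-omics cancer cohorts.

## The problem

Bulk multi-omics profiles (mRNA expression, miRNA expression, gene-level
methylation) of a tumour cohort are high-dimensional and noisy, yet they can
harbour patient subgroups that differ in prognosis.  A common two-stage
recipe trains an autoencoder purely for reconstruction, filters the latent
("bottleneck") features by univariate Cox regression, and clusters patients
on what survives.  `survclustae` implements the alternative this package is
built around: push the survival signal and the clustering objective *into*
the autoencoder's loss, so the 100-dimensional bottleneck is shaped for
prognostic grouping while it is being learned.

## The model

Each patient's omics blocks are stacked into one vector `x`.  An encoder
φ and decoder ψ (hidden widths 1000–100–1000, sigmoid; baseline variant
500–100–500, tanh) are trained under a weighted objective built from

- reconstruction, `L_R = (1/n) Σᵢ ‖xᵢ − ψ(φ(xᵢ))‖²` — the mean *per-sample*
  squared error (not the element mean; the loss weights below are calibrated
  to this convention);
- survival, `L_S = −Σᵢ δᵢ { W′φ(xᵢ) − log Σ_{j∈R(tᵢ)} exp(W′φ(xⱼ)) }` — the
  negative Cox partial log-likelihood of a linear risk score read off the
  bottleneck through a one-unit branch `W` (δᵢ the death indicator, `R(tᵢ)`
  the risk set, Breslow handling of ties; the training loop averages this
  term over the batch);
- clustering, `L_C = (1/n){ Σᵢ ‖φ(xᵢ) − μᵢ‖² − Σᵢ ‖φ(xᵢ) − λᵢ‖² }` with μᵢ
  the nearest and λᵢ the second-nearest centroid — tighten clusters, push
  them apart.

The hybrids are `L_RC = 0.25·L_R + 0.75·L_C`, `L_RS = 0.25·L_R + 0.75·L_S`
and `L_RSC = 0.25·L_R + 0.50·L_S + 0.25·L_C`.  Training follows a bespoke
loop: a one-epoch reconstruction warm-up, centroid seeding at the two
farthest-apart bottleneck vectors, full-batch Adam steps with samples held
in descending-survival order (never shuffled), and a centroid-mean update
plus reassignment after every epoch.  Downstream, subgroups are labelled
(final centroids, or k-means with silhouette-selected k ∈ 2..5), scored by
pairwise log-rank tests, and traced back to original omics features via
one-way ANOVA with a top-10% + Bonferroni (P < 0.005) rule and a
ten-run consensus ("robust" = selected in every run).

Everything, including the networks and their gradients, is plain
numpy/scipy; survival statistics lean on lifelines, clustering on
scikit-learn.

## Worked example

A seeded synthetic cohort plants two subgroups (60/60 of 120 samples) that
shift 43 of 630 features by three noise SDs and multiply the event hazard
by 5.  Training the hybrid loss and labelling with the final centroids
(`examples/02_train_hybrid_autoencoder.py`):

```
bottleneck: 120 x 100
silhouette trace: 0.016 (seeded) -> 0.064 (epoch 40)
cluster sizes: [60, 60], log-rank P = 7.13e-11
agreement with planted subgroups: 98.3%
```

The per-epoch silhouette rises from the crude farthest-pair seeding to the
trained representation, and the recovered subgroups split survival at
P ≈ 7e-11 while agreeing with the planted labels for 118 of 120 patients.
`examples/03_survival_statistics.py` fits the univariate Cox model on the
true label — hazard ratio 4.87 with the 95% CI covering the simulated
log 5 — and `examples/04_feature_discovery.py` recovers 100% of the planted
features in each omics block.  The other examples cover simulation, the
survival statistics and the full loss-comparison report; a thin CLI
(`survclustae simulate`, `survclustae run`) drives the same pipeline from
TSV files and a YAML config.

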