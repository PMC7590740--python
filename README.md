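# flowot

Optimal-transport template building and automated gating for flow cytometry.

Flow cytometry measures a handful of scatter/fluorescence markers on
hundreds of thousands of cells per sample, and *gating* assigns each cell
(event) to a discrete cell type.  Supervised gating from a historical
database is hard because cytometries vary for biological reasons (different
individuals, health status) and technical reasons (different instruments,
settings, centres).  `flowot` addresses this by

1. summarising every gated cytometry as a weighted Gaussian mixture, one
   component `(m_k, S_k, p_k)` per cell type;
2. comparing whole cytometries with the **similarity distance**
   `d_S = d_OT / d_NT ∈ [0, 1]`, where `d_OT` is the optimal-transport cost
   between the two component sets (ground cost: the closed-form 2-Wasserstein
   distance `W2(N(m_i,S_i), N(m_j,S_j))` between Gaussians) and `d_NT` is the
   cost of the naive product coupling — 0 means same clusters with same
   weights, 1 means transport can do no better than proportional spreading;
3. meta-clustering the database on the `d_S` matrix (hierarchical linkage,
   DBSCAN or HDBSCAN) and condensing each group into a **template** cytometry
   via Wasserstein barycenters — by per-label pooling, density clustering of
   the pooled components, or trimmed k-barycenters;
4. gating a new cytometry with **tclust** (trimmed model-based clustering
   maximising the pseudo-likelihood
   `Σ_j Σ_{i∈C_j} log p_j φ(x_i; m_j, S_j)` with `⌈nα⌉` events trimmed and a
   cluster-covariance eigenvalue-ratio bound `c`), initialised from every
   template; assigning the fitted mixture to its nearest template in `d_S`;
   and labelling events by OT **label transfer** (fuzzy scores
   `s^l_k = w*_kl / p^j_l`, hardened by the Hungarian method), QDA from the
   template, or a supervised learner trained on the most similar database
   cytometry.

It is written for computational cytometrists and methods researchers who
want a transparent, classical alternative to deep-learning gating: every
intermediate object (distance matrix, dendrogram, templates, transport
plans) is inspectable.

## Worked example

```python
import flowot as fo

# a synthetic database: 3 generative conditions x 5 gated cytometries,
# 4 cell types, 5% uniform outliers, per-individual and per-centre noise
cfg = fo.SynthConfig(seed=7)
db, groups, params = fo.generate_database(cfg)

meta, templates = fo.optimal_flow_templates(
    db, cluster_method="complete", n_groups=3, template_method="pooling")
print([sorted(g) for g in meta.groups])

target, truth = fo.generate_target(params, group=1, seed=99)
labels, report = fo.optimal_flow_classification(
    target, db, cluster_method="complete", n_groups=3,
    template_method="pooling", strategy="label_transfer")
print(report["assigned_members"])
print(round(fo.median_f_measure(truth, labels), 3))
```

prints

```
[['g1s1', 'g1s2', 'g1s3', 'g1s4', 'g1s5'], ['g2s1', ...], ['g3s1', ...]]
['g2s1', 'g2s2', 'g2s3', 'g2s4', 'g2s5']
0.972
```

— the meta-clustering recovers the three generative conditions exactly, the
target drawn from condition 2 is assigned to the condition-2 template, and
the transferred labels agree with the withheld truth at median F-measure
0.97 (the median, over cell types, of the harmonic mean of per-type recall
and precision; small diagnostic populations count as much as dominant ones).

The same pipeline is scriptable:

```sh
flowot simulate --groups 3 --per-group 5 --seed 7 --out db/
flowot templates --input db/ --cluster-method complete --n-groups 3 \
    --template-method pooling --out bundle.json
flowot classify --target db/g2s1.csv --database db/ --n-groups 3 \
    --strategy label-transfer --seed 7 --out labels.csv
flowot evaluate --truth db/g2s1.csv --pred labels.csv --metric median-fmeasure
```

Estimator-style classes (`TrimmedGaussianMixture`, `CytometryTemplates`,
`TemplateGatingClassifier`) follow scikit-learn conventions (`fit`,
`predict`, `get_params`, fitted attributes with trailing underscores) and
compose with sklearn model selection.

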