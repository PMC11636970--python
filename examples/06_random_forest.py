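"""Random-forest discrimination of MK vs NS from the taxa layer.

A stratified 70/30 split, per-tree out-of-bag mean decrease in accuracy
for feature importance, a top-5 biomarker panel, and a Mann-Whitney AUC
with a stratified bootstrap 95% CI on the held-out test samples.
"""

import keloidomics as k

tab, meta, truth = k.generate_microbiome(n_diff=10, effect_log2fc=2.0, seed=6)
filt = k.ecology.prevalence_filter(tab)
rep = k.classifier.classify_layer(filt.data, meta, layer="taxa",
                                  train_frac=0.7, top_k=5, n_trees=500,
                                  seed=6)
print(f"train {len(rep.train_ids)} / test {len(rep.test_ids)} samples")
print(f"test AUC = {rep.auc:.3f} (95% CI {rep.auc_ci[0]:.3f}-{rep.auc_ci[1]:.3f})")
print("top-5 panel by mean decrease in accuracy:")
for f in rep.panel:
    mark = "planted" if f in set(truth.diff_taxon_ids()) else "background"
    print(f"  {f}: importance {rep.importance[f]:.4f} ({mark})")
print("An AUC near 1 with a planted-taxa panel shows the forest keys on "
      "the genuine group signal rather than compositional noise.")
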