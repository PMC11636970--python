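"""Per-cell metabolic pathway activity with QC and cluster comparison.

Cells with < 200 or > 6000 total UMIs are removed, each surviving cell is
scored for each gene set by the rank-AUC statistic (high when the set's
genes crowd the top of the cell's expression ranking), and the top-scoring
cluster per set is tested against the rest.
"""

import keloidomics as k

sets = k.make_gene_sets(n_sets=4, set_size=30, n_genes=1000, seed=7)
cm, truth = k.generate_cells(n_cells_per_cluster=60,
                             clusters=[f"C{i+1}" for i in range(6)],
                             n_genes=1000, sets=sets,
                             active_map={"pathway_1": ["C2"]},
                             activity_fc=4.0, seed=7)
kept = k.singlecell.qc_filter(cm, umi_min=200, umi_max=6000)
print(f"QC: {len(kept.cell_ids)} of {len(cm.cell_ids)} cells kept "
      "(200 <= total UMI <= 6000)")

scores = k.singlecell.pathway_score(kept, sets, top_frac=0.05)
out = k.singlecell.cluster_score_compare(scores, kept.cluster)
print(out[["top_cluster", "p_top_vs_rest"]])
print("pathway_1 was planted active in cluster C2: its top-scoring "
      "cluster should be C2 with a tiny rank-sum p; the other pathways' "
      "top clusters are chance, with unremarkable p-values.")
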