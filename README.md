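# avekit

Analysis toolkit for the transcriptional identity and migration of the
anterior visceral endoderm (AVE), the signalling centre that breaks
anterior-posterior symmetry in the early mouse embryo. The package
re-implements, as a tested Python library, the computational procedures a
study of AVE identity and migration needs:

- **QC + normalization** of plate-based scRNA-seq counts (five per-cell
  criteria; pooled-deconvolution size factors; `ln(x/s + 1)`).
- **Clustering with information-theoretic model selection**: Spearman
  distance `d = (1 - rho)/2`, average-linkage hierarchical clustering with
  a deepsplit-indexed hybrid cut, and the number of clusters chosen where
  the average Variation of Information
  `VI(p, q) = H(p) + H(q) - 2 I(p; q)` against half-gene re-clusterings
  'kicks' upward; PAM splits, kNN outlier flags and pairwise-Wilcoxon
  marker ranking.
- **Sub-clustering** with Leiden over a (k, resolution) grid, gene
  subsampling robustness, and a merge rule that dissolves clusters lacking
  two *specific* markers; supervised signature splits.
- **Diffusion pseudotime**: adaptive-kernel diffusion maps, the
  accumulated operator `M = (I - (T - 1 pi^T))^-1 - I` with
  `dpt(x) = ||M_root - M_x||`, spline-based trend tests (F-test, FDR) and
  high-in-AVE / low-in-AVE trend grouping.
- **Isoform usage**: per-gene chi-squared contingency tests between
  clusters after removing single-isoform-dominated genes.
- **Cell-cell communication**: per ligand-receptor pair alpha the directed
  weight `w_ij = (phi_i phi_j)(p_i p_j)` from expressing fractions and
  scaled non-zero means, median-filtered across pairs; bootstrap
  sign-inversion p-values for PCA loadings of a signalling pathway.
- **(Phospho)proteomics**: peptide-to-protein aggregation, cyclic-loess
  normalization, moderated-t differential abundance, RNA fold-change
  comparison, and site-matched kinase-substrate bipartite networks.
- **Motion phenotyping**: dense-flow superpixel tracking (forward and
  reverse), the frozen neighbour mesh, the mesh strain curve
  `mean_e |L_e(t) - L_e(0)| / L_e(0)`, motion source/sink saliency maps,
  and PCA over concatenated forward+reverse strain signatures.

Deposited embryo data are not required: `avekit.simulate` generates
negative-binomial cluster-structured counts (markers, pseudotime
gradients, ligand-receptor patterns, isoform splits, QC failures) and
migration videos with planted sources, sinks and speeds — with ground
truth, so every stage is tested by parameter recovery.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from avekit.clustering import cluster_with_vi_selection
from avekit.expression import normalize_log, select_hvgs
from avekit.simulate import ExpressionSimSpec, simulate_counts

spec = ExpressionSimSpec(n_cells_per_cluster=[100, 100, 100],
                         n_genes=2000, seed=1)
m, truth = simulate_counts(spec)
mn = normalize_log(m, method="library")
sel = cluster_with_vi_selection(mn, select_hvgs(mn, n_top=300),
                                n_subsamples=50, seed=0)
for d, v in sel.avg_vi.items():
    print(f"deepsplit {d}: avg VI {v:.3f}")
part = sel.chosen_partition
print("chosen deepsplit:", sel.chosen_deepsplit,
      "| clusters:", len(set(part)),
      "| ARI:", round(adjusted_rand_score(truth['cluster_labels'], part), 3))
```

prints

```
deepsplit 0: avg VI 0.007
deepsplit 1: avg VI 0.061
deepsplit 2: avg VI 0.666
deepsplit 3: avg VI 1.066
deepsplit 4: avg VI 1.760
chosen deepsplit: 1 | clusters: 3 | ARI: 1.0
```

The VI curve sits on a low plateau through deepsplit 1 and kicks upward at
deepsplit 2, so deepsplit 1 is selected; its partition recovers the three
planted clusters exactly (adjusted Rand index 1.0). The `examples/`
directory walks through every other capability the same way — QC,
sub-clustering with the merge rule, pseudotime trends (dpt vs planted
latent time: Spearman 0.98; 100/100 planted monotone genes found and
grouped 50/50 into high-in-AVE / low-in-AVE), isoform switching,
communication graphs, proteomics and motion phenotyping:

```bash
python examples/02_cluster_model_selection.py
python examples/04_pseudotime_trends.py
python examples/08_motion_phenotyping.py
```

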