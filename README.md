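# ieaclust

Independent enrichment analysis (IEA) of gene lists.

A differential-expression experiment produces a list of genes that usually
mixes several biological programmes under distinct regulatory control.
Standard over-representation analysis tests the whole list at once and can
miss programme-level signal. `ieaclust` instead:

1. **clusters** the gene list into subgroups for every k in 1..k_max by
   non-negative matrix factorization (multiplicative updates, generalized
   Kullback-Leibler divergence) of a binary gene x annotation matrix — one
   clustering per annotation system (e.g. GO terms and transcription-factor
   target annotations), with no expression values needed;
2. **selects** the number of clusters with AIC under a per-cluster Bernoulli
   model, plus the dAIC variant that first filters out annotation columns
   distributed randomly across all multi-cluster solutions;
3. **links** adjacent clustering levels into a non-nested tree via the phi
   coefficient of gene memberships, so coherent clusters can be tracked
   across levels;
4. **cross-evaluates** every cluster by one-sided Fisher's exact enrichment
   with Benjamini-Hochberg FDR — descriptively within the clustering system
   (DEA) and inferentially against the *other* system (IEA: TFs enriched in
   GO-homogeneous clusters and vice versa), plus Fisher *inter-correlation*
   between cluster pairs of the two trees.

The IEA p-value for annotation x in cluster y is the upper hypergeometric
tail P(X >= a) for a carriers of x among the n cluster genes, given K
carriers among the N genes of the whole list. Because y was formed without
using x's annotation system, this is an ordinary exact test; the same value
computed within the clustering system (DEA) is circular and is reported only
as a ranking score.

Intended users: bioinformaticians analysing DE gene lists from bulk or
single-cell transcriptomics who want regulator hypotheses per functional
subgroup, not a flat term list.

## Worked example

Simulate a coupled two-system dataset with four planted clusters, then run
the full pipeline:

```bash
ieaclust simulate --out demo/inputs --n-genes 200 --k-true 4 --seed 7
ieaclust run --genes demo/inputs/genes.txt \
    --system-one demo/inputs/system_one.tsv --system-two demo/inputs/system_two.tsv \
    --label-one GO --label-two TF --k-max 6 --seed 7 --out demo/out
```

which prints the files written:

```
enrichment_GO   demo/out/enrichment_GO.tsv
enrichment_TF   demo/out/enrichment_TF.tsv
inter_correlation       demo/out/inter_correlation.tsv
tree_GO demo/out/tree_GO.json
tree_TF demo/out/tree_TF.json
```

The same analysis from Python (see `examples/` for narrative scripts):

```python
>>> import ieaclust as ic
>>> ds = ic.generate(ic.SyntheticParams(seed=7))
>>> levels = ic.build_levels(ds.system_one, k_max=6, seed=7)
>>> retained = ic.daic_dimension_filter(ds.system_one, levels)
>>> scores = ic.daic_scores(ds.system_one, levels, retained)
>>> ic.select_best_level(scores, use_daic=True)
4
>>> best = next(lv for lv in levels if lv.k_requested == 4)
>>> recs = ic.enrich_clusters(best, ds.system_two, ds.gene_list, mode="IEA")
>>> r = min(recs, key=lambda r: r.p_fdr)
>>> r.annotation, r.a, r.n, r.K_list, r.N, float(r.p_fdr)
('S2_c1_sig1', 46, 50, 51, 200, 1.1976575324585415e-32)
```

Read: dAIC picks the planted four-cluster level; the strongest IEA hit says
46 of the 50 genes in one GO-derived cluster carry second-system annotation
`S2_c1_sig1`, versus 51 carriers in the whole 200-gene list — enrichment far
beyond chance (FDR p ≈ 1e-32), correctly recovering the planted
cross-system coupling.

Every enrichment row carries the full 2x2 table (`count_in_cluster`,
`count_in_list`, cluster and list sizes), the raw p and the BH-adjusted p,
its mode (`DEA`/`IEA`/`LIST_VS_GENOME`) and background (`list`/`genome`).

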