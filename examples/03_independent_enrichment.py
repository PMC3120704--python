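"""IEA vs DEA: why cross-system enrichment is the interpretable one.

Clusters are formed from system one only, then tested for enrichment of
system-two annotations (IEA — an ordinary exact test) and of system-one
annotations (DEA — circular, a descriptive score only). With a coupled
generator both show signal; the difference is what the p-values mean.
"""

import ieaclust as ic

ds = ic.generate(ic.SyntheticParams(coupling=1.0, seed=5))
levels = ic.build_levels(ds.system_one, k_max=4, seed=5)
best = levels[-1]  # the planted k = 4 level

iea = ic.enrich_clusters(best, ds.system_two, ds.gene_list, mode="IEA")
dea = ic.enrich_clusters(best, ds.system_one, ds.gene_list, mode="DEA")

print("top IEA hits (inferential; FDR-corrected):")
for r in sorted(iea, key=lambda r: r.p_fdr)[:4]:
    print(f"  cluster {r.cluster_index}: {r.annotation}  "
          f"{r.a}/{r.n} vs {r.K_list}/{r.N}  FDR p = {r.p_fdr:.2e}")

n_sig = sum(r.p_fdr < 0.1 for r in iea)
print(f"{n_sig} of {len(iea)} IEA tests significant at FDR < 0.1")
best_dea = min(dea, key=lambda r: r.p_fdr)
print(f"strongest DEA score (descriptive only): cluster {best_dea.cluster_index} "
      f"{best_dea.annotation}, FDR p = {best_dea.p_fdr:.2e}")
print("-> each cluster's planted second-system annotation should appear among "
      "the IEA hits: the regulator of each functional subgroup is recovered "
      "without ever using system two for clustering.")
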