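"""End-to-end run from files, exactly as the command-line tool does it.

A simulated dataset is written in the pipeline's input formats (gene list +
two gene/annotation TSV files), analysed with `run_pipeline`, and the
cross-tree inter-correlation table is read back: with strong coupling the
top pairs should be the matched planted clusters of the two trees.
"""

import tempfile
from pathlib import Path

import ieaclust as ic
from ieaclust.synthetic import write_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = ic.generate(ic.SyntheticParams(n_genes=150, k_true=3, seed=13))
    inputs = write_dataset(ds, Path(tmp) / "inputs")
    config = ic.RunConfig(
        gene_list_path=inputs["genes"],
        system_one_path=inputs["system_one"],
        system_two_path=inputs["system_two"],
        out_dir=str(Path(tmp) / "out"),
        system_one_label="GO",
        system_two_label="TF",
        k_max=5,
        seed=13,
    )
    result = ic.run_pipeline(config)

    for label in ("GO", "TF"):
        tree = result.systems[label].tree
        print(f"{label} tree: best AIC level {tree.best_aic_level}, "
              f"best dAIC level {tree.best_daic_level}")
    print("top inter-correlation pairs (GO cluster x TF cluster):")
    for r in result.inter_correlation[:3]:
        print(f"  GO L{r.level_a} c{r.cluster_a} x TF L{r.level_b} c{r.cluster_b}: "
              f"overlap {r.overlap}/{min(r.size_a, r.size_b)}  FDR p = {r.p_fdr:.2e}")
    print("files written:", ", ".join(sorted(result.output_paths)))
print("-> near-total overlaps with tiny p confirm the two annotation systems "
      "carve the gene list into the same planted subgroups.")
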