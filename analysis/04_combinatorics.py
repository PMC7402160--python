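"""Combinatorial analytics: stacked fractions, pair matrix, clustering, PCA.

From the step-01 reads, builds the enhancer stacked bin-fraction ranking, the
enhancer x promoter weighted-mean expression matrix, hierarchically clusters
it, and runs both PCA orientations (enhancers in promoter space and the
dual), reporting PC1's explained variance.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import combisort as cs
from combisort.simulate import read_bins_tsv, read_reads_tsv


def main(outdir: Path = Path("results")) -> None:
    records = read_reads_tsv(outdir / "reads.tsv")
    bins = read_bins_tsv(outdir / "bins.tsv").set_index("bin")
    cells = bins["C_b"].to_dict()
    gates = cs.SortGates()

    # stacked fractions + rank order of enhancers
    single, _ = cs.tally(records, cells, level="single_element")
    prev_e = cs.normalize_prevalence(cs.counts_for_class(single, "enhancer"), gates)
    sf = cs.stacked_fractions(prev_e)
    top = sf.rank.sort_values().index[:3]
    bottom = sf.rank.sort_values().index[-3:]
    print("enhancer ranking: strongest", list(top), "weakest", list(bottom))
    stacked = sf.fractions.copy()
    stacked["weighted_mean"] = sf.weighted_mean
    stacked["rank"] = sf.rank
    stacked.to_csv(outdir / "stacked_fractions_enhancer.tsv", sep="\t")

    # enhancer x promoter pair matrix from pair-level weighted means
    pair, _ = cs.tally(records, cells, level="element_pair")
    prev_pair = cs.normalize_prevalence(pair, gates)
    wm = pd.Series(
        {
            key: cs.weighted_mean_expression(row.values, gates=gates)
            for key, row in prev_pair.x.iterrows()
            if row.sum() > 0
        }
    )
    pm = cs.pairwise_matrix(wm)
    pm.values.to_csv(outdir / "pair_matrix.tsv", sep="\t")
    print(f"pair matrix: {pm.values.shape[0]} enhancers x {pm.values.shape[1]} "
          f"promoters, {pm.n_missing} unobserved pairs")

    clust = cs.cluster_matrix(pm)
    pd.DataFrame({"row_order": pd.Series(clust.row_order),
                  "col_order": pd.Series(clust.col_order)}).to_csv(
        outdir / "cluster_orders.tsv", sep="\t", index=False)
    groups = clust.row_clusters(3)
    sizes = pd.Series(list(groups.values())).value_counts().sort_index()
    print(f"hierarchical clustering at k=3 enhancer groups of sizes {list(sizes.values)}")

    for axis, name in (("rows", "enhancers"), ("cols", "promoters")):
        pca = cs.pca_elements(pm, samples_axis=axis)
        print(f"PCA ({name} as samples): PC1 {100 * pca.explained_fraction[0]:.1f}%, "
              f"PC2 {100 * pca.explained_fraction[1]:.1f}% of variance")
        pca.scores.to_csv(outdir / f"pca_scores_{name}.tsv", sep="\t")
        np.savetxt(outdir / f"pca_variance_{name}.tsv", pca.explained_fraction)


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    main(ap.parse_args().outdir)
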