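"""Score cross-cohort similarity from LICN membership and expression.

R1 is the Jaccard coefficient of IC-lncRNA sets, R2 the Pearson
correlation of mean IC-lncRNA expression; cohorts are clustered on
1 - (R1 + R2)/2 and the dendrogram serialised as Newick.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORTS, DATA, RESULTS, load_pairs

from lncoop.io import read_matrix
from lncoop.licn import build_networks
from lncoop.similarity import build_similarity, cluster_cancers


def main() -> None:
    pairs = load_pairs(RESULTS / "cooperation_pairs.tsv")
    immune_terms = set()
    for label in COHORTS:
        immune_terms |= set((DATA / label / "immune_terms.txt").read_text().split())
    nets = build_networks(pairs, immune_terms=immune_terms)

    licn_nodes = {c: set(g.nodes()) for c, g in nets.licn.items()}
    mean_expr = {c: read_matrix(DATA / c / "lncrna_expr.tsv").mean(axis=1)
                 for c in licn_nodes}
    sim = build_similarity(licn_nodes, mean_expr)
    sim.combined.to_csv(RESULTS / "cancer_similarity.tsv", sep="\t")
    out = cluster_cancers(sim, n_clusters=2)
    (RESULTS / "cancer_dendrogram.nwk").write_text(out["newick"] + "\n")
    out["clusters"].to_csv(RESULTS / "cancer_clusters.tsv", sep="\t")
    for a in sim.combined.index:
        for b in sim.combined.columns:
            if a < b:
                print(f"{a} ~ {b}: R1={sim.r1.loc[a, b]:.3f} "
                      f"R2={sim.r2.loc[a, b]:.3f} "
                      f"combined={sim.combined.loc[a, b]:.3f}")
    print("clusters:", dict(out["clusters"]))


if __name__ == "__main__":
    main()
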