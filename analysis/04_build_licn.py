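"""Build cooperation networks and immune cooperative networks (LICNs).

Assembles the pan-cancer cooperation network from the detected pairs,
extracts LICNs from the immune-flagged modules, identifies and classifies
degree hubs, and writes topology and catalog summaries.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORTS, DATA, RESULTS, load_pairs

from lncoop.io import write_network
from lncoop.licn import (
    build_networks,
    classify_hubs,
    hubs_to_frame,
    identify_hubs,
    summarize_topology,
    summary_counts,
)


def main() -> None:
    pairs = load_pairs(RESULTS / "cooperation_pairs.tsv")
    immune_terms = set()
    for label in COHORTS:
        immune_terms |= set((DATA / label / "immune_terms.txt").read_text().split())
    nets = build_networks(pairs, immune_terms=immune_terms)

    write_network(nets.pan, RESULTS / "pan_cooperation_network.tsv")
    write_network(nets.pan_licn, RESULTS / "pan_licn.tsv")
    write_network(nets.pan, RESULTS / "pan_cooperation_network.graphml",
                  fmt="graphml")

    pan_hubs = identify_hubs(nets.pan_licn)
    per_hubs = {c: identify_hubs(g) for c, g in nets.licn.items()
                if g.number_of_nodes()}
    cls = classify_hubs(pan_hubs, per_hubs)
    hubs_to_frame(nets.pan_licn, cls).to_csv(RESULTS / "hubs.tsv",
                                             sep="\t", index=False)

    topo = summarize_topology(nets.pan, n_random=100, seed=5)
    counts = summary_counts(pairs, nets,
                            n_lncrna_universe=COHORTS["CXA"].n_lncrna)
    (RESULTS / "topology_report.json").write_text(json.dumps(topo, indent=1))
    (RESULTS / "summary_counts.json").write_text(json.dumps(counts, indent=1))

    print(f"pan-cancer network: {nets.pan.number_of_nodes()} lncRNAs, "
          f"{nets.pan.number_of_edges()} cooperations; "
          f"LICN: {nets.pan_licn.number_of_nodes()} IC-lncRNAs, "
          f"{nets.pan_licn.number_of_edges()} immune cooperations")
    tally = {}
    for c in cls:
        tally[c.category] = tally.get(c.category, 0) + 1
    print(f"hubs: {len(pan_hubs)} ({tally}); "
          f"multi-cancer lncRNAs {counts['pct_multi_cancer_lncrnas']}%, "
          f"cancer-specific edges {counts['pct_cancer_specific_edges']}%")
    print(f"clustering {topo['mean_clustering']:.3f} vs null "
          f"{topo['null_mean_clustering']:.3f} (p={topo['clustering_p']:.3f}); "
          f"power-law alpha {topo['powerlaw_alpha']:.2f}")


if __name__ == "__main__":
    main()
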