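"""Relate lncRNA expression to immune-cell infiltration in cohort CXS.

Spearman screening at |R| > 0.3 and p < 0.05, median-split differential
expression against CD8 T-cell infiltration, and Fisher overlap of the
differential set with the IC-lncRNAs.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, RESULTS, load_pairs

import pandas as pd

from lncoop.infiltration import correlate_infiltration, fisher_overlap, median_split_de
from lncoop.io import read_matrix


def main() -> None:
    d = DATA / "CXS"
    expr = read_matrix(d / "lncrna_expr.tsv")
    infil = pd.read_csv(d / "infiltration.tsv", sep="\t", index_col=0)

    assoc = correlate_infiltration(expr, infil)
    assoc.to_csv(RESULTS / "infiltration_assoc.tsv", sep="\t", index=False)
    hits = assoc[assoc.passes]
    print(f"{len(hits)} lncRNA-cell associations pass |R|>0.3, p<0.05 "
          f"(strongest: {hits.iloc[hits.spearman_r.abs().argmax()].lncrna} ~ "
          f"{hits.iloc[hits.spearman_r.abs().argmax()].cell_type}, "
          f"rho={hits.spearman_r.abs().max():.2f})" if len(hits) else
          "no association passes the cutoffs")

    de = median_split_de(expr, infil, "CD8_Tcell")
    de.to_csv(RESULTS / "infiltration_de.tsv", sep="\t")
    de_set = set(de.index[de.de])
    print(f"{len(de_set)} lncRNAs differential across the CD8 T-cell median split")

    pairs = load_pairs(RESULTS / "cooperation_pairs.tsv")
    ic = set()
    for p in pairs:
        if p.cancer_label == "CXS":
            ic |= {p.lncrna_a, p.lncrna_b}
    res = fisher_overlap(de_set, ic, set(expr.index))
    report = {"table": res.table, "odds_ratio": res.odds_ratio,
              "ci95": [res.ci_low, res.ci_high], "p": res.p,
              "corrected": res.corrected}
    (RESULTS / "infiltration_fisher.json").write_text(json.dumps(report, indent=1))
    print(f"DE x IC overlap: OR={res.odds_ratio:.2f} "
          f"[{res.ci_low:.2f}, {res.ci_high:.2f}], p={res.p:.3g}")


if __name__ == "__main__":
    main()
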