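"""Generate the synthetic multi-omics cohorts and write them to disk.

Each cohort gets aligned lncRNA/mRNA/CNV/methylation matrices, GO BP gene
sets with immune flags, a protein-interaction network, TIMER-style
infiltration fractions, a clinical table and the planted ground truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORTS, DATA, ensure_dirs

from lncoop.synthetic import (
    generate_annotation,
    generate_clinical,
    generate_omics_bundle,
    write_study,
)


def main() -> None:
    ensure_dirs()
    for label, cfg in COHORTS.items():
        bundle, truth = generate_omics_bundle(cfg)
        bundle.cancer_label = label
        genesets, ppi = generate_annotation(cfg)
        infiltration, clinical = generate_clinical(cfg, bundle, truth)
        outdir = DATA / label
        write_study(outdir, bundle, truth, genesets, ppi,
                    infiltration, clinical, config=cfg)
        print(f"{label}: {bundle.n_samples} samples, "
              f"{len(bundle.lncrna_expr)} lncRNAs, {len(bundle.mrna_expr)} mRNAs, "
              f"{len(truth.true_pairs)} planted cooperative pairs, "
              f"{ppi.number_of_edges()} PPI edges -> {outdir}")


if __name__ == "__main__":
    main()
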