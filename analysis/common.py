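"""Shared study definitions for the analysis drivers.

Two synthetic cancer cohorts ("CXA", "CXB") at the default study
conditions, plus an immune/survival scenario cohort ("CXS") carrying
infiltration links, a planted hazard lncRNA and separated latent
subtypes. Every driver regenerates deterministically from these configs.
"""

from pathlib import Path

from lncoop.synthetic import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

COHORTS = {
    "CXA": SimulationConfig(seed=101),
    "CXB": SimulationConfig(seed=202),
    "CXS": SimulationConfig(
        seed=303,
        subtype_sep=6.0,
        infiltration_link=[("lnc0001", "CD8_Tcell", 0.6),
                           ("lnc0002", "CD4_Tcell", 0.5)],
        hazard_link=[("lnc0003", 0.8)],
    ),
}

COOP_SEED = 17
N_RANDOM = 200  # edge-switch networks per cohort


def ensure_dirs() -> None:
    DATA.mkdir(parents=True, exist_ok=True)


def load_pairs(path):
    """Rebuild CooperationPair objects from the detection driver's table."""
    import pandas as pd

    from lncoop.cooperation import CooperationPair, FunctionalModule

    df = pd.read_csv(path, sep="\t")
    pairs = {}
    for row in df.itertuples(index=False):
        key = (row.lncrna_a, row.lncrna_b, row.cancer)
        if key not in pairs:
            pairs[key] = CooperationPair(
                lncrna_a=row.lncrna_a, lncrna_b=row.lncrna_b,
                cancer_label=row.cancer, n_shared=int(row.n_shared),
                overlap_p=float(row.overlap_p), modules=[])
        pairs[key].modules.append(FunctionalModule(
            lncrna_a=row.lncrna_a, lncrna_b=row.lncrna_b, go_term=row.go_term,
            genes=frozenset(str(row.module_genes).split(",")),
            enrich_p=float(row.enrich_p), min_dist_ok=True,
            cpl_real=float(row.cpl), cpl_p=float(row.cpl_p)))
    return list(pairs.values())
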