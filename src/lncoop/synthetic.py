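"""Synthetic multi-omics study generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: mRNA expression
follows a linear model in gene-level copy number, promoter methylation and
the expression of regulating lncRNAs plus Gaussian noise; planted
cooperative lncRNA pairs share a GO-coherent target module that forms a
clique in the protein-interaction network; immune-cell infiltration
fractions are rank-transformed noisy functions of designated lncRNAs; and
survival times are exponential with a per-sample log-hazard linear in
designated (standardised) lncRNA expressions, under independent uniform
censoring.

Every draw is governed by ``SimulationConfig.seed``; the three generation
entry points use disjoint, order-independent substreams so that e.g.
annotation can be regenerated without replaying the omics draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from lncoop.errors import ConfigurationError
from lncoop.io import GeneSetCollection, OmicsBundle, write_gmt, write_matrix, write_ppi

__all__ = [
    "PPIModel",
    "SimulationConfig",
    "PlantedPair",
    "GroundTruth",
    "generate_omics_bundle",
    "generate_annotation",
    "generate_clinical",
    "write_study",
]

CELL_TYPES = ("B_cell", "CD4_Tcell", "CD8_Tcell", "macrophage", "neutrophil", "dendritic")

# substream tags keeping the three generators' draws independent
_STREAM_STRUCTURE, _STREAM_OMICS, _STREAM_ANNOT, _STREAM_CLINICAL = 0, 1, 2, 3


@dataclass(frozen=True)
class PPIModel:
    """Background interaction-graph parameters (Erdős–Rényi null)."""

    n_nodes: int | None = None  # default: the mRNA universe
    mean_degree: float = 4.0


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study.

    Effects are the linear-model coefficients shared by every planted
    regulation; ``infiltration_link`` and ``hazard_link`` designate
    lncRNAs tied to immune-cell fractions (target Spearman rho) and to
    survival (log-hazard per standard deviation of expression).
    """

    n_samples: int = 300
    n_lncrna: int = 30
    n_mrna: int = 300
    n_planted_pairs: int = 5
    module_size: int = 4
    n_private_targets: int = 3
    effect_lncrna: float = 2.0
    effect_cnv: float = 1.0
    effect_meth: float = -1.0
    noise_sd: float = 1.0
    ppi_model: PPIModel = field(default_factory=PPIModel)
    n_go_terms: int = 20
    go_term_size: int = 10
    immune_frac: float = 0.5
    infiltration_link: list = field(default_factory=list)
    hazard_link: list = field(default_factory=list)
    n_subtypes: int = 2
    subtype_sep: float = 3.0
    n_subtype_features: int = 6
    baseline_hazard: float = 0.1
    censor_window: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_lncrna", "n_mrna", "n_go_terms",
                     "go_term_size", "n_subtypes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_planted_pairs < 0 or self.n_private_targets < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.n_planted_pairs and self.module_size < 3:
            raise ConfigurationError("module_size must be >= 3")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        n_reserved = min(self.n_subtype_features, self.n_lncrna)
        if 2 * self.n_planted_pairs > self.n_lncrna - n_reserved:
            raise ConfigurationError(
                f"{self.n_planted_pairs} planted pairs need "
                f"{2 * self.n_planted_pairs} distinct lncRNAs beyond the "
                f"{n_reserved} subtype-feature lncRNAs; have {self.n_lncrna}"
            )
        n_target_mrna = self.n_planted_pairs * (
            self.module_size + 2 * self.n_private_targets)
        if self.module_size > self.n_mrna or n_target_mrna > self.n_mrna:
            raise ConfigurationError("planted targets exceed the mRNA universe")
        if self.n_planted_pairs and self.go_term_size < self.module_size:
            raise ConfigurationError("go_term_size must be >= module_size")
        if not 0 <= self.immune_frac <= 1:
            raise ConfigurationError("immune_frac must be in [0, 1]")

    @property
    def lncrna_ids(self) -> list[str]:
        return [f"lnc{i:04d}" for i in range(1, self.n_lncrna + 1)]

    @property
    def mrna_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_mrna + 1)]

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(1, self.n_samples + 1)]


@dataclass(frozen=True)
class PlantedPair:
    """One true cooperative lncRNA pair and its planted functional module."""

    lncrna_a: str
    lncrna_b: str
    module_genes: frozenset
    go_term: str
    immune: bool

    @property
    def key(self) -> frozenset:
        return frozenset((self.lncrna_a, self.lncrna_b))


@dataclass
class GroundTruth:
    """What was planted: regulations, cooperative pairs, latent subtypes."""

    true_targets: dict  # (lncrna, mrna) -> coefficient
    true_pairs: list  # of PlantedPair
    true_subtype: pd.Series  # sample -> 1..n_subtypes

    @property
    def pair_keys(self) -> set:
        return {p.key for p in self.true_pairs}

    def targets_of(self, lncrna: str) -> set:
        return {m for (l, m) in self.true_targets if l == lncrna}

    def to_json(self) -> str:
        return json.dumps({
            "true_targets": [[l, m, c] for (l, m), c in sorted(self.true_targets.items())],
            "true_pairs": [
                {"lncrna_a": p.lncrna_a, "lncrna_b": p.lncrna_b,
                 "module_genes": sorted(p.module_genes),
                 "go_term": p.go_term, "immune": p.immune}
                for p in self.true_pairs
            ],
            "true_subtype": {s: int(v) for s, v in self.true_subtype.items()},
        }, indent=1)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _planted_structure(config: SimulationConfig):
    """Deterministic planted layout shared by all three generators.

    Returns (pairs, target_map) where target_map maps each target mRNA to
    the list of lncRNAs regulating it. Planted lncRNAs, module genes and
    private targets are all disjoint draws from their universes.
    """
    rng = _rng(config, _STREAM_STRUCTURE)
    lnc_ids = config.lncrna_ids
    mrna_ids = config.mrna_ids
    n_pairs = config.n_planted_pairs
    # the first n_subtype_features lncRNAs carry the latent subtype shift and
    # are reserved: regulatory ground truth stays orthogonal to subtype structure
    n_reserved = min(config.n_subtype_features, config.n_lncrna)
    pool = np.arange(n_reserved, config.n_lncrna)
    chosen_lnc = pool[rng.choice(pool.size, size=2 * n_pairs, replace=False)]
    per_pair_mrna = config.module_size + 2 * config.n_private_targets
    chosen_mrna = rng.choice(config.n_mrna, size=n_pairs * per_pair_mrna, replace=False)
    immune_flags = np.zeros(n_pairs, dtype=bool)
    n_immune = int(round(config.immune_frac * n_pairs))
    if n_immune:
        immune_flags[rng.choice(n_pairs, size=n_immune, replace=False)] = True

    pairs: list[PlantedPair] = []
    target_map: dict[str, list[str]] = {}
    for k in range(n_pairs):
        a = lnc_ids[chosen_lnc[2 * k]]
        b = lnc_ids[chosen_lnc[2 * k + 1]]
        block = chosen_mrna[k * per_pair_mrna:(k + 1) * per_pair_mrna]
        module = [mrna_ids[i] for i in block[: config.module_size]]
        priv_a = [mrna_ids[i] for i in
                  block[config.module_size: config.module_size + config.n_private_targets]]
        priv_b = [mrna_ids[i] for i in block[config.module_size + config.n_private_targets:]]
        immune = bool(immune_flags[k])
        term = f"GO_PLANTED_{'IMMUNE_T_CELL_' if immune else ''}{k + 1:03d}"
        pairs.append(PlantedPair(a, b, frozenset(module), term, immune))
        for g in module:
            target_map.setdefault(g, []).extend([a, b])
        for g in priv_a:
            target_map.setdefault(g, []).append(a)
        for g in priv_b:
            target_map.setdefault(g, []).append(b)
    return pairs, target_map


def generate_omics_bundle(config: SimulationConfig) -> tuple[OmicsBundle, GroundTruth]:
    """Draw the aligned four-layer bundle and its ground truth.

    Planted targets follow
    ``y = b0 + effect_cnv*cnv + effect_meth*meth + effect_lncrna*sum(lnc) + noise``;
    non-targets carry the copy-number and methylation terms but are
    independent of every lncRNA. CNV and methylation are drawn
    independently of lncRNA expression.
    """
    config.validate()
    pairs, target_map = _planted_structure(config)
    rng = _rng(config, _STREAM_OMICS)
    n, samples = config.n_samples, config.sample_ids

    subtype = rng.integers(1, config.n_subtypes + 1, size=n)
    lnc = rng.normal(3.0, 1.0, size=(config.n_lncrna, n))
    # latent subtypes shift designated lncRNAs (unit sd => sep is in sd units);
    # the sign alternates across features so subtypes differ in profile shape,
    # not only in overall level (correlation distances ignore constant offsets)
    n_sub_feat = min(config.n_subtype_features, config.n_lncrna)
    centered = (subtype - (config.n_subtypes + 1) / 2.0) / max(config.n_subtypes - 1, 1)
    for i in range(n_sub_feat):
        sign = 1.0 if i % 2 == 0 else -1.0
        lnc[i] += sign * config.subtype_sep * centered
    lnc_df = pd.DataFrame(lnc, index=config.lncrna_ids, columns=samples)

    cnv = rng.normal(2.0, 0.5, size=(config.n_mrna, n))
    meth = expit(rng.normal(0.0, 1.0, size=(config.n_mrna, n)))
    cnv_df = pd.DataFrame(cnv, index=config.mrna_ids, columns=samples)
    meth_df = pd.DataFrame(meth, index=config.mrna_ids, columns=samples)

    b0 = 5.0
    mrna = (b0 + config.effect_cnv * cnv + config.effect_meth * meth
            + rng.normal(0.0, config.noise_sd, size=(config.n_mrna, n)))
    mrna_df = pd.DataFrame(mrna, index=config.mrna_ids, columns=samples)
    true_targets: dict = {}
    for g, regulators in target_map.items():
        for l in regulators:
            mrna_df.loc[g] += config.effect_lncrna * lnc_df.loc[l]
            true_targets[(l, g)] = config.effect_lncrna

    bundle = OmicsBundle(lncrna_expr=lnc_df, mrna_expr=mrna_df,
                         cnv=cnv_df, meth=meth_df, cancer_label="SYN")
    bundle.validate()
    truth = GroundTruth(
        true_targets=true_targets,
        true_pairs=pairs,
        true_subtype=pd.Series(subtype, index=samples, name="subtype"),
    )
    return bundle, truth


def generate_annotation(config: SimulationConfig) -> tuple[GeneSetCollection, nx.Graph]:
    """Draw GO-style gene sets and a PPI graph honouring the planted layout.

    Each planted module gets its own GO term (module genes padded with
    random genes to ``go_term_size``) and forms a clique in the PPI graph,
    guaranteeing the within-module distance criterion; the background
    graph is Erdős–Rényi at the configured mean degree and background
    terms are uniform draws without replacement from the mRNA universe.
    """
    config.validate()
    pairs, _ = _planted_structure(config)
    rng = _rng(config, _STREAM_ANNOT)
    mrna_ids = config.mrna_ids

    terms: dict[str, tuple[str, frozenset]] = {}
    immune_flags: dict[str, bool] = {}
    for p in pairs:
        pad_pool = [g for g in mrna_ids if g not in p.module_genes]
        n_pad = config.go_term_size - len(p.module_genes)
        pad = rng.choice(len(pad_pool), size=n_pad, replace=False) if n_pad else []
        genes = frozenset(p.module_genes) | {pad_pool[i] for i in pad}
        desc = "planted immune module" if p.immune else "planted module"
        terms[p.go_term] = (desc, frozenset(genes))
        immune_flags[p.go_term] = p.immune
    for k in range(config.n_go_terms):
        tid = f"GO_BG_{k + 1:04d}"
        idx = rng.choice(config.n_mrna, size=config.go_term_size, replace=False)
        terms[tid] = ("background term", frozenset(mrna_ids[i] for i in idx))
        immune_flags[tid] = False
    genesets = GeneSetCollection(terms=terms, immune_flags=immune_flags)

    n_nodes = config.ppi_model.n_nodes or config.n_mrna
    p_edge = min(config.ppi_model.mean_degree / max(n_nodes - 1, 1), 1.0)
    seed_int = int(rng.integers(0, 2**31 - 1))
    ppi = nx.fast_gnp_random_graph(n_nodes, p_edge, seed=seed_int)
    ppi = nx.relabel_nodes(ppi, {i: mrna_ids[i] if i < config.n_mrna else f"x{i:04d}"
                                 for i in ppi.nodes()})
    for p in pairs:  # planted clique gadget: pairwise distance 1
        genes = sorted(p.module_genes)
        for i, gi in enumerate(genes):
            for gj in genes[i + 1:]:
                ppi.add_edge(gi, gj)
    return genesets, ppi


def _rank_fraction(values: np.ndarray) -> np.ndarray:
    """Map values to (0,1) by rank; ties broken by input order."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks / (len(values) + 1)


def generate_clinical(
    config: SimulationConfig, bundle: OmicsBundle, truth: GroundTruth | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw TIMER-style infiltration fractions and a clinical table.

    Infiltration per cell type is the rank transform of a noisy linear
    function of the linked lncRNA, with the Pearson mixing weight set to
    ``2*sin(pi*rho/6)`` so the requested strength is a Spearman target;
    unlinked cell types are pure-noise ranks. Survival is exponential with
    log-hazard linear in the standardised expression of ``hazard_link``
    lncRNAs, censored by an independent uniform time.

    Returns (infiltration, clinical): samples x cell types, and a table
    with os_time/os_event/age/stage/breslow_depth/mitotic_rate columns.
    """
    config.validate()
    rng = _rng(config, _STREAM_CLINICAL)
    samples = bundle.samples
    n = len(samples)

    links: dict[str, tuple[str, float]] = {}
    for lnc_id, cell_type, strength in config.infiltration_link:
        if lnc_id not in bundle.lncrna_expr.index:
            raise ConfigurationError(f"infiltration_link: unknown lncRNA {lnc_id!r}")
        if cell_type not in CELL_TYPES:
            raise ConfigurationError(f"infiltration_link: unknown cell type {cell_type!r}")
        links[cell_type] = (lnc_id, float(strength))

    infil = {}
    for ct in CELL_TYPES:
        if ct in links:
            lnc_id, rho = links[ct]
            x = bundle.lncrna_expr.loc[lnc_id].to_numpy(dtype=float)
            z = (x - x.mean()) / (x.std() or 1.0)
            r = float(np.clip(2.0 * np.sin(np.pi * rho / 6.0), -1.0, 1.0))
            latent = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * rng.normal(size=n)
        else:
            latent = rng.normal(size=n)
        infil[ct] = _rank_fraction(latent)
    infiltration = pd.DataFrame(infil, index=pd.Index(samples, name="sample_id"))

    log_hazard = np.full(n, np.log(config.baseline_hazard))
    for lnc_id, beta in config.hazard_link:
        if lnc_id not in bundle.lncrna_expr.index:
            raise ConfigurationError(f"hazard_link: unknown lncRNA {lnc_id!r}")
        x = bundle.lncrna_expr.loc[lnc_id].to_numpy(dtype=float)
        log_hazard += float(beta) * (x - x.mean()) / (x.std() or 1.0)
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    censor_time = rng.uniform(0.0, config.censor_window, size=n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    subtype = (truth.true_subtype.reindex(samples).to_numpy()
               if truth is not None else np.ones(n, dtype=int))
    clinical = pd.DataFrame({
        "os_time": os_time,
        "os_event": os_event,
        "age": np.round(rng.normal(60.0, 10.0, size=n)),
        "stage": rng.choice(["I", "II", "III", "IV"], size=n,
                            p=[0.3, 0.3, 0.25, 0.15]),
        "breslow_depth": np.exp(rng.normal(0.5 + 0.4 * (subtype - 1), 0.6, size=n)),
        "mitotic_rate": rng.poisson(2.0 + 2.0 * (subtype - 1), size=n),
    }, index=pd.Index(samples, name="sample_id"))
    return infiltration, clinical


def write_study(
    outdir,
    bundle: OmicsBundle,
    truth: GroundTruth,
    genesets: GeneSetCollection,
    ppi: nx.Graph,
    infiltration: pd.DataFrame,
    clinical: pd.DataFrame,
    config: SimulationConfig | None = None,
) -> None:
    """Serialise a full synthetic study to one directory of text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.lncrna_expr, out / "lncrna_expr.tsv")
    write_matrix(bundle.mrna_expr, out / "mrna_expr.tsv")
    write_matrix(bundle.cnv, out / "cnv.tsv")
    write_matrix(bundle.meth, out / "meth.tsv")
    write_gmt(genesets, out / "go_bp.gmt")
    with open(out / "immune_terms.txt", "w") as fh:
        for t in sorted(genesets.immune_terms):
            fh.write(t + "\n")
    write_ppi(ppi, out / "ppi.tsv")
    infiltration.to_csv(out / "infiltration.tsv", sep="\t")
    clinical.to_csv(out / "clinical.tsv", sep="\t")
    (out / "ground_truth.json").write_text(truth.to_json())
    if config is not None:
        cfg = asdict(config)
        (out / "config.json").write_text(json.dumps(cfg, indent=1, default=list))
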