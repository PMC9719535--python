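"""Readers, writers and the aligned multi-omics container.

All tabular formats are plain TSV: matrices are features x samples with a
header row of sample IDs, gene sets are GMT, protein interactions a
two-column edge list. Expression is expected on log2 scale throughout; an
optional ingest transform handles raw inputs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from lncoop.errors import AlignmentError, ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsBundle",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "align_bundle",
    "read_gmt",
    "write_gmt",
    "read_ppi",
    "write_ppi",
    "write_network",
]


@dataclass
class OmicsBundle:
    """Sample-aligned multi-omics matrices for one cancer type.

    All matrices are features x samples with identical sample columns in
    identical order. ``cnv`` and ``meth`` are indexed by mRNA gene IDs
    (gene-level copy number and promoter methylation beta values);
    expression matrices are log2 scale.
    """

    lncrna_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    cnv: pd.DataFrame
    meth: pd.DataFrame
    cancer_label: str = ""

    @property
    def samples(self) -> list[str]:
        return list(self.lncrna_expr.columns)

    @property
    def n_samples(self) -> int:
        return self.lncrna_expr.shape[1]

    def validate(self) -> None:
        cols = list(self.lncrna_expr.columns)
        for name in ("mrna_expr", "cnv", "meth"):
            other = list(getattr(self, name).columns)
            if other != cols:
                raise ValidationError(
                    f"{name} samples differ from lncrna_expr samples"
                )
        for name in ("lncrna_expr", "mrna_expr", "cnv", "meth"):
            idx = getattr(self, name).index
            if idx.duplicated().any():
                dup = idx[idx.duplicated()][0]
                raise ValidationError(f"duplicated feature ID {dup!r} in {name}")
        vals = self.meth.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("methylation beta values outside [0, 1]")


@dataclass
class GeneSetCollection:
    """GO BP-style gene sets with per-term immune flags.

    ``terms`` maps term ID to (description, gene set); ``immune_flags`` is
    defined for every term; ``category_map`` optionally assigns an immune
    category name to flagged terms.
    """

    terms: dict[str, tuple[str, frozenset]]
    immune_flags: dict[str, bool] = field(default_factory=dict)
    category_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"gene set {tid!r} is empty")
        for tid in self.terms:
            self.immune_flags.setdefault(tid, False)

    def genes(self, term: str) -> frozenset:
        return self.terms[term][1]

    @property
    def immune_terms(self) -> set:
        return {t for t, f in self.immune_flags.items() if f}

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def read_matrix(
    path,
    expected_range: tuple[float, float] | None = None,
    max_missing_frac: float = 0.2,
    log2_transform: bool = False,
) -> pd.DataFrame:
    """Read a features x samples TSV matrix with validation.

    Rejects duplicated feature or sample IDs, reports non-numeric cells
    with their coordinates, drops features with more than
    ``max_missing_frac`` missing cells, and optionally applies log2(x+1)
    for raw (not yet log-transformed) expression inputs.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set = set()
    for name in header:  # pandas silently mangles duplicates, so check raw
        if name in seen:
            raise ValidationError(f"{path}: duplicated sample column {name!r}")
        seen.add(name)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicated feature ID {dup!r}")
    mat = raw.apply(pd.to_numeric, errors="coerce")
    # distinguish true NA strings from unparseable cells
    na_mask = raw.isna() | raw.isin(["NA", "NaN", "nan", ""])
    bad = mat.isna() & ~na_mask
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at feature "
            f"{mat.index[r]!r}, sample {mat.columns[c]!r}"
        )
    missing_frac = mat.isna().mean(axis=1)
    drop = missing_frac > max_missing_frac
    if drop.any():
        logger.info("%s: dropping %d features with >%d%% missing",
                    path, int(drop.sum()), int(100 * max_missing_frac))
        mat = mat.loc[~drop]
    if log2_transform:
        mat = np.log2(mat + 1.0)
    if expected_range is not None:
        lo, hi = expected_range
        vals = mat.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < lo or finite.max() > hi):
            offender = finite[(finite < lo) | (finite > hi)][0]
            raise ValidationError(
                f"{path}: value {offender} outside expected range [{lo}, {hi}]"
            )
    return mat


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="feature_id")


def align_bundle(
    lncrna: pd.DataFrame,
    mrna: pd.DataFrame,
    cnv: pd.DataFrame,
    meth: pd.DataFrame,
    cancer_label: str = "",
) -> OmicsBundle:
    """Restrict all matrices to their shared samples, in a common order.

    The shared order follows the lncRNA matrix. The number of dropped
    samples is logged; an empty intersection is an error.
    """
    shared = [s for s in lncrna.columns
              if s in mrna.columns and s in cnv.columns and s in meth.columns]
    if not shared:
        raise AlignmentError("no sample shared by all four matrices")
    n_dropped = (len(set(lncrna.columns) | set(mrna.columns)
                     | set(cnv.columns) | set(meth.columns)) - len(shared))
    if n_dropped:
        logger.info("align_bundle: dropped %d unmatched samples", n_dropped)
    bundle = OmicsBundle(
        lncrna_expr=lncrna[shared],
        mrna_expr=mrna[shared],
        cnv=cnv[shared],
        meth=meth[shared],
        cancer_label=cancer_label,
    )
    bundle.validate()
    return bundle


def read_gmt(path, immune_flags: dict[str, bool] | None = None) -> GeneSetCollection:
    """Read a GMT file: per line, term ID, description, then gene IDs."""
    terms: dict[str, tuple[str, frozenset]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{i}: GMT line has {len(fields)} fields, need >= 3")
            tid, desc, genes = fields[0], fields[1], fields[2:]
            if tid in terms:
                raise ValidationError(f"{path}:{i}: duplicated term {tid!r}")
            terms[tid] = (desc, frozenset(g for g in genes if g))
    return GeneSetCollection(terms=terms, immune_flags=dict(immune_flags or {}))


def write_gmt(genesets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, genes) in genesets.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


def read_ppi(path) -> nx.Graph:
    """Read a two-column TSV edge list into a simple undirected graph.

    Reversed duplicates collapse to one edge; self-loops are dropped with
    a warning; an empty graph is an error.
    """
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{i}: edge line needs 2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                n_self += 1
                continue
            g.add_edge(a, b)
    if n_self:
        warnings.warn(f"{path}: dropped {n_self} self-loop(s)", stacklevel=2)
    if g.number_of_nodes() == 0:
        raise ValidationError(f"{path}: empty interaction network")
    return g


def write_ppi(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


def write_network(g: nx.Graph, path, fmt: str = "tsv") -> None:
    """Export a cooperation network as edge-list TSV or GraphML.

    The TSV carries edge attributes ``cancers`` (comma-joined) and
    ``immune`` when present on the graph.
    """
    if fmt == "graphml":
        h = nx.Graph()
        h.add_nodes_from(g.nodes())
        for a, b, d in g.edges(data=True):
            attrs = {}
            for k, v in d.items():
                attrs[k] = ",".join(sorted(v)) if isinstance(v, (set, frozenset)) else v
            h.add_edge(a, b, **attrs)
        nx.write_graphml(h, path)
        return
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("node1\tnode2\tcancers\timmune\n")
        for a, b, d in g.edges(data=True):
            cancers = ",".join(sorted(d.get("cancers", ())))
            immune = int(bool(d.get("immune", False)))
            fh.write(f"{a}\t{b}\t{cancers}\t{immune}\n")
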