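"""Readers and writers for the plain-text formats the pipeline exchanges.

All tables are tab-delimited UTF-8 with LF line endings.  Gene symbols are
upper-cased on input by default (``uppercase=False`` disables this), since
interaction databases, pathway libraries and GWAS annotation files rarely
agree on capitalisation.  Numbers round-trip at 12 significant digits.
"""

from __future__ import annotations

import logging
import os
import re
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_ppi",
    "read_gmt",
    "read_gene_scores",
    "write_gene_scores",
    "read_snp_assoc",
    "write_snp_assoc",
    "read_snp_gene_map",
    "write_genotypes",
    "read_genotypes",
    "read_alias_table",
    "apply_aliases",
    "write_sif",
    "write_modules",
    "write_enrichment",
    "write_background",
    "read_background",
]

_FLOAT_FMT = "%.12g"

# header tokens recognised when auto-detecting a header row in edge lists
_EDGE_HEADER_RE = re.compile(
    r"^(gene|node|protein|interactor|symbol|source|target)[_a-z0-9]*$", re.I
)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _symbol(tok: str, uppercase: bool) -> str:
    tok = tok.strip()
    return tok.upper() if uppercase else tok


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def read_ppi(path: str | os.PathLike, fmt: str = "tab", uppercase: bool = True) -> nx.Graph:
    """Load an undirected protein–protein interaction network.

    Parameters
    ----------
    path:
        Edge-list file.  ``fmt="tab"`` expects two tab-separated gene symbols
        per row (an optional header row is auto-detected); ``fmt="sif"``
        expects Cytoscape SIF rows ``source <type> target [target ...]``.
    uppercase:
        Upper-case all gene symbols (default).

    Returns a simple :class:`networkx.Graph`: self-loops are dropped with a
    warning, and duplicate or reciprocal rows collapse to one undirected edge.
    """
    if fmt not in ("tab", "sif"):
        raise ValueError(f"unknown PPI format {fmt!r}; expected 'tab' or 'sif'")
    graph = nx.Graph()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t") if fmt == "tab" else line.split()
            if fmt == "tab":
                if lineno == 1 and len(fields) >= 2 and all(
                    _EDGE_HEADER_RE.match(f.strip()) for f in fields[:2]
                ):
                    continue  # header row
                if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                    raise FormatError(f"{path}: line {lineno}: expected two gene symbols")
                pairs = [(fields[0], fields[1])]
            else:  # sif
                if len(fields) == 1:
                    graph.add_node(_symbol(fields[0], uppercase))
                    continue
                if len(fields) == 2:
                    raise FormatError(
                        f"{path}: line {lineno}: SIF row needs source, type and >=1 target"
                    )
                pairs = [(fields[0], t) for t in fields[2:]]
            for a, b in pairs:
                a, b = _symbol(a, uppercase), _symbol(b, uppercase)
                if a == b:
                    log.warning("%s: line %d: self-loop %s-%s dropped", path, lineno, a, b)
                    continue
                graph.add_edge(a, b)
                n_rows += 1
    if graph.number_of_edges() == 0:
        raise FormatError(f"{path}: no valid interaction rows found")
    log.info(
        "read_ppi: %s -> %d nodes, %d edges (%d edge rows)",
        path, graph.number_of_nodes(), graph.number_of_edges(), n_rows,
    )
    return graph


def write_sif(edges: Iterable[tuple[str, str]], path: str | os.PathLike,
              interaction: str = "pp") -> None:
    """Write undirected edges as Cytoscape SIF (one interaction per row)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{interaction}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT pathway library
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike, uppercase: bool = True) -> dict[str, set[str]]:
    """Load a GMT gene-set library as ``{pathway name: gene set}``.

    Each line is ``name <tab> description <tab> gene [<tab> gene ...]``.
    Pathway names must be unique; lines with fewer than three fields are
    rejected with their line number.
    """
    library: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT rows need name, description and >=1 gene"
                )
            name = fields[0].strip()
            if name in library:
                raise FormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
            genes = {_symbol(g, uppercase) for g in fields[2:] if g.strip()}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            library[name] = genes
    log.info("read_gmt: %s -> %d pathways", path, len(library))
    return library


# ---------------------------------------------------------------------------
# gene-level score tables
# ---------------------------------------------------------------------------

def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_gene_scores(path: str | os.PathLike, uppercase: bool = True) -> pd.DataFrame:
    """Read a gene score table into a DataFrame (index gene, column ``p``).

    The minimal format is two tab-separated columns ``gene <tab> p``.  A
    header row is auto-detected (non-numeric second field); when present and
    it names a ``p`` column, the p-values are taken from that column, so the
    richer audit tables written by the gene test load back directly.
    Duplicate genes and p-values outside [0, 1] are errors.
    """
    genes: list[str] = []
    ps: list[float] = []
    p_col = 1
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected gene and p-value")
            if lineno == 1 and not _is_number(fields[1]):
                header = [f.strip().lower() for f in fields]
                if "p" in header:
                    p_col = header.index("p")
                continue  # header
            gene = _symbol(fields[0], uppercase)
            p = float(fields[p_col])
            if not (0.0 <= p <= 1.0):
                raise FormatError(f"{path}: line {lineno}: gene {gene}: p={p} outside [0, 1]")
            genes.append(gene)
            ps.append(p)
    df = pd.DataFrame({"p": ps}, index=pd.Index(genes, name="gene"))
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate gene rows: {sorted(set(dup))}")
    if df.empty:
        raise FormatError(f"{path}: no score rows found")
    return df


def write_gene_scores(scores: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a gene score table (index = gene; any numeric/bool columns kept)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        cols = list(scores.columns)
        fh.write("gene\t" + "\t".join(cols) + "\n")
        for gene, row in scores.iterrows():
            vals = []
            for c in cols:
                v = row[c]
                if isinstance(v, (bool,)) or str(scores[c].dtype) == "bool":
                    vals.append(str(bool(v)))
                elif isinstance(v, float):
                    vals.append(_fmt(v))
                else:
                    vals.append(str(v))
            fh.write(f"{gene}\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# SNP-level tables
# ---------------------------------------------------------------------------

def read_snp_assoc(path: str | os.PathLike) -> pd.DataFrame:
    """Read SNP association results: columns snp, chrom, pos, p."""
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str})
    required = {"snp", "chrom", "pos", "p"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] < 0) | (df["p"] > 1), "snp"].iloc[0]
        raise FormatError(f"{path}: SNP {bad}: p-value outside [0, 1]")
    if (df["pos"] < 0).any():
        raise FormatError(f"{path}: negative base-pair positions")
    return df


def write_snp_assoc(df: pd.DataFrame, path: str | os.PathLike) -> None:
    out = df.copy()
    out["p"] = out["p"].map(_fmt)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_snp_gene_map(path: str | os.PathLike, uppercase: bool = True) -> pd.DataFrame:
    """Read a many-to-many SNP -> gene annotation table (columns snp, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns snp and gene")
    if uppercase:
        df["gene"] = df["gene"].str.upper()
    return df


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def write_genotypes(G, path: str | os.PathLike) -> None:
    """Write a dosage matrix as a tab table: rows = individuals, columns = SNPs.

    Missing dosages become empty cells.  SNP metadata goes to a sibling file
    ``<path>.snps.tsv`` (columns snp, chrom, pos, block).
    """
    df = pd.DataFrame(G.dosages, columns=list(G.snps["snp"]))
    df.index.name = "individual"
    df.to_csv(path, sep="\t", float_format="%g", lineterminator="\n")
    G.snps.to_csv(f"{os.fspath(path)}.snps.tsv", sep="\t", index=False,
                  lineterminator="\n")


def read_genotypes(path: str | os.PathLike):
    """Load a dosage table written by :func:`write_genotypes`."""
    from .gwas_sim import GenotypeMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = f"{os.fspath(path)}.snps.tsv"
    if os.path.exists(meta_path):
        snps = pd.read_csv(meta_path, sep="\t", dtype={"snp": str, "chrom": str})
    else:
        snps = pd.DataFrame({"snp": list(df.columns), "chrom": "NA",
                             "pos": range(len(df.columns)), "block": 0})
    return GenotypeMatrix(dosages=df.to_numpy(dtype=float), snps=snps)


# ---------------------------------------------------------------------------
# identifier aliasing
# ---------------------------------------------------------------------------

def read_alias_table(path: str | os.PathLike, uppercase: bool = True) -> dict[str, str]:
    """Read a two-column ``alias <tab> canonical`` symbol translation table."""
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {lineno}: expected alias and canonical symbol")
            mapping[_symbol(fields[0], uppercase)] = _symbol(fields[1], uppercase)
    return mapping


def apply_aliases(graph: nx.Graph, aliases: Mapping[str, str]) -> nx.Graph:
    """Relabel network nodes through an alias table; untranslated nodes kept."""
    relabel = {n: aliases.get(n, n) for n in graph.nodes}
    out = nx.relabel_nodes(graph, relabel, copy=True)
    out.remove_edges_from(nx.selfloop_edges(out))
    return out


# ---------------------------------------------------------------------------
# module / enrichment output
# ---------------------------------------------------------------------------

def write_modules(modules, outdir: str | os.PathLike, graph: nx.Graph,
                  scores: pd.DataFrame | None = None, prefix: str = "module") -> None:
    """Export modules as a summary table, node/edge attribute tables and SIF.

    ``modules`` is an iterable of objects with ``genes``, ``Z`` and ``S``
    attributes (and optionally ``start``).  The SIF files carry the induced
    PPI edges of each module so they load directly into network viewers.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    modules = list(modules)
    with open(os.path.join(outdir, f"{prefix}_summary.tsv"), "w", encoding="utf-8",
              newline="\n") as fh:
        fh.write("rank\tsize\tstart_node\tZ\tS\tgenes\n")
        for rank, m in enumerate(modules, start=1):
            start = getattr(m, "start", "") or ""
            fh.write(
                f"{rank}\t{len(m.genes)}\t{start}\t{_fmt(m.Z)}\t{_fmt(m.S)}\t"
                + ";".join(sorted(m.genes)) + "\n"
            )
    with open(os.path.join(outdir, f"{prefix}_nodes.tsv"), "w", encoding="utf-8",
              newline="\n") as fh:
        fh.write("rank\tgene\tp\tz\tnode_weight\n")
        for rank, m in enumerate(modules, start=1):
            for gene in sorted(m.genes):
                if scores is not None and gene in scores.index:
                    row = scores.loc[gene]
                    fh.write(
                        f"{rank}\t{gene}\t{_fmt(row['p'])}\t{_fmt(row['z'])}\t"
                        f"{_fmt(row['node_weight'])}\n"
                    )
                else:
                    fh.write(f"{rank}\t{gene}\t\t\t\n")
    with open(os.path.join(outdir, f"{prefix}_edges.tsv"), "w", encoding="utf-8",
              newline="\n") as fh:
        fh.write("rank\tgene_a\tgene_b\n")
        for rank, m in enumerate(modules, start=1):
            sub = graph.subgraph(m.genes)
            for a, b in sorted(tuple(sorted(e)) for e in sub.edges):
                fh.write(f"{rank}\t{a}\t{b}\n")
    for rank, m in enumerate(modules, start=1):
        sub = graph.subgraph(m.genes)
        write_sif(sorted(tuple(sorted(e)) for e in sub.edges),
                  os.path.join(outdir, f"{prefix}_{rank}.sif"))


def write_enrichment(rows: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an enrichment result table (pathway, overlap, p, p_adj, z, combined, genes)."""
    out = rows.copy()
    for col in ("p", "p_adj", "z", "combined"):
        if col in out.columns:
            out[col] = out[col].map(_fmt)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# background calibration table
# ---------------------------------------------------------------------------

def write_background(bg, path: str | os.PathLike) -> None:
    """Serialize a background table as three columns: k, mu, sigma."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("k\tmu\tsigma\n")
        for k in range(1, bg.k_max + 1):
            fh.write(f"{k}\t{_fmt(bg.mu[k - 1])}\t{_fmt(bg.sigma[k - 1])}\n")


def read_background(path: str | os.PathLike):
    """Load a background table written by :func:`write_background`."""
    from .score import BackgroundTable  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    if not {"k", "mu", "sigma"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns k, mu, sigma")
    df = df.sort_values("k")
    if list(df["k"]) != list(range(1, len(df) + 1)):
        raise FormatError(f"{path}: k values must be contiguous from 1")
    return BackgroundTable(mu=df["mu"].to_numpy(), sigma=df["sigma"].to_numpy(),
                           n_draws=0)
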