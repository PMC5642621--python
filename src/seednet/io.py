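"""Readers and writers for the external formats the pipeline touches.

Formats: STRING-style protein links (whitespace-separated, header
``protein1 protein2 combined_score``), expression TSV (genes x samples,
``NA`` for missing), seed-gene lists (one symbol per line), clinical TSV,
and network exports (edge TSV, SIF, GraphML).  Also loads the packaged
reference tables: the 52 published seed genes and the 82 linker genes
with their printed ranking scores.
"""

from __future__ import annotations

import csv
import logging
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd

from .types import SeednetError, SeedSet, Subnetwork, validate_graph

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

#: The six published candidate genes (ranking score strictly above 1).
CANDIDATE_GENES = ("KRT19", "BARD1", "MST1R", "S100A14", "LGALS1", "RNF168")


def _read_id_map(id_map) -> dict[str, str] | None:
    """Accept a mapping, a two-column TSV path, or None (identity)."""
    if id_map is None:
        return None
    if isinstance(id_map, dict):
        return dict(id_map)
    mapping: dict[str, str] = {}
    with open(id_map, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                parts = line.split()
            if len(parts) != 2:
                raise SeednetError(f"id-map line is not two columns: {line!r}")
            mapping[parts[0]] = parts[1]
    return mapping


def read_string_links(path, score_min: int = 0, id_map=None) -> nx.Graph:
    """Read a STRING-dialect links file into an undirected weighted graph.

    Parameters
    ----------
    path
        Whitespace-separated file with one header line and columns
        ``protein1 protein2 combined_score`` (score is an integer in
        0-1000).
    score_min
        Keep only edges with ``combined_score >= score_min``.
    id_map
        Optional protein-to-gene mapping (dict or two-column TSV path);
        identifiers absent from the map are skipped and counted.  The
        default is the identity mapping.

    Returns
    -------
    networkx.Graph
        Edge weights are ``combined_score / 1000``; reciprocal duplicate
        rows are collapsed to one undirected edge (keeping the larger
        score if they disagree); self-loops are dropped; only nodes with
        at least one retained edge appear.
    """
    mapping = _read_id_map(id_map)
    graph = nx.Graph()
    n_unmapped = 0
    n_selfloop = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        required = ["protein1", "protein2", "combined_score"]
        if header[:3] != required:
            raise SeednetError(
                f"line 1: expected header {' '.join(required)!r}, got {' '.join(header)!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise SeednetError(f"line {lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_score = parts[0], parts[1], parts[2]
            try:
                score = int(raw_score)
            except ValueError as exc:
                raise SeednetError(f"line {lineno}: non-integer score {raw_score!r}") from exc
            if not 0 <= score <= 1000:
                raise SeednetError(f"line {lineno}: score {score} outside 0-1000")
            if score < score_min or score == 0:
                continue
            if mapping is not None:
                if a not in mapping or b not in mapping:
                    n_unmapped += 1
                    continue
                a, b = mapping[a], mapping[b]
            if a == b:
                n_selfloop += 1
                continue
            w = score / 1000.0
            if graph.has_edge(a, b):
                graph[a][b]["weight"] = max(graph[a][b]["weight"], w)
            else:
                graph.add_edge(a, b, weight=w)
    if n_unmapped:
        logger.warning("skipped %d link rows with unmapped identifiers", n_unmapped)
    if n_selfloop:
        logger.warning("dropped %d self-interaction rows", n_selfloop)
    return validate_graph(graph)


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes-x-samples expression TSV.

    First column holds gene identifiers, remaining columns one sample
    each.  Cells equal to ``NA`` (or empty) are recorded as missing, not
    zero.  Duplicate gene ids and non-numeric cells are rejected.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=[MISSING_TOKEN, ""],
        keep_default_na=False,
        dtype=str,
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise SeednetError(f"duplicate gene ids: {dups}")
    if df.columns.has_duplicates:
        raise SeednetError("duplicate sample ids")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise SeednetError(f"non-numeric expression cell: {exc}") from exc
    values.index = values.index.astype(str).str.strip()
    values.index.name = "gene"
    return values


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="gene")


def read_seed_list(path, network: nx.Graph) -> SeedSet:
    """Read a one-symbol-per-line seed list and filter it to the network.

    Seeds absent from the network go into ``dropped`` with a logged
    warning, mirroring how published seed lists shrink when mapped onto
    a common network.
    """
    if network.number_of_nodes() == 0:
        raise SeednetError("cannot filter seeds against an empty network")
    seen: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            symbol = line.strip()
            if symbol and symbol not in seen:
                seen.append(symbol)
    if not seen:
        raise SeednetError(f"seed list {path!s} is empty")
    genes = tuple(g for g in seen if g in network)
    dropped = tuple(g for g in seen if g not in network)
    if dropped:
        logger.warning("%d seed genes absent from the network: %s", len(dropped), ", ".join(dropped))
    return SeedSet(genes=genes, dropped=dropped)


def load_reference_tables() -> tuple[list[str], dict[str, float]]:
    """Load the packaged published tables.

    Returns
    -------
    (seeds, linker_rs)
        ``seeds`` is the list of 52 seed genes; ``linker_rs`` maps each
        of the 82 linker genes to its printed ranking score.
    """
    data = resources.files("seednet") / "data"
    seeds = [
        line.strip()
        for line in (data / "seed_genes.txt").read_text().splitlines()
        if line.strip()
    ]
    linker_rs: dict[str, float] = {}
    lines = (data / "linker_ranking_scores.tsv").read_text().splitlines()
    for line in lines[1:]:
        gene, rs = line.split("\t")
        linker_rs[gene] = float(rs)
    if len(seeds) != 52 or len(set(seeds)) != 52:
        raise SeednetError(f"seed fixture corrupted: {len(seeds)} entries")
    if len(linker_rs) != 82:
        raise SeednetError(f"linker fixture corrupted: {len(linker_rs)} entries")
    if not all(0 < rs <= 2 for rs in linker_rs.values()):
        raise SeednetError("linker fixture corrupted: RS outside (0, 2]")
    return seeds, linker_rs


def read_clinical_table(path) -> pd.DataFrame:
    """Read a per-sample clinical TSV.

    Expected columns: ``sample``, ``os_days`` (overall survival, days),
    ``event`` (1 death / 0 censored), and optional categorical covariates
    (``gender``, ``alcohol``, ``smoking``).  Any field may be missing.
    """
    df = pd.read_csv(path, sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False, dtype=str)
    if "sample" not in df.columns:
        raise SeednetError("clinical table lacks a 'sample' column")
    if df["sample"].duplicated().any():
        raise SeednetError("duplicate sample ids in clinical table")
    df = df.set_index("sample")
    for col in ("os_days", "event"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if "os_days" in df.columns and (df["os_days"].dropna() < 0).any():
        raise SeednetError("negative survival times in clinical table")
    return df


def write_clinical_table(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, index_label="sample")


def _sorted_edges(graph: nx.Graph):
    return sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True))


def write_network(graph: nx.Graph, path, format: str = "edge-tsv", node_attrs: dict | None = None) -> None:
    """Write a network as edge TSV, SIF, or GraphML.

    Rows are ordered lexicographically by endpoint pair so repeated runs
    produce byte-identical files.  ``node_attrs`` (e.g. role labels) are
    attached as node attributes in GraphML and ignored by the edge-list
    formats.
    """
    validate_graph(graph)
    path = Path(path)
    fmt = format.lower()
    if fmt in ("edge-tsv", "tsv"):
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene_a", "gene_b", "weight"])
            for u, v, d in _sorted_edges(graph):
                writer.writerow([u, v, repr(float(d["weight"]))])
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, _ in _sorted_edges(graph):
                fh.write(f"{u}\tinteracts\t{v}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif fmt == "graphml":
        out = nx.Graph()
        out.add_nodes_from(sorted(graph.nodes))
        for u, v, d in _sorted_edges(graph):
            out.add_edge(u, v, **{k: v2 for k, v2 in d.items() if v2 is not None})
        if node_attrs:
            for attr, values in node_attrs.items():
                nx.set_node_attributes(out, values, attr)
        nx.write_graphml(out, path)
    else:
        raise SeednetError(f"unknown network format {format!r}")


def read_edge_tsv(path) -> nx.Graph:
    """Read the edge-TSV dialect written by :func:`write_network`."""
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:3] != ["gene_a", "gene_b", "weight"]:
            raise SeednetError(f"not an edge TSV: {path!s}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise SeednetError(f"line {lineno}: expected 3 columns")
            graph.add_edge(row[0], row[1], weight=float(row[2]))
    return validate_graph(graph)


def write_subnetwork(sub: Subnetwork, path, format: str = "graphml") -> None:
    """Export a role-annotated subnetwork (GraphML keeps the roles)."""
    write_network(sub.graph, path, format=format, node_attrs={"role": sub.roles})
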