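"""Reading and writing interaction networks and expression tables.

Interaction networks arrive either as a plain 2-3 column TSV edge list or as
a BioGRID-style tab-delimited export.  Genetic interactions are excluded by
default: only records whose experimental system is on the physical-interaction
list are kept, after which the network is reduced to a simple undirected graph
and its giant component.

Gene identifiers are opaque, case-sensitive strings; no ORF/gene-name mapping
is attempted here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "InteractionRecord",
    "ExpressionProfile",
    "PHYSICAL_SYSTEMS",
    "read_interactions",
    "build_network",
    "giant_component",
    "read_expression",
    "write_edge_list",
    "write_weighted_edge_list",
    "read_weighted_edge_list",
    "write_expression",
]

#: Experimental-system labels counted as physical interactions (in vitro and
#: in vivo), used as the default filter for BioGRID-style exports.
PHYSICAL_SYSTEMS: frozenset[str] = frozenset(
    {
        "Biochemical Activity",
        "Co-crystal Structure",
        "Far Western",
        "Protein-peptide",
        "Protein-RNA",
        "Reconstituted Complex",
        "Affinity Capture-MS",
        "Affinity Capture-RNA",
        "Affinity Capture-Western",
        "Co-fractionation",
        "Co-localization",
        "Co-purification",
        "FRET",
        "Two-hybrid",
    }
)

#: Default (BioGRID tab2-layout) header names for the three columns we need.
BIOGRID_TAB2_COLUMNS: dict[str, str] = {
    "gene_a": "Official Symbol Interactor A",
    "gene_b": "Official Symbol Interactor B",
    "system": "Experimental System",
}


@dataclass(frozen=True)
class InteractionRecord:
    """One reported protein-protein interaction."""

    gene_a: str
    gene_b: str
    experimental_system: str | None = None


@dataclass
class ExpressionProfile:
    """Gene id -> nonnegative expression value (absolute level or ratio).

    Missing genes are simply absent from ``values``; after alignment to a
    network, :func:`stressnet.weighting.impute_missing` records how many
    network nodes lacked a value in ``n_missing_on_network``.
    """

    values: dict[str, float] = field(default_factory=dict)
    n_missing_on_network: int | None = None

    def __post_init__(self) -> None:
        for gene, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"expression value for {gene!r} must be finite and >= 0, got {v}")

    def copy(self) -> "ExpressionProfile":
        return replace(self, values=dict(self.values))

    def __len__(self) -> int:
        return len(self.values)


def read_interactions(
    path: str | Path,
    format: str = "simple_tsv",
    allowed_systems: Iterable[str] | str = "physical",
    column_names: Mapping[str, str] | None = None,
) -> list[InteractionRecord]:
    """Read interaction records from a TSV file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"simple_tsv"`` (2-3 columns: gene_a, gene_b, [system], no header)
        or ``"biogrid_tab"`` (header-based column lookup, tab2 layout names
        by default, override with ``column_names``).
    allowed_systems
        ``"all"`` keeps every record; ``"physical"`` (default) keeps the
        physical-interaction systems in :data:`PHYSICAL_SYSTEMS`; any other
        iterable is used as an explicit allow-list.  Records without a system
        label are always kept.
    """
    path = Path(path)
    if format not in ("simple_tsv", "biogrid_tab"):
        raise ValueError(f"unknown format {format!r}; expected 'simple_tsv' or 'biogrid_tab'")
    if isinstance(allowed_systems, str):
        if allowed_systems == "all":
            allowed: frozenset[str] | None = None
        elif allowed_systems == "physical":
            allowed = PHYSICAL_SYSTEMS
        else:
            raise ValueError(f"allowed_systems must be 'all', 'physical' or a set, got {allowed_systems!r}")
    else:
        allowed = frozenset(allowed_systems)

    records: list[InteractionRecord] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        if format == "simple_tsv":
            for lineno, row in enumerate(reader, start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) not in (2, 3) or not row[0].strip() or not row[1].strip():
                    raise ValueError(f"{path}:{lineno}: malformed edge-list line: {row!r}")
                system = row[2].strip() if len(row) == 3 and row[2].strip() else None
                records.append(InteractionRecord(row[0].strip(), row[1].strip(), system))
        else:
            cols = dict(BIOGRID_TAB2_COLUMNS)
            if column_names:
                cols.update(column_names)
            try:
                header = next(reader)
            except StopIteration as exc:
                raise ValueError(f"{path}:1: empty BioGRID file") from exc
            try:
                ia = header.index(cols["gene_a"])
                ib = header.index(cols["gene_b"])
            except ValueError as exc:
                raise ValueError(f"{path}:1: missing interactor columns {cols['gene_a']!r}/{cols['gene_b']!r}") from exc
            isys = header.index(cols["system"]) if cols["system"] in header else None
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) <= max(ia, ib) or not row[ia].strip() or not row[ib].strip():
                    raise ValueError(f"{path}:{lineno}: malformed BioGRID line")
                system = None
                if isys is not None and len(row) > isys and row[isys].strip():
                    system = row[isys].strip()
                records.append(InteractionRecord(row[ia].strip(), row[ib].strip(), system))

    if allowed is not None:
        records = [r for r in records if r.experimental_system is None or r.experimental_system in allowed]
    return records


def build_network(records: Sequence[InteractionRecord]) -> nx.Graph:
    """Build a simple undirected graph: self-loops removed, duplicates collapsed."""
    if not records:
        raise ValueError("no interaction records supplied")
    g = nx.Graph()
    for r in records:
        if r.gene_a == r.gene_b:
            continue
        g.add_edge(r.gene_a, r.gene_b)
    if g.number_of_edges() == 0:
        raise ValueError("network is empty after removing self-interactions")
    return g


def giant_component(graph: nx.Graph) -> nx.Graph:
    """Vertex-induced subgraph on the largest connected component.

    Ties in component size are broken in favour of the component containing
    the smallest node id, so the result is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(graph))
    max_size = max(len(c) for c in comps)
    tied = [c for c in comps if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    return graph.subgraph(best).copy()


def read_expression(path: str | Path, value_transform: str = "linear") -> ExpressionProfile:
    """Read a two-column (gene id, value) TSV expression table.

    ``value_transform="from_log2"`` applies ``2**x`` to each value, the native
    scale of log-ratio microarray exports; ``"linear"`` takes values as-is and
    rejects negatives.  Duplicate gene ids are an error.
    """
    path = Path(path)
    if value_transform not in ("linear", "from_log2"):
        raise ValueError(f"unknown value_transform {value_transform!r}")
    values: dict[str, float] = {}
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            gene = row[0].strip()
            try:
                x = float(row[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value {row[1]!r}") from exc
            if value_transform == "from_log2":
                x = 2.0**x
            if x < 0:
                raise ValueError(f"{path}:{lineno}: negative expression value {x} for {gene!r}")
            if gene in values:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            values[gene] = x
    return ExpressionProfile(values=values)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write an unweighted edge list as 2-column TSV, sorted for determinism."""
    edges = sorted((min(a, b), max(a, b)) for a, b in graph.edges())
    with Path(path).open("w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_weighted_edge_list(graph: nx.Graph, path: str | Path, weight: str = "weight") -> None:
    """Write (node_a, node_b, weight) TSV with 6 significant digits."""
    rows = sorted((min(a, b), max(a, b), d[weight]) for a, b, d in graph.edges(data=True))
    with Path(path).open("w") as fh:
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{_fmt(w)}\n")


def read_weighted_edge_list(path: str | Path) -> nx.Graph:
    """Read a 3-column (node_a, node_b, weight) TSV into a graph."""
    g = nx.Graph()
    with Path(path).open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row:
                continue
            if len(row) != 3:
                raise ValueError(f"{path}:{lineno}: expected three columns")
            g.add_edge(row[0], row[1], weight=float(row[2]))
    return g


def write_expression(profile: ExpressionProfile, path: str | Path) -> None:
    """Write a (gene_id, value) TSV, sorted by gene id."""
    with Path(path).open("w") as fh:
        for gene in sorted(profile.values):
            fh.write(f"{gene}\t{_fmt(profile.values[gene])}\n")
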