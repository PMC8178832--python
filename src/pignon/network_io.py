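"""Parse interaction files and build the filtered, connected PPI graph.

Supported inputs are BioGRID tab-delimited release files (official gene
symbols + organism taxon columns), STRING ``protein.links`` files
(``protein1 protein2 combined_score``) and a plain two-column edge TSV (the
format the synthetic fixture generator writes).

The built network is a simple undirected graph restricted to its largest
connected component, with promiscuous hub proteins (degree >= hub cutoff,
default 1000) removed. Connectivity is a hard requirement downstream: the
clustering statistic sums shortest-path distances, which must all be finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import networkx as nx

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """An input file does not conform to its declared format."""


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction row: two protein identifiers, their taxa and an
    optional confidence score on STRING's integer 0-1000 scale."""

    protein_a: str
    protein_b: str
    taxon_a: Optional[int] = None
    taxon_b: Optional[int] = None
    score: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("protein identifiers must be non-empty")
        if self.score is not None and not (0 <= self.score <= 1000):
            raise ValueError(f"score {self.score} outside [0, 1000]")


def _normalize_id(identifier: str) -> str:
    # Case-insensitive matching across input namespaces: trim and upper-case.
    return identifier.strip().upper()


def _find_column(header: Sequence[str], *candidates: str) -> int:
    lowered = [h.strip().lower() for h in header]
    for cand in candidates:
        if cand.lower() in lowered:
            return lowered.index(cand.lower())
    raise FormatError(f"missing required column: {candidates[0]!r}")


def parse_biogrid(
    stream: Iterable[str],
    taxon: int = 9606,
    physical_only: bool = False,
) -> list[InteractionRecord]:
    """Parse a BioGRID tab-delimited release, keeping within-taxon rows.

    Parameters
    ----------
    stream
        Lines of a BioGRID tab-delimited file with a header row containing
        ``Official Symbol Interactor A/B`` and ``Organism Interactor A/B``.
    taxon
        NCBI taxon identifier both interactors must match (9606 = human).
    physical_only
        If true and an ``Experimental System Type`` column is present, keep
        only rows typed ``physical``.
    """
    it: Iterator[str] = iter(stream)
    try:
        header = next(it).rstrip("\n").split("\t")
    except StopIteration:
        raise FormatError("empty file: no header row") from None
    col_a = _find_column(header, "Official Symbol Interactor A")
    col_b = _find_column(header, "Official Symbol Interactor B")
    col_ta = _find_column(header, "Organism Interactor A", "Organism ID Interactor A")
    col_tb = _find_column(header, "Organism Interactor B", "Organism ID Interactor B")
    col_sys = None
    try:
        col_sys = _find_column(header, "Experimental System Type")
    except FormatError:
        if physical_only:
            raise FormatError(
                "physical_only requested but no 'Experimental System Type' column"
            ) from None

    records: list[InteractionRecord] = []
    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        try:
            ta, tb = int(fields[col_ta]), int(fields[col_tb])
        except (IndexError, ValueError):
            raise FormatError(f"line {lineno}: malformed organism taxon field")
        if ta != taxon or tb != taxon:
            continue
        if physical_only and col_sys is not None:
            if fields[col_sys].strip().lower() != "physical":
                continue
        records.append(
            InteractionRecord(
                protein_a=_normalize_id(fields[col_a]),
                protein_b=_normalize_id(fields[col_b]),
                taxon_a=ta,
                taxon_b=tb,
            )
        )
    return records


def parse_string(
    stream: Iterable[str],
    min_score: int = 400,
    inclusive: bool = False,
    aliases: Optional[dict[str, str]] = None,
) -> list[InteractionRecord]:
    """Parse a STRING protein-links file, keeping confident interactions.

    Rows with ``combined_score > min_score`` are kept (the repository's
    "medium confidence above 0.4" on the integer 0-1000 scale); set
    ``inclusive=True`` for ``>=``. Identifiers pass through unchanged unless
    an ``aliases`` map (e.g. ENSP -> gene symbol) is given.
    """
    records: list[InteractionRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.replace("\t", " ").split()
        if lineno == 1 and fields[-1].lower() == "combined_score":
            continue  # header
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected 3 fields, got {len(fields)}")
        try:
            score = int(fields[2])
        except ValueError:
            raise FormatError(f"line {lineno}: non-integer combined_score {fields[2]!r}")
        keep = score >= min_score if inclusive else score > min_score
        if not keep:
            continue
        a, b = fields[0], fields[1]
        if aliases is not None:
            a = aliases.get(a, a)
            b = aliases.get(b, b)
        records.append(
            InteractionRecord(
                protein_a=_normalize_id(a), protein_b=_normalize_id(b), score=score
            )
        )
    return records


def read_edge_tsv(stream: Iterable[str]) -> list[InteractionRecord]:
    """Read a plain two-column (optionally scored third column) edge TSV."""
    records: list[InteractionRecord] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected at least 2 columns")
        score = None
        if len(fields) >= 3 and fields[2]:
            try:
                score = int(fields[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer score {fields[2]!r}")
        records.append(
            InteractionRecord(
                protein_a=_normalize_id(fields[0]),
                protein_b=_normalize_id(fields[1]),
                score=score,
            )
        )
    return records


def build_network(
    records: Union[Sequence[InteractionRecord], Iterable[tuple[str, str]]],
    hub_cutoff: int = 1000,
    relcc: bool = True,
) -> nx.Graph:
    """Build the filtered PPI graph: dedupe -> LCC -> hub removal -> re-LCC.

    Self-loops and duplicate edges are collapsed, the largest connected
    component is taken, vertices of degree >= ``hub_cutoff`` ("interact with
    less than ``hub_cutoff`` other proteins") are removed, and — because hub
    removal can disconnect the graph while the distance statistic requires
    finite pairwise distances — the largest component is re-taken
    (``relcc=False`` reproduces the literal LCC-then-hub order).

    Raises ``ValueError`` if no network remains.
    """
    g = nx.Graph()
    for rec in records:
        if isinstance(rec, InteractionRecord):
            a, b = rec.protein_a, rec.protein_b
        else:
            a, b = _normalize_id(rec[0]), _normalize_id(rec[1])
        if a == b:
            continue
        g.add_edge(a, b)
    logger.info("after dedupe/self-loop removal: %d vertices, %d edges",
                g.number_of_nodes(), g.number_of_edges())
    if g.number_of_edges() == 0:
        raise ValueError("no network remains after parsing")

    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    logger.info("after LCC: %d vertices, %d edges",
                g.number_of_nodes(), g.number_of_edges())

    hubs = [v for v, d in g.degree() if d >= hub_cutoff]
    g.remove_nodes_from(hubs)
    logger.info("after hub removal (degree >= %d, %d removed): %d vertices, %d edges",
                hub_cutoff, len(hubs), g.number_of_nodes(), g.number_of_edges())
    if g.number_of_edges() == 0:
        raise ValueError("no network remains after hub filtering")

    if relcc and not nx.is_connected(g):
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        logger.info("after re-LCC: %d vertices, %d edges",
                    g.number_of_nodes(), g.number_of_edges())

    _validate_network(g, hub_cutoff, require_connected=relcc)
    return g


def _validate_network(g: nx.Graph, hub_cutoff: int, require_connected: bool = True) -> None:
    assert nx.number_of_selfloops(g) == 0, "self-loops survived filtering"
    if g.number_of_nodes():
        assert max(d for _, d in g.degree()) < hub_cutoff, "hub survived filtering"
    if require_connected:
        assert nx.is_connected(g), "graph is not connected"
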