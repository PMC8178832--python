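"""Synthetic networks, annotations and expression tables with planted signal.

The generator emulates the three real inputs (interaction network,
quantitative proteomics table, annotation catalog) at desk scale so the full
pipeline runs with no downloads:

* a scale-free-like network (Barabasi-Albert preferential attachment),
  because PPI degree distributions are heavy-tailed;
* background annotations drawn with partial topological locality — real GO
  terms annotate proteins that are innately clustered in PPI networks, and a
  generator without that property would make the unweighted benchmark run
  trivially empty;
* signal terms grown as self-avoiding walks: connected subgraphs (so their
  internal edges exist and can be shortened by expression weighting) that are
  only mildly hop-clustered, so detecting them genuinely requires the
  differential-expression signal carried by their fold-changes;
* an expression table whose condition ratio reproduces the planted
  fold-changes: signal proteins centred on the effect size, background
  proteins centred on 1 with log-normal noise.

Everything is deterministic given the seed, and the writers emit the same
file formats the real pipeline reads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from pignon.annotations import AnnotationCatalog

_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_vertices: int = 200
    edges_per_vertex: int = 2          # preferential-attachment parameter
    n_terms: int = 50                  # background terms
    term_size_range: tuple[int, int] = (5, 15)
    module_size: int = 10              # planted signal term size
    effect: float = 4.0                # signal fold-change centre (!= 1 to plant signal)
    noise_sd: float = 0.1              # log-normal sd of background fold-changes
    background_locality: float = 0.7   # probability a background member is a neighbour
    n_signal_terms: int = 1
    samples_per_condition: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.module_size > self.n_vertices:
            raise ValueError("planted module larger than the network")
        if self.effect <= 0:
            raise ValueError("effect must be positive")
        if not (0 <= self.background_locality <= 1):
            raise ValueError("background_locality must be in [0, 1]")
        if self.term_size_range[0] < 3:
            raise ValueError("terms smaller than 3 are filtered out downstream")


@dataclass
class Fixture:
    network: nx.Graph
    expression: pd.DataFrame
    condition_map: dict[str, str]
    catalog: AnnotationCatalog
    signal_terms: list[str]
    fold_changes_true: dict[str, float] = field(default_factory=dict)

    conditions: tuple[str, str] = ("case", "control")


def _grow_walk(g: nx.Graph, size: int, rng: np.random.Generator) -> set[str]:
    """Self-avoiding walk of ``size`` vertices (connected, chain-like).

    When the walk head has no unvisited neighbour, growth resumes from an
    earlier walk vertex, so the result is always a connected subgraph.
    """
    nodes = sorted(g.nodes)
    start = nodes[rng.integers(len(nodes))]
    walk = [start]
    visited = {start}
    while len(walk) < size:
        extended = False
        for anchor in reversed(walk):  # prefer the head: stringy growth
            options = sorted(set(g.neighbors(anchor)) - visited)
            if options:
                nxt = options[rng.integers(len(options))]
                walk.append(nxt)
                visited.add(nxt)
                extended = True
                break
        if not extended:  # component exhausted (tiny graphs only)
            break
    return visited


def _grow_background(
    g: nx.Graph, size: int, locality: float, rng: np.random.Generator
) -> set[str]:
    """Protein set grown with probability ``locality`` from the boundary."""
    nodes = sorted(g.nodes)
    members = {nodes[rng.integers(len(nodes))]}
    while len(members) < size:
        neighbours: set[str] = set()
        if locality > 0:
            for v in members:
                neighbours.update(g.neighbors(v))
            neighbours -= members
        if neighbours and rng.random() < locality:
            pool = sorted(neighbours)
        else:
            pool = sorted(set(nodes) - members)
        members.add(pool[rng.integers(len(pool))])
    return members


def generate_fixture(spec: SyntheticSpec) -> Fixture:
    """Generate one deterministic (network, expression, annotations) bundle."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    g_raw = nx.barabasi_albert_graph(
        spec.n_vertices, spec.edges_per_vertex, seed=int(rng.integers(2**31))
    )
    width = len(str(spec.n_vertices))
    mapping = {i: f"P{i:0{width}d}" for i in g_raw.nodes}
    g = nx.relabel_nodes(g_raw, mapping)
    assert nx.is_connected(g)

    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    signal_terms: list[str] = []
    signal_proteins: set[str] = set()
    for i in range(spec.n_signal_terms):
        tid = f"SIG:{i + 1:04d}"
        members = _grow_walk(g, spec.module_size, rng)
        terms[tid] = members
        names[tid] = f"planted signal module {i + 1}"
        namespaces[tid] = _NAMESPACES[i % 3]
        signal_terms.append(tid)
        signal_proteins |= members
    lo, hi = spec.term_size_range
    for i in range(spec.n_terms):
        tid = f"BG:{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        terms[tid] = _grow_background(g, size, spec.background_locality, rng)
        names[tid] = f"background term {i + 1}"
        namespaces[tid] = _NAMESPACES[i % 3]
    catalog = AnnotationCatalog(terms=terms, names=names, namespaces=namespaces)

    proteins = sorted(g.nodes)
    fc_true: dict[str, float] = {}
    for p in proteins:
        noise = float(np.exp(rng.normal(0.0, spec.noise_sd))) if spec.noise_sd > 0 else 1.0
        fc_true[p] = spec.effect * noise if p in signal_proteins else noise

    # Expression: control = baseline abundance, case = baseline x fold-change;
    # per-sample log-normal scatter at half the fold-change noise scale.
    sample_sd = spec.noise_sd / 2.0
    baseline = np.exp(rng.normal(8.0, 1.0, size=len(proteins)))
    data = {}
    cond_map: dict[str, str] = {}
    case, control = "case", "control"
    for r in range(spec.samples_per_condition):
        s = f"{control}_{r + 1}"
        scatter = (np.exp(rng.normal(0.0, sample_sd, size=len(proteins)))
                   if sample_sd > 0 else 1.0)
        data[s] = baseline * scatter
        cond_map[s] = control
    fc_vec = np.array([fc_true[p] for p in proteins])
    for r in range(spec.samples_per_condition):
        s = f"{case}_{r + 1}"
        scatter = (np.exp(rng.normal(0.0, sample_sd, size=len(proteins)))
                   if sample_sd > 0 else 1.0)
        data[s] = baseline * fc_vec * scatter
        cond_map[s] = case
    expression = pd.DataFrame(data, index=pd.Index(proteins, name="protein"))

    return Fixture(
        network=g,
        expression=expression,
        condition_map=cond_map,
        catalog=catalog,
        signal_terms=signal_terms,
        fold_changes_true=fc_true,
        conditions=(case, control),
    )


def write_fixture(fixture: Fixture, out_dir: str) -> dict[str, str]:
    """Write the bundle in the pipeline's input formats; returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "network": os.path.join(out_dir, "network.tsv"),
        "expression": os.path.join(out_dir, "expression.tsv"),
        "conditions": os.path.join(out_dir, "conditions.tsv"),
        "annotations": os.path.join(out_dir, "annotations.gmt"),
    }
    with open(paths["network"], "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in fixture.network.edges()):
            fh.write(f"{u}\t{v}\n")
    fixture.expression.to_csv(paths["expression"], sep="\t", float_format="%.8g")
    with open(paths["conditions"], "w") as fh:
        for sample, cond in sorted(fixture.condition_map.items()):
            fh.write(f"{sample}\t{cond}\n")
    with open(paths["annotations"], "w") as fh:
        for term in sorted(fixture.catalog.terms):
            name = fixture.catalog.names.get(term, "")
            ns = fixture.catalog.namespaces.get(term, "")
            desc = f"{name}|{ns}" if ns else name
            members = "\t".join(sorted(fixture.catalog.terms[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")
    return paths
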