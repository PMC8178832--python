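"""Per-protein fold-changes and expression weighting of PPI edges.

The fold-change f(v) of a protein is the ratio of its mean expression in the
numerator condition to its mean in the denominator condition; proteins the
experiment did not quantify keep f(v) = 1 (no differential expression). An
edge's weight is w(e) = m if m <= 1 else 1/m, where m is the arithmetic mean
of its endpoints' fold-changes — so strong dysregulation in either direction
shortens the edge, and w(e) is always in (0, 1].
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def read_expression_tsv(path_or_buf) -> pd.DataFrame:
    """Read a protein x sample expression TSV (first column = protein ID)."""
    df = pd.read_csv(path_or_buf, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.upper()
    return df


def read_condition_map(path_or_buf) -> dict[str, str]:
    """Read a two-column sample -> condition TSV (no header required)."""
    df = pd.read_csv(path_or_buf, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("condition map needs two columns: sample, condition")
    if df.iloc[0, 0].strip().lower() in ("sample", "sample_id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def read_fold_changes_tsv(path_or_buf) -> dict[str, float]:
    """Read a pre-computed two-column protein -> fold-change TSV."""
    df = pd.read_csv(path_or_buf, sep="\t", header=None, comment="#")
    if isinstance(df.iloc[0, 1], str):
        df = df.iloc[1:]
    fc = {
        str(p).strip().upper(): float(v)
        for p, v in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
    bad = [p for p, v in fc.items() if not v > 0]
    if bad:
        raise ValueError(f"non-positive fold-changes for: {bad[:5]}")
    return fc


def compute_fold_changes(
    expr: pd.DataFrame,
    condition_map: Mapping[str, str],
    cond_num: str,
    cond_den: str,
) -> dict[str, float]:
    """Fold-change per protein: mean(cond_num) / mean(cond_den).

    Means ignore missing values. Proteins with no usable value in either
    condition, or with a zero denominator mean (degenerate quantification),
    are assigned f = 1.
    """
    num_samples = [s for s in expr.columns if condition_map.get(s) == cond_num]
    den_samples = [s for s in expr.columns if condition_map.get(s) == cond_den]
    if not num_samples:
        raise ValueError(f"condition {cond_num!r} has no samples in the table")
    if not den_samples:
        raise ValueError(f"condition {cond_den!r} has no samples in the table")

    num_mean = expr[num_samples].mean(axis=1, skipna=True)
    den_mean = expr[den_samples].mean(axis=1, skipna=True)

    fc: dict[str, float] = {}
    n_degenerate = 0
    for protein in expr.index:
        a, b = num_mean[protein], den_mean[protein]
        if math.isnan(a) or math.isnan(b):
            fc[str(protein)] = 1.0
        elif b == 0 or a <= 0:
            fc[str(protein)] = 1.0
            n_degenerate += 1
        else:
            fc[str(protein)] = float(a / b)
    if n_degenerate:
        logger.warning(
            "%d proteins with degenerate quantification (zero/negative mean) set to f=1",
            n_degenerate,
        )
    return fc


def edge_weight(f1: float, f2: float, mean: str = "arithmetic") -> float:
    """Weight of the edge joining proteins with fold-changes f1 and f2.

    m = mean(f1, f2); returns m if m <= 1 else 1/m, hence a value in (0, 1]
    that equals 1 exactly when m = 1.
    """
    if not (f1 > 0 and f2 > 0):
        raise ValueError(f"fold-changes must be positive, got ({f1}, {f2})")
    if mean == "arithmetic":
        m = (f1 + f2) / 2.0
    elif mean == "geometric":
        m = math.sqrt(f1 * f2)
    else:
        raise ValueError(f"unknown mean {mean!r}")
    return m if m <= 1.0 else 1.0 / m


def weight_network(
    network: nx.Graph,
    fold_changes: Mapping[str, float],
    mode: str = "weighted",
    mean: str = "arithmetic",
) -> nx.Graph:
    """Attach a ``weight`` in (0, 1] to every edge of a copy of ``network``.

    mode="weighted" applies :func:`edge_weight` to the endpoint fold-changes
    (vertices absent from ``fold_changes`` default to 1); mode="unweighted"
    sets every weight to exactly 1, turning distances into hop counts.
    """
    if mode not in ("weighted", "unweighted"):
        raise ValueError(f"unknown mode {mode!r}")
    fc = {str(k).strip().upper(): float(v) for k, v in fold_changes.items()}
    unmatched = set(fc) - set(network.nodes)
    if unmatched:
        logger.info("%d quantified proteins not in the network", len(unmatched))

    g = network.copy()
    if mode == "unweighted":
        nx.set_edge_attributes(g, 1.0, "weight")
        return g
    for u, v in g.edges():
        g[u][v]["weight"] = edge_weight(fc.get(u, 1.0), fc.get(v, 1.0), mean=mean)
    return g


def weighted_vertex_count(fold_changes: Mapping[str, float], vertices: Iterable[str]) -> int:
    """Number of network vertices carrying a fold-change different from 1."""
    vs = set(vertices)
    return int(np.sum([1 for p, f in fold_changes.items() if p in vs and f != 1.0]))
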