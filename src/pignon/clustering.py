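"""Shortest-path distances, the TPD clustering statistic and its null models.

The clustering of a protein set S is the total pairwise distance

    TPD(S) = sum over unordered pairs {u, v} in S of s(u, v),

where s is the weighted shortest-path distance in the expression-weighted
network; a small TPD means the set is tightly clustered. Significance comes
from a per-set-size Monte-Carlo null: random sets of annotated proteins are
drawn (uniformly, or with probability proportional to annotation counts),
their TPDs summarised by mean and standard deviation, and the lower tail of
the fitted normal gives the probability of a clustering at least as tight as
the observed one. The normal closes the resolution gap of raw Monte-Carlo
sampling, whose smallest estimable p-value is 1/n_samples.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path
from scipy.stats import norm

from pignon.annotations import AnnotationCatalog

_TINY = np.nextafter(0.0, 1.0)
_ALMOST_ONE = np.nextafter(1.0, 0.0)


@dataclass
class DistanceMatrix:
    """All-pairs shortest-path distances with a vertex -> row index."""

    index: dict[str, int]
    d: np.ndarray

    @property
    def vertices(self) -> list[str]:
        return list(self.index)

    def rows(self, proteins: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.index[p] for p in proteins), dtype=np.intp)


def all_pairs_distances(
    wn: nx.Graph,
    method: str = "dijkstra",
    dtype=np.float64,
) -> DistanceMatrix:
    """Exact weighted all-pairs shortest-path distances of a connected graph.

    Uses one Dijkstra run per source by default (equivalent to
    Floyd-Warshall on positive weights; pass ``method="floyd-warshall"`` to
    run the classic algorithm instead).
    """
    if wn.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if not nx.is_connected(wn):
        raise ValueError("graph must be connected (distances must be finite)")
    nodes = sorted(wn.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    csgraph = nx.to_scipy_sparse_array(wn, nodelist=nodes, weight="weight", format="csr")
    scipy_method = {"dijkstra": "D", "floyd-warshall": "FW"}[method]
    d = shortest_path(csgraph, method=scipy_method, directed=False)
    assert np.all(np.isfinite(d)), "infinite distance in a connected graph"
    return DistanceMatrix(index=index, d=np.asarray(d, dtype=dtype))


def tpd(dist: DistanceMatrix, proteins: Iterable[str]) -> float:
    """Total pairwise distance of a protein set (each pair counted once)."""
    rows = dist.rows(proteins)
    if rows.size < 2:
        raise ValueError("TPD requires at least 2 proteins")
    sub = dist.d[np.ix_(rows, rows)]
    return float(sub.sum() / 2.0)


def _tpd_of_index_sets(d: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """TPD for each row of ``idx`` (k x n matrix of vertex indices)."""
    k, n = idx.shape
    acc = np.zeros(k, dtype=np.float64)
    for i in range(n - 1):
        acc += d[idx[:, i][:, None], idx[:, i + 1:]].sum(axis=1)
    return acc


def sample_index_sets(
    k: int,
    m: int,
    size: int,
    rng: np.random.Generator,
    w: Optional[np.ndarray] = None,
) -> np.ndarray:
    """``k`` random ``size``-subsets of range(m), one per row.

    Uniform without replacement by default. With positive weights ``w``, each
    subset follows sequential weighted draws without replacement
    (probabilities renormalised after every draw), realised via
    exponential-key order statistics — the vertex with the smallest
    Exp(1)/w_i key is the first draw, the next smallest the second, and so
    on — which is distributionally identical to the sequential scheme and
    vectorises.
    """
    if size > m:
        raise ValueError(f"set size {size} exceeds {m} eligible items")
    if size == m:
        return np.tile(np.arange(m), (k, 1))
    keys = rng.random((k, m)) if w is None else rng.exponential(size=(k, m)) / w
    return np.argpartition(keys, size - 1, axis=1)[:, :size]


def sample_tpds(
    dist: DistanceMatrix,
    eligible: Sequence[str],
    size: int,
    n_samples: int,
    rng: np.random.Generator,
    weights: Optional[Mapping[str, float]] = None,
    chunk: int = 8192,
) -> np.ndarray:
    """TPDs of ``n_samples`` random ``size``-subsets of ``eligible``.

    Uniform sampling without replacement by default; with ``weights``
    (annotation counts), subsets follow the weighted scheme of
    :func:`sample_index_sets`.
    """
    m = len(eligible)
    if size < 2:
        raise ValueError("set size must be >= 2")
    rows = dist.rows(eligible)
    w = None
    if weights is not None:
        w = np.array([float(weights[p]) for p in eligible])
        if np.any(w <= 0):
            raise ValueError("sampling weights must be positive")

    out = np.empty(n_samples, dtype=np.float64)
    done = 0
    while done < n_samples:
        k = min(chunk, n_samples - done)
        pick = sample_index_sets(k, m, size, rng, w=w)
        out[done:done + k] = _tpd_of_index_sets(dist.d, rows[pick])
        done += k
    return out


@dataclass
class NullModel:
    """Per-set-size (mu, sigma) of the TPD distribution from Monte Carlo."""

    mode: str  # "unweighted" | "weighted" sampling
    entries: dict[int, tuple[float, float, int]] = field(default_factory=dict)

    def get(self, size: int) -> tuple[float, float]:
        mu, sigma, _ = self.entries[size]
        return mu, sigma

    def covers(self, sizes: Iterable[int]) -> bool:
        return all(s in self.entries for s in sizes)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("size\tmean\tsd\tn_samples\tmode\n")
            for size in sorted(self.entries):
                mu, sigma, n = self.entries[size]
                fh.write(f"{size}\t{mu!r}\t{sigma!r}\t{n}\t{self.mode}\n")

    @classmethod
    def from_tsv(cls, path) -> "NullModel":
        entries: dict[int, tuple[float, float, int]] = {}
        mode = "unweighted"
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("size"):
                raise ValueError("null-model TSV must start with a header row")
            for line in fh:
                size, mu, sigma, n, mode = line.rstrip("\n").split("\t")
                entries[int(size)] = (float(mu), float(sigma), int(n))
        return cls(mode=mode, entries=entries)


def network_digest(wn: nx.Graph) -> str:
    """Digest of the weighted edge list, for keying null-model caches."""
    h = hashlib.sha256()
    for u, v, w in sorted(
        (min(u, v), max(u, v), data.get("weight", 1.0)) for u, v, data in wn.edges(data=True)
    ):
        h.update(f"{u}\t{v}\t{w:.12g}\n".encode())
    return h.hexdigest()[:16]


def build_null_model(
    dist: DistanceMatrix,
    eligible: Sequence[str],
    sizes: Iterable[int],
    n_samples: int,
    rng: np.random.Generator,
    weights: Optional[Mapping[str, float]] = None,
) -> NullModel:
    """Monte-Carlo null model: TPD mean and sd per requested set size.

    ``eligible`` must be the network vertices carrying at least one
    annotation; ``weights`` switches to annotation-count-proportional
    sampling.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2 (sd undefined otherwise)")
    model = NullModel(mode="weighted" if weights is not None else "unweighted")
    for size in sorted(set(sizes)):
        samples = sample_tpds(dist, eligible, size, n_samples, rng, weights=weights)
        model.entries[size] = (float(samples.mean()), float(samples.std(ddof=1)), n_samples)
    return model


def clustering_pvalue(tpd_obs: float, mu: float, sigma: float) -> float:
    """Lower-tail normal probability of a TPD at least as small as observed.

    With a degenerate null (sigma = 0, which occurs only when the sampled
    size equals the whole eligible set) the p-value is 1 when the observation
    is at or above the mean and the smallest positive float otherwise.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return 1.0 if tpd_obs >= mu else float(_TINY)
    p = norm.cdf((tpd_obs - mu) / sigma)
    return float(min(max(p, _TINY), _ALMOST_ONE))


@dataclass(frozen=True)
class ClusteringScore:
    """Observed TPD and normal-approximation p-value of one term."""

    term: str
    size: int  # effective size |S_T intersected with V|
    tpd: float
    p_value: float


def score_terms(
    dist: DistanceMatrix,
    catalog: AnnotationCatalog,
    null: NullModel,
) -> list[ClusteringScore]:
    """Score every catalog term against the size-matched null entry.

    The effective set is the term's proteins restricted to the network
    (absent proteins cannot contribute distances); the null entry for the
    effective size supplies (mu, sigma).
    """
    vertices = set(dist.index)
    scores: list[ClusteringScore] = []
    for term in sorted(catalog.terms):
        eff = catalog.terms[term] & vertices
        n = len(eff)
        if n not in null.entries:
            raise KeyError(
                f"term {term!r}: no null model for effective size {n}"
            )
        t = tpd(dist, eff)
        mu, sigma = null.get(n)
        scores.append(ClusteringScore(term=term, size=n, tpd=t,
                                      p_value=clustering_pvalue(t, mu, sigma)))
    return scores
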