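"""Empirical FDR from shuffled catalogs, significance calls and the
weighted-vs-unweighted contrast.

The FDR at a p-value threshold p is the number of shuffled-catalog terms
scoring below p over the number of real terms scoring below p — shuffled
terms carry no biology, so any clustering they show calibrates the false
discovery rate. Terms are deemed significant below the largest threshold
whose estimated FDR is under the target (default 0.001); when no threshold
reaches the target, the point with the smallest FDR estimated above zero is
used instead, provided that estimate is still small (see
``operative_threshold`` / ``call_significant``). Finally the weighted-network
results are contrasted with the unweighted-network results: terms
significant only with expression weighting are the method's readout of
dysregulated, clustered annotations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from pignon.clustering import ClusteringScore

logger = logging.getLogger(__name__)

ScoreSets = Union[Sequence[ClusteringScore], Sequence[Sequence[ClusteringScore]]]


def _as_score_sets(shuffled: ScoreSets) -> list[Sequence[ClusteringScore]]:
    if len(shuffled) and isinstance(shuffled[0], ClusteringScore):
        return [shuffled]  # a single shuffled catalog
    return list(shuffled)


def _pvalues(scores: Sequence[ClusteringScore]) -> np.ndarray:
    return np.sort(np.array([s.p_value for s in scores], dtype=np.float64))


def estimate_fdr(
    real_scores: Sequence[ClusteringScore],
    shuffled_scores: ScoreSets,
    p: float,
) -> float:
    """FDR(p) = (#shuffled terms with p-value < p) / (#real with p-value < p).

    With several shuffled catalogs the numerator is their average count.
    Returns NaN (with a warning) when no real term scores below p.
    """
    if not len(real_scores):
        raise ValueError("real score list is empty")
    sets = _as_score_sets(shuffled_scores)
    if not sets or not len(sets[0]):
        raise ValueError("shuffled score list is empty")
    n_real = int(np.sum(_pvalues(real_scores) < p))
    n_shuf = float(np.mean([np.sum(_pvalues(s) < p) for s in sets]))
    if n_real == 0:
        logger.warning("FDR undefined at p=%g: no real term below threshold", p)
        return math.nan
    return n_shuf / n_real


@dataclass
class FDRCurve:
    """Step-function FDR evaluated at every distinct real p-value.

    Each point carries (p, FDR(p), #real < p, mean #shuffled < p); counts use
    the strict inequality of the estimator's indicator functions, so the
    smallest point's FDR is NaN (0/0).
    """

    points: list[tuple[float, float, int, float]]


def fdr_curve(
    real_scores: Sequence[ClusteringScore],
    shuffled_scores: ScoreSets,
) -> FDRCurve:
    real_p = _pvalues(real_scores)
    shuf_sets = [_pvalues(s) for s in _as_score_sets(shuffled_scores)]
    eval_points = np.unique(real_p)
    n_real = np.searchsorted(real_p, eval_points, side="left")
    n_shuf = np.mean(
        [np.searchsorted(s, eval_points, side="left") for s in shuf_sets], axis=0
    )
    points = []
    for p, nr, ns in zip(eval_points, n_real, n_shuf):
        fdr = ns / nr if nr > 0 else math.nan
        points.append((float(p), float(fdr), int(nr), float(ns)))
    return FDRCurve(points=points)


@dataclass(frozen=True)
class OperativeThreshold:
    p: float
    fdr: float
    is_fallback: bool  # True when no point reached the target


def operative_threshold(curve: FDRCurve, target: float = 0.001) -> OperativeThreshold:
    """Pick the p-value threshold that controls the FDR at ``target``.

    Returns the largest evaluated p whose FDR is below the target; when no
    point qualifies, falls back to the point with the smallest FDR estimated
    above zero (flagged ``is_fallback``). Raises if every point's FDR is zero
    or undefined — the shuffled scores then carry no information and more
    shuffles are needed.
    """
    if not (0 < target < 1):
        raise ValueError("target must be in (0, 1)")
    finite = [(p, f) for p, f, _, _ in curve.points if not math.isnan(f)]
    if not any(f > 0 for _, f in finite):
        raise ValueError(
            "all FDR estimates are 0 or undefined; increase the number of "
            "shuffled catalogs or terms"
        )
    below = [(p, f) for p, f in finite if f < target]
    if below:
        p, f = max(below, key=lambda pf: pf[0])
        return OperativeThreshold(p=p, fdr=f, is_fallback=False)
    positive = [(p, f) for p, f in finite if f > 0]
    f_min = min(f for _, f in positive)
    p_at = max(p for p, f in positive if f == f_min)
    return OperativeThreshold(p=p_at, fdr=f_min, is_fallback=True)


@dataclass(frozen=True)
class SignificanceCall:
    significant: frozenset          # term identifiers
    fdr_level: float                # operative FDR level of the call
    is_fallback: bool               # True when the level exceeded the target
    p_threshold: Optional[float]    # largest p-value among called terms


def call_significant(
    real_scores: Sequence[ClusteringScore],
    shuffled_scores: ScoreSets,
    target: float = 0.001,
    fallback_cap: float = 10.0,
) -> SignificanceCall:
    """Call terms whose estimated FDR is under the target.

    A term is significant when its own FDR (the step curve evaluated at its
    p-value, inclusive counts) is below ``target``. When no term qualifies,
    the smallest FDR estimated above zero becomes the operative level — the
    published rule for runs whose estimates never dip under the target — but
    that fallback is honoured only while it stays within ``fallback_cap`` x
    ``target``; beyond that the estimate certifies nothing and no term is
    called, which keeps null inputs from yielding "significant" terms at
    estimated FDRs orders of magnitude above the target.
    """
    fdrs = term_fdrs(real_scores, shuffled_scores)
    called = {t for t, f in fdrs.items() if f < target}
    level, fallback = target, False
    if not called:
        positive = sorted(f for f in fdrs.values() if f > 0)
        if positive and positive[0] <= fallback_cap * target:
            level, fallback = positive[0], True
            called = {t for t, f in fdrs.items() if f <= level}
        else:
            if positive:
                logger.info(
                    "smallest positive FDR %.3g exceeds %.3g; no terms called",
                    positive[0], fallback_cap * target,
                )
            return SignificanceCall(significant=frozenset(), fdr_level=target,
                                    is_fallback=False, p_threshold=None)
    p_thr = max(s.p_value for s in real_scores if s.term in called)
    return SignificanceCall(significant=frozenset(called), fdr_level=level,
                            is_fallback=fallback, p_threshold=p_thr)


def term_fdrs(
    real_scores: Sequence[ClusteringScore],
    shuffled_scores: ScoreSets,
) -> dict[str, float]:
    """Per-term FDR with inclusive counts: (#shuffled <= p) / (#real <= p).

    This is the step curve evaluated just above each term's own p-value, so
    the denominator always includes the term itself and the value is finite.
    """
    real_p = _pvalues(real_scores)
    shuf_sets = [_pvalues(s) for s in _as_score_sets(shuffled_scores)]
    out: dict[str, float] = {}
    for s in real_scores:
        nr = int(np.searchsorted(real_p, s.p_value, side="right"))
        ns = float(np.mean([np.searchsorted(sp, s.p_value, side="right")
                            for sp in shuf_sets]))
        out[s.term] = ns / nr
    return out


@dataclass
class ResultRow:
    """One output line: a term's clustering score, FDR and verdicts."""

    term: str
    name: str
    namespace: str
    size_total: int
    size_in_network: int
    tpd: float
    p_value: float
    fdr: float
    significant: bool
    unique_to_weighted: Optional[bool] = None


def build_result_rows(
    real_scores: Sequence[ClusteringScore],
    shuffled_scores: ScoreSets,
    catalog,
    target: float = 0.001,
    fallback_cap: float = 10.0,
) -> tuple[list[ResultRow], SignificanceCall]:
    """Assemble per-term result rows from scores and shuffled-score sets."""
    call = call_significant(real_scores, shuffled_scores,
                            target=target, fallback_cap=fallback_cap)
    fdrs = term_fdrs(real_scores, shuffled_scores)
    rows = []
    for s in real_scores:
        rows.append(ResultRow(
            term=s.term,
            name=catalog.names.get(s.term, ""),
            namespace=catalog.namespaces.get(s.term, ""),
            size_total=len(catalog.terms[s.term]),
            size_in_network=s.size,
            tpd=s.tpd,
            p_value=s.p_value,
            fdr=fdrs[s.term],
            significant=s.term in call.significant,
        ))
    rows.sort(key=lambda r: (r.p_value, r.term))
    return rows, call


def contrast_results(
    weighted: Sequence[ResultRow],
    unweighted: Sequence[ResultRow],
) -> list[ResultRow]:
    """Flag weighted-significant terms absent from the unweighted calls.

    Returns all weighted rows with ``unique_to_weighted`` set; the unique
    terms are the method's final readout — annotations whose detection
    required the differential-expression weighting.
    """
    unweighted_sig = {r.term for r in unweighted if r.significant}
    return [
        replace(r, unique_to_weighted=(r.significant and r.term not in unweighted_sig))
        for r in weighted
    ]


def results_to_frame(rows: Sequence[ResultRow]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in rows])
    return df.rename(columns={"term": "term_id", "name": "term_name"})


def write_results_tsv(rows: Sequence[ResultRow], path) -> None:
    results_to_frame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
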