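"""Annotation catalogs: loading, network filtering and marginal-preserving
shuffling.

A catalog maps each term (e.g. a propagated GO term) to the set of proteins
it annotates. For the empirical FDR, term-protein associations are shuffled
by repeated pair swaps that exactly preserve both bipartite marginals: every
term keeps its set size and every protein keeps its number of annotations,
but which proteins carry which terms is randomised.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """An annotation file does not conform to GMT or two-column TSV."""


@dataclass
class AnnotationCatalog:
    """Term -> protein-set catalog with optional term names/namespaces."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    shuffled: bool = False

    @property
    def protein_counts(self) -> Counter:
        """Number of terms annotating each protein."""
        counts: Counter = Counter()
        for proteins in self.terms.values():
            counts.update(proteins)
        return counts

    @property
    def n_associations(self) -> int:
        return sum(len(s) for s in self.terms.values())

    def term_sizes(self) -> dict[str, int]:
        return {t: len(s) for t, s in self.terms.items()}

    def copy(self) -> "AnnotationCatalog":
        return AnnotationCatalog(
            terms={t: set(s) for t, s in self.terms.items()},
            names=dict(self.names),
            namespaces=dict(self.namespaces),
            shuffled=self.shuffled,
        )


def _norm(p: str) -> str:
    return p.strip().upper()


def load_annotations(stream: Iterable[str]) -> AnnotationCatalog:
    """Load a GMT (term, description, members...) or two-column TSV catalog.

    The format is sniffed per file: lines with three or more tab-separated
    fields are GMT records, two-field lines are (term, protein) pairs.
    Duplicate (term, protein) rows collapse silently. Annotations are assumed
    to be pre-propagated up the ontology.
    """
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 3:  # GMT
            term = fields[0].strip()
            if not term:
                raise FormatError(f"line {lineno}: empty term identifier")
            desc = fields[1].strip()
            members = {_norm(f) for f in fields[2:] if f.strip()}
            if not members:
                raise FormatError(f"line {lineno}: GMT record with no members")
            terms.setdefault(term, set()).update(members)
            if desc:
                # convention: "name|namespace" or plain name in the GMT
                # description slot
                if "|" in desc:
                    name, ns = desc.split("|", 1)
                    names[term] = name.strip()
                    namespaces[term] = ns.strip()
                else:
                    names[term] = desc
        elif len(fields) == 2:  # term<TAB>protein
            term, protein = fields[0].strip(), _norm(fields[1])
            if not term or not protein:
                raise FormatError(f"line {lineno}: empty term or protein field")
            terms.setdefault(term, set()).add(protein)
        else:
            raise FormatError(f"line {lineno}: expected 2 or >=3 tab-separated fields")
    return AnnotationCatalog(terms=terms, names=names, namespaces=namespaces)


def filter_annotations(
    catalog: AnnotationCatalog,
    network_vertices: Iterable[str],
    min_size: int = 3,
    max_size: int = 1000,
    min_coverage: float = 0.5,
) -> AnnotationCatalog:
    """Keep terms sized in [min_size, max_size] that the network represents.

    A term survives iff min_size <= |S_T| <= max_size, at least
    ``min_coverage`` of its proteins are network vertices, and the in-network
    part itself still has ``min_size`` proteins (null models only exist for
    sizes the bounds cover).
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not (0 < min_coverage <= 1):
        raise ValueError("min_coverage must be in (0, 1]")
    vertices = {_norm(v) for v in network_vertices}
    kept: dict[str, set[str]] = {}
    for term, proteins in catalog.terms.items():
        n = len(proteins)
        if not (min_size <= n <= max_size):
            continue
        in_net = proteins & vertices
        if len(in_net) / n < min_coverage:
            continue
        if len(in_net) < min_size:
            continue
        kept[term] = set(proteins)
    logger.info("annotation filter: %d of %d terms kept", len(kept), len(catalog.terms))
    return AnnotationCatalog(
        terms=kept,
        names={t: catalog.names[t] for t in kept if t in catalog.names},
        namespaces={t: catalog.namespaces[t] for t in kept if t in catalog.namespaces},
        shuffled=catalog.shuffled,
    )


def shuffle_annotations(
    catalog: AnnotationCatalog,
    n_swaps: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    swap_multiplier: int = 1000,
) -> AnnotationCatalog:
    """Randomise term-protein associations by repeated pair swaps.

    Each attempt draws two associations (T1, p1), (T2, p2) uniformly and
    exchanges their proteins. The attempt is rejected (but still consumed)
    when T1 = T2, or when either term already annotates the other protein,
    which keeps all sets duplicate-free. Both marginals — per-term set sizes
    and per-protein annotation counts — are preserved exactly.

    ``n_swaps`` defaults to ``swap_multiplier`` x the number of associations.
    """
    if rng is None:
        rng = np.random.default_rng()
    out = catalog.copy()
    out.shuffled = True

    assoc_term: list[str] = []
    assoc_prot: list[str] = []
    for term, proteins in out.terms.items():
        for p in sorted(proteins):  # sorted: bit-reproducible given the seed
            assoc_term.append(term)
            assoc_prot.append(p)
    n_assoc = len(assoc_term)
    if n_assoc < 2:
        logger.warning("catalog has < 2 associations; returning unchanged copy")
        return out
    if n_swaps is None:
        n_swaps = swap_multiplier * n_assoc
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")

    sets = out.terms
    block = 65536
    done = 0
    while done < n_swaps:
        k = min(block, n_swaps - done)
        draws = rng.integers(0, n_assoc, size=(k, 2))
        for i, j in draws:
            t1, p1 = assoc_term[i], assoc_prot[i]
            t2, p2 = assoc_term[j], assoc_prot[j]
            if t1 == t2 or p1 in sets[t2] or p2 in sets[t1]:
                continue
            s1, s2 = sets[t1], sets[t2]
            s1.remove(p1)
            s2.remove(p2)
            s1.add(p2)
            s2.add(p1)
            assoc_prot[i], assoc_prot[j] = p2, p1
        done += k
    return out
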