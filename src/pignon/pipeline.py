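"""End-to-end orchestration: build -> weight -> distances -> null models ->
scoring -> shuffling/FDR -> weighted-vs-unweighted contrast.

Both network passes (expression-weighted and all-ones) run from one config;
their significant-term sets are contrasted to flag the terms unique to the
weighted analysis. Null models are cached as TSV keyed by a digest of the
weighted edge list, and a run manifest records every parameter, seed and
input digest needed to reproduce the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from pignon import annotations as ann
from pignon import clustering as clu
from pignon import expression as expr
from pignon import network_io as nio
from pignon import significance as sig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one run; defaults mirror the published analysis."""

    network_file: str = ""
    network_format: str = "edges"          # edges | biogrid | string
    annotation_file: str = ""
    expression_file: Optional[str] = None
    condition_file: Optional[str] = None
    cond_num: Optional[str] = None         # numerator condition label
    cond_den: Optional[str] = None
    fold_change_file: Optional[str] = None # alternative to the three above

    taxon: int = 9606
    string_min_score: int = 400
    physical_only: bool = False
    hub_cutoff: int = 1000
    relcc: bool = True

    min_size: int = 3
    max_size: int = 1000
    min_coverage: float = 0.5

    sampling_mode: str = "weighted"        # null-model sampling: weighted | unweighted
    n_samples: int = 1_000_000             # per set size (10x fewer than the full-scale 10^7)
    swap_multiplier: int = 1000            # swaps = multiplier x associations
    n_shuffles: int = 1                    # shuffled catalogs averaged in the FDR
    fdr_target: float = 0.001
    fallback_cap: float = 10.0             # accept fallback FDR up to cap x target

    seed: int = 0
    out_dir: str = "pignon_out"
    cache_nulls: bool = True

    def validate(self) -> None:
        for path in (self.network_file, self.annotation_file):
            if not path or not os.path.exists(path):
                raise FileNotFoundError(f"input file not found: {path!r}")
        if self.fold_change_file is None:
            for path in (self.expression_file, self.condition_file):
                if not path or not os.path.exists(path):
                    raise FileNotFoundError(f"input file not found: {path!r}")
            if not (self.cond_num and self.cond_den):
                raise ValueError("cond_num and cond_den are required with an expression table")
        elif not os.path.exists(self.fold_change_file):
            raise FileNotFoundError(f"input file not found: {self.fold_change_file!r}")
        if self.network_format not in ("edges", "biogrid", "string"):
            raise ValueError(f"unknown network format {self.network_format!r}")
        if self.sampling_mode not in ("weighted", "unweighted"):
            raise ValueError(f"unknown sampling mode {self.sampling_mode!r}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class PipelineResult:
    weighted_rows: list
    unweighted_rows: list
    contrast_rows: list
    calls: dict
    output_files: dict[str, str] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def _file_digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@_stage("network")
def _load_network(cfg: RunConfig):
    with open(cfg.network_file) as fh:
        if cfg.network_format == "biogrid":
            records = nio.parse_biogrid(fh, taxon=cfg.taxon, physical_only=cfg.physical_only)
        elif cfg.network_format == "string":
            records = nio.parse_string(fh, min_score=cfg.string_min_score)
        else:
            records = nio.read_edge_tsv(fh)
    return nio.build_network(records, hub_cutoff=cfg.hub_cutoff, relcc=cfg.relcc)


@_stage("fold-changes")
def _load_fold_changes(cfg: RunConfig) -> dict[str, float]:
    if cfg.fold_change_file is not None:
        return expr.read_fold_changes_tsv(cfg.fold_change_file)
    table = expr.read_expression_tsv(cfg.expression_file)
    cond_map = expr.read_condition_map(cfg.condition_file)
    return expr.compute_fold_changes(table, cond_map, cfg.cond_num, cfg.cond_den)


@_stage("annotations")
def _load_catalog(cfg: RunConfig, network) -> ann.AnnotationCatalog:
    with open(cfg.annotation_file) as fh:
        catalog = ann.load_annotations(fh)
    filtered = ann.filter_annotations(
        catalog, network.nodes,
        min_size=cfg.min_size, max_size=cfg.max_size, min_coverage=cfg.min_coverage,
    )
    if not filtered.terms:
        raise ValueError("no annotation terms survive the network filter")
    return filtered


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run both network passes and the contrast; write result TSVs.

    Outputs under ``config.out_dir``: ``results_weighted.tsv``,
    ``results_unweighted.tsv``, ``results_contrast.tsv`` (weighted rows with
    the unique-to-weighted flag), cached null models and ``manifest.json``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    network = _load_network(config)
    fold_changes = _load_fold_changes(config)
    catalog = _load_catalog(config, network)

    shuffle_rng = np.random.default_rng(rng.integers(2**31))
    shuffled_catalogs = [
        ann.filter_annotations(
            ann.shuffle_annotations(catalog, rng=shuffle_rng,
                                    swap_multiplier=config.swap_multiplier),
            network.nodes,
            min_size=config.min_size, max_size=config.max_size,
            min_coverage=config.min_coverage,
        )
        for _ in range(config.n_shuffles)
    ]

    counts = catalog.protein_counts
    eligible = sorted(v for v in network.nodes if counts.get(v, 0) > 0)
    weights = ({p: float(counts[p]) for p in eligible}
               if config.sampling_mode == "weighted" else None)

    vertices = set(network.nodes)
    sizes: set[int] = set()
    for cat in [catalog, *shuffled_catalogs]:
        for proteins in cat.terms.values():
            sizes.add(len(proteins & vertices))

    rows_by_mode: dict[str, list] = {}
    calls: dict[str, sig.SignificanceCall] = {}
    out_files: dict[str, str] = {}
    for mode in ("weighted", "unweighted"):
        wn = expr.weight_network(network, fold_changes, mode=mode)
        dist = clu.all_pairs_distances(wn)
        null = _null_model_cached(config, wn, dist, eligible, sizes, weights, rng)
        real_scores = clu.score_terms(dist, catalog, null)
        shuffled_scores = [clu.score_terms(dist, c, null) for c in shuffled_catalogs]
        rows, call = sig.build_result_rows(
            real_scores, shuffled_scores, catalog,
            target=config.fdr_target, fallback_cap=config.fallback_cap,
        )
        rows_by_mode[mode] = rows
        calls[mode] = call
        path = os.path.join(config.out_dir, f"results_{mode}.tsv")
        sig.write_results_tsv(rows, path)
        out_files[mode] = path
        logger.info("%s pass: %d terms scored, %d significant",
                    mode, len(rows), sum(r.significant for r in rows))

    contrast = sig.contrast_results(rows_by_mode["weighted"], rows_by_mode["unweighted"])
    contrast_path = os.path.join(config.out_dir, "results_contrast.tsv")
    sig.write_results_tsv(contrast, contrast_path)
    out_files["contrast"] = contrast_path

    manifest = {
        "config": dataclasses.asdict(config),
        "input_digests": {
            k: _file_digest(p)
            for k, p in {
                "network": config.network_file,
                "annotations": config.annotation_file,
                "expression": config.expression_file,
                "conditions": config.condition_file,
                "fold_changes": config.fold_change_file,
            }.items()
            if p
        },
        "n_terms_tested": len(catalog.terms),
        "n_significant": {m: sum(r.significant for r in rows_by_mode[m])
                          for m in rows_by_mode},
        "n_unique_to_weighted": sum(bool(r.unique_to_weighted) for r in contrast),
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    out_files["manifest"] = manifest_path

    return PipelineResult(
        weighted_rows=rows_by_mode["weighted"],
        unweighted_rows=rows_by_mode["unweighted"],
        contrast_rows=contrast,
        calls=calls,
        output_files=out_files,
    )


def _null_model_cached(config, wn, dist, eligible, sizes, weights, rng) -> clu.NullModel:
    mode = "weighted" if weights is not None else "unweighted"
    cache_path = os.path.join(
        config.out_dir,
        f"null_{clu.network_digest(wn)}_{mode}_{config.n_samples}.tsv",
    )
    if config.cache_nulls and os.path.exists(cache_path):
        cached = clu.NullModel.from_tsv(cache_path)
        if cached.covers(sizes):
            logger.info("null model reused from %s", cache_path)
            # keep the rng stream identical whether or not the cache hit
            np.random.default_rng(rng.integers(2**31))
            return cached
    null_rng = np.random.default_rng(rng.integers(2**31))
    null = clu.build_null_model(dist, eligible, sizes, config.n_samples,
                                null_rng, weights=weights)
    if config.cache_nulls:
        null.to_tsv(cache_path)
    return null
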