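"""Orchestration of the dual-mode screening framework.

The differential mode pairs every enrichment approach with every two-group
test against binary activation/inhibition labels; the correlative mode pairs
them with every correlation test against a continuous state.  Unsupervised
scorers are tested at the signature-score level; the two supervised
approaches (preranked GSEA, ORA) consume the same association method applied
gene-wise.  Per-direction one-sided p-values are combined within each
dataset by the twelve combiners, geometric-mean combined across datasets,
and transformed into the ADI/IDI/DI ranking.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (BinaryLabels, ContinuousState, ExpressionDataset, RunConfig,
                         SignatureCollection, validate_inputs)
from .enrichment import (ALL_SCORERS, SUPERVISED_SCORERS, UNSUPERVISED_SCORERS,
                         GeneRanking, assess_collinearity, fgsea_test, ora_test,
                         score_signatures)
from .association import (COR_TESTS, DIFF_TESTS, correlation_stats_matrix,
                          differential_stats_matrix, two_to_one)
from .combine import (COMBINERS, DirectionalityTable, build_directionality_table,
                      combine_across_datasets, combine_within_dataset)

logger = logging.getLogger("metascreener")


@dataclass(frozen=True)
class PipelineSpec:
    scorer: str
    test: str
    supervised: bool


def _resolve_registry(config: RunConfig) -> tuple[list[str], list[str]]:
    scorers = config.scorers if config.scorers is not None else list(ALL_SCORERS)
    unknown = set(scorers) - set(ALL_SCORERS)
    if unknown:
        raise ValueError(f"unknown scorers {sorted(unknown)}")
    if config.mode == "cor":
        tests = config.cor_tests if config.cor_tests is not None else list(COR_TESTS)
        unknown = set(tests) - set(COR_TESTS)
    else:
        tests = config.diff_tests if config.diff_tests is not None else list(DIFF_TESTS)
        unknown = set(tests) - set(DIFF_TESTS)
    if unknown:
        raise ValueError(f"unknown association tests {sorted(unknown)}")
    if not scorers or not tests:
        raise ValueError("enabled scorer/test sets must be non-empty")
    return scorers, tests


def enumerate_pipelines(config: RunConfig) -> list[PipelineSpec]:
    """Every (scorer x association test) pair enabled by the configuration."""
    if config.mode not in ("diff", "cor"):
        raise ValueError("pipeline enumeration requires mode 'diff' or 'cor'")
    scorers, tests = _resolve_registry(config)
    return [PipelineSpec(s, t, s in SUPERVISED_SCORERS) for s in scorers for t in tests]


def _stable_seed(base: int, *keys: str) -> int:
    h = zlib.crc32("|".join(keys).encode())
    return int((base * 1_000_003 + h) % (2 ** 31 - 1))


def _gene_level_ranking(dataset: ExpressionDataset, test: str, config: RunConfig,
                        mode: str) -> tuple[GeneRanking, dict[str, np.ndarray]]:
    """Gene-wise association statistics turned into a signed ranking statistic:
    -log10(p) x log2FC in differential mode, -log10(p) x r (or slope) in
    correlative mode."""
    X = dataset.matrix
    if mode == "diff":
        if config.linear_scale:
            X = np.log2(X + 1.0)
        mask = dataset.annotation.mask(dataset.samples)
        d = differential_stats_matrix(X, mask, test, n_perm=config.n_perm_assoc,
                                      seed=_stable_seed(config.seed, dataset.name, test, "genes"))
    else:
        y = dataset.annotation.vector(dataset.samples)
        d = correlation_stats_matrix(X, y, test, n_perm=config.n_perm_assoc,
                                     seed=_stable_seed(config.seed, dataset.name, test, "genes"))
    stat = -np.log10(np.maximum(d["p_two"], 1e-300)) * d["effect"]
    s = pd.Series(stat, index=dataset.genes)
    return GeneRanking(s, provenance=f"{dataset.name}:{test}"), d


def _ora_lists(d: dict[str, np.ndarray], genes: list[str], top_k: int,
               mode: str) -> tuple[list[str], list[str]]:
    """Directional top-k gene lists: ranked by ascending p within direction in
    differential mode, by coefficient magnitude within direction in
    correlative mode."""
    effect, p = d["effect"], d["p_two"]
    genes = np.asarray(genes)
    up, dn = effect > 0, effect < 0
    if mode == "diff":
        key_up = p[up]
        key_dn = p[dn]
    else:
        key_up = -np.abs(effect[up])
        key_dn = -np.abs(effect[dn])
    up_sorted = genes[up][np.argsort(key_up, kind="stable")]
    dn_sorted = genes[dn][np.argsort(key_dn, kind="stable")]
    return list(up_sorted[:top_k]), list(dn_sorted[:top_k])


def _dataset_direction_lists(dataset: ExpressionDataset, signatures: SignatureCollection,
                             retained: list[str], scorers: list[str], tests: list[str],
                             config: RunConfig, mode: str) -> dict[str, tuple[list, list]]:
    """All per-pipeline (p_act, p_inh) pairs for one dataset, keyed by signature."""
    lists: dict[str, tuple[list, list]] = {s: ([], []) for s in retained}
    sigs = signatures.subset(retained)

    active_scorers = list(scorers)
    if ("mlm" in active_scorers or "mdt" in active_scorers) and len(retained) >= 2:
        rep = assess_collinearity(sigs, universe=dataset.genes)
        if not rep.multivariate_safe:
            active_scorers = [s for s in active_scorers if s not in ("mlm", "mdt")]
            logger.info("dataset %s: mlm/mdt disabled (collinear signatures)", dataset.name)

    if mode == "diff":
        mask = dataset.annotation.mask(dataset.samples)
    else:
        state = dataset.annotation.vector(dataset.samples)

    for scorer in active_scorers:
        if scorer in SUPERVISED_SCORERS:
            continue
        sm = score_signatures(dataset, sigs, scorer, config,
                              seed=_stable_seed(config.seed, dataset.name, scorer))
        S = sm.values.to_numpy()
        for test in tests:
            seed = _stable_seed(config.seed, dataset.name, scorer, test)
            if mode == "diff":
                d = differential_stats_matrix(S, mask, test,
                                              n_perm=config.n_perm_assoc, seed=seed)
            else:
                d = correlation_stats_matrix(S, state, test,
                                             n_perm=config.n_perm_assoc, seed=seed)
            for i, sig in enumerate(sm.signatures):
                dp = two_to_one(float(d["p_two"][i]), int(d["direction"][i]))
                lists[sig][0].append(dp.p_act)
                lists[sig][1].append(dp.p_inh)

    supervised = [s for s in active_scorers if s in SUPERVISED_SCORERS]
    if supervised:
        for test in tests:
            ranking, d = _gene_level_ranking(dataset, test, config, mode)
            if "fgsea" in supervised:
                for sig in retained:
                    try:
                        _, _, p_two, direction = fgsea_test(
                            ranking, sigs[sig], n_perm=config.n_perm_fgsea,
                            seed=_stable_seed(config.seed, dataset.name, "fgsea", test, sig))
                    except ValueError as exc:
                        logger.warning("fgsea %s/%s/%s skipped: %s",
                                       dataset.name, test, sig, exc)
                        continue
                    dp = two_to_one(p_two, direction)
                    lists[sig][0].append(dp.p_act)
                    lists[sig][1].append(dp.p_inh)
            if "ora" in supervised:
                top_k = min(config.ora_top_k, len(dataset.genes) // 2)
                up, dn = _ora_lists(d, dataset.genes, top_k, mode)
                for sig in retained:
                    p_act, p_inh, _, _ = ora_test(up, dn, sigs[sig], dataset.genes)
                    lists[sig][0].append(min(p_act, 1.0 - 1e-16))
                    lists[sig][1].append(min(p_inh, 1.0 - 1e-16))
    return lists


def _run(datasets: list[ExpressionDataset], signatures: SignatureCollection,
         config: RunConfig, mode: str) -> DirectionalityTable:
    config_mode = RunConfig(**{**config.__dict__, "mode": mode})
    report = validate_inputs(datasets, signatures, config_mode)
    usable = []
    for ds in datasets:
        if ds.name in report.excluded_datasets:
            logger.warning("dataset %s dropped: %s", ds.name,
                           report.excluded_datasets[ds.name])
        else:
            usable.append(ds)
    if not usable:
        raise ValueError("no usable datasets after validation")
    scorers, tests = _resolve_registry(config_mode)
    combiners = config.combiners if config.combiners is not None else list(COMBINERS)

    per_dataset: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for ds in sorted(usable, key=lambda d: d.name):
        retained = report.retained_signatures(ds.name, signatures)
        if not retained:
            logger.warning("dataset %s: no signature passes coverage; skipped", ds.name)
            continue
        lists = _dataset_direction_lists(ds, signatures, retained, scorers, tests,
                                         config_mode, mode)
        per_dataset[ds.name] = {
            sig: combine_within_dataset(pa, pi, combiners,
                                        invt_df=config.invt_df,
                                        votep_alpha=config.votep_alpha,
                                        wilkinson_r=config.wilkinson_r)
            for sig, (pa, pi) in lists.items() if pa
        }
    if not per_dataset:
        raise ValueError("no dataset produced pipeline results")

    per_signature: dict[str, dict[str, tuple[float, float]]] = {}
    for sig in signatures.names:
        entries = [per_dataset[d][sig] for d in per_dataset if sig in per_dataset[d]]
        if entries:
            per_signature[sig] = combine_across_datasets(entries)
    return build_directionality_table(per_signature, per_dataset)


def diff_metascreener(datasets: list[ExpressionDataset], signatures: SignatureCollection,
                      config: RunConfig | None = None) -> DirectionalityTable:
    """Differential-mode screen: binary labels, two-group association tests."""
    return _run(datasets, signatures, config or RunConfig(mode="diff"), "diff")


def cor_metascreener(datasets: list[ExpressionDataset], signatures: SignatureCollection,
                     config: RunConfig | None = None) -> DirectionalityTable:
    """Correlative-mode screen: continuous states, correlation tests."""
    return _run(datasets, signatures, config or RunConfig(mode="cor"), "cor")


def unsupervised_score(datasets: list[ExpressionDataset], signatures: SignatureCollection,
                       contrasts: dict[str, dict[str, BinaryLabels | ContinuousState]],
                       config: RunConfig | None = None) -> dict[str, DirectionalityTable]:
    """Run one screen per user-defined contrast (label set or reference state
    per dataset), e.g. one hallmark panel per subtype-vs-rest contrast."""
    config = config or RunConfig()
    out = {}
    for cname, per_ds in contrasts.items():
        redecorated = []
        for ds in datasets:
            if ds.name not in per_ds:
                continue
            redecorated.append(ExpressionDataset(ds.name, ds.values, per_ds[ds.name]))
        if not redecorated:
            raise ValueError(f"contrast {cname!r} matches no dataset")
        kinds = {type(d.annotation) for d in redecorated}
        if kinds == {BinaryLabels}:
            out[cname] = diff_metascreener(redecorated, signatures, config)
        elif kinds == {ContinuousState}:
            out[cname] = cor_metascreener(redecorated, signatures, config)
        else:
            raise ValueError(f"contrast {cname!r} mixes label and state annotations")
    return out
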