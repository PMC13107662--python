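"""Perturbation scenarios and the Pearson-consistency robustness metric.

Robustness is measured by rerunning a screen on perturbed inputs and
correlating the perturbed DI vector with the original one.  The scenarios
cover dataset exclusion, random gene loss, additive/multiplicative Gaussian
noise with zero-thresholding, random elimination of enrichment methods or
combiners, per-method single-pipeline cycles, and an extreme loss-plus-noise
stress test with matched single-dataset/single-method baselines.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, RunConfig, SignatureCollection
from .enrichment import SUPERVISED_SCORERS, UNSUPERVISED_SCORERS, ALL_SCORERS
from .combine import COMBINERS, DirectionalityTable
from .screener import cor_metascreener, diff_metascreener

logger = logging.getLogger("metascreener")

KINDS = ("drop_datasets", "drop_genes", "gaussian_noise", "drop_scorers",
         "drop_combiners", "single_scorer", "single_combiner", "extreme")


@dataclass
class PerturbationSpec:
    kind: str
    repetitions: int = 30
    base_seed: int = 0
    drop_count: int = 3                 # drop_datasets
    gene_fraction: float = 0.3          # drop_genes / extreme
    noise_mean: float = 0.0
    noise_sd_range: tuple[float, float] = (0.05, 0.2)
    noise_proportion_range: tuple[float, float] = (0.0, 1.0)
    scorer_fraction: float = 0.3        # drop_scorers
    combiner_count: int = 4             # drop_combiners

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.noise_sd_range[0] > self.noise_sd_range[1]:
            raise ValueError("noise sd range must satisfy low <= high")


def default_scenarios(repetitions: int = 30, base_seed: int = 0) -> dict[str, PerturbationSpec]:
    """The seven evaluation scenarios plus the extreme stress test."""
    def mk(kind, **kw):
        kw.setdefault("repetitions", repetitions)
        return PerturbationSpec(kind, base_seed=base_seed, **kw)
    return {
        "drop_datasets": mk("drop_datasets", drop_count=3),
        "drop_genes": mk("drop_genes", gene_fraction=0.3),
        "gaussian_noise": mk("gaussian_noise"),
        "drop_scorers": mk("drop_scorers"),
        "drop_combiners": mk("drop_combiners"),
        "single_scorer": mk("single_scorer"),
        "single_combiner": mk("single_combiner", repetitions=len(COMBINERS)),
        "extreme": mk("extreme", gene_fraction=0.7, noise_mean=1.0,
                      noise_sd_range=(1.0, 2.0), noise_proportion_range=(0.5, 1.0)),
    }


@dataclass
class ConsistencyResult:
    scenario: str
    r_values: list[float]

    @property
    def median(self) -> float:
        arr = np.asarray([r for r in self.r_values if np.isfinite(r)])
        return float(np.median(arr)) if len(arr) else float("nan")

    @property
    def iqr(self) -> tuple[float, float]:
        arr = np.asarray([r for r in self.r_values if np.isfinite(r)])
        if not len(arr):
            return (float("nan"), float("nan"))
        return (float(np.percentile(arr, 25)), float(np.percentile(arr, 75)))


def _noise_one(X: np.ndarray, rng: np.random.Generator, mean: float,
               sd_range: tuple[float, float], prop_range: tuple[float, float],
               multiplicative: bool) -> np.ndarray:
    """Gaussian noise on a random fraction of entries, then zero-thresholding.

    The sd and the perturbed-entry proportion are drawn per dataset."""
    sd = rng.uniform(*sd_range)
    rho = rng.uniform(*prop_range)
    if rho == 0.0:
        return X
    mask = rng.random(X.shape) < rho
    eps = rng.normal(mean, sd, size=X.shape)
    if multiplicative:
        Y = np.where(mask, X * (1.0 + eps), X)
    else:
        Y = np.where(mask, X + eps, X)
    return np.maximum(Y, 0.0)


def perturb(datasets: list[ExpressionDataset], spec: PerturbationSpec, rep_index: int,
            config: RunConfig) -> tuple[list[ExpressionDataset], RunConfig]:
    """One perturbation draw, fully determined by (base seed, rep index).

    Data-level kinds return modified datasets; registry-level kinds return a
    modified configuration instead.  For the noise kinds the first half of
    the repetitions is additive, the second half multiplicative.
    """
    if rep_index >= spec.repetitions:
        raise ValueError("rep_index out of range")
    rng = np.random.default_rng([spec.base_seed % (2 ** 31), rep_index])
    multiplicative = rep_index >= spec.repetitions // 2

    if spec.kind == "drop_datasets":
        if spec.drop_count >= len(datasets):
            raise ValueError("cannot drop all datasets")
        keep = sorted(rng.choice(len(datasets), size=len(datasets) - spec.drop_count,
                                 replace=False))
        return [datasets[i] for i in keep], config
    if spec.kind == "drop_genes":
        out = []
        for ds in datasets:
            n_keep = len(ds.genes) - int(np.floor(spec.gene_fraction * len(ds.genes)))
            keep = np.sort(rng.choice(len(ds.genes), size=n_keep, replace=False))
            out.append(ds.with_values(ds.values.iloc[keep]))
        return out, config
    if spec.kind == "gaussian_noise":
        out = []
        for ds in datasets:
            Y = _noise_one(ds.matrix, rng, spec.noise_mean, spec.noise_sd_range,
                           spec.noise_proportion_range, multiplicative)
            out.append(ds.with_values(pd.DataFrame(Y, index=ds.genes, columns=ds.samples)))
        return out, config
    if spec.kind == "extreme":
        out = []
        for ds in datasets:
            n_keep = len(ds.genes) - int(np.floor(spec.gene_fraction * len(ds.genes)))
            keep = np.sort(rng.choice(len(ds.genes), size=n_keep, replace=False))
            sub = ds.values.iloc[keep]
            Y = _noise_one(sub.to_numpy(), rng, spec.noise_mean, spec.noise_sd_range,
                           spec.noise_proportion_range, multiplicative)
            out.append(ds.with_values(pd.DataFrame(Y, index=sub.index, columns=sub.columns)))
        return out, config
    if spec.kind == "drop_scorers":
        enabled = config.scorers if config.scorers is not None else list(ALL_SCORERS)
        n_drop = min(int(np.floor(spec.scorer_fraction * len(enabled))), len(enabled) - 1)
        drop = set(rng.choice(len(enabled), size=n_drop, replace=False))
        return datasets, replace(config, scorers=[s for i, s in enumerate(enabled)
                                                  if i not in drop])
    if spec.kind == "drop_combiners":
        enabled = config.combiners if config.combiners is not None else list(COMBINERS)
        n_drop = min(spec.combiner_count, len(enabled) - 1)
        drop = set(rng.choice(len(enabled), size=n_drop, replace=False))
        return datasets, replace(config, combiners=[c for i, c in enumerate(enabled)
                                                    if i not in drop])
    if spec.kind == "single_scorer":
        enabled = config.scorers if config.scorers is not None else list(ALL_SCORERS)
        return datasets, replace(config, scorers=[enabled[rep_index % len(enabled)]])
    if spec.kind == "single_combiner":
        enabled = config.combiners if config.combiners is not None else list(COMBINERS)
        return datasets, replace(config, combiners=[enabled[rep_index % len(enabled)]])
    raise AssertionError(spec.kind)


def consistency(di_original: pd.Series, di_perturbed: pd.Series) -> float:
    """Pearson correlation of the two DI vectors over shared signatures."""
    common = di_original.index.intersection(di_perturbed.index)
    if len(common) < 3:
        raise ValueError("consistency needs >=3 shared signatures")
    a = di_original.loc[common].to_numpy()
    b = di_perturbed.loc[common].to_numpy()
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("constant DI vector: consistency undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _screen(datasets: list[ExpressionDataset], signatures: SignatureCollection,
            config: RunConfig) -> DirectionalityTable:
    runner = cor_metascreener if config.mode == "cor" else diff_metascreener
    return runner(datasets, signatures, config)


def run_scenarios(datasets: list[ExpressionDataset], signatures: SignatureCollection,
                  config: RunConfig, specs: dict[str, PerturbationSpec],
                  original: DirectionalityTable | None = None
                  ) -> dict[str, ConsistencyResult]:
    """Perturb-rerun-correlate loop for each scenario.

    The signature-coverage gate is disabled for the reruns: the protocol
    deliberately evaluates a fixed signature panel on degraded data (under
    70% gene loss every signature would otherwise fall below any sensible
    coverage threshold and the comparison would be empty)."""
    config = replace(config, min_set_coverage=0.0)
    if original is None:
        original = _screen(datasets, signatures, config)
    out = {}
    for name, spec in specs.items():
        rs = []
        for rep in range(spec.repetitions):
            pert_ds, pert_cfg = perturb(datasets, spec, rep, config)
            table = _screen(pert_ds, signatures, pert_cfg)
            rs.append(consistency(original.di, table.di))
        out[name] = ConsistencyResult(name, rs)
    return out


def benchmark_single_pipelines(datasets: list[ExpressionDataset],
                               signatures: SignatureCollection, config: RunConfig,
                               extreme_spec: PerturbationSpec,
                               repetitions: int = 30,
                               scorers: list[str] | None = None) -> pd.DataFrame:
    """Traditional single-dataset / single-method baseline under extreme stress.

    For each enrichment method: repeatedly pick one dataset at random, apply
    the extreme perturbation, run that lone method's pipelines on it, and
    correlate with the same lone pipeline's unperturbed result.  Rows are
    repetitions, columns methods.
    """
    config = replace(config, min_set_coverage=0.0)   # as in run_scenarios
    scorers = scorers or (config.scorers if config.scorers is not None else list(ALL_SCORERS))
    baseline_cache: dict[tuple[str, str], pd.Series] = {}
    rows = {}
    for scorer in scorers:
        single_cfg = replace(config, scorers=[scorer])
        rs = []
        for rep in range(repetitions):
            rng = np.random.default_rng([extreme_spec.base_seed % (2 ** 31),
                                         zlib.crc32(scorer.encode()), rep])
            ds = datasets[int(rng.integers(len(datasets)))]
            key = (scorer, ds.name)
            if key not in baseline_cache:
                baseline_cache[key] = _screen([ds], signatures, single_cfg).di
            rep_spec = replace(extreme_spec, base_seed=int(rng.integers(2 ** 31)))
            pert_ds, _ = perturb([ds], rep_spec, rep % rep_spec.repetitions, single_cfg)
            table = _screen(pert_ds, signatures, single_cfg)
            rs.append(consistency(baseline_cache[key], table.di))
        rows[scorer] = rs
    return pd.DataFrame(rows)
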