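"""Canned evaluation protocols on synthetic cohorts.

These encode the package's standard benchmark conditions: planted-signal
recovery in both screening modes, the perturbation-robustness comparison
(moderate gene loss vs. extreme loss plus strong noise, framework vs.
single-dataset/single-method baselines), and the end-to-end directional
drug-screen recovery.  Problem sizes are fixed here so that results are
comparable across runs; every function is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data_model import ExpressionDataset, RunConfig
from .screener import cor_metascreener, diff_metascreener
from .robustness import (PerturbationSpec, benchmark_single_pipelines,
                         consistency, perturb, run_scenarios)
from .drug_screen import (DRUG_SCREEN_SCORERS, DRUG_SCREEN_TESTS,
                          consensus_drugs, derive_drug_signatures,
                          directional_drug_screen)
from .synthetic import generate_cohort, generate_drug_panel

# reduced-but-representative registry: rank-based, standardization-based,
# summary and model-based single-sample scorers plus both supervised methods
RECOVERY_SCORERS = ["zscore", "mean", "ssgsea", "aucell", "ucell", "viper",
                    "ulm", "fgsea", "ora"]
RECOVERY_DIFF_TESTS = ["ttest", "wilcoxon", "limma"]
RECOVERY_COR_TESTS = ["pearson", "spearman", "kendall"]


def recovery_run(seed: int, mode: str) -> dict:
    """One planted-signal recovery run: 5 datasets of 1000 genes x 100
    samples, 10 signatures of 30 genes (one activated, one inhibited, eight
    decoys), effect size 2 gene-level standard deviations."""
    gen_mode = "binary" if mode == "diff" else "continuous"
    datasets, signatures, truth = generate_cohort(
        n_datasets=5, n_genes=1000, n_samples=100,
        signature_sizes=[30] * 10, directions=[1, -1] + [0] * 8,
        effect_size=2.0, mode=gen_mode, seed=seed)
    config = RunConfig(mode=mode, seed=seed, scorers=list(RECOVERY_SCORERS),
                       diff_tests=list(RECOVERY_DIFF_TESTS),
                       cor_tests=list(RECOVERY_COR_TESTS),
                       n_perm_assoc=200, n_perm_fgsea=200, n_perm_scorer=50)
    runner = diff_metascreener if mode == "diff" else cor_metascreener
    table = runner(datasets, signatures, config)
    activated = next(s for s, d in truth.directions.items() if d == 1)
    inhibited = next(s for s, d in truth.directions.items() if d == -1)
    di = table.di
    return {
        "activated": activated, "inhibited": inhibited,
        "di_activated": float(di[activated]), "di_inhibited": float(di[inhibited]),
        "rank_activated": int(table.table.loc[activated, "rank"]),
        "rank_inhibited": int(table.table.loc[inhibited, "rank"]),
        "n_signatures": len(di),
    }


def recovery_success(result: dict) -> bool:
    """Activated first with positive DI and inhibited last with negative DI."""
    return (result["rank_activated"] == 1 and result["di_activated"] > 0
            and result["rank_inhibited"] == result["n_signatures"]
            and result["di_inhibited"] < 0)


def _robustness_setup(seed: int):
    datasets, signatures, _ = generate_cohort(
        n_datasets=3, n_genes=400, n_samples=60,
        signature_sizes=[25] * 8, directions=[1, -1] + [0] * 6,
        effect_size=2.0, seed=seed)
    config = RunConfig(mode="diff", seed=seed,
                       scorers=["zscore", "mean", "ssgsea", "ulm"],
                       diff_tests=["ttest", "wilcoxon"],
                       n_perm_assoc=100, n_perm_scorer=50)
    return datasets, signatures, config


def robustness_experiment(seed: int, repetitions: int = 10) -> dict:
    """Consistency under moderate vs. extreme perturbation, plus the
    single-dataset/single-method baseline under the extreme perturbation.

    Returns the median Pearson consistency of: 30% random gene removal,
    the extreme scenario (70% gene removal followed by strong noise), and
    the per-scorer single-pipeline baselines under the same extreme
    perturbation."""
    datasets, signatures, config = _robustness_setup(seed)
    specs = {
        "drop_genes": PerturbationSpec("drop_genes", gene_fraction=0.3,
                                       repetitions=repetitions, base_seed=seed),
        "extreme": PerturbationSpec("extreme", gene_fraction=0.7, noise_mean=1.0,
                                    noise_sd_range=(1.0, 2.0),
                                    noise_proportion_range=(0.5, 1.0),
                                    repetitions=repetitions, base_seed=seed),
    }
    scen = run_scenarios(datasets, signatures, config, specs)
    baseline = benchmark_single_pipelines(datasets, signatures, config,
                                          specs["extreme"], repetitions=repetitions)
    per_scorer_medians = baseline.median(axis=0)
    return {
        "median_drop_genes": scen["drop_genes"].median,
        "median_extreme": scen["extreme"].median,
        "baseline_median_of_medians": float(per_scorer_medians.median()),
        "per_scorer_baseline_medians": per_scorer_medians.to_dict(),
    }


def _module_tracking_datasets(module: list[str], n_genes: int, n_datasets: int,
                              n_samples: int, effect: float, seed: int
                              ) -> list[ExpressionDataset]:
    """Screen cohorts on the panel's gene universe whose module genes track a
    latent sample state (the screening phenotype)."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    idx = [genes.index(g) for g in module]
    out = []
    for d in range(n_datasets):
        mu = rng.uniform(2.0, 10.0, n_genes)
        sigma = rng.uniform(0.5, 1.5, n_genes)
        X = rng.normal(mu[:, None], sigma[:, None], size=(n_genes, n_samples))
        latent = rng.standard_normal(n_samples)
        X[idx, :] += effect * np.outer(sigma[idx], latent)
        samples = [f"E{d}S{j:02d}" for j in range(n_samples)]
        out.append(ExpressionDataset(f"screen{d}", pd.DataFrame(X, index=genes,
                                                                columns=samples)))
    return out


def drug_screen_experiment(seed: int, n_drugs: int = 50, top_k: int = 5) -> dict:
    """End-to-end directional drug screen on a synthetic panel.

    A 20-line panel with one true drug (100-gene planted sensitivity module)
    among decoys; signature pairs are derived per drug, then three
    screening experiments (phenotype = overlapping 60-gene windows of the
    module, positive orientation, independent cohorts) are intersected at
    the given top-k.

    The gene universe is deliberately large (10k): cracking the top-100
    differential lists then demands an alignment with the line strata that
    the sensitivity-sorted contrast of the true drug clears comfortably but
    a decoy's random stratification essentially never does, keeping decoy
    signatures at chance overlap with the planted module."""
    n_genes = 10_000
    panel, truth = generate_drug_panel(n_lines=20, n_genes=n_genes,
                                       n_drugs=n_drugs, n_true_drugs=1,
                                       module_size=100, n_programs=1,
                                       effect_size=3.0, seed=seed)
    true_drug = truth.true_drugs[0]
    module = truth.modules[true_drug]

    pairs = []
    for drug in panel.drugs:
        pairs.append(derive_drug_signatures(panel, drug, top_n=100))
    true_pair = next(p for p in pairs if p.drug == true_drug)
    covered = set(true_pair.sens_genes) | set(true_pair.res_genes)
    recovery = len(set(module) & covered) / len(module)

    config = RunConfig(mode="cor", seed=seed, scorers=list(DRUG_SCREEN_SCORERS),
                       cor_tests=list(DRUG_SCREEN_TESTS))
    results = []
    windows = [module[0:60], module[20:80], module[40:100]]
    for e, window in enumerate(windows):
        # modest cohorts keep the decoy noise floor high enough that weak
        # spurious signatures cannot place consistently across experiments
        datasets = _module_tracking_datasets(window, n_genes, 1, 30,
                                             effect=2.0, seed=seed * 10 + e + 1)
        results.append(directional_drug_screen(
            datasets, window, pairs, "positive",
            replace(config, seed=seed * 10 + e + 1), top_k=top_k,
            experiment=f"exp{e}"))
    consensus = consensus_drugs(results, k=top_k)
    return {
        "true_drug": true_drug,
        "module_recovery": recovery,
        "per_experiment_rank_of_true": [r.ranked.index(true_drug) + 1 for r in results],
        "consensus": sorted(consensus),
        "consensus_is_true_drug": consensus == {true_drug},
    }
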