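"""Seeded generators for synthetic multi-dataset cohorts and drug panels.

The cohort generator emulates the framework's training inputs: several
independent expression datasets sharing a gene universe, a signature
collection in which some signatures are planted as directionally responsive
(group-shifted in the binary mode, state-correlated in the continuous mode)
and the rest are decoys, plus the matching per-sample annotation.  Gene
baselines are Gaussian with gene-specific means and dispersions; optional
zero-inflation mimics single-cell dropout.  The drug-panel generator
emulates a cell-line screen: an expression matrix over cell lines and
per-drug sensitivity values (IC50-like, higher = more resistant), with
planted sensitivity-associated gene modules for a subset of drugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (ACTIVATION, INHIBITION, BinaryLabels, ContinuousState,
                         ExpressionDataset, SignatureCollection)


@dataclass
class PlantedTruth:
    """Ground truth recorded with every generated cohort."""

    directions: dict[str, int]            # signature -> {+1, -1, 0 (decoy)}
    effect_size: float                    # in units of gene-level sd
    member_genes: dict[str, list[str]]
    mode: str
    noise_sd: float
    dropout_rate: float


@dataclass
class DrugPanel:
    """Cell-line expression plus per-drug sensitivity values."""

    expression: pd.DataFrame              # genes x cell lines
    sensitivity: pd.DataFrame             # drugs x cell lines (NaN = unmeasured)

    @property
    def drugs(self) -> list[str]:
        return list(self.sensitivity.index)


@dataclass
class DrugPanelTruth:
    true_drugs: list[str]
    modules: dict[str, list[str]]         # drug -> planted sensitivity module
    submodules: dict[str, list[list[str]]]  # drug -> independently driven sub-programs
    effect_size: float


def generate_cohort(n_datasets: int = 5, n_genes: int = 1000, n_samples: int = 100,
                    signature_sizes: list[int] | None = None,
                    directions: list[int] | None = None,
                    effect_size: float = 2.0, noise_sd: float = 0.0,
                    mode: str = "binary", dropout_rate: float = 0.0,
                    seed: int = 0) -> tuple[list[ExpressionDataset], SignatureCollection, PlantedTruth]:
    """Generate a multi-dataset cohort with planted directional signatures.

    Baseline expression of gene g is N(mu_g, sigma_g) with mu_g ~ U[2, 10]
    and sigma_g ~ U[0.5, 1.5], drawn once per dataset.  In binary mode the
    member genes of a +1 signature are shifted by +effect_size * sigma_g in
    the activation samples (mirrored for -1); in continuous mode they gain a
    slope of effect_size * sigma_g per unit of a standardized latent state,
    which is emitted (with observation noise) as the annotation.  Planted
    signatures occupy disjoint gene blocks; decoys draw from unshifted genes.
    """
    if signature_sizes is None:
        signature_sizes = [30] * 10
    if directions is None:
        directions = [1, -1] + [0] * (len(signature_sizes) - 2)
    if len(directions) != len(signature_sizes):
        raise ValueError("signature_sizes and directions must align")
    if sum(signature_sizes) > n_genes:
        raise ValueError("signatures exceed the gene universe")
    if max(signature_sizes) > n_genes / 10:
        raise ValueError("signature sizes must stay below n_genes / 10")
    if effect_size < 0:
        raise ValueError("effect size must be non-negative")

    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    # disjoint gene blocks per signature, assigned once for the whole cohort
    perm = rng.permutation(n_genes)
    sig_names = [f"SIG{k:02d}" for k in range(len(signature_sizes))]
    members: dict[str, list[str]] = {}
    cursor = 0
    for name, size in zip(sig_names, signature_sizes):
        members[name] = sorted(genes[i] for i in perm[cursor:cursor + size])
        cursor += size
    truth_dir = dict(zip(sig_names, directions))

    datasets = []
    for d in range(n_datasets):
        mu = rng.uniform(2.0, 10.0, size=n_genes)
        sigma = rng.uniform(0.5, 1.5, size=n_genes)
        X = rng.normal(mu[:, None], sigma[:, None], size=(n_genes, n_samples))
        samples = [f"D{d}S{j:03d}" for j in range(n_samples)]
        gene_idx = {g: i for i, g in enumerate(genes)}

        if mode == "binary":
            act = np.zeros(n_samples, dtype=bool)
            act[rng.permutation(n_samples)[: n_samples // 2]] = True
            for name, direction in truth_dir.items():
                if direction == 0:
                    continue
                idx = [gene_idx[g] for g in members[name]]
                shift = direction * effect_size * sigma[idx]
                X[np.ix_(idx, np.where(act)[0])] += shift[:, None]
            ann = BinaryLabels({s: ACTIVATION if a else INHIBITION
                                for s, a in zip(samples, act)})
        elif mode == "continuous":
            latent = rng.standard_normal(n_samples)
            for name, direction in truth_dir.items():
                if direction == 0:
                    continue
                idx = [gene_idx[g] for g in members[name]]
                X[idx, :] += direction * effect_size * np.outer(sigma[idx], latent)
            observed = latent + 0.1 * rng.standard_normal(n_samples)
            ann = ContinuousState(dict(zip(samples, observed.astype(float))))
        else:
            raise ValueError("mode must be 'binary' or 'continuous'")

        if noise_sd > 0:
            X = X + rng.normal(0.0, noise_sd, size=X.shape)
        if dropout_rate > 0:
            X = np.where(rng.random(X.shape) < dropout_rate, 0.0, X)
        datasets.append(ExpressionDataset(
            name=f"dataset{d}",
            values=pd.DataFrame(X, index=genes, columns=samples),
            annotation=ann))

    signatures = SignatureCollection({n: list(g) for n, g in members.items()})
    truth = PlantedTruth(truth_dir, effect_size, members, mode, noise_sd, dropout_rate)
    return datasets, signatures, truth


def generate_drug_panel(n_lines: int = 20, n_genes: int = 1000, n_drugs: int = 50,
                        n_true_drugs: int = 1, module_size: int = 100,
                        n_programs: int = 1, effect_size: float = 2.0,
                        seed: int = 0) -> tuple[DrugPanel, DrugPanelTruth]:
    """Generate a cell-line drug panel with planted sensitivity modules.

    Each true drug gets an exclusive gene module split into ``n_programs``
    sub-programs driven by independent latent per-line factors; the drug's
    sensitivity value (IC50-like, higher = more resistant) is a decreasing
    monotone function of the mean factor plus noise, so module-high lines
    are sensitive.  Decoy drugs receive sensitivities independent of
    expression.

    The multi-program structure mimics a multi-target compound and keeps
    decoy contrasts honest: a random stratification of the lines can tap one
    program's factor by chance, but the joint alignment of all programs with
    the sensitivity ranking is specific to the true drug.
    """
    if n_lines < 12:
        raise ValueError("panel needs at least 12 cell lines")
    if n_true_drugs * module_size > n_genes // 2:
        raise ValueError("planted modules exceed half the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    lines = [f"CL{i:02d}" for i in range(n_lines)]
    mu = rng.uniform(2.0, 10.0, size=n_genes)
    # wide dispersion spread, as in real expression panels; a diffuse
    # variance prior also keeps moderated tests honest about the module's
    # factor-driven extra variance
    sigma = np.exp(rng.uniform(np.log(0.25), np.log(2.5), size=n_genes))
    X = rng.normal(mu[:, None], sigma[:, None], size=(n_genes, n_lines))

    drugs = [f"DRUG{k:03d}" for k in range(n_drugs)]
    true_drugs = drugs[:n_true_drugs]
    perm = rng.permutation(n_genes)
    modules: dict[str, list[str]] = {}
    submodules: dict[str, list[list[str]]] = {}
    sens = np.empty((n_drugs, n_lines))
    cursor = 0
    for k, drug in enumerate(drugs):
        if drug in true_drugs:
            idx = perm[cursor:cursor + module_size]
            cursor += module_size
            modules[drug] = [genes[i] for i in sorted(idx)]
            blocks = np.array_split(idx, n_programs)
            submodules[drug] = [[genes[i] for i in sorted(b)] for b in blocks]
            # evenly graded susceptibility across the panel (standardized
            # rank grid): every line occupies a distinct susceptibility level
            grid = np.linspace(-1.0, 1.0, n_lines)
            factors = np.vstack([rng.permutation(grid / grid.std())
                                 for _ in range(n_programs)])
            for b, f in zip(blocks, factors):
                X[b, :] += effect_size * np.outer(sigma[b], f)
            # higher module expression -> more sensitive -> lower IC50
            sens[k] = -factors.mean(axis=0) * np.sqrt(n_programs) \
                + 0.1 * rng.standard_normal(n_lines)
        else:
            sens[k] = rng.standard_normal(n_lines)

    panel = DrugPanel(
        expression=pd.DataFrame(X, index=genes, columns=lines),
        sensitivity=pd.DataFrame(sens, index=drugs, columns=lines))
    return panel, DrugPanelTruth(true_drugs, modules, submodules, effect_size)
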