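"""Drug-signature derivation and the directional drug screen.

For each drug in a cell-line panel, lines are stratified by rank into
highly resistant (top quarter by sensitivity value, IC50-like) and highly
sensitive (bottom quarter); moderated differential expression between the
two strata yields the resistance signature Drug_R (up in resistant lines)
and the sensitivity signature Drug_S (down in resistant lines).  A
directional screen then scores every Drug_S/Drug_R pair against a phenotype
state (single-sample enrichment of a phenotype signature) with the
correlative-mode screener and ranks drugs by the signed difference of the
two directionality indices; consensus over several screening experiments is
the intersection of their top-k sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .association import moderated_ttest
from .data_model import ContinuousState, ExpressionDataset, RunConfig, SignatureCollection
from .enrichment import score_signatures
from .screener import cor_metascreener
from .synthetic import DrugPanel

logger = logging.getLogger("metascreener")

# reduced registry used for screening experiments: three representative
# unsupervised scorers crossed with three correlation tests
DRUG_SCREEN_SCORERS = ["gsva", "ssgsea", "zscore"]
DRUG_SCREEN_TESTS = ["pearson", "spearman", "kendall"]


@dataclass
class DrugSignaturePair:
    drug: str
    sens_genes: list[str]     # Drug_S: down in resistant lines
    res_genes: list[str]      # Drug_R: up in resistant lines

    def __post_init__(self) -> None:
        if set(self.sens_genes) & set(self.res_genes):
            raise ValueError(f"{self.drug}: Drug_S and Drug_R overlap")


@dataclass
class DrugScreenResult:
    experiment: str
    scores: pd.DataFrame      # index drug: DI_S, DI_R, score
    top_k: int

    @property
    def ranked(self) -> list[str]:
        return list(self.scores.index)

    @property
    def top_set(self) -> set[str]:
        return set(self.scores.index[: self.top_k])


def derive_drug_signatures(panel: DrugPanel, drug: str, min_lines: int = 12,
                           quantile: float = 0.25, top_n: int = 100) -> DrugSignaturePair:
    """Signature pair from rank-based stratification of the drug's lines.

    Group sizes are proportions of the measured lines (floor(q * n), at
    least 2), never absolute thresholds on the sensitivity values, so any
    monotone transform of the measurements leaves the result unchanged.
    Genes are ranked by ascending moderated-test p-value within each effect
    direction, ties broken by descending |effect|.
    """
    sens = panel.sensitivity.loc[drug].dropna()
    if len(sens) < min_lines:
        raise ValueError(f"{drug}: only {len(sens)} measured lines (< {min_lines})")
    order = sens.sort_values(ascending=False, kind="mergesort").index  # most resistant first
    n = len(order)
    n_grp = max(int(np.floor(quantile * n)), 2)
    resistant = list(order[:n_grp])
    sensitive = list(order[-n_grp:])
    if set(resistant) & set(sensitive):
        raise ValueError(f"{drug}: resistant and sensitive strata overlap (n={n})")

    lines = resistant + sensitive
    X = panel.expression[lines].to_numpy()
    mask = np.array([ln in set(resistant) for ln in lines])
    d = moderated_ttest(X, mask)     # effect = mean(resistant) - mean(sensitive)
    genes = np.asarray(panel.expression.index)

    def top(direction: int) -> list[str]:
        sel = d["effect"] * direction > 0
        idx = np.where(sel)[0]
        key = np.lexsort((-np.abs(d["effect"][idx]), d["p_two"][idx]))
        return list(genes[idx[key][:top_n]])

    return DrugSignaturePair(drug, sens_genes=top(-1), res_genes=top(+1))


def derive_all_drug_signatures(panel: DrugPanel, min_lines: int = 12,
                               quantile: float = 0.25, top_n: int = 100
                               ) -> tuple[list[DrugSignaturePair], dict[str, str]]:
    """Per-drug signature pairs; drugs failing the line-count rule are
    skipped with the reason recorded."""
    pairs, skipped = [], {}
    for drug in panel.drugs:
        try:
            pairs.append(derive_drug_signatures(panel, drug, min_lines, quantile, top_n))
        except ValueError as exc:
            skipped[drug] = str(exc)
            logger.warning("drug %s skipped: %s", drug, exc)
    return pairs, skipped


def _phenotype_states(datasets: list[ExpressionDataset], phenotype_genes: list[str],
                      config: RunConfig) -> list[ExpressionDataset]:
    """Attach single-sample enrichment scores of the phenotype signature as
    the continuous state of each dataset."""
    pheno = SignatureCollection({"phenotype": list(phenotype_genes)})
    out = []
    for ds in datasets:
        sm = score_signatures(ds, pheno, "ssgsea", config)
        state = ContinuousState(dict(zip(ds.samples, sm.values.iloc[0].astype(float))))
        out.append(ExpressionDataset(ds.name, ds.values, state))
    return out


def directional_drug_screen(datasets: list[ExpressionDataset],
                            phenotype_genes: list[str],
                            pairs: list[DrugSignaturePair],
                            orientation: str = "positive",
                            config: RunConfig | None = None,
                            top_k: int = 35,
                            experiment: str = "experiment") -> DrugScreenResult:
    """One directional screening experiment.

    With positive orientation, drugs whose sensitivity program tracks the
    phenotype (Drug_S DI high) and whose resistance program opposes it
    (Drug_R DI low) rank first: score = DI(Drug_S) - DI(Drug_R).  Negative
    orientation flips the sign, prioritizing drugs that spare
    phenotype-high samples.
    """
    if not pairs:
        raise ValueError("no drug signature pairs supplied")
    if orientation not in ("positive", "negative"):
        raise ValueError("orientation must be 'positive' or 'negative'")
    config = config or RunConfig(mode="cor", scorers=list(DRUG_SCREEN_SCORERS),
                                 cor_tests=list(DRUG_SCREEN_TESTS))
    config = replace(config, mode="cor")
    if config.scorers is None:
        config = replace(config, scorers=list(DRUG_SCREEN_SCORERS))
    if config.cor_tests is None:
        config = replace(config, cor_tests=list(DRUG_SCREEN_TESTS))

    sigs = {}
    for pair in pairs:
        sigs[f"{pair.drug}__S"] = list(pair.sens_genes)
        sigs[f"{pair.drug}__R"] = list(pair.res_genes)
    collection = SignatureCollection(sigs)

    staged = _phenotype_states(datasets, phenotype_genes, config)
    table = cor_metascreener(staged, collection, config)
    di = table.di

    sign = 1.0 if orientation == "positive" else -1.0
    rows = {}
    for pair in pairs:
        s_name, r_name = f"{pair.drug}__S", f"{pair.drug}__R"
        if s_name not in di.index and r_name not in di.index:
            logger.warning("drug %s dropped: both signatures below coverage", pair.drug)
            continue
        di_s = float(di.get(s_name, 0.0))
        di_r = float(di.get(r_name, 0.0))
        rows[pair.drug] = {"DI_S": di_s, "DI_R": di_r,
                           "score": sign * (di_s - di_r)}
    if not rows:
        raise ValueError("every drug was dropped for coverage")
    scores = pd.DataFrame.from_dict(rows, orient="index")
    scores["_name"] = scores.index
    scores = scores.sort_values(["score", "_name"], ascending=[False, True],
                                kind="mergesort").drop(columns="_name")
    return DrugScreenResult(experiment, scores, top_k)


def consensus_drugs(results: list[DrugScreenResult], k: int | None = None) -> set[str]:
    """Intersection of the experiments' top-k drug sets."""
    if len(results) < 2:
        raise ValueError("consensus needs >=2 experiments")
    sets = [set(r.scores.index[: (k if k is not None else r.top_k)]) for r in results]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out
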