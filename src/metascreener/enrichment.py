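"""Single-sample enrichment scorers and supervised group-level enrichment.

Twenty-one unsupervised scorers map (expression matrix, signature) to one
activity score per sample; they fall into rank-based (ssgsea, gsva, aucell,
ucell, singscore, viper), standardization-based (zscore, plage, pca),
summary (median, mean, wmean, wsum and their permutation-normalized
variants) and model-based (ulm, mlm, udt, mdt) families.  Two supervised
methods (preranked GSEA and over-representation analysis) consume gene-level
association statistics directly and yield directional p-values without a
per-sample score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionDataset, SignatureCollection, RunConfig

logger = logging.getLogger("metascreener")

UNSUPERVISED_SCORERS: list[str] = [
    "gsva", "ssgsea", "zscore", "plage", "pca", "aucell", "ucell", "singscore",
    "median", "mean", "ulm", "mlm", "udt", "mdt", "viper",
    "wmean", "norm_wmean", "corr_wmean", "wsum", "norm_wsum", "corr_wsum",
]
SUPERVISED_SCORERS: list[str] = ["fgsea", "ora"]
ALL_SCORERS: list[str] = UNSUPERVISED_SCORERS + SUPERVISED_SCORERS


@dataclass
class ScoreMatrix:
    """Signature x sample activity scores from one scorer on one dataset."""

    scorer: str
    values: pd.DataFrame  # signatures x samples

    @property
    def signatures(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneRanking:
    """Signed per-gene ranking statistic with its provenance."""

    stats: pd.Series  # gene -> signed real
    provenance: str = ""

    def __post_init__(self) -> None:
        self.stats = self.stats[np.isfinite(self.stats)]
        if len(self.stats) < 3:
            raise ValueError("gene ranking needs at least 3 finite genes")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Per-gene z-scores across samples; zero-variance genes map to 0."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mu) / sd
    Z[~np.isfinite(Z)] = 0.0
    return Z


def _membership(genes: list[str], signatures: SignatureCollection,
                names: list[str]) -> np.ndarray:
    """0/1 matrix, signatures x genes, restricted to genes in the dataset."""
    idx = {g: i for i, g in enumerate(genes)}
    M = np.zeros((len(names), len(genes)))
    for r, name in enumerate(names):
        for g in signatures[name]:
            if g in idx:
                M[r, idx[g]] = 1.0
    return M


def _set_indices(genes: list[str], signature_genes: list[str]) -> np.ndarray:
    idx = {g: i for i, g in enumerate(genes)}
    return np.array(sorted(idx[g] for g in signature_genes if g in idx), dtype=int)


def _rank_columns_desc(X: np.ndarray) -> np.ndarray:
    """Average ranks per column with rank 1 = highest expression."""
    n = X.shape[0]
    asc = stats.rankdata(X, axis=0)
    return n + 1 - asc


def _orient_sign(scores: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Flip a sign-ambiguous component so it correlates non-negatively with
    the set's mean expression profile."""
    ref = reference - reference.mean()
    sc = scores - scores.mean()
    if float(sc @ ref) < 0:
        return -scores
    return scores


# ---------------------------------------------------------------------------
# individual scorers (each returns an array of len(samples) for one set,
# or a full matrix when vectorization across signatures is natural)
# ---------------------------------------------------------------------------

def _score_zscore(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    n = M.sum(axis=1, keepdims=True)
    return (M @ Z) / np.sqrt(n)


def _score_plage(Z: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    out = np.zeros((len(sets), Z.shape[1]))
    for r, idx in enumerate(sets):
        sub = Z[idx, :]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        out[r] = _orient_sign(vt[0], sub.mean(axis=0))
    return out


def _score_pca(Z: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    out = np.zeros((len(sets), Z.shape[1]))
    for r, idx in enumerate(sets):
        sub = Z[idx, :]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        out[r] = _orient_sign(s[0] * vt[0], sub.mean(axis=0))
    return out


def _score_ssgsea(X: np.ndarray, sets: list[np.ndarray], alpha: float) -> np.ndarray:
    """Barbie-style weighted KS statistic, weight = rank value ** alpha.

    The highest-expressed gene in a sample carries rank value N; the walk
    visits genes in descending expression order and the (unnormalized) score
    is the sum of the running difference between the weighted hit CDF and the
    uniform miss CDF.
    """
    n_genes, n_samples = X.shape
    rank_desc = _rank_columns_desc(X)            # 1 = highest
    rank_value = (n_genes + 1 - rank_desc) ** alpha   # N = highest
    order = np.argsort(rank_desc, axis=0, kind="stable")  # descending expression
    H = np.zeros((len(sets), n_genes))
    for r, idx in enumerate(sets):
        H[r, idx] = 1.0
    n_g = H.sum(axis=1, keepdims=True)
    out = np.zeros((len(sets), n_samples))
    for j in range(n_samples):
        ordered = order[:, j]
        hit = H[:, ordered]                              # sigs x ordered genes
        wh = hit * rank_value[ordered, j][None, :]
        p_hit = np.cumsum(wh, axis=1) / wh.sum(axis=1, keepdims=True)
        p_miss = np.cumsum(1.0 - hit, axis=1) / (n_genes - n_g)
        out[:, j] = (p_hit - p_miss).sum(axis=1)
    return out


def _gaussian_ecdf(X: np.ndarray, bandwidth_factor: float) -> np.ndarray:
    """Per-gene Gaussian-kernel cumulative density estimate at the observed
    values (bandwidth = gene sd / bandwidth_factor)."""
    sd = X.std(axis=1, ddof=1, keepdims=True)
    h = np.where(sd > 0, sd / bandwidth_factor, 1.0)
    # E_k Phi((x_j - x_k) / h), per gene; loop genes to bound memory
    out = np.empty_like(X, dtype=float)
    for g in range(X.shape[0]):
        diff = (X[g][:, None] - X[g][None, :]) / h[g]
        out[g] = stats.norm.cdf(diff).mean(axis=1)
    return out


def _score_gsva(X: np.ndarray, sets: list[np.ndarray], bandwidth_factor: float) -> np.ndarray:
    """GSVA-style statistic: kernel ECDF per gene, symmetric rank statistic per
    sample, weighted KS walk (tau=1), ES = max positive + max negative
    deviation (signed-sum convention)."""
    n_genes, n_samples = X.shape
    E = _gaussian_ecdf(X, bandwidth_factor)
    rank_desc = _rank_columns_desc(E)
    weight = np.abs(n_genes / 2.0 - rank_desc)      # symmetric rank statistic
    order = np.argsort(rank_desc, axis=0, kind="stable")
    H = np.zeros((len(sets), n_genes))
    for r, idx in enumerate(sets):
        H[r, idx] = 1.0
    n_g = H.sum(axis=1, keepdims=True)
    out = np.zeros((len(sets), n_samples))
    for j in range(n_samples):
        ordered = order[:, j]
        hit = H[:, ordered]
        wh = hit * weight[ordered, j][None, :]
        denom = np.maximum(wh.sum(axis=1, keepdims=True), 1e-300)
        walk = np.cumsum(wh, axis=1) / denom \
            - np.cumsum(1.0 - hit, axis=1) / (n_genes - n_g)
        out[:, j] = np.maximum(walk.max(axis=1), 0.0) + np.minimum(walk.min(axis=1), 0.0)
    return out


def _score_aucell(X: np.ndarray, sets: list[np.ndarray], max_rank: int) -> np.ndarray:
    """Area under the set-recovery curve over the top `max_rank` ranks, scaled
    by the maximal achievable area.  Ties broken by stable input order."""
    n_genes, n_samples = X.shape
    out = np.zeros((len(sets), n_samples))
    # stable descending order: sort by -expression, stable
    order = np.argsort(-X, axis=0, kind="stable")
    position = np.empty_like(order)
    rows = np.arange(n_genes)
    for j in range(n_samples):
        position[order[:, j], j] = rows
    for r, idx in enumerate(sets):
        n_g = len(idx)
        k = np.arange(1, min(n_g, max_rank) + 1)
        max_area = float(k.sum() + n_g * max(0, max_rank - n_g))
        pos = position[idx, :] + 1  # 1-based ranks of set genes, per sample
        # cumulative hit count integrated over ranks 1..max_rank
        area = np.clip(max_rank - pos + 1, 0, None).sum(axis=0)
        out[r] = area / max_area
    return out


def _score_ucell(X: np.ndarray, sets: list[np.ndarray], r_max: int) -> np.ndarray:
    rank_desc = np.minimum(_rank_columns_desc(X), r_max)
    out = np.zeros((len(sets), X.shape[1]))
    for r, idx in enumerate(sets):
        n_g = len(idx)
        u = rank_desc[idx, :].sum(axis=0) - n_g * (n_g + 1) / 2.0
        out[r] = 1.0 - u / (n_g * r_max)
    return out


def _score_singscore(X: np.ndarray, sets: list[np.ndarray]) -> np.ndarray:
    """Mean rank of set genes (ascending ranks), rescaled to [0, 1] by the
    theoretical extremes of the mean rank (unsigned-set convention)."""
    n_genes = X.shape[0]
    rank_asc = stats.rankdata(X, axis=0)
    out = np.zeros((len(sets), X.shape[1]))
    for r, idx in enumerate(sets):
        n_g = len(idx)
        mean_rank = rank_asc[idx, :].mean(axis=0)
        lo = (n_g + 1) / 2.0
        hi = n_genes - (n_g - 1) / 2.0
        out[r] = (mean_rank - lo) / (hi - lo)
    return out


def _score_viper(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Simplified one-tailed aREA: quantile-transform each sample, average the
    normal scores over the set, scale by sqrt(set size)."""
    n_genes = X.shape[0]
    rank_asc = stats.rankdata(X, axis=0)
    Z = stats.norm.ppf((rank_asc - 0.5) / n_genes)
    n = M.sum(axis=1, keepdims=True)
    return (M @ Z) / np.sqrt(n)


def _score_ulm(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """t-statistic of the slope from regressing each sample's expression
    vector on the signature's 0/1 membership vector."""
    n_genes = X.shape[0]
    df = n_genes - 2
    Xc = X - X.mean(axis=0, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    ss_x = (Xc ** 2).sum(axis=0, keepdims=True)
    ss_m = (Mc ** 2).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ Xc) / np.sqrt(ss_m * ss_x)
        t = r * np.sqrt(df / np.maximum(1e-300, 1.0 - r ** 2))
    t[~np.isfinite(t)] = 0.0
    return t


def _score_mlm(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Joint multivariate regression of each sample's expression on all
    membership columns; score = per-signature coefficient t-statistic."""
    n_genes, n_samples = X.shape
    n_sig = M.shape[0]
    D = np.column_stack([np.ones(n_genes), M.T])      # genes x (1 + sigs)
    dof = n_genes - D.shape[1]
    if dof < 1:
        raise ValueError("mlm needs more genes than signatures")
    G = np.linalg.pinv(D.T @ D)
    H = G @ D.T
    beta = H @ X                                       # (1+sigs) x samples
    resid = X - D @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(G), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    t[~np.isfinite(t)] = 0.0
    return t[1:, :][:n_sig]


def _score_trees(X: np.ndarray, M: np.ndarray, multivariate: bool,
                 max_depth: int, min_leaf: int) -> np.ndarray:
    from sklearn.tree import DecisionTreeRegressor

    n_sig, n_samples = M.shape[0], X.shape[1]
    out = np.zeros((n_sig, n_samples))
    if multivariate:
        D = M.T  # genes x signatures
        for j in range(n_samples):
            tree = DecisionTreeRegressor(max_depth=max_depth, min_samples_leaf=min_leaf,
                                         random_state=0)
            tree.fit(D, X[:, j])
            imp = tree.tree_.compute_feature_importances(normalize=False)
            out[:, j] = imp
    else:
        for r in range(n_sig):
            D = M[r][:, None]
            for j in range(n_samples):
                tree = DecisionTreeRegressor(max_depth=max_depth, min_samples_leaf=min_leaf,
                                             random_state=0)
                tree.fit(D, X[:, j])
                out[r, j] = tree.tree_.compute_feature_importances(normalize=False)[0]
    return out


def _wstats(X: np.ndarray, M: np.ndarray, kind: str) -> np.ndarray:
    """Weighted mean/sum with unit weights: wmean = set mean, wsum = set sum."""
    n = M.sum(axis=1, keepdims=True)
    s = M @ X
    return s / n if kind == "wmean" else s


def _perm_null_wstats(X: np.ndarray, M: np.ndarray, kind: str, n_perm: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Gene-label permutation null for wmean/wsum; returns (perm, sig, sample)."""
    n_genes = X.shape[0]
    null = np.empty((n_perm, M.shape[0], X.shape[1]))
    for p in range(n_perm):
        perm = rng.permutation(n_genes)
        null[p] = _wstats(X[perm], M, kind)
    return null


# ---------------------------------------------------------------------------
# public scoring entry point
# ---------------------------------------------------------------------------

def score_signatures(dataset: ExpressionDataset, signatures: SignatureCollection,
                     scorer: str, config: RunConfig | None = None,
                     seed: int | None = None) -> ScoreMatrix:
    """Score every signature in every sample with one unsupervised scorer.

    Signatures with fewer than 2 genes present are skipped (degenerate for
    SVD-based scorers and uninformative elsewhere) with a warning.
    """
    config = config or RunConfig()
    if scorer not in UNSUPERVISED_SCORERS:
        raise ValueError(f"unknown unsupervised scorer {scorer!r}")
    X = dataset.matrix
    genes = dataset.genes
    names, sets = [], []
    for name in signatures.names:
        idx = _set_indices(genes, signatures[name])
        if len(idx) < 2:
            logger.warning("scorer %s: signature %s has <2 genes in %s; skipped",
                           scorer, name, dataset.name)
            continue
        names.append(name)
        sets.append(idx)
    if not names:
        raise ValueError(f"no scorable signatures in dataset {dataset.name}")
    M = _membership(genes, signatures, names)
    for r, idx in enumerate(sets):   # keep membership consistent with sets
        M[r] = 0.0
        M[r, idx] = 1.0

    rng = np.random.default_rng(config.seed if seed is None else seed)

    if scorer == "zscore":
        S = _score_zscore(_standardize_rows(X), M)
    elif scorer == "plage":
        S = _score_plage(_standardize_rows(X), sets)
    elif scorer == "pca":
        S = _score_pca(_standardize_rows(X), sets)
    elif scorer == "ssgsea":
        S = _score_ssgsea(X, sets, config.ssgsea_alpha)
    elif scorer == "gsva":
        S = _score_gsva(X, sets, config.gsva_bandwidth_factor)
    elif scorer == "aucell":
        max_rank = int(np.ceil(config.aucell_max_rank_fraction * X.shape[0]))
        S = _score_aucell(X, sets, max_rank)
    elif scorer == "ucell":
        S = _score_ucell(X, sets, min(config.ucell_max_rank, X.shape[0]))
    elif scorer == "singscore":
        S = _score_singscore(X, sets)
    elif scorer == "median":
        S = np.vstack([np.median(X[idx, :], axis=0) for idx in sets])
    elif scorer == "mean":
        S = np.vstack([X[idx, :].mean(axis=0) for idx in sets])
    elif scorer == "viper":
        S = _score_viper(X, M)
    elif scorer == "ulm":
        S = _score_ulm(X, M)
    elif scorer == "mlm":
        S = _score_mlm(X, M)
    elif scorer in ("udt", "mdt"):
        S = _score_trees(X, M, scorer == "mdt", config.tree_max_depth, config.tree_min_leaf)
    elif scorer in ("wmean", "wsum"):
        S = _wstats(X, M, scorer)
    elif scorer in ("norm_wmean", "norm_wsum", "corr_wmean", "corr_wsum"):
        kind = "wmean" if scorer.endswith("wmean") else "wsum"
        base = _wstats(X, M, kind)
        null = _perm_null_wstats(X, M, kind, config.n_perm_scorer, rng)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        if scorer.startswith("norm"):
            with np.errstate(invalid="ignore", divide="ignore"):
                S = (base - mu) / sd
            S[~np.isfinite(S)] = 0.0   # degenerate null guard: score 0
        else:
            exceed = (np.abs(null - mu) >= np.abs(base - mu)).sum(axis=0)
            p = np.maximum(exceed, 1) / (config.n_perm_scorer + 1)
            p = np.maximum(p, 1.0 / (config.n_perm_scorer + 1))
            S = base * (-np.log10(p))
    else:  # pragma: no cover
        raise AssertionError(scorer)

    if not np.isfinite(S).all():
        raise FloatingPointError(f"scorer {scorer} produced non-finite scores")
    return ScoreMatrix(scorer, pd.DataFrame(S, index=names, columns=dataset.samples))


# ---------------------------------------------------------------------------
# supervised: preranked GSEA and ORA
# ---------------------------------------------------------------------------

def _es_walk(stat_sorted: np.ndarray, hit: np.ndarray) -> float:
    """Classic preranked enrichment score: member steps weighted by |stat|,
    non-member steps uniform; ES = extremum of the running sum."""
    w = np.abs(stat_sorted)
    wh = np.where(hit, w, 0.0)
    denom = wh.sum()
    if denom == 0:
        return 0.0
    n_miss = int((~hit).sum())
    if n_miss == 0:
        raise ValueError("signature covers the whole ranking")
    walk = np.cumsum(np.where(hit, wh / denom, -1.0 / n_miss))
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def fgsea_test(ranking: GeneRanking, signature_genes: list[str], n_perm: int = 500,
               seed: int = 0) -> tuple[float, float, float, int]:
    """Preranked GSEA with a random same-size gene-set null.

    Returns ``(ES, NES, p_two, direction)``.  The null draws `n_perm` gene
    sets of the same size uniformly; NES divides ES by the mean |null ES|
    of the same sign; the permutation p is two-tailed.  When the number of
    distinct same-size sets is at most ``n_perm`` the null is enumerated
    exhaustively and the p-value is exact (observed set included).
    """
    from itertools import combinations
    from math import comb as _comb
    stats_ = ranking.stats
    if stats_.nunique() == 1:
        raise ValueError("all ranking statistics equal: no ordering")
    order = np.argsort(-stats_.to_numpy(), kind="stable")
    sorted_stats = stats_.to_numpy()[order]
    sorted_genes = stats_.index.to_numpy()[order]
    members = set(signature_genes)
    hit = np.array([g in members for g in sorted_genes])
    n_hit = int(hit.sum())
    if n_hit < 2:
        raise ValueError("fewer than 2 signature genes in the ranking")
    es = _es_walk(sorted_stats, hit)

    n_genes = len(sorted_genes)
    exhaustive = _comb(n_genes, n_hit) <= n_perm
    if exhaustive:
        null = np.empty(_comb(n_genes, n_hit))
        for b, idx in enumerate(combinations(range(n_genes), n_hit)):
            h = np.zeros(n_genes, dtype=bool)
            h[list(idx)] = True
            null[b] = _es_walk(sorted_stats, h)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            h = np.zeros(n_genes, dtype=bool)
            h[rng.choice(n_genes, size=n_hit, replace=False)] = True
            null[b] = _es_walk(sorted_stats, h)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    denom = np.abs(same_sign).mean() if len(same_sign) else 1.0
    nes = es / denom if denom > 0 else 0.0
    if exhaustive:
        p_pos = (null >= es - 1e-12).mean()
        p_neg = (null <= es + 1e-12).mean()
    else:
        p_pos = (1 + int((null >= es).sum())) / (1 + n_perm)
        p_neg = (1 + int((null <= es).sum())) / (1 + n_perm)
    p_two = min(1.0, 2.0 * min(p_pos, p_neg))
    return es, nes, p_two, int(np.sign(es))


def ora_test(up_list: list[str], down_list: list[str], signature_genes: list[str],
             universe: list[str]) -> tuple[float, float, int, int]:
    """One-sided hypergeometric over-representation against directional top-k
    gene lists; returns ``(p_act, p_inh, overlap_up, overlap_down)``."""
    uni = set(universe)
    if len(up_list) > len(uni) or len(down_list) > len(uni):
        raise ValueError("top-k list larger than the universe")
    sig = set(signature_genes) & uni
    n_g = len(sig)
    n_uni = len(uni)

    def tail(top: list[str]) -> tuple[float, int]:
        k = len(top)
        ov = len(sig & set(top))
        if k == 0:
            return 1.0, 0
        return float(stats.hypergeom.sf(ov - 1, n_uni, n_g, k)), ov

    p_act, ov_up = tail(up_list)
    p_inh, ov_dn = tail(down_list)
    return p_act, p_inh, ov_up, ov_dn


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    """Pairwise signature overlap/correlation and per-signature VIF over the
    membership design matrix; drives auto-disabling of joint multivariate
    scorers (mlm, mdt) when collinearity is severe."""

    jaccard: pd.DataFrame
    score_correlation: pd.DataFrame | None
    vif: pd.Series
    multivariate_safe: bool
    vif_threshold: float = 10.0


def assess_collinearity(signatures: SignatureCollection,
                        score_profiles: ScoreMatrix | None = None,
                        universe: list[str] | None = None,
                        vif_threshold: float = 10.0) -> CollinearityReport:
    names = signatures.names
    if len(names) < 2:
        raise ValueError("collinearity assessment needs >=2 signatures")
    sets = {n: set(signatures[n]) for n in names}
    jac = pd.DataFrame(1.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            jac.loc[a, b] = jac.loc[b, a] = inter / union if union else 0.0

    corr = None
    if score_profiles is not None:
        corr = score_profiles.values.T.corr()

    if universe is None:
        universe = sorted(set().union(*sets.values()))
    M = _membership(universe, signatures, names).T   # genes x signatures
    vif = {}
    for i, name in enumerate(names):
        y = M[:, i]
        others = np.delete(M, i, axis=1)
        D = np.column_stack([np.ones(len(universe)), others])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            vif[name] = np.inf
            continue
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot
        vif[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    vif_s = pd.Series(vif)
    safe = bool(np.nanmax(vif_s.to_numpy()) <= vif_threshold)
    if not safe:
        logger.info("collinearity: max VIF %.2f > %.1f; mlm/mdt will be disabled",
                    float(np.nanmax(vif_s.replace(np.inf, np.nan).to_numpy())) if np.isfinite(vif_s).any() else np.inf,
                    vif_threshold)
    return CollinearityReport(jac, corr, vif_s, safe, vif_threshold)
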