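"""Phenotype association tests and the directional p-value conversion.

Six two-group differential tests quantify activity differences between
activation and inhibition samples; ten correlation tests quantify the
relation of an activity profile to a continuous phenotypic state.  Every
test reports a two-tailed p-value plus an effect sign, which the two-to-one
rule splits into complementary one-sided activation/inhibition p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats, special

P_MIN = 1e-300

DIFF_TESTS: list[str] = ["limma", "ttest", "anova", "wilcoxon", "kruskal", "permutation"]
COR_TESTS: list[str] = ["pearson", "kendall", "spearman", "lm", "biweight",
                        "distance", "percentage", "blomqvist", "hoeffding", "gamma"]


@dataclass
class AssociationResult:
    method: str
    statistic: float
    effect: float
    direction: int        # sign of the effect; 0 for exact ties
    p_two: float

    def __post_init__(self) -> None:
        self.p_two = float(np.clip(self.p_two, P_MIN, 1.0))
        if not np.isfinite(self.statistic):
            self.statistic = 0.0


@dataclass
class DirectionalP:
    p_act: float
    p_inh: float


def two_to_one(p_two: float, direction: int) -> DirectionalP:
    """Split a two-tailed p into complementary one-sided p-values.

    A non-negative direction puts the evidence on the activation side
    (p_act = p/2); a negative direction mirrors it.  Ties (direction 0)
    are routed as non-negative, which yields the information-free (0.5, 0.5)
    at p_two = 1.  Always p_act + p_inh = 1.
    """
    p_two = float(np.clip(p_two, P_MIN, 1.0))
    half = p_two / 2.0
    if direction >= 0:
        return DirectionalP(half, 1.0 - half)
    return DirectionalP(1.0 - half, half)


def _sign(x: float, tol: float = 0.0) -> int:
    if x > tol:
        return 1
    if x < -tol:
        return -1
    return 0


# ---------------------------------------------------------------------------
# limma-style moderated t (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) for variances."""
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0 or len(s2) < 2:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = float(2.0 * _trigamma_inverse(e_var)[0])
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_ttest(X: np.ndarray, mask: np.ndarray) -> dict[str, np.ndarray]:
    """Two-group moderated t over the rows of X (variance pooled across rows).

    Follows the standard empirical-Bayes recipe: per-row pooled residual
    variance with df = n - 2, squeezed toward a fitted scaled-F prior; the
    moderated t has df = d0 + n - 2.  With fewer than 3 rows there is
    nothing to pool and the ordinary pooled-variance t is used.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if min(n1, n0) < 2:
        raise ValueError("each class needs >=2 samples")
    a, b = X[:, mask], X[:, ~mask]
    diff = a.mean(axis=1) - b.mean(axis=1)
    df_resid = n1 + n0 - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
         ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if X.shape[0] >= 3:
        d0, s0_2 = _fit_f_dist(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_2)
            df_total = 1e12
        else:
            s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
    else:
        s2_post, df_total = s2, df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / se
    t[~np.isfinite(t)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.where(np.isfinite(p), p, 1.0), P_MIN, 1.0)
    return {"statistic": t, "effect": diff, "p_two": p,
            "direction": np.sign(diff).astype(int)}


# ---------------------------------------------------------------------------
# differential tests (vectorized over rows; scalar wrapper below)
# ---------------------------------------------------------------------------

def _rank_two_group(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row average ranks, rank sum of group 1 and tie-correction term."""
    R = stats.rankdata(X, axis=1)
    r1 = R[:, mask].sum(axis=1)
    # tie correction sum t^3 - t per row
    Xs = np.sort(X, axis=1)
    ties = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        _, counts = np.unique(Xs[i], return_counts=True)
        ties[i] = float((counts ** 3 - counts).sum())
    return R, r1, ties


def _wilcoxon_matrix(X: np.ndarray, mask: np.ndarray) -> dict[str, np.ndarray]:
    n1, n0 = int(mask.sum()), int((~mask).sum())
    n = n1 + n0
    _, r1, ties = _rank_two_group(X, mask)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n0 / 2.0
    tie_term = ties / ((n) * (n - 1))
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - mu) / np.sqrt(var)
    z[~np.isfinite(z)] = 0.0
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_MIN, 1.0)
    effect = 2.0 * u1 / (n1 * n0) - 1.0     # rank-biserial displacement
    p = np.where(effect == 0.0, 1.0, p)
    return {"statistic": u1, "effect": effect, "p_two": p,
            "direction": np.sign(effect).astype(int)}


def _kruskal_matrix(X: np.ndarray, mask: np.ndarray) -> dict[str, np.ndarray]:
    n1, n0 = int(mask.sum()), int((~mask).sum())
    n = n1 + n0
    R, r1, ties = _rank_two_group(X, mask)
    r0 = R.sum(axis=1) - r1
    h = 12.0 / (n * (n + 1)) * (r1 ** 2 / n1 + r0 ** 2 / n0) - 3.0 * (n + 1)
    correction = 1.0 - ties / (n ** 3 - n)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = h / correction
    h[~np.isfinite(h)] = 0.0
    h = np.maximum(h, 0.0)
    p = np.clip(stats.chi2.sf(h, df=1), P_MIN, 1.0)
    effect = r1 / n1 - r0 / n0             # mean-rank displacement
    p = np.where(effect == 0.0, 1.0, p)
    return {"statistic": h, "effect": effect, "p_two": p,
            "direction": np.sign(effect).astype(int)}


def _permutation_matrix(X: np.ndarray, mask: np.ndarray, n_perm: int,
                        seed: int) -> dict[str, np.ndarray]:
    """Label-permutation test of the mean difference.

    When the number of distinct label assignments is at most n_perm the null
    is enumerated exhaustively (exact p, observed assignment included);
    otherwise Monte-Carlo with the add-one estimator.
    """
    n1 = int(mask.sum())
    n = len(mask)
    obs = X[:, mask].mean(axis=1) - X[:, ~mask].mean(axis=1)
    n_total = comb(n, n1)
    if n_total <= n_perm:
        masks = np.zeros((n_total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n1)):
            masks[i, list(idx)] = True
        W = (masks / n1 - (~masks) / (n - n1)).T     # n x n_total
        null = X @ W
        p = (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1) / n_total
    else:
        rng = np.random.default_rng(seed)
        W = np.empty((n, n_perm))
        base = np.concatenate([np.full(n1, 1.0 / n1), np.full(n - n1, -1.0 / (n - n1))])
        for b in range(n_perm):
            W[:, b] = rng.permutation(base)
        null = X @ W
        p = (1.0 + (np.abs(null) >= np.abs(obs)[:, None] - 1e-12).sum(axis=1)) / (1.0 + n_perm)
    p = np.clip(p, P_MIN, 1.0)
    p = np.where(obs == 0.0, 1.0, p)
    return {"statistic": obs, "effect": obs, "p_two": p,
            "direction": np.sign(obs).astype(int)}


def differential_stats_matrix(X: np.ndarray, mask: np.ndarray, method: str,
                              n_perm: int = 1000, seed: int = 0) -> dict[str, np.ndarray]:
    """Row-wise two-group differential statistics (vectorized).

    ``mask`` is True for activation samples; effect = mean(activation) -
    mean(inhibition) (rank displacement for the rank tests).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mask = np.asarray(mask, dtype=bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if min(n1, n0) < 2:
        raise ValueError(f"each class needs >=2 samples (got {n1} vs {n0})")
    a, b = X[:, mask], X[:, ~mask]
    diff = a.mean(axis=1) - b.mean(axis=1)

    if method == "limma":
        return moderated_ttest(X, mask)
    if method == "ttest":
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.where(np.isfinite(t), t, 0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        p = np.where((t == 0.0) & (diff == 0.0), 1.0, p)
        return {"statistic": t, "effect": diff, "p_two": np.clip(p, P_MIN, 1.0),
                "direction": np.sign(diff).astype(int)}
    if method == "anova":
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(a, b, axis=1)
        f = np.where(np.isfinite(f), f, 0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        return {"statistic": f, "effect": diff, "p_two": np.clip(p, P_MIN, 1.0),
                "direction": np.sign(diff).astype(int)}
    if method == "wilcoxon":
        return _wilcoxon_matrix(X, mask)
    if method == "kruskal":
        return _kruskal_matrix(X, mask)
    if method == "permutation":
        return _permutation_matrix(X, mask, n_perm, seed)
    raise ValueError(f"unknown differential test {method!r}")


def differential_test(scores: np.ndarray, mask: np.ndarray, method: str,
                      n_perm: int = 1000, seed: int = 0) -> AssociationResult:
    """Scalar two-group test on one activity profile.

    The Wilcoxon rank-sum test is exact when both groups have <=10 samples
    and no ties are present, otherwise tie-corrected normal approximation.
    """
    scores = np.asarray(scores, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if min(n1, n0) < 2:
        raise ValueError(f"each class needs >=2 samples (got {n1} vs {n0})")
    if method == "wilcoxon" and max(n1, n0) <= 10:
        a, b = scores[mask], scores[~mask]
        has_ties = len(np.unique(scores)) < len(scores)
        how = "asymptotic" if has_ties else "exact"
        u1, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=how)
        effect = 2.0 * float(u1) / (n1 * n0) - 1.0
        if effect == 0.0:
            p = 1.0
        return AssociationResult(method, float(u1), effect, _sign(effect), float(p))
    d = differential_stats_matrix(scores[None, :], mask, method, n_perm=n_perm, seed=seed)
    return AssociationResult(method, float(d["statistic"][0]), float(d["effect"][0]),
                             int(d["direction"][0]), float(d["p_two"][0]))


# ---------------------------------------------------------------------------
# correlation tests
# ---------------------------------------------------------------------------

def _t_p_from_r(r: float, n: int) -> float:
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return P_MIN
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def _bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation with tuning constant c = 9."""
    def weights(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return v - med
        u = (v - med) / (9.0 * mad)
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        return (v - med) * w
    a, b = weights(x), weights(y)
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _percentage_bend(x: np.ndarray, y: np.ndarray, beta: float = 0.2) -> float:
    """Percentage-bend correlation (bend constant beta)."""
    def psi(v: np.ndarray) -> np.ndarray:
        n = len(v)
        med = np.median(v)
        w = np.sort(np.abs(v - med))
        m = int(np.floor((1.0 - beta) * n + 0.5))
        omega = w[m - 1]
        if omega == 0:
            return np.sign(v - med)
        z = (v - med) / omega
        i1, i2 = int((z < -1).sum()), int((z > 1).sum())
        s = v[np.abs(z) <= 1].sum()
        theta = (omega * (i2 - i1) + s) / (n - i1 - i2)
        return np.clip((v - theta) / omega, -1.0, 1.0)
    a, b = psi(x), psi(y)
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def _blomqvist(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Quadrant (medial) correlation about the medians with exact binomial p."""
    a = x - np.median(x)
    b = y - np.median(y)
    prod = a * b
    nc = int((prod > 0).sum())
    nd = int((prod < 0).sum())
    if nc + nd == 0:
        return 0.0, 1.0
    beta = (nc - nd) / (nc + nd)
    p = stats.binomtest(nc, nc + nd, 0.5).pvalue
    return float(beta), float(p)


def _hoeffding_d(x: np.ndarray, y: np.ndarray) -> float:
    """Hoeffding's D with midrank tie handling."""
    n = len(x)
    r = stats.rankdata(x)
    s = stats.rankdata(y)
    # bivariate rank: Q_i = 1 + #{j: x_j < x_i and y_j < y_i} with half-credit ties
    lx = (x[None, :] < x[:, None]).astype(float) + 0.5 * (x[None, :] == x[:, None])
    ly = (y[None, :] < y[:, None]).astype(float) + 0.5 * (y[None, :] == y[:, None])
    np.fill_diagonal(lx, 0.0)
    np.fill_diagonal(ly, 0.0)
    q = 1.0 + (lx * ly).sum(axis=1)
    d1 = float(((q - 1) * (q - 2)).sum())
    d2 = float(((r - 1) * (r - 2) * (s - 1) * (s - 2)).sum())
    d3 = float(((r - 2) * (s - 2) * (q - 1)).sum())
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * d1 + d2 - 2 * (n - 2) * d3) / denom


def _distance_corr_parts(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    def centered(v: np.ndarray) -> np.ndarray:
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()
    return centered(x), centered(y)


def _dcor_from_parts(A: np.ndarray, B: np.ndarray) -> float:
    dcov2 = (A * B).mean()
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    denom = np.sqrt(dvar_x * dvar_y)
    if denom <= 0 or dcov2 <= 0:
        return 0.0
    return float(np.sqrt(dcov2 / denom))


def _gamma_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Goodman-Kruskal gamma with the standard normal-approximation test."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    iu = np.triu_indices(len(x), k=1)
    c = int((prod[iu] > 0).sum())
    d = int((prod[iu] < 0).sum())
    if c + d == 0:
        return 0.0, 1.0
    g = (c - d) / (c + d)
    if abs(g) >= 1.0:
        return float(np.sign(g)), P_MIN
    z = g * np.sqrt((c + d) / (len(x) * (1.0 - g * g)))
    return float(g), float(2.0 * stats.norm.sf(abs(z)))


def correlation_test(scores: np.ndarray, state: np.ndarray, method: str,
                     n_perm: int = 1000, seed: int = 0) -> AssociationResult:
    """Association between an activity profile and a continuous state.

    Distance correlation and Hoeffding's D are non-negative measures; their
    direction is borrowed from the Pearson sign on the same data so the
    downstream directional split remains defined.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(state, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("correlation tests need n >= 5")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("constant input vector")
    rng = np.random.default_rng(seed)

    if method in ("pearson", "lm"):
        r = float(np.corrcoef(x, y)[0, 1])
        p = _t_p_from_r(r, n)
        if method == "pearson":
            return AssociationResult(method, r, r, _sign(r), p)
        slope = r * np.std(y, ddof=1) / np.std(x, ddof=1)
        t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
        return AssociationResult(method, float(t), float(slope), _sign(slope), p)
    if method == "spearman":
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        r = float(np.corrcoef(rx, ry)[0, 1])
        return AssociationResult(method, r, r, _sign(r), _t_p_from_r(r, n))
    if method == "kendall":
        tau, p = stats.kendalltau(x, y, variant="b", method="asymptotic")
        tau = float(tau) if np.isfinite(tau) else 0.0
        p = float(p) if np.isfinite(p) else 1.0
        return AssociationResult(method, tau, tau, _sign(tau), p)
    if method == "biweight":
        r = _bicor(x, y)
        return AssociationResult(method, r, r, _sign(r), _t_p_from_r(r, n))
    if method == "percentage":
        r = _percentage_bend(x, y)
        return AssociationResult(method, r, r, _sign(r), _t_p_from_r(r, n))
    if method == "blomqvist":
        b, p = _blomqvist(x, y)
        return AssociationResult(method, b, b, _sign(b), p)
    if method == "gamma":
        g, p = _gamma_corr(x, y)
        return AssociationResult(method, g, g, _sign(g), p)
    if method == "hoeffding":
        d = _hoeffding_d(x, y)
        null = np.empty(n_perm)
        for b_ in range(n_perm):
            null[b_] = _hoeffding_d(x, rng.permutation(y))
        p = (1.0 + int((null >= d).sum())) / (1.0 + n_perm)
        pearson_sign = _sign(float(np.corrcoef(x, y)[0, 1]))
        return AssociationResult(method, float(d), float(d) * (pearson_sign or 1),
                                 pearson_sign, p)
    if method == "distance":
        A, B = _distance_corr_parts(x, y)
        r = _dcor_from_parts(A, B)
        null = np.empty(n_perm)
        for b_ in range(n_perm):
            perm = rng.permutation(n)
            null[b_] = _dcor_from_parts(A, B[np.ix_(perm, perm)])
        p = (1.0 + int((null >= r).sum())) / (1.0 + n_perm)
        pearson_sign = _sign(float(np.corrcoef(x, y)[0, 1]))
        return AssociationResult(method, r, r * (pearson_sign or 1), pearson_sign, p)
    raise ValueError(f"unknown correlation test {method!r}")


def correlation_stats_matrix(X: np.ndarray, state: np.ndarray, method: str,
                             n_perm: int = 1000, seed: int = 0) -> dict[str, np.ndarray]:
    """Row-wise correlation statistics; vectorized for the linear-model family
    (pearson, spearman, lm), looped for the specialty measures."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(state, dtype=float)
    n = X.shape[1]
    if method in ("pearson", "spearman", "lm"):
        if method == "spearman":
            Xr = stats.rankdata(X, axis=1)
            yr = stats.rankdata(y)
        else:
            Xr, yr = X, y
        xc = Xr - Xr.mean(axis=1, keepdims=True)
        yc = yr - yr.mean()
        denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ yc) / denom
        r = np.where(np.isfinite(r), np.clip(r, -1.0, 1.0), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
        p = np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), P_MIN, 1.0)
        if method == "lm":
            with np.errstate(invalid="ignore", divide="ignore"):
                slope = r * np.std(y, ddof=1) / X.std(axis=1, ddof=1)
            slope = np.where(np.isfinite(slope), slope, 0.0)
            return {"statistic": np.where(np.isfinite(t), t, 0.0), "effect": slope,
                    "p_two": p, "direction": np.sign(slope).astype(int)}
        return {"statistic": r, "effect": r, "p_two": p,
                "direction": np.sign(r).astype(int)}
    out = {"statistic": [], "effect": [], "p_two": [], "direction": []}
    for i in range(X.shape[0]):
        res = correlation_test(X[i], y, method, n_perm=n_perm, seed=seed + i)
        out["statistic"].append(res.statistic)
        out["effect"].append(res.effect)
        out["p_two"].append(res.p_two)
        out["direction"].append(res.direction)
    return {k: np.asarray(v) for k, v in out.items()}
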