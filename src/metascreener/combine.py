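"""Meta-analysis p-value combination and the directionality indices.

Twelve combiners merge the per-pipeline one-sided p-values within each
dataset (ten classical meta-analysis methods, the Cauchy combination test,
and the descriptive geometric mean); across datasets only the geometric mean
is used.  The combined activation/inhibition p-values are mapped to
ADI = mean over combiners of -log10(p_act) and IDI = mean of log10(p_inh),
and DI = ADI + IDI is the signed net evidence used for ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("metascreener")

P_MIN = 1e-300
P_MAX = 1.0 - 1e-16

COMBINERS: list[str] = ["invt", "invchisq", "logitp", "meanp", "meanz", "sumlog",
                        "sumz", "sump", "votep", "wilkinsonp", "cct", "geomean"]
METAP_COMBINERS: list[str] = COMBINERS[:10]


@dataclass
class CombinerResult:
    method: str
    p: float
    k: int

    def __post_init__(self) -> None:
        self.p = float(np.clip(self.p, P_MIN, 1.0))


def _clamp_input(ps: np.ndarray) -> np.ndarray:
    if np.any((ps <= 0) | (ps >= 1)):
        logger.debug("p-values at 0 or 1 clamped to the open unit interval")
    return np.clip(ps, P_MIN, P_MAX)


def _irwin_hall_cdf(s: float, k: int) -> float:
    """P(sum of k iid U(0,1) <= s).

    Exact alternating-sum form for k <= 30 (using the symmetry
    IH(s) = 1 - IH(k - s) to keep the sum short); the alternating terms
    overflow float64 for larger k, where the normal approximation
    N(k/2, k/12) is already accurate to well below combiner tolerances.
    """
    if s <= 0:
        return 0.0
    if s >= k:
        return 1.0
    if k > 30:
        return float(stats.norm.cdf((s - k / 2.0) / np.sqrt(k / 12.0)))
    if s > k / 2.0:
        return 1.0 - _irwin_hall_cdf(k - s, k)
    total = 0.0
    for j in range(int(np.floor(s)) + 1):
        total += (-1) ** j * comb(k, j) * (s - j) ** k
    return total / factorial(k)


def combine_pvalues(ps, method: str, invt_df: int = 100, votep_alpha: float = 0.5,
                    wilkinson_r: int = 1) -> CombinerResult:
    """Combine one-sided p-values with one of the twelve methods.

    All calibrated methods return a p-value that is uniform under independent
    uniform inputs; the geometric mean is a descriptive summary, not a
    calibrated test, but shares the (0, 1] range.
    """
    ps = np.asarray(list(ps), dtype=float)
    k = len(ps)
    if k == 0:
        raise ValueError("cannot combine an empty p-value list")
    ps = _clamp_input(ps)

    if method == "sumlog":          # Fisher
        x = -2.0 * np.log(ps).sum()
        p = stats.chi2.sf(x, df=2 * k)
    elif method == "sumz":          # Stouffer
        z = stats.norm.isf(ps).sum() / np.sqrt(k)
        p = stats.norm.sf(z)
    elif method == "meanz":
        z = stats.norm.isf(ps)
        sd = z.std(ddof=1) if k > 1 else 0.0
        if sd == 0.0:
            m = z.mean()
            p = 0.5 if m == 0 else (P_MIN if m > 0 else 1.0)
        else:
            t = z.mean() / (sd / np.sqrt(k))
            p = stats.t.sf(t, df=k - 1)
    elif method == "meanp":         # Edgington's mean-p normal form
        if k < 4:
            # normal approximation is poor for tiny k; fall back to the exact
            # Irwin-Hall form on the mean
            p = _irwin_hall_cdf(ps.sum(), k)
        else:
            z = (0.5 - ps.mean()) * np.sqrt(12.0 * k)
            p = stats.norm.sf(z)
    elif method == "sump":          # Edgington's additive method (exact)
        p = _irwin_hall_cdf(ps.sum(), k)
    elif method == "logitp":
        c = np.sqrt(k * np.pi ** 2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
        t = -np.sum(np.log(ps / (1.0 - ps))) / c
        p = stats.t.sf(t, df=5 * k + 4)
    elif method == "invchisq":
        x = stats.chi2.isf(ps, df=1).sum()
        p = stats.chi2.sf(x, df=k)
    elif method == "invt":
        nu = invt_df
        z = stats.t.isf(ps, df=nu).sum() / np.sqrt(k * nu / (nu - 2.0))
        p = stats.norm.sf(z)
    elif method == "votep":
        pos = int((ps <= votep_alpha).sum())
        p = stats.binom.sf(pos - 1, k, 0.5)
    elif method == "wilkinsonp":
        r = min(wilkinson_r, k)
        p_r = np.sort(ps)[r - 1]
        p = stats.beta.cdf(p_r, r, k - r + 1)
    elif method == "cct":           # Cauchy combination test
        t = np.mean(np.tan((0.5 - ps) * np.pi))
        p = 0.5 - np.arctan(t) / np.pi
    elif method == "geomean":
        p = float(np.exp(np.log(ps).mean()))
    else:
        raise ValueError(f"unknown combiner {method!r}")
    return CombinerResult(method, float(p), k)


def combine_within_dataset(p_act: list[float], p_inh: list[float],
                           combiners: list[str] | None = None,
                           **kwargs) -> dict[str, tuple[float, float]]:
    """Apply each combiner independently to the activation and inhibition
    one-sided p-value lists of one dataset."""
    combiners = combiners or COMBINERS
    if len(p_act) != len(p_inh) or len(p_act) == 0:
        raise ValueError("direction lists must be same non-zero length")
    out = {}
    for m in combiners:
        out[m] = (combine_pvalues(p_act, m, **kwargs).p,
                  combine_pvalues(p_inh, m, **kwargs).p)
    return out


def combine_across_datasets(per_dataset: list[dict[str, tuple[float, float]]]
                            ) -> dict[str, tuple[float, float]]:
    """Geometric mean per combiner and direction across datasets."""
    if not per_dataset:
        raise ValueError("no datasets to combine")
    combiners = list(per_dataset[0])
    out = {}
    for m in combiners:
        pa = np.array([d[m][0] for d in per_dataset])
        pi = np.array([d[m][1] for d in per_dataset])
        out[m] = (float(np.exp(np.log(np.clip(pa, P_MIN, 1.0)).mean())),
                  float(np.exp(np.log(np.clip(pi, P_MIN, 1.0)).mean())))
    return out


@dataclass
class SignatureIndices:
    adi: float
    idi: float
    di: float
    per_combiner: dict[str, tuple[float, float]] = field(default_factory=dict)


def directionality_indices(per_combiner: dict[str, tuple[float, float]]) -> SignatureIndices:
    """ADI/IDI/DI from the per-combiner directional p-values.

    ADI averages -log10(p_act) over the enabled combiners (non-negative),
    IDI averages log10(p_inh) (non-positive), and DI is their sum.
    """
    if not per_combiner:
        raise ValueError("no combiner results")
    adi = float(np.mean([-np.log10(max(pa, P_MIN)) for pa, _ in per_combiner.values()]))
    idi = float(np.mean([np.log10(max(pi, P_MIN)) for _, pi in per_combiner.values()]))
    return SignatureIndices(adi, idi, adi + idi, dict(per_combiner))


@dataclass
class DirectionalityTable:
    """Final per-signature ranking with per-combiner and per-dataset detail."""

    table: pd.DataFrame                     # signature-indexed: ADI, IDI, DI, rank
    per_combiner: dict[str, dict[str, tuple[float, float]]]
    per_dataset: dict[str, dict[str, dict[str, tuple[float, float]]]]

    @property
    def di(self) -> pd.Series:
        return self.table["DI"]

    def to_tsv(self, path) -> None:
        wide = self.table.copy()
        for m in sorted({m for pc in self.per_combiner.values() for m in pc}):
            wide[f"ADI_{m}"] = [-np.log10(max(self.per_combiner[s][m][0], P_MIN))
                                if m in self.per_combiner[s] else np.nan for s in wide.index]
            wide[f"IDI_{m}"] = [np.log10(max(self.per_combiner[s][m][1], P_MIN))
                                if m in self.per_combiner[s] else np.nan for s in wide.index]
        wide.to_csv(path, sep="\t", index_label="signature")


def build_directionality_table(per_signature: dict[str, dict[str, tuple[float, float]]],
                               per_dataset: dict[str, dict[str, dict[str, tuple[float, float]]]] | None = None
                               ) -> DirectionalityTable:
    """Assemble, sort (DI desc, ADI desc, name) and rank the final table."""
    rows = {}
    for sig, pc in per_signature.items():
        ind = directionality_indices(pc)
        rows[sig] = {"ADI": ind.adi, "IDI": ind.idi, "DI": ind.di}
    df = pd.DataFrame.from_dict(rows, orient="index")
    # deterministic order: DI desc, ties by ADI desc, then name asc
    df["_name"] = df.index
    df = df.sort_values(["DI", "ADI", "_name"], ascending=[False, False, True],
                        kind="mergesort").drop(columns="_name")
    df["rank"] = np.arange(1, len(df) + 1)
    return DirectionalityTable(df, per_signature, per_dataset or {})
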