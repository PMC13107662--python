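"""Core domain types and file I/O.

An :class:`ExpressionDataset` is a named gene-by-sample numeric matrix with a
per-sample annotation — either binary activation/inhibition labels (for the
differential mode) or a continuous state value per sample (for the
correlative mode).  Gene signatures are held in a :class:`SignatureCollection`
backed by the GMT format.  All run-time options live in :class:`RunConfig`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("metascreener")

ACTIVATION = "activation"
INHIBITION = "inhibition"


def canonical_gene(symbol: str) -> str:
    """Canonical form of a gene symbol: whitespace-stripped, uppercase.

    Idempotent by construction; no external symbol remapping is attempted.
    """
    return str(symbol).strip().upper()


@dataclass
class BinaryLabels:
    """Mapping sample id -> activation/inhibition group label."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {ACTIVATION, INHIBITION}
        if bad:
            raise ValueError(f"labels must be '{ACTIVATION}' or '{INHIBITION}', got {sorted(bad)}")

    def mask(self, samples: list[str]) -> np.ndarray:
        """Boolean array: True where the sample is in the activation group."""
        return np.array([self.labels[s] == ACTIVATION for s in samples])

    def group_sizes(self, samples: list[str]) -> tuple[int, int]:
        m = self.mask(samples)
        return int(m.sum()), int((~m).sum())


@dataclass
class ContinuousState:
    """Mapping sample id -> real-valued phenotypic state."""

    values: dict[str, float]

    def vector(self, samples: list[str]) -> np.ndarray:
        return np.array([float(self.values[s]) for s in samples])

    def is_constant(self, samples: list[str]) -> bool:
        v = self.vector(samples)
        return bool(np.all(v == v[0]))


@dataclass
class ExpressionDataset:
    """Named gene x sample expression matrix plus per-sample annotation.

    ``values`` is a pandas DataFrame indexed by canonical gene symbols with
    sample ids as columns.  Units are arbitrary but assumed comparable within
    the dataset (recalibration is the caller's responsibility).
    """

    name: str
    values: pd.DataFrame
    annotation: BinaryLabels | ContinuousState | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError(f"dataset {self.name}: duplicate gene symbols after canonicalization")
        if self.values.columns.has_duplicates:
            raise ValueError(f"dataset {self.name}: duplicate sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError(f"dataset {self.name}: non-finite values in matrix")
        if self.annotation is not None:
            covered = (
                set(self.annotation.labels)
                if isinstance(self.annotation, BinaryLabels)
                else set(self.annotation.values)
            )
            missing = set(self.samples) - covered
            if missing:
                raise ValueError(
                    f"dataset {self.name}: annotation missing for samples {sorted(missing)[:5]}"
                )

    def subset_samples(self, samples: list[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.name, self.values[samples], self.annotation)

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        return ExpressionDataset(self.name, values, self.annotation)


@dataclass
class SignatureCollection:
    """Ordered mapping signature name -> deduplicated gene list."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"signature {name!r} is empty")
            deduped = list(dict.fromkeys(canonical_gene(g) for g in genes))
            if len(deduped) < len(genes):
                logger.warning("signature %s: %d duplicate genes dropped", name, len(genes) - len(deduped))
            self.sets[name] = deduped

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def subset(self, names: list[str]) -> "SignatureCollection":
        return SignatureCollection({n: list(self.sets[n]) for n in names},
                                   {n: self.descriptions.get(n, "") for n in names})

    def coverage(self, dataset: ExpressionDataset) -> dict[str, float]:
        """Fraction of each signature's genes present in the dataset."""
        present = set(dataset.genes)
        return {n: sum(g in present for g in gs) / len(gs) for n, gs in self.sets.items()}


@dataclass
class RunConfig:
    """All knobs of a screening run; every stochastic step derives from ``seed``."""

    mode: str = "diff"  # diff | cor | unsupervised
    scorers: list[str] | None = None      # None -> full registry
    diff_tests: list[str] | None = None
    cor_tests: list[str] | None = None
    combiners: list[str] | None = None
    min_set_coverage: float = 0.5
    seed: int = 0
    # enrichment parameters
    ora_top_k: int = 1000
    aucell_max_rank_fraction: float = 0.05   # top 5% of genes by default
    ucell_max_rank: int = 1500
    ssgsea_alpha: float = 0.25
    gsva_bandwidth_factor: float = 4.0       # kernel bandwidth = gene sd / factor
    n_perm_scorer: int = 100                 # norm_/corr_ wmean/wsum null size
    n_perm_fgsea: int = 500
    tree_max_depth: int = 3
    tree_min_leaf: int = 5
    # association parameters
    n_perm_assoc: int = 1000
    invt_df: int = 100
    votep_alpha: float = 0.5
    wilkinson_r: int = 1
    linear_scale: bool = False               # apply log2(x+1) before gene-level FC
    out_dir: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _collapse_duplicate_genes(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if df.index.has_duplicates:
        n = int(df.index.duplicated().sum())
        logger.warning("%s: collapsing %d duplicate gene rows by mean", name, n)
        df = df.groupby(level=0, sort=False).mean()
    return df


def read_expression_matrix(path: str | Path, fmt: str | None = None,
                           name: str | None = None) -> ExpressionDataset:
    """Read a gene x sample matrix from TSV/CSV or a Matrix Market triplet.

    TSV/CSV layout: first column gene symbols, header row of sample ids.
    MTX triplet: ``path`` is the coordinate file; sidecar files with suffixes
    ``.genes.txt`` and ``.samples.txt`` (one name per line) must sit next to it.
    Duplicate gene rows (after canonicalization) are collapsed by mean.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}.get(path.suffix, "tsv")
    name = name or path.stem

    if fmt == "mtx":
        from scipy.io import mmread

        genes_file = path.with_suffix(".genes.txt")
        samples_file = path.with_suffix(".samples.txt")
        if not genes_file.exists() or not samples_file.exists():
            raise FileNotFoundError(f"mtx triplet requires {genes_file} and {samples_file}")
        mat = np.asarray(mmread(path).todense(), dtype=float)
        genes = [canonical_gene(g) for g in genes_file.read_text().split()]
        samples = samples_file.read_text().split()
        df = pd.DataFrame(mat, index=genes, columns=samples)
    else:
        sep = "\t" if fmt == "tsv" else ","
        header = Path(path).open().readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) < len(header):
            dup = next(h for h in header if header.count(h) > 1)
            raise ValueError(f"{path}: duplicate sample id {dup!r}")
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        bad = df.columns[df.dtypes == object]
        if len(bad):
            col = bad[0]
            row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(f"{path}: malformed numeric cell at row {row!r}, column {col!r}")
        df.index = [canonical_gene(g) for g in df.index]

    if pd.Index(df.columns).has_duplicates:
        dup = pd.Index(df.columns)[pd.Index(df.columns).duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df = _collapse_duplicate_genes(df, name)
    return ExpressionDataset(name=name, values=df.astype(float))


def write_expression_matrix(dataset: ExpressionDataset, path: str | Path) -> None:
    # %.17g round-trips float64 exactly
    dataset.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_gmt(path: str | Path) -> SignatureCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        name, description, *genes = fields
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise ValueError(f"{path}:{lineno}: signature {name!r} has no genes")
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate signature name {name!r}")
        sets[name] = genes
        desc[name] = description
    return SignatureCollection(sets, desc)


def write_gmt(signatures: SignatureCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, signatures.descriptions.get(name, "")] + genes)
        for name, genes in signatures.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation(path: str | Path, kind: str = "auto") -> BinaryLabels | ContinuousState:
    """Read a two-column TSV ``sample <tab> label-or-value`` (no header required).

    ``kind='auto'`` returns BinaryLabels when every value is one of the two
    group labels, ContinuousState otherwise.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "value"], dtype=str)
    if df["sample"].iloc[0] in ("sample", "sample_id"):
        df = df.iloc[1:]
    mapping = dict(zip(df["sample"], df["value"]))
    vals = set(mapping.values())
    if kind == "binary" or (kind == "auto" and vals <= {ACTIVATION, INHIBITION}):
        return BinaryLabels(mapping)
    return ContinuousState({k: float(v) for k, v in mapping.items()})


def write_annotation(ann: BinaryLabels | ContinuousState, path: str | Path) -> None:
    mapping = ann.labels if isinstance(ann, BinaryLabels) else ann.values
    Path(path).write_text("".join(f"{k}\t{v}\n" for k, v in mapping.items()))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Report-only outcome of input validation; never mutates its inputs.

    ``coverage[dataset][signature]`` is the fraction of the signature's genes
    present in the dataset; signatures under ``min_set_coverage`` there are
    listed in ``excluded_signatures[dataset]``.  Datasets unusable in the
    requested mode (constant state, one-sample class) appear in
    ``excluded_datasets`` with a reason.
    """

    coverage: dict[str, dict[str, float]]
    excluded_signatures: dict[str, list[str]]
    excluded_datasets: dict[str, str]

    def retained_signatures(self, dataset_name: str, signatures: SignatureCollection) -> list[str]:
        dropped = set(self.excluded_signatures.get(dataset_name, []))
        return [n for n in signatures.names if n not in dropped]


def validate_inputs(datasets: list[ExpressionDataset], signatures: SignatureCollection,
                    config: RunConfig) -> ValidationReport:
    coverage: dict[str, dict[str, float]] = {}
    excluded_sigs: dict[str, list[str]] = {}
    excluded_ds: dict[str, str] = {}
    for ds in datasets:
        cov = signatures.coverage(ds)
        coverage[ds.name] = cov
        excluded_sigs[ds.name] = [n for n, c in cov.items() if c < config.min_set_coverage]
        if config.mode == "cor":
            if not isinstance(ds.annotation, ContinuousState):
                excluded_ds[ds.name] = "no continuous state annotation"
            elif ds.annotation.is_constant(ds.samples):
                excluded_ds[ds.name] = "constant state (zero variance)"
        elif config.mode == "diff":
            if not isinstance(ds.annotation, BinaryLabels):
                excluded_ds[ds.name] = "no binary labels"
            else:
                n1, n0 = ds.annotation.group_sizes(ds.samples)
                if min(n1, n0) < 2:
                    excluded_ds[ds.name] = f"class with <2 samples ({n1} vs {n0})"
    return ValidationReport(coverage, excluded_sigs, excluded_ds)
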