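"""Transcriptomic machinery: expression units, ClaNC signatures, ssGSEA, ORA.

ClaNC (classification to nearest centroids) selects an equal number of
signature genes per class by a pooled-SD t-like statistic and predicts by
standardized distance to class centroids; the signature size is chosen by
stratified cross-validation. ssGSEA scores one sample at a time with a
rank-weighted running sum. Over-representation of a gene list in a gene set
is tested with the one-sided hypergeometric (Fisher) tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ClancModel",
    "EnrichmentResult",
    "rpkm",
    "log_transform",
    "clanc_train",
    "clanc_predict",
    "clanc_cv",
    "ssgsea",
    "fisher_ora",
    "read_gmt",
    "write_gmt",
]


# --------------------------------------------------------------------------
# expression units


def rpkm(counts: pd.DataFrame, gene_lengths, library_sizes) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM[g, s] = 1e9 * counts[g, s] / (length[g] * library_size[s]).
    """
    counts = pd.DataFrame(counts)
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative read counts")
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive for every gene")
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("library sizes must be positive for every sample")
    values = 1e9 * counts.to_numpy(dtype=float) / np.outer(lengths, libs)
    out = pd.DataFrame(values, index=counts.index, columns=counts.columns)
    out.attrs["transform"] = "raw"
    return out


def log_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1), correcting the skew of raw RPKM; refuses to re-apply."""
    if expr.attrs.get("transform") == "log":
        raise ValueError("expression matrix is already log-transformed")
    if (expr.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    out = np.log2(expr + 1.0)
    out.attrs["transform"] = "log"
    return out


# --------------------------------------------------------------------------
# ClaNC


@dataclass
class ClancModel:
    class_labels: list
    centroids: pd.DataFrame  # union of selected genes x classes
    pooled_sd: pd.Series  # per selected gene
    selected_genes: dict  # class -> list of exactly `genes_per_class` genes
    genes_per_class: int
    s0: float
    cv_curve: pd.Series | None = None


def _class_stats(values: np.ndarray, labels: np.ndarray, classes: list):
    n = values.shape[1]
    overall = values.mean(axis=1)
    means = {}
    ss_within = np.zeros(values.shape[0])
    for c in classes:
        cols = labels == c
        means[c] = values[:, cols].mean(axis=1)
        ss_within += ((values[:, cols] - means[c][:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss_within / (n - len(classes)))
    return overall, means, pooled_sd


def clanc_train(expr: pd.DataFrame, labels, genes_per_class: int) -> ClancModel:
    """Select a balanced signature and build class centroids.

    Per gene g and class c the score is
    ``d[g,c] = (mean_c - overall_mean) / (m_c * (pooled_sd + s0))`` with
    ``m_c = sqrt(1/n_c - 1/n)``; genes are assigned greedily to classes in
    decreasing |d| under a per-class quota of ``genes_per_class``, no gene
    serving two classes. ``s0`` is the median pooled SD (shrinkage offset).
    """
    expr = pd.DataFrame(expr)
    labels = pd.Series(labels, index=expr.columns if not isinstance(labels, pd.Series) else None)
    if isinstance(labels, pd.Series):
        labels = labels.reindex(expr.columns)
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("need >=2 classes")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise ValueError(f"every class needs >=2 samples, got {counts.to_dict()}")
    if genes_per_class * len(classes) > expr.shape[0]:
        raise ValueError(
            f"quota unsatisfiable: {genes_per_class} x {len(classes)} classes "
            f"> {expr.shape[0]} genes"
        )
    values = expr.to_numpy(dtype=float)
    lab = labels.to_numpy()
    n = values.shape[1]
    overall, means, pooled_sd = _class_stats(values, lab, classes)
    s0 = float(np.median(pooled_sd))
    d = np.empty((values.shape[0], len(classes)))
    for ci, c in enumerate(classes):
        m_c = np.sqrt(1.0 / counts[c] - 1.0 / n)
        d[:, ci] = (means[c] - overall) / (m_c * (pooled_sd + s0))

    order = np.argsort(-np.abs(d), axis=None)  # flat indices, decreasing |d|
    selected: dict = {c: [] for c in classes}
    taken = np.zeros(values.shape[0], dtype=bool)
    need = genes_per_class * len(classes)
    assigned = 0
    for flat in order:
        g, ci = np.unravel_index(flat, d.shape)
        c = classes[ci]
        if taken[g] or len(selected[c]) >= genes_per_class:
            continue
        selected[c].append(expr.index[g])
        taken[g] = True
        assigned += 1
        if assigned == need:
            break
    union = [g for c in classes for g in selected[c]]
    centroids = pd.DataFrame({c: pd.Series(means[c], index=expr.index)[union] for c in classes})
    return ClancModel(
        class_labels=classes,
        centroids=centroids,
        pooled_sd=pd.Series(pooled_sd, index=expr.index)[union],
        selected_genes=selected,
        genes_per_class=genes_per_class,
        s0=s0,
    )


def clanc_predict(model: ClancModel, expr: pd.DataFrame) -> pd.Series:
    """Nearest-centroid labels: argmin over classes of the standardized
    squared distance over that class's own signature genes; ties go to the
    first class in model order."""
    expr = pd.DataFrame(expr)
    missing = [g for g in model.centroids.index if g not in expr.index]
    if missing:
        raise ValueError(f"expression matrix lacks model genes: {missing[:5]}")
    scores = np.zeros((expr.shape[1], len(model.class_labels)))
    for ci, c in enumerate(model.class_labels):
        genes = model.selected_genes[c]
        x = expr.loc[genes].to_numpy(dtype=float)
        mu = model.centroids.loc[genes, c].to_numpy()[:, None]
        sd = (model.pooled_sd.loc[genes].to_numpy() + model.s0)[:, None]
        scores[:, ci] = (((x - mu) / sd) ** 2).sum(axis=0)
    best = np.argmin(scores, axis=1)  # argmin takes the first minimum: tie rule
    return pd.Series([model.class_labels[i] for i in best], index=expr.columns)


def clanc_cv(expr: pd.DataFrame, labels, candidate_sizes, n_folds: int = 5,
             seed: int = 0):
    """Stratified-CV misclassification per candidate signature size.

    Returns ``(cv_curve, chosen)`` where chosen is the smallest size
    attaining the minimum mean error.
    """
    expr = pd.DataFrame(expr)
    labels = pd.Series(labels, index=expr.columns) if not isinstance(labels, pd.Series) else labels.reindex(expr.columns)
    counts = labels.value_counts()
    if (counts < n_folds).any():
        raise ValueError(
            f"class too small to stratify into {n_folds} folds: {counts.to_dict()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cols = np.arange(expr.shape[1])
    errors = {size: [] for size in candidate_sizes}
    for train_idx, test_idx in skf.split(cols, labels.to_numpy()):
        tr = expr.iloc[:, train_idx]
        te = expr.iloc[:, test_idx]
        y_tr = labels.iloc[train_idx]
        y_te = labels.iloc[test_idx]
        for size in candidate_sizes:
            model = clanc_train(tr, y_tr, size)
            pred = clanc_predict(model, te)
            errors[size].append(float((pred.to_numpy() != y_te.to_numpy()).mean()))
    curve = pd.Series({s: float(np.mean(e)) for s, e in errors.items()}).sort_index()
    chosen = int(min(s for s, v in curve.items() if v == curve.min()))
    return curve, chosen


# --------------------------------------------------------------------------
# ssGSEA


def _ssgsea_sample(values: np.ndarray, genes: np.ndarray, in_set: np.ndarray,
                   alpha: float) -> float:
    """Running-sum enrichment score for one sample.

    Genes are ranked by expression descending (ties broken by gene id);
    in-set genes contribute weights (N - position)^alpha normalised over the
    set, out-of-set genes a uniform ECDF step.
    """
    n = values.size
    order = np.lexsort((genes, -values))  # descending value, then gene id
    in_sorted = in_set[order]
    weights = (n - np.arange(n)).astype(float) ** alpha
    w_in = np.where(in_sorted, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    n_out = n - in_sorted.sum()
    p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(expr: pd.DataFrame, gene_sets: dict, alpha: float = 0.25,
           normalize: bool = False) -> pd.DataFrame:
    """Single-sample GSEA scores (gene sets x patients).

    With ``normalize=True`` all scores are rescaled by the global
    max-minus-min across the score matrix (Barbie-style min-max); off by
    default.
    """
    expr = pd.DataFrame(expr)
    genes = expr.index.to_numpy()
    gene_pos = pd.Index(genes)
    n = len(genes)
    values = expr.to_numpy(dtype=float)
    rows = {}
    for name, members in gene_sets.items():
        in_set = np.zeros(n, dtype=bool)
        idx = gene_pos.get_indexer(pd.Index(members).unique())
        idx = idx[idx >= 0]
        if idx.size == 0:
            raise ValueError(f"gene set {name!r} has no overlap with the matrix")
        if idx.size == n:
            raise ValueError(f"gene set {name!r} covers the whole gene universe")
        in_set[idx] = True
        rows[name] = [
            _ssgsea_sample(values[:, j], genes, in_set, alpha)
            for j in range(values.shape[1])
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)
    if normalize:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    return out


# --------------------------------------------------------------------------
# over-representation


@dataclass
class EnrichmentResult:
    set_name: str
    statistic: float  # odds ratio
    p_value: float
    adjusted_p: float | None
    direction: str
    overlap: int


def fisher_ora(gene_list, gene_set, universe, set_name: str = "") -> EnrichmentResult:
    """One-sided hypergeometric over-representation of a list in a set.

    p = P(overlap >= observed) drawing |list| genes from the universe;
    the odds ratio uses a 0.5 continuity correction when any 2x2 cell is 0.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    gl = set(gene_list) & universe
    gs = set(gene_set) & universe
    overlap = len(gl & gs)
    m = len(universe)
    p = float(stats.hypergeom.sf(overlap - 1, m, len(gs), len(gl)))
    a = overlap
    b = len(gl) - overlap
    c = len(gs) - overlap
    d = m - len(gl) - len(gs) + overlap
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds = (a * d) / (b * c)
    return EnrichmentResult(
        set_name=set_name,
        statistic=float(odds),
        p_value=min(p, 1.0),
        adjusted_p=None,
        direction="over",
        overlap=overlap,
    )


# --------------------------------------------------------------------------
# GMT files


def read_gmt(path) -> dict:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
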