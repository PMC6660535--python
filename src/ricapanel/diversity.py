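"""Population-structure analyses: pairwise polymorphism, PCA, Ward
clustering, silhouette-based cluster-number selection, and PC-space
nearest-centroid classification of unlabeled accessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import GenotypeError, GenotypeMatrix


# ---------------------------------------------------------------------------
# pairwise polymorphism
# ---------------------------------------------------------------------------

@dataclass
class PairwisePolymorphism:
    """Symmetric polymorphic-SNP counts over accession pairs plus per-pair
    physical gap summaries between adjacent polymorphic SNPs."""

    counts: pd.DataFrame
    pair_gaps: pd.DataFrame  # columns pair_a, pair_b, median_gap_bp, min_gap_bp, max_gap_bp
    group_summary: pd.DataFrame | None


def pairwise_polymorphism(
    gm: GenotypeMatrix,
    groups: pd.Series | None = None,
    compute_gaps: bool = True,
) -> PairwisePolymorphism:
    """Polymorphic-SNP counts for every accession pair.

    A locus is polymorphic between two accessions when both carry
    non-missing homozygotes with different alleles.  Gap summaries are the
    median/min/max physical distance between adjacent polymorphic loci
    within chromosomes (undefined for pairs with < 2 polymorphic loci on
    every chromosome).
    """
    if gm.n_samples < 2:
        raise GenotypeError("need at least two samples")
    dose = gm.dosage()
    hom0 = (dose == 0.0).astype(np.float64)
    hom2 = (dose == 2.0).astype(np.float64)
    counts = hom0 @ hom2.T
    counts = counts + counts.T
    np.fill_diagonal(counts, 0.0)
    cdf = pd.DataFrame(counts.astype(int), index=gm.samples, columns=gm.samples)

    gap_rows = []
    if compute_gaps:
        pos = np.array([m.pos_bp for m in gm.markers], dtype=np.int64)
        chrom = pd.factorize(np.array([m.chrom for m in gm.markers]))[0]
        is0 = dose == 0.0
        is2 = dose == 2.0
        n = gm.n_samples
        for i in range(n):
            for j in range(i + 1, n):
                poly = (is0[i] & is2[j]) | (is2[i] & is0[j])
                idx = np.nonzero(poly)[0]
                if len(idx) >= 2:
                    same_chrom = chrom[idx[1:]] == chrom[idx[:-1]]
                    gaps = (pos[idx[1:]] - pos[idx[:-1]])[same_chrom]
                else:
                    gaps = np.array([], dtype=np.int64)
                if len(gaps):
                    gap_rows.append(
                        {
                            "pair_a": gm.samples[i],
                            "pair_b": gm.samples[j],
                            "n_polymorphic": len(idx),
                            "median_gap_bp": float(np.median(gaps)),
                            "min_gap_bp": float(gaps.min()),
                            "max_gap_bp": float(gaps.max()),
                        }
                    )
                else:
                    gap_rows.append(
                        {
                            "pair_a": gm.samples[i],
                            "pair_b": gm.samples[j],
                            "n_polymorphic": len(idx),
                            "median_gap_bp": np.nan,
                            "min_gap_bp": np.nan,
                            "max_gap_bp": np.nan,
                        }
                    )
    pair_gaps = pd.DataFrame(
        gap_rows,
        columns=["pair_a", "pair_b", "n_polymorphic", "median_gap_bp", "min_gap_bp", "max_gap_bp"],
    )

    summary = None
    if groups is not None:
        groups = groups.reindex(gm.samples)
        labels = sorted(set(groups.dropna()))
        rows = []
        arr = cdf.to_numpy()
        for a_i, ga in enumerate(labels):
            for gb in labels[a_i:]:
                ia = np.nonzero((groups == ga).to_numpy())[0]
                ib = np.nonzero((groups == gb).to_numpy())[0]
                if ga == gb:
                    vals = arr[np.ix_(ia, ib)][np.triu_indices(len(ia), k=1)]
                else:
                    vals = arr[np.ix_(ia, ib)].ravel()
                if len(vals) == 0:
                    continue
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "n_pairs": len(vals),
                        "mean_polymorphic": float(np.mean(vals)),
                        "median_polymorphic": float(np.median(vals)),
                        "q25": float(np.percentile(vals, 25)),
                        "q75": float(np.percentile(vals, 75)),
                    }
                )
        summary = pd.DataFrame(rows)
    return PairwisePolymorphism(counts=cdf, pair_gaps=pair_gaps, group_summary=summary)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """PCA of the dosage matrix with an auditable preprocessing record."""

    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    column_means: np.ndarray
    preprocessing: dict


def imputed_dosage(gm: GenotypeMatrix, scale: bool = False) -> np.ndarray:
    """0/1/2 dosage with per-marker mean imputation (and optional unit
    scaling); the shared preprocessing for PCA/clustering/kernels."""
    dose = gm.dosage()
    col_mean = np.nanmean(np.where(np.isnan(dose), np.nan, dose), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.nonzero(np.isnan(dose))
    dose[idx] = col_mean[idx[1]]
    if scale:
        sd = dose.std(axis=0, ddof=0)
        dose = dose / np.where(sd > 0, sd, 1.0)
    return dose


def pca(gm: GenotypeMatrix, scale: bool = False) -> PCAResult:
    """PCA on centered (optionally unit-scaled) mean-imputed dosages.

    Components carry a deterministic sign: the largest-magnitude loading of
    each component is positive.  Variance-explained fractions are over all
    components and sum to 1.
    """
    if gm.n_samples < 2 or gm.n_markers < 2:
        raise GenotypeError("PCA needs at least 2 samples and 2 markers")
    X = imputed_dosage(gm, scale=scale)
    mu = X.mean(axis=0)
    Xc = X - mu
    if not np.any(Xc):
        raise GenotypeError("zero-variance matrix: PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention
    for k in range(Vt.shape[0]):
        peak = np.argmax(np.abs(Vt[k]))
        if Vt[k, peak] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = s**2 / (gm.n_samples - 1)
    ratio = var / var.sum()
    scores = U * s
    cols = [f"PC{k+1}" for k in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=gm.samples, columns=cols),
        explained_variance_ratio=ratio,
        loadings=Vt.T,
        column_means=mu,
        preprocessing={"coding": "alt-allele dosage 0/1/2", "imputation": "marker mean",
                       "centered": True, "scaled": bool(scale)},
    )


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Ward dendrogram with a standard linkage matrix and Newick export."""

    linkage: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left = walk(node.get_left())
            right = walk(node.get_right())
            dl = node.dist - node.get_left().dist
            dr = node.dist - node.get_right().dist
            return f"({left}:{dl:.6g},{right}:{dr:.6g})"

        return walk(tree) + ";"


def ward_cluster(data: GenotypeMatrix | np.ndarray | pd.DataFrame) -> Dendrogram:
    """Agglomerative clustering with Euclidean distance and Ward linkage
    (squared dissimilarities in the Lance–Williams update)."""
    if isinstance(data, GenotypeMatrix):
        X = imputed_dosage(data)
        labels = list(data.samples)
    elif isinstance(data, pd.DataFrame):
        X = data.to_numpy(dtype=float)
        labels = [str(i) for i in data.index]
    else:
        X = np.asarray(data, dtype=float)
        labels = [str(i) for i in range(len(X))]
    if len(X) < 2:
        raise GenotypeError("clustering needs at least two items")
    if np.isnan(X).any():
        raise GenotypeError("NaN in clustering input; impute first")
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage=Z, labels=labels)


# ---------------------------------------------------------------------------
# silhouette k selection and PC-space classification
# ---------------------------------------------------------------------------

def pick_k_silhouette(
    scores: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(2, 11),
    seed: int = 0,
    n_init: int = 10,
) -> tuple[int, dict[int, float]]:
    """Average silhouette width of k-means clusterings over ``k_range``;
    best k is the argmax, ties resolved toward the smaller k."""
    X = scores.to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(scores, dtype=float)
    widths: dict[int, float] = {}
    for k in sorted(k_range):
        if k >= len(X):
            raise ValueError(f"k={k} must be smaller than the number of items {len(X)}")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        widths[k] = float(silhouette_score(X, lab)) if len(set(lab)) > 1 else 0.0
    best = max(widths, key=lambda k: (widths[k], -k))
    return best, widths


def silhouette_pc_subspace(result: PCAResult, min_var: float = 0.8, max_pc: int = 10) -> pd.DataFrame:
    """The PC score subspace used for cluster-number selection: the leading
    components capturing at least ``min_var`` of the variance, capped."""
    cum = np.cumsum(result.explained_variance_ratio)
    n = int(np.searchsorted(cum, min_var) + 1)
    n = min(max(n, 1), max_pc, result.scores.shape[1])
    return result.scores.iloc[:, :n]


def classify_undetermined(
    scores: pd.DataFrame,
    labeled: pd.Series,
    n_pcs: int = 2,
) -> pd.Series:
    """Nearest-centroid assignment of unlabeled samples in leading PC space.

    Centroids come from the labeled samples of each group; exact distance
    ties leave the sample unassigned (None).
    """
    labeled = labeled.dropna()
    groups = sorted(set(labeled))
    if len(groups) < 1:
        raise GenotypeError("no labeled samples provided")
    X = scores.iloc[:, :n_pcs]
    centroids = {}
    for g in groups:
        members = labeled.index[labeled == g]
        members = [s for s in members if s in X.index]
        if not members:
            raise GenotypeError(f"group {g!r} has no labeled samples among the scores")
        centroids[g] = X.loc[members].mean(axis=0).to_numpy()
    out = {}
    for s in X.index:
        if s in labeled.index:
            continue
        d = {g: float(np.linalg.norm(X.loc[s].to_numpy() - c)) for g, c in centroids.items()}
        ranked = sorted(d.items(), key=lambda kv: kv[1])
        if len(ranked) > 1 and np.isclose(ranked[0][1], ranked[1][1]):
            out[s] = None
        else:
            out[s] = ranked[0][0]
    return pd.Series(out, dtype=object)
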