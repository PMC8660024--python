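"""The three prototypical statistics computed from a region x gene matrix.

* **Correlated gene expression (CGE)** — region-by-region Pearson correlation
  of expression profiles across genes, compared against inter-regional
  Euclidean distance: the Spearman correlation over the strictly upper
  triangles of the two matrices.  Transcriptional similarity in the brain is
  expected to decay with separation distance, so this statistic is normally
  negative.

* **Gene co-expression (GCE)** — pairwise Euclidean distance between gene
  columns, scored against a set of gene-module labels with the silhouette
  statistic

  .. math:: s = \\frac{1}{N} \\sum_{i=1}^{N}
            \\frac{b(i) - a(i)}{\\max\\{a(i), b(i)\\}}

  where ``a(i)`` is the mean distance of gene *i* to the other genes of its
  module and ``b(i)`` the mean distance to the nearest neighbouring module.
  Positive values indicate assortative modules.  Genes in singleton modules
  contribute s_i = 0, as does the fully degenerate a = b = 0 case.

* **Regional gene expression (RGE)** — the absolute Spearman correlation
  between a regional phenotype vector and the region scores of the first
  principal component of the (column mean-centered) expression matrix.  The
  absolute value is taken because the sign of a principal component is
  arbitrary.

Regions flagged missing are dropped before every analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .errors import DegenerateInputError, ParameterError
from .types import ExpressionMatrix

#: largest tolerated fraction of undefined (constant-row) CGE pairs
MAX_UNDEFINED_CGE = 0.10


@dataclass(frozen=True)
class AnalysisEstimates:
    """Per-pipeline triplet of statistics."""

    cge_rho: float
    gce_silhouette: float
    rge_rho: float

    def as_tuple(self) -> tuple:
        return (self.cge_rho, self.gce_silhouette, self.rge_rho)


@dataclass(frozen=True)
class SilhouetteTerms:
    """Per-point silhouette ingredients (a = within, b = nearest-other)."""

    a: np.ndarray
    b: np.ndarray
    n: int
    s: float


def _present(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return matrix.drop_missing()


def cge_distance_correlation(
    matrix: ExpressionMatrix, centroids: pd.DataFrame
) -> float:
    """Spearman correlation between inter-regional distance and CGE.

    The CGE matrix is the Pearson correlation between region rows across
    genes; the statistic compares its strictly upper triangle with that of
    the Euclidean distance matrix of region centroids.  Pairs involving a
    constant region row are undefined; more than 10% undefined pairs raises.
    """
    matrix = _present(matrix)
    n = len(matrix.region_ids)
    if n < 3:
        raise DegenerateInputError(
            f"CGE requires at least 3 non-missing regions; got {n}"
        )
    missing_centroids = set(int(r) for r in matrix.region_ids) - set(
        int(i) for i in centroids.index
    )
    if missing_centroids:
        raise ParameterError(
            f"centroids missing for regions {sorted(missing_centroids)[:5]}"
        )
    coords = centroids.loc[matrix.region_ids, ["x", "y", "z"]].to_numpy(float)
    dist = squareform(pdist(coords))
    with np.errstate(invalid="ignore", divide="ignore"):
        cge = np.corrcoef(matrix.values)
    iu = np.triu_indices(n, k=1)
    cge_ut, dist_ut = cge[iu], dist[iu]
    undefined = ~np.isfinite(cge_ut)
    if undefined.mean() > MAX_UNDEFINED_CGE:
        raise DegenerateInputError(
            f"{undefined.mean():.0%} of CGE pairs are undefined "
            "(constant region rows)"
        )
    ok = ~undefined
    return float(spearmanr(dist_ut[ok], cge_ut[ok]).statistic)


def silhouette_terms(dist: np.ndarray, labels: np.ndarray) -> SilhouetteTerms:
    """Evaluate the silhouette statistic from a precomputed distance matrix."""
    labels = np.asarray(labels)
    n = len(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ParameterError("silhouette requires at least 2 modules")
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = members[labels[i]]
        others = own[own != i]
        if len(others) == 0:  # singleton module: s_i = 0 by convention
            continue
        a[i] = dist[i, others].mean()
        b[i] = min(dist[i, members[c]].mean() for c in uniq if c != labels[i])
        denom = max(a[i], b[i])
        s[i] = 0.0 if denom == 0 else (b[i] - a[i]) / denom
    return SilhouetteTerms(a=a, b=b, n=n, s=float(s.mean()))


def gce_silhouette(
    matrix: ExpressionMatrix, module_labels: pd.Series
) -> Tuple[float, SilhouetteTerms]:
    """Silhouette of gene modules on Euclidean gene-gene distances.

    Genes are restricted to the labeled set; distances are computed between
    gene columns over non-missing regions.
    """
    matrix = _present(matrix)
    genes = [g for g in matrix.gene_symbols if g in module_labels.index]
    if len(genes) < 2:
        raise DegenerateInputError("fewer than 2 labeled genes in the matrix")
    cols = [matrix.gene_symbols.index(g) for g in genes]
    points = matrix.values[:, cols].T  # genes x regions
    labels = module_labels.loc[genes].to_numpy()
    dist = squareform(pdist(points))
    terms = silhouette_terms(dist, labels)
    return terms.s, terms


def pc1_scores(values: np.ndarray) -> np.ndarray:
    """Region scores of the first principal component after column
    mean-centering, via singular value decomposition."""
    centered = values - values.mean(axis=0, keepdims=True)
    if not np.any(centered):
        raise DegenerateInputError("expression matrix has zero variance")
    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, 0] * sv[0]


def rge_pc1_correlation(
    matrix: ExpressionMatrix, phenotype: pd.Series
) -> float:
    """|Spearman rho| between the phenotype and PC1 region scores."""
    matrix = _present(matrix)
    n = len(matrix.region_ids)
    if n < 3:
        raise DegenerateInputError(
            f"RGE requires at least 3 non-missing regions; got {n}"
        )
    missing = set(int(r) for r in matrix.region_ids) - set(
        int(i) for i in phenotype.index
    )
    if missing:
        raise ParameterError(
            f"phenotype missing for regions {sorted(missing)[:5]}"
        )
    scores = pc1_scores(matrix.values)
    phen = phenotype.loc[matrix.region_ids].to_numpy(float)
    return float(abs(spearmanr(scores, phen).statistic))


def compute_estimates(
    matrix: ExpressionMatrix,
    centroids: pd.DataFrame,
    module_labels: Optional[pd.Series] = None,
    phenotype: Optional[pd.Series] = None,
) -> AnalysisEstimates:
    """All three statistics for one expression matrix (NaN where an input
    is not supplied)."""
    cge = cge_distance_correlation(matrix, centroids)
    gce = np.nan
    if module_labels is not None:
        gce, _ = gce_silhouette(matrix, module_labels)
    rge = np.nan
    if phenotype is not None:
        rge = rge_pc1_correlation(matrix, phenotype)
    return AnalysisEstimates(cge_rho=cge, gce_silhouette=gce, rge_rho=rge)
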