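"""Pairwise transcript-expression similarity, clustering, and heatmaps.

Two complementary comparisons are provided.  The *score* method works on a
per-gene fit vector: for each candidate family, the family's Akaike weight
multiplies its fitted parameters, and the blocks are concatenated in a
fixed order.  Two vectors u, v are compared through their Euclidean
distance d and the cosine of their angle:

    distance_value = min(1 - ln(d)/ln(d_max), 1)
    S = cos(theta) * distance_value

where d_max is the largest pairwise distance in the dataset.  S lies in
[-1, 1]; a score near 1 requires vectors that are both closely aligned and
of similar magnitude.  The *integral* method instead samples the two
best-fit curves over the diel cycle, min-max normalizes each (shape-only
comparison, invariant to positive affine rescaling), and returns the mean
absolute difference in [0, 1].

Clustering applies Ward-criterion agglomeration to the rows of the square
dissimilarity matrix (score converted as 1 - S; integral used directly).
Feeding the square matrix rows to the hierarchy as feature vectors is a
deliberate, documented dialect of the underlying routine.  Heatmaps are
assembled blockwise, one truncated-dendrogram leaf at a time, with a
stacked per-gene family-weight sidebar.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Mapping, Sequence, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .curves import CurveFitEnsemble, FAMILIES, FAMILY_ORDER, PERIOD
from .errors import ValidationError

log = logging.getLogger(__name__)

#: Default curve-sampling interval (h) for the integral method.
DEFAULT_DT = 0.1

#: Fixed slot layout of the fit vector: one block per family, in order.
VECTOR_SLOTS: Tuple[Tuple[str, int], ...] = tuple(
    (name, FAMILIES[name].n_params) for name in FAMILY_ORDER)
VECTOR_LENGTH = sum(n for _, n in VECTOR_SLOTS)


@dataclass
class FitVector:
    gene_id: str
    vector: np.ndarray


@dataclass
class PairScore:
    d: float
    cos_theta: float
    distance_value: float
    score: float


@dataclass
class SimilarityMatrix:
    genes: List[str]
    values: np.ndarray  # square, symmetric
    method: str  # "score" | "integral"


def vectorize(ensemble: CurveFitEnsemble) -> FitVector:
    """Weight-scaled parameter concatenation over all families.

    Zero-weight families contribute zero blocks (their parameters may be
    absent from the ensemble, e.g. for degenerate fixture ensembles).
    """
    parts = []
    for name, n_slots in VECTOR_SLOTS:
        if name not in ensemble.weights:
            raise ValidationError(
                f"gene {ensemble.gene_id}: missing weight for family '{name}'")
        w = ensemble.weights[name]
        fit = ensemble.fits.get(name)
        if w == 0.0 or fit is None or not all(map(math.isfinite, fit.params)):
            parts.append(np.zeros(n_slots))
        else:
            params = np.asarray(fit.params, dtype=float)
            if len(params) != n_slots:
                raise ValidationError(
                    f"gene {ensemble.gene_id}: family '{name}' has "
                    f"{len(params)} params, expected {n_slots}")
            parts.append(w * params)
    return FitVector(ensemble.gene_id, np.concatenate(parts))


def distance_value(d: float, dm: float) -> float:
    """Log-compressed mapping of a distance onto [0, 1] (natural log)."""
    if dm <= 0:
        raise ValidationError("dm must be positive")
    if d <= 0:
        return 1.0
    return min(1.0 - math.log(d) / math.log(dm), 1.0)


def score_pair(u: FitVector, v: FitVector, dm: float) -> PairScore:
    """Similarity score of two fit vectors given the dataset-wide d_max."""
    nu, nv = np.linalg.norm(u.vector), np.linalg.norm(v.vector)
    if nu == 0 or nv == 0:
        zero = u.gene_id if nu == 0 else v.gene_id
        raise ValidationError(
            f"gene {zero}: zero fit vector, angle undefined")
    d = float(np.linalg.norm(u.vector - v.vector))
    cos_theta = float(np.clip(u.vector @ v.vector / (nu * nv), -1.0, 1.0))
    if d == 0:
        cos_theta = 1.0  # identical vectors
    dv = distance_value(d, dm)
    return PairScore(d, cos_theta, dv, cos_theta * dv)


def _normalized_samples(ensemble: CurveFitEnsemble, grid: np.ndarray) -> np.ndarray:
    y = np.asarray(ensemble.query(grid), dtype=float)
    lo, hi = float(y.min()), float(y.max())
    if hi - lo <= 1e-12:  # flat curve: shape undefined, map to mid-scale
        log.warning("gene %s: flat curve in integral comparison", ensemble.gene_id)
        return np.full_like(y, 0.5)
    return (y - lo) / (hi - lo)


def integral_dissimilarity(e1: CurveFitEnsemble, e2: CurveFitEnsemble,
                           dt: float = DEFAULT_DT) -> float:
    """Mean absolute difference of min-max-normalized diel curves, in [0,1]."""
    n = PERIOD / dt
    if abs(n - round(n)) > 1e-9:
        raise ValidationError(f"dt={dt} must divide the {PERIOD}-h period evenly")
    grid = np.arange(0.0, PERIOD, dt)
    return float(np.mean(np.abs(_normalized_samples(e1, grid)
                                - _normalized_samples(e2, grid))))


def pairwise_matrix(ensembles: Sequence[CurveFitEnsemble], method: str = "integral",
                    dt: float = DEFAULT_DT) -> SimilarityMatrix:
    """All-pairs similarity (score) or dissimilarity (integral) matrix."""
    if len(ensembles) < 2:
        raise ValidationError("need at least 2 genes")
    genes = [e.gene_id for e in ensembles]
    n = len(ensembles)
    if method == "score":
        vecs = np.vstack([vectorize(e).vector for e in ensembles])
        dists = pdist(vecs)
        dm = float(dists.max())
        if dm <= 0:
            raise ValidationError("all fit vectors identical; dm undefined")
        if dm <= 1.0:
            # The log mapping needs dm > 1 to be monotone; rescale so the
            # largest distance maps to e.
            scale = math.e / dm
            log.warning("dataset d_max=%g <= 1; rescaling distances by %g",
                        dm, scale)
            dists = dists * scale
            dm = math.e
        dsq = squareform(dists)
        norms = np.linalg.norm(vecs, axis=1)
        if np.any(norms == 0):
            bad = genes[int(np.flatnonzero(norms == 0)[0])]
            raise ValidationError(f"gene {bad}: zero fit vector, angle undefined")
        cos = np.clip((vecs @ vecs.T) / np.outer(norms, norms), -1.0, 1.0)
        vals = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                d = dsq[i, j]
                c = 1.0 if i == j else cos[i, j]
                vals[i, j] = c * distance_value(d, dm)
        np.fill_diagonal(vals, 1.0)
    elif method == "integral":
        grid = np.arange(0.0, PERIOD, dt)
        norm = np.vstack([_normalized_samples(e, grid) for e in ensembles])
        vals = np.zeros((n, n))
        for i in range(n):
            diffs = np.abs(norm[i + 1:] - norm[i])
            if len(diffs):
                vals[i, i + 1:] = diffs.mean(axis=1)
        vals = vals + vals.T
    else:
        raise ValidationError(f"unknown method '{method}'")
    return SimilarityMatrix(genes, vals, method)


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_labels: np.ndarray  # cluster id per gene, 1..n_leaves
    leaf_order: np.ndarray  # gene indices in dendrogram order
    n_leaves: int


def to_dissimilarity(matrix: SimilarityMatrix) -> np.ndarray:
    """Score matrices convert as 1 - S; integral matrices pass through."""
    return 1.0 - matrix.values if matrix.method == "score" else matrix.values


def cluster(matrix: SimilarityMatrix, n_leaves: int) -> ClusterResult:
    """Ward-criterion hierarchy over the dissimilarity-matrix rows."""
    n = len(matrix.genes)
    if n_leaves > n:
        raise ValidationError(f"n_leaves={n_leaves} exceeds gene count {n}")
    dis = to_dissimilarity(matrix)
    # Rows of the square matrix serve as observations (documented dialect);
    # silence the library's uncondensed-matrix heuristic warning.
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Z = hierarchy.linkage(dis, method="ward")
    labels = hierarchy.fcluster(Z, t=n_leaves, criterion="maxclust")
    order = np.asarray(hierarchy.leaves_list(Z))
    return ClusterResult(Z, labels, order, n_leaves)


def assemble_heatmap(matrix: SimilarityMatrix, clustering: ClusterResult,
                     weights: Mapping[str, Mapping[str, float]], out_path,
                     highlight: Sequence[str] = (), sidebar_px: int = 6) -> np.ndarray:
    """Render the leaf-ordered similarity map plus a stacked-weight sidebar.

    The map is painted one dendrogram-leaf block of rows at a time (memory
    stays bounded by one block), stitched into the final square image, and
    written as PNG.  Each gene's sidebar row stacks the eight family
    weights as colored segments; a gene dominated by one family shows that
    family's color across most of its row.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    order = clustering.leaf_order
    vals = matrix.values[np.ix_(order, order)]
    lo, hi = float(vals.min()), float(vals.max())
    span = (hi - lo) or 1.0
    cmap = colormaps["viridis"]
    n = len(order)
    img = np.empty((n, n + sidebar_px * 8, 4))
    # blockwise fill, one leaf at a time
    ordered_labels = clustering.leaf_labels[order]
    family_colors = {name: colormaps["tab10"](i % 10)
                     for i, name in enumerate(FAMILY_ORDER)}
    genes_in_order = [matrix.genes[i] for i in order]
    for leaf in np.unique(ordered_labels):
        rows = np.flatnonzero(ordered_labels == leaf)
        block = cmap((vals[rows] - lo) / span)
        img[rows, :n] = block
        for r in rows:
            gene = genes_in_order[r]
            w = weights[gene]
            col = n
            for name in FAMILY_ORDER:
                seg = int(round(max(w.get(name, 0.0), 0.0) * sidebar_px * 8))
                seg = min(seg, n + sidebar_px * 8 - col)
                img[r, col:col + seg] = family_colors[name]
                col += seg
            if col < img.shape[1]:
                img[r, col:] = (1.0, 1.0, 1.0, 1.0)
    for gene in highlight:
        if gene in genes_in_order:
            r = genes_in_order.index(gene)
            img[r, :n, :3] = np.clip(img[r, :n, :3] + 0.25, 0, 1)
    plt.imsave(out_path, img)
    return img
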