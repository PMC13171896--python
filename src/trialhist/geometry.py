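"""Dimensionality and cross-session similarity of encoding dynamics.

The encoding weights of a variable form a neurons x (conditions x
timepoints) matrix. PCA across the neuron population yields (i) the
dimensionality of the population code — the minimum number of components
explaining 90% of the weight variance — and (ii) low-dimensional
trajectories of the encoding dynamics (e.g., the four trial-history
contexts traced over aligned trial time in the top principal components).

Trajectory shapes are compared between sessions with full Procrustes
analysis: the target shape X1 is optimally translated, uniformly scaled and
rotated onto the reference X2, and the residual disparity

    D^2(X1, X2) = || X2 - b X1 G - k^T ||^2,

normalized by the total variance of the reference, gives a dissimilarity in
[0, 1] (0 for identical shapes, 1 for maximal dissimilarity).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .encoding import DesignMatrix, EncodingFit


# --------------------------------------------------------------------------
# weight extraction and PCA
# --------------------------------------------------------------------------

def weight_tensor(
    fit: EncodingFit, design: DesignMatrix, variable: str
) -> tuple[np.ndarray, list]:
    """Neurons x (conditions x timepoints) weight matrix for one variable.

    Columns are ordered condition-major (all timepoints of the first
    condition, then the next); the returned column order lists the
    (condition, lag-or-bin) detail of each column. Columns are mean-centered
    across neurons.
    """
    if variable not in design.blocks:
        raise KeyError(f"variable {variable!r} not in design")
    sl = design.blocks[variable]
    W = fit.weights[sl, :].T  # neurons x columns
    order = [design.column_map[c][1] for c in range(sl.start, sl.stop)]
    return W - W.mean(axis=0, keepdims=True), order


def pca_dimensionality(weights: np.ndarray, threshold: float = 0.90) -> int:
    """Smallest number of PCs explaining at least ``threshold`` variance.

    ``weights`` has neurons as rows (observations); variance is taken
    across the neuron population.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    W = weights - weights.mean(axis=0, keepdims=True)
    sv = np.linalg.svd(W, compute_uv=False)
    var = sv**2
    tot = var.sum()
    if tot == 0:
        return 0
    cum = np.cumsum(var) / tot
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


@dataclass
class WeightShape:
    """Trajectory coordinates of a variable's encoding dynamics.

    ``matrix`` is (conditions x timepoints) rows by ``k`` PCA dims, rows
    ordered condition-major as recorded in ``row_order``.
    """

    matrix: np.ndarray
    variable: str
    row_order: list
    session: str | None = None
    subject: str | None = None


def project_dynamics(
    weights: np.ndarray,
    k: int,
    variable: str = "",
    row_order: list | None = None,
    session: str | None = None,
    subject: str | None = None,
) -> WeightShape:
    """Top-k principal coordinates of the weight columns.

    With neurons as observations, each principal component assigns a
    loading to every (condition, timepoint) column; plotting component 1
    against component 2 traces one trajectory per condition over aligned
    time. Loadings are scaled by the component standard deviations so the
    shape carries the variance structure.
    """
    n_obs, n_feat = weights.shape
    k = int(min(k, n_obs, n_feat))
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(weights)
    coords = pca.components_.T * np.sqrt(pca.explained_variance_)[None, :]
    return WeightShape(
        matrix=coords,
        variable=variable,
        row_order=row_order or list(range(n_feat)),
        session=session,
        subject=subject,
    )


# --------------------------------------------------------------------------
# Procrustes
# --------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    distance: float
    scale: float
    rotation: np.ndarray
    location: np.ndarray
    target: str | None = None
    reference: str | None = None


def procrustes_distance(
    target: WeightShape | np.ndarray, reference: WeightShape | np.ndarray
) -> ProcrustesResult:
    """Normalized full-Procrustes dissimilarity of two point configurations.

    Finds the translation, orthogonal rotation (reflections permitted) and
    positive uniform scale of the target minimizing the squared Frobenius
    distance to the reference; the residual is normalized by the centered
    reference's total variance so identical-up-to-similarity shapes score 0
    and maximally dissimilar ones 1.
    """
    X1 = target.matrix if isinstance(target, WeightShape) else np.asarray(target, float)
    X2 = (
        reference.matrix
        if isinstance(reference, WeightShape)
        else np.asarray(reference, float)
    )
    if X1.shape != X2.shape:
        raise ValueError(
            f"shape mismatch {X1.shape} vs {X2.shape}: both shapes must use "
            "the same row count and the per-variable maximal dimensionality"
        )
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    A, B = X1 - mu1, X2 - mu2
    na2 = float((A**2).sum())
    nb2 = float((B**2).sum())
    if na2 == 0 or nb2 == 0:
        raise ValueError("degenerate (zero-variance) shape")
    U, s, Vt = np.linalg.svd(A.T @ B)
    rotation = U @ Vt
    scale = float(s.sum() / na2)
    distance = float(max(0.0, 1.0 - s.sum() ** 2 / (na2 * nb2)))
    location = mu2 - scale * (mu1 @ rotation)
    return ProcrustesResult(
        distance=distance,
        scale=scale,
        rotation=rotation,
        location=location,
        target=getattr(target, "session", None),
        reference=getattr(reference, "session", None),
    )


def pairwise_similarity(
    shapes: list[WeightShape],
) -> pd.DataFrame:
    """Procrustes distances for every ordered session pair of one variable.

    Each unordered pair contributes one ordered comparison with the
    earlier-listed session as reference; rows are tagged within- vs
    across-subject. Subjects contributing a single session simply produce no
    within-subject rows.
    """
    rows = []
    for i, j in combinations(range(len(shapes)), 2):
        ref, tgt = shapes[i], shapes[j]
        res = procrustes_distance(tgt, ref)
        rows.append(
            {
                "variable": tgt.variable,
                "target": tgt.session,
                "reference": ref.session,
                "pair": (
                    "within-subject"
                    if tgt.subject is not None and tgt.subject == ref.subject
                    else "across-subject"
                ),
                "distance": res.distance,
            }
        )
    return pd.DataFrame(rows)
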