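"""Cortex / medulla / calyx separation inside the registered kidney contour.

Clustering runs on the average of the registered global-inversion images,
which show the best gray-value separation between calyces, medulla,
cortex and background.  Each pixel inside (a slightly dilated) kidney
contour is described by two features: its min-max-normalized gray value,
premultiplied by the user parameter alpha, and its normalized distance to
the kidney's center of gravity.  The distance feature makes the clusters
spatially coherent; alpha shifts the cortex/medulla boundary (alpha = 1
by default).  Clusters are mapped to anatomical labels geometrically:
the lowest-gray cluster is background, the most central of the rest is
the calyceal region, and of the remaining two the more peripheral is
cortex.  A final morphological filter demotes every cortex pixel that
touches a non-cortex label, trading a slightly under-segmented cortex for
the guarantee that the cortical ROI contains cortex only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import disk
from sklearn.cluster import KMeans

from .perfusion import AslSeries
from .transform import warp_image

__all__ = [
    "BACKGROUND",
    "CALYX",
    "MEDULLA",
    "CORTEX",
    "ClusterParams",
    "average_registered_globals",
    "cluster_compartments",
    "purify_cortex",
]

BACKGROUND, CALYX, MEDULLA, CORTEX = 0, 1, 2, 3

#: Neighbor scan order for cortex demotion: direct neighbors before diagonals.
_NEIGHBOR_ORDER = ((-1, 0), (1, 0), (0, -1), (0, 1), (-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class ClusterParams:
    """K-means settings; ``alpha`` premultiplies the gray-value feature."""

    alpha: float = 1.0
    k: int = 4
    distance_weight: float = 1.0
    seed: int = 0
    max_iter: int = 300

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k < 3:
            raise ValueError("need at least 3 clusters (calyx, medulla, cortex)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def average_registered_globals(series: AslSeries, registrations, order: int = 3) -> np.ndarray:
    """Mean of the good pairs' global images, resampled into the reference frame.

    Each global image is pulled back by the inverse of its recovered
    transform (cubic interpolation by default, to keep the compartment
    edges that clustering relies on as sharp as possible); pairs flagged
    bad by QC are excluded.
    """
    good = [i for i, r in enumerate(registrations) if r.is_good]
    if not good:
        raise ValueError("no good registrations: cannot average global images")
    if len(registrations) != series.n_pairs:
        raise ValueError("one registration result per pair is required")
    acc = np.zeros(series.shape, dtype=float)
    for i in good:
        r = registrations[i]
        acc += warp_image(series.pairs[i][0], r.transform, r.center, inverse=True, order=order)
    return acc / len(good)


def cluster_compartments(
    avg_image: np.ndarray,
    kidney_mask: np.ndarray,
    params: ClusterParams | None = None,
    dilate_px: int = 2,
    label_map: dict[int, int] | None = None,
) -> np.ndarray:
    """Label the kidney interior as calyx / medulla / cortex (+ background).

    Features per pixel inside the ``dilate_px``-dilated kidney mask:
    (alpha * normalized gray, distance_weight * normalized distance to the
    kidney's center of gravity).  Lloyd's k-means with a fixed seed
    assigns clusters, which are then mapped to labels; pass ``label_map``
    (cluster index -> label) to override the geometric mapping.  Nonzero
    labels are restricted to the undilated kidney mask.
    """
    params = params or ClusterParams()
    avg_image = np.asarray(avg_image, dtype=float)
    kidney_mask = np.asarray(kidney_mask, dtype=bool)
    if avg_image.shape != kidney_mask.shape:
        raise ValueError("image and kidney mask must share one shape")
    if not kidney_mask.any():
        raise ValueError("kidney mask is empty")
    region = (
        binary_dilation(kidney_mask, structure=disk(dilate_px)) if dilate_px > 0 else kidney_mask
    )
    n_px = int(region.sum())
    if n_px < params.k:
        raise ValueError(f"only {n_px} pixels in the clustering region for k={params.k}")

    g = avg_image[region]
    gmin, gmax = float(g.min()), float(g.max())
    g_norm = (g - gmin) / (gmax - gmin) if gmax > gmin else np.zeros_like(g)
    rr, cc = np.nonzero(region)
    com_r, com_c = (float(v.mean()) for v in np.nonzero(kidney_mask))
    d = np.hypot(rr - com_r, cc - com_c)
    dmax = float(d.max())
    d_norm = d / dmax if dmax > 0 else np.zeros_like(d)
    features = np.column_stack([params.alpha * g_norm, params.distance_weight * d_norm])

    km = KMeans(
        n_clusters=params.k,
        n_init=10,
        random_state=params.seed,
        max_iter=params.max_iter,
    ).fit(features)
    assign = km.labels_

    if label_map is None:
        label_map = _geometric_label_map(params.k, g_norm, d_norm, assign)
    labels = np.zeros(avg_image.shape, dtype=np.int64)
    labels[rr, cc] = np.array([label_map[a] for a in assign], dtype=np.int64)
    labels[~kidney_mask] = BACKGROUND
    return labels


def _geometric_label_map(
    k: int, g_norm: np.ndarray, d_norm: np.ndarray, assign: np.ndarray
) -> dict[int, int]:
    """Background = darkest cluster; calyx = most central; cortex = most peripheral."""
    mean_gray = np.array([g_norm[assign == j].mean() for j in range(k)])
    mean_dist = np.array([d_norm[assign == j].mean() for j in range(k)])
    mapping: dict[int, int] = {}
    clusters = list(range(k))
    if k == 4:
        bg = int(np.argmin(mean_gray))
        mapping[bg] = BACKGROUND
        clusters.remove(bg)
    elif k != 3:
        raise ValueError("the geometric cluster-label mapping supports k in {3, 4}; pass label_map")
    calyx = min(clusters, key=lambda j: mean_dist[j])
    clusters.remove(calyx)
    mapping[calyx] = CALYX
    cortex = max(clusters, key=lambda j: mean_dist[j])
    clusters.remove(cortex)
    mapping[cortex] = CORTEX
    mapping[clusters[0]] = MEDULLA
    return mapping


def purify_cortex(mask: np.ndarray, demote_to: str = "background") -> np.ndarray:
    """Demote every cortex pixel whose 8-neighborhood contains non-cortex.

    The surviving cortex is a strict subset of the input and contains no
    pixels adjacent to medulla, calyx or background, so the cortical ROI
    is guaranteed pure at the price of slight under-segmentation.

    ``demote_to`` controls where the stripped boundary layer goes:

    - ``"background"`` (default): demoted pixels are excluded from every
      compartment.  They are exactly the pixels whose compartment is
      uncertain; folding them into the medulla would bias the medullary
      mean upward by cortical signal.
    - ``"neighbor"``: each demoted pixel takes the label of its first
      non-cortex neighbor in a fixed scan order (direct neighbors before
      diagonals).

    Neighborhoods are evaluated on the input mask (one simultaneous
    pass); outside the image the mask is edge-replicated, so an
    all-cortex region touching the border is left alone.  If nothing
    survives, a warning is emitted and the empty-cortex mask returned.
    """
    if demote_to not in ("background", "neighbor"):
        raise ValueError("demote_to must be 'background' or 'neighbor'")
    mask = np.asarray(mask)
    if not np.isin(mask, [BACKGROUND, CALYX, MEDULLA, CORTEX]).all():
        raise ValueError("compartment mask contains unknown labels")
    padded = np.pad(mask, 1, mode="edge")
    cortex = mask == CORTEX
    out = mask.copy()
    undecided = cortex.copy()
    rows, cols = mask.shape
    for dr, dc in _NEIGHBOR_ORDER:
        nb = padded[1 + dr : 1 + dr + rows, 1 + dc : 1 + dc + cols]
        sel = undecided & (nb != CORTEX)
        out[sel] = BACKGROUND if demote_to == "background" else nb[sel]
        undecided[sel] = False
    if cortex.any() and not (out == CORTEX).any():
        warnings.warn("cortex empty after morphological purification", stacklevel=2)
    return out
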