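"""ROI segmentation by k-means clustering of per-pixel Z-score dynamics.

Foreground pixels are flattened to a (pixels x time) matrix of Z-scores and
grouped by k-means under the cosine distance ``1 - cos(u, v)``, so pixels with
the same temporal dynamics cluster together regardless of brightness.  The
initial cluster count is the colony area divided by a mean desired ROI area
(150 px^2, i.e. 1260 µm^2 at 2.9 µm/pixel).  Spatially discontinuous clusters
are split into connected components, components below a minimum area
(12 px = 101 µm^2) are pruned as noise, and per-ROI intensity traces are
extracted from the corrected stack and normalized to a robust baseline
(dF/F0).  The split/prune step makes the final ROI count insensitive to the
initial k.

The cosine k-means follows the classic batch-then-online scheme: Lloyd
iterations to convergence, then single-point moves accepted only when they
decrease the total within-cluster cosine distance, repeated over several
replicates with random initializations keeping the best objective.  For unit
rows the objective is ``J = N - sum_c ||s_c||`` with ``s_c`` the per-cluster
vector sum, which the online phase exploits for exact move gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

from .io import ROILabelMap, StimulusProtocol
from .mask import ColonyMask
from .normalize import CorrectedStack, ZStack

__all__ = [
    "PixelMatrix",
    "ROITraceSet",
    "ROISegmenter",
    "initial_cluster_count",
    "cluster_pixels",
    "split_disconnected",
    "prune_small",
    "extract_traces",
    "exclude_nonresponsive",
]


@dataclass
class PixelMatrix:
    """Foreground-pixel Z-score matrix (rows = pixels, columns = frames)."""

    values: np.ndarray
    ys: np.ndarray
    xs: np.ndarray
    frame_shape: tuple[int, int]

    @classmethod
    def from_zstack(cls, z: ZStack) -> "PixelMatrix":
        ys, xs = np.nonzero(z.mask)
        return cls(
            values=np.ascontiguousarray(z.data[:, ys, xs].T),
            ys=ys,
            xs=xs,
            frame_shape=z.mask.shape,
        )

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]


@dataclass
class ROITraceSet:
    """Per-ROI intensity traces with baseline and dF/F0 normalization."""

    roi_ids: np.ndarray
    traces: np.ndarray  # (K, t) raw integrated (mean) intensity
    f0: np.ndarray  # (K,) baseline
    dff: np.ndarray  # (K, t) normalized (F - F0) / F0
    areas: np.ndarray  # (K,) pixel areas
    centroids: np.ndarray  # (K, 2) (y, x)
    frame_interval_s: float = 1.0

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def subset(self, keep: np.ndarray) -> "ROITraceSet":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return ROITraceSet(
            roi_ids=self.roi_ids[keep],
            traces=self.traces[keep],
            f0=self.f0[keep],
            dff=self.dff[keep],
            areas=self.areas[keep],
            centroids=self.centroids[keep],
            frame_interval_s=self.frame_interval_s,
        )


def initial_cluster_count(foreground_px: int, mean_roi_area_px2: int = 150) -> int:
    """Initial k: colony pixel area over desired mean ROI area, at least 1."""
    if foreground_px < 1:
        raise ValueError("foreground pixel count must be >= 1")
    if mean_roi_area_px2 < 1:
        raise ValueError("mean ROI area must be >= 1")
    return max(1, foreground_px // mean_roi_area_px2)


# ---------------------------------------------------------------------------
# cosine k-means


def _unit_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(X, axis=1)
    ok = norms > 0
    U = np.zeros_like(X, dtype=float)
    U[ok] = X[ok] / norms[ok, None]
    return U, ok


def _batch_phase(U: np.ndarray, C: np.ndarray, max_iter: int) -> np.ndarray:
    labels = None
    for _ in range(max_iter):
        cn = np.linalg.norm(C, axis=1)
        cn[cn == 0] = 1.0
        sim = U @ (C / cn[:, None]).T
        new = np.argmax(sim, axis=1)
        if labels is not None and np.array_equal(new, labels):
            break
        labels = new
        # recompute centroids; drop empty clusters
        k = C.shape[0]
        sums = np.zeros_like(C)
        np.add.at(sums, labels, U)
        counts = np.bincount(labels, minlength=k)
        keep = counts > 0
        C = sums[keep] / counts[keep, None]
        if not keep.all():
            remap = np.cumsum(keep) - 1
            labels = remap[labels]
    return labels


def _online_phase(U: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                  max_passes: int = 5) -> np.ndarray:
    k = labels.max() + 1
    S = np.zeros((k, U.shape[1]))
    np.add.at(S, labels, U)
    counts = np.bincount(labels, minlength=k).astype(int)
    norms = np.linalg.norm(S, axis=1)
    for _ in range(max_passes):
        moved = 0
        for i in rng.permutation(len(labels)):
            a = labels[i]
            if counts[a] <= 1:
                continue
            x = U[i]
            dots = S @ x
            # ||s_b + x|| for all b; exact for unit x
            gain_all = np.sqrt(np.maximum(norms**2 + 2.0 * dots + 1.0, 0.0)) - norms
            loss = norms[a] - np.sqrt(max(norms[a] ** 2 - 2.0 * dots[a] + 1.0, 0.0))
            gain_all[a] = -np.inf
            b = int(np.argmax(gain_all))
            if gain_all[b] - loss > 1e-10:
                S[a] -= x
                S[b] += x
                counts[a] -= 1
                counts[b] += 1
                norms[a] = np.linalg.norm(S[a])
                norms[b] = np.linalg.norm(S[b])
                labels[i] = b
                moved += 1
        if moved == 0:
            break
    return labels


def _objective(U: np.ndarray, labels: np.ndarray) -> float:
    k = labels.max() + 1
    S = np.zeros((k, U.shape[1]))
    np.add.at(S, labels, U)
    return float(len(labels) - np.linalg.norm(S, axis=1).sum())


def cluster_pixels(
    matrix: PixelMatrix | np.ndarray,
    k: int,
    seed: int | None = 0,
    replicates: int = 10,
    max_iter: int = 100,
) -> np.ndarray:
    """Cosine k-means over pixel time series; returns a cluster id per row.

    Runs ``replicates`` random initializations (batch Lloyd phase followed by
    an online single-point refinement phase) and keeps the assignment with the
    lowest total within-cluster cosine distance.  Deterministic for a fixed
    seed.  Rows with zero norm (flat Z-traces) cannot carry a cosine distance
    and are assigned afterward to the centroid nearest in Euclidean distance.
    """
    X = matrix.values if isinstance(matrix, PixelMatrix) else np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of pixels ({n})")
    U, ok = _unit_rows(X)
    idx_ok = np.nonzero(ok)[0]
    Uo = U[idx_ok]
    rng = np.random.default_rng(seed)

    if len(idx_ok) == 0:
        return np.zeros(n, dtype=int)
    k_eff = min(k, len(idx_ok))

    best_labels, best_obj = None, np.inf
    for _ in range(max(1, replicates)):
        init = rng.choice(len(idx_ok), size=k_eff, replace=False)
        labels = _batch_phase(Uo, Uo[init].copy(), max_iter)
        labels = _online_phase(Uo, labels, rng)
        obj = _objective(Uo, labels)
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, labels.copy()

    out = np.zeros(n, dtype=int)
    out[idx_ok] = best_labels
    if (~ok).any():
        kk = best_labels.max() + 1
        C = np.zeros((kk, X.shape[1]))
        np.add.at(C, best_labels, X[idx_ok])
        C /= np.bincount(best_labels, minlength=kk)[:, None]
        flat = np.nonzero(~ok)[0]
        d = ((X[flat][:, None, :] - C[None]) ** 2).sum(-1)
        out[flat] = np.argmin(d, axis=1)
    return out


# ---------------------------------------------------------------------------
# split / prune / traces


def _renumber_by_centroid(labels2d: np.ndarray) -> np.ndarray:
    """Renumber ROI ids 1..K in raster order of their centroids."""
    ids = np.unique(labels2d)
    ids = ids[ids > 0]
    if ids.size == 0:
        return np.zeros_like(labels2d)
    cents = []
    for i in ids:
        ys, xs = np.nonzero(labels2d == i)
        cents.append((ys.mean(), xs.mean()))
    order = np.lexsort(([c[1] for c in cents], [c[0] for c in cents]))
    out = np.zeros_like(labels2d)
    for new, pos in enumerate(order, start=1):
        out[labels2d == ids[pos]] = new
    return out


def split_disconnected(
    assignment: np.ndarray,
    mask: ColonyMask | np.ndarray | PixelMatrix,
    pixel_matrix: PixelMatrix | None = None,
) -> ROILabelMap:
    """Split each cluster into spatially connected (8-connectivity) ROIs.

    ``assignment`` is the per-foreground-pixel cluster id (raster order of the
    mask's foreground pixels, as produced by :class:`PixelMatrix`).
    """
    if isinstance(mask, PixelMatrix):
        pixel_matrix, mask_arr = mask, None
        shape = pixel_matrix.frame_shape
    else:
        mask_arr = mask.mask if isinstance(mask, ColonyMask) else np.asarray(mask, dtype=bool)
        shape = mask_arr.shape
    labels2d = np.zeros(shape, dtype=np.int32)
    if pixel_matrix is not None:
        ys, xs = pixel_matrix.ys, pixel_matrix.xs
    else:
        ys, xs = np.nonzero(mask_arr)
    if len(ys) != len(assignment):
        raise ValueError("assignment length does not match mask foreground count")
    cluster2d = np.full(shape, -1, dtype=np.int64)
    cluster2d[ys, xs] = assignment
    next_id = 1
    for c in np.unique(assignment):
        comp = measure.label(cluster2d == c, connectivity=2)
        for j in range(1, comp.max() + 1):
            labels2d[comp == j] = next_id
            next_id += 1
    return ROILabelMap(labels=_renumber_by_centroid(labels2d))


def prune_small(labels: ROILabelMap, min_area_px2: int = 12) -> ROILabelMap:
    """Drop ROIs smaller than ``min_area_px2`` pixels (they reflect noise)."""
    if min_area_px2 < 1:
        raise ValueError("min_area_px2 must be >= 1")
    arr = labels.labels.copy()
    areas = np.bincount(arr.ravel())
    for i in range(1, len(areas)):
        if 0 < areas[i] < min_area_px2:
            arr[arr == i] = 0
    if not (arr > 0).any():
        raise ValueError(
            "all ROIs were pruned; review min_area_px2 or the segmentation inputs"
        )
    return ROILabelMap(labels=_renumber_by_centroid(arr), pixel_size_um=labels.pixel_size_um)


def extract_traces(
    corrected: CorrectedStack | np.ndarray,
    labels: ROILabelMap,
    baseline_percentile: float = 1.0,
) -> ROITraceSet:
    """Integrate corrected intensity over each ROI and normalize to baseline.

    The per-ROI trace is the mean background-subtracted intensity per frame;
    the baseline F0 is a robust minimum (the ``baseline_percentile``-th
    percentile, 0 = strict minimum) and dF/F0 = (F - F0)/F0.
    """
    data = corrected if isinstance(corrected, np.ndarray) else corrected.data
    lab = labels.labels
    if data.shape[1:] != lab.shape:
        raise ValueError("stack frames and label map differ in shape")
    K = labels.n_rois
    if K == 0:
        raise ValueError("label map contains no ROIs")
    t = data.shape[0]
    flat_lab = lab.ravel()
    counts = np.bincount(flat_lab, minlength=K + 1)[1:]
    flat = data.reshape(t, -1)
    sums = np.zeros((t, K + 1))
    for fr in range(t):
        sums[fr] = np.bincount(flat_lab, weights=flat[fr], minlength=K + 1)
    traces = (sums[:, 1:] / counts).T  # (K, t)

    if baseline_percentile <= 0:
        f0 = traces.min(axis=1)
    else:
        f0 = np.percentile(traces, baseline_percentile, axis=1)
    f0 = np.maximum(f0, 1e-9)
    dff = (traces - f0[:, None]) / f0[:, None]

    cents = np.zeros((K, 2))
    ys, xs = np.nonzero(lab)
    vals = lab[ys, xs]
    for i in range(1, K + 1):
        sel = vals == i
        cents[i - 1] = (ys[sel].mean(), xs[sel].mean())
    return ROITraceSet(
        roi_ids=np.arange(1, K + 1),
        traces=traces,
        f0=f0,
        dff=dff,
        areas=counts.astype(int),
        centroids=cents,
        frame_interval_s=getattr(corrected, "frame_interval_s", 1.0),
    )


def exclude_nonresponsive(
    traces: ROITraceSet,
    protocol: StimulusProtocol,
    threshold: float = 1.0,
    window_s: float = 300.0,
) -> tuple[ROITraceSet, list[dict]]:
    """Drop ROIs whose peak dF/F0 within ``window_s`` of the first stimulus
    onset is below ``threshold`` (default 100% of baseline).

    Such regions lack calcium waves (dim non-viable material or constitutively
    bright debris); typical stimulus responses peak around 250% dF/F0, so the
    rule removes only clear non-responders.  Returns the retained subset and an
    exclusion report.
    """
    if protocol.n_pulses < 1:
        raise ValueError("protocol must contain at least one pulse")
    on = protocol.onsets[0]
    times = traces.times()
    win = (times >= on) & (times <= on + window_s)
    peak = traces.dff[:, win].max(axis=1) if win.any() else np.zeros(traces.n_rois)
    keep = peak >= threshold
    report = [
        {"roi_id": int(traces.roi_ids[i]), "max_dff_in_window": float(peak[i]),
         "reason": "max dF/F0 below threshold"}
        for i in np.nonzero(~keep)[0]
    ]
    return traces.subset(keep), report


class ROISegmenter(BaseEstimator):
    """Estimator partitioning colony pixels into ROIs with homogeneous dynamics.

    ``fit(zstack)`` clusters foreground Z-traces by cosine k-means (k = colony
    area / ``mean_roi_area_px2`` unless ``n_clusters`` is given), splits
    spatially disconnected clusters, prunes sub-``min_area_px2`` fragments and
    stores ``labels_`` (:class:`~mosswave.io.ROILabelMap`) and ``n_rois_``.
    ``extract(corrected)`` then returns the ROI trace set.
    """

    def __init__(
        self,
        mean_roi_area_px2: int = 150,
        min_area_px2: int = 12,
        n_clusters: int | None = None,
        replicates: int = 10,
        random_state: int | None = 0,
        baseline_percentile: float = 1.0,
    ):
        self.mean_roi_area_px2 = mean_roi_area_px2
        self.min_area_px2 = min_area_px2
        self.n_clusters = n_clusters
        self.replicates = replicates
        self.random_state = random_state
        self.baseline_percentile = baseline_percentile

    def fit(self, X: ZStack, y=None) -> "ROISegmenter":
        pm = PixelMatrix.from_zstack(X)
        k = self.n_clusters or initial_cluster_count(pm.n_pixels, self.mean_roi_area_px2)
        assignment = cluster_pixels(pm, k=k, seed=self.random_state,
                                    replicates=self.replicates)
        raw = split_disconnected(assignment, pm)
        pruned = prune_small(raw, self.min_area_px2)
        pruned.pixel_size_um = X.pixel_size_um
        self.pixel_matrix_ = pm
        self.initial_k_ = int(k)
        self.labels_ = pruned
        self.n_rois_ = pruned.n_rois
        return self

    def fit_predict(self, X: ZStack, y=None) -> np.ndarray:
        return self.fit(X).labels_.labels

    def extract(self, corrected: CorrectedStack) -> ROITraceSet:
        if not hasattr(self, "labels_"):
            raise RuntimeError("ROISegmenter is not fitted")
        return extract_traces(corrected, self.labels_, self.baseline_percentile)
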