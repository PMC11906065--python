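"""Stages 2–3 of the margination pipeline: clustering and NCC delineation.

Foreground pixel time-series are reduced with PCA and grouped with k-means;
the clusters "most representative" of the perfused regions are the ones
with the highest accumulated fluorescence (area under the cluster-center
curve).  Every pixel trace is then scored by normalized cross-correlation
(NCC) against each selected center, and the difference of the two NCC maps
delineates the flow regions: positive difference -> region 1, negative ->
region 2, near zero -> the margin between them.

The NCC of two equal-length signals a, b with sample standard deviations
s_a, s_b is

    NCC = 1/(T-1) · Σ_t ((a_t − ā)/s_a) · ((b_t − b̄)/s_b)

which is 1 for identical signals, −1 for negated ones, and near 0 for
unrelated ones.  The (T−1) denominator in both the prefactor and the
sample SDs makes ncc(a, a) exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from icgmargin.exceptions import (
    DomainError,
    EmptyClusterError,
    UndefinedCorrelationError,
    ValidationError,
)
from icgmargin.preprocess import (
    PixelTimeSeriesMatrix,
    extract_timeseries,
    isolate_fluorescence_channel,
    threshold_foreground,
)
from icgmargin.video_io import BinaryMask, VideoStack

#: Half-width of the NCC-difference band treated as the region margin.
DEFAULT_EPSILON = 0.05
#: Default number of k-means clusters: two perfused regions plus headroom
#: for background / transition pixel populations.
DEFAULT_K = 4
#: Cap on retained PCA components (fewer if 99% variance is reached earlier).
DEFAULT_MAX_COMPONENTS = 10
DEFAULT_VARIANCE_TARGET = 0.99


@dataclass
class ClusteringResult:
    """k-means grouping of pixel traces with centers in intensity space.

    ``centers_ts[j]`` is the mean of the *original* (not PCA-reduced)
    traces of cluster ``j``; ``auc[j]`` is its accumulated fluorescence,
    the sum of the center trace over time at unit frame spacing.
    """

    embedding: np.ndarray  # (N, d)
    labels: np.ndarray  # (N,)
    centers_ts: np.ndarray  # (k, T)
    auc: np.ndarray  # (k,)
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def k(self) -> int:
        return self.centers_ts.shape[0]


@dataclass
class NCCMaps:
    """Per-pixel NCC against the two selected cluster centers.

    Maps are H×W with NaN at pixels outside the foreground or with
    zero-variance traces; defined values satisfy |ncc| <= 1 and
    |ncc_diff| <= 2.
    """

    ncc_c1: np.ndarray
    ncc_c2: np.ndarray
    ncc_diff: np.ndarray


@dataclass
class MarginationResult:
    """Delineated flow regions: two region masks and the margin between them.

    ``chamber1_mask`` collects foreground pixels with ncc_diff > +epsilon,
    ``chamber2_mask`` those with ncc_diff < −epsilon, ``boundary_mask``
    those with |ncc_diff| <= epsilon.  The three masks are disjoint.
    """

    chamber1_mask: BinaryMask
    chamber2_mask: BinaryMask
    boundary_mask: BinaryMask
    epsilon: float
    maps: NCCMaps | None = None


def reduce_pca(
    matrix: PixelTimeSeriesMatrix,
    n_components: int,
) -> tuple[np.ndarray, PCA]:
    """Project centered pixel traces onto the top principal axes.

    Deterministic (covariance eigendecomposition, no randomized solver);
    component sign is fixed by convention: the largest-magnitude loading of
    each component is made positive.  Returns the (N, d) embedding and the
    fitted :class:`sklearn.decomposition.PCA` (for explained variance and
    inverse transforms).
    """
    n, t = matrix.traces.shape
    if not 1 <= n_components < min(n, t) + 1:
        raise DomainError(
            f"n_components must satisfy 1 <= d <= min(N, T) = {min(n, t)}, got {n_components}"
        )
    if n_components >= t or n_components >= n:
        raise DomainError(f"n_components {n_components} must be < N ({n}) and < T ({t})")
    pca = PCA(n_components=n_components, svd_solver="covariance_eigh")
    emb = pca.fit_transform(matrix.traces)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components), np.abs(pca.components_).argmax(axis=1)]
    )
    flip[flip == 0] = 1.0
    pca.components_ *= flip[:, None]
    emb = emb * flip[None, :]
    return emb, pca


def choose_n_components(
    matrix: PixelTimeSeriesMatrix,
    max_components: int = DEFAULT_MAX_COMPONENTS,
    variance_target: float = DEFAULT_VARIANCE_TARGET,
) -> int:
    """Smallest d reaching ``variance_target`` explained variance, capped.

    The perfusion dynamics are low-rank (a handful of wash-in/wash-out
    curve families), so a small d suffices; the cap bounds the k-means cost.
    """
    cap = min(max_components, matrix.n_pixels - 1, matrix.n_frames - 1)
    _, pca = reduce_pca(matrix, cap)
    cum = np.cumsum(pca.explained_variance_ratio_)
    reached = np.nonzero(cum >= variance_target)[0]
    return int(reached[0]) + 1 if reached.size else cap


def cluster_kmeans(
    matrix: PixelTimeSeriesMatrix,
    embedding: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
    explained_variance_ratio: np.ndarray | None = None,
) -> ClusteringResult:
    """k-means on the PCA embedding; centers mapped back to intensity space.

    Standard k-means with k-means++ seeding, best of ``n_restarts`` by
    inertia, deterministic under a fixed ``seed``.  Cluster-center
    time-series are the per-cluster mean of the ORIGINAL traces so the NCC
    stage is independent of the PCA choice.  Raises
    :class:`EmptyClusterError` if any cluster ends empty.
    """
    n = embedding.shape[0]
    if k < 2:
        raise DomainError(f"k must be >= 2, got {k}")
    if n < 10 * k:
        raise DomainError(f"need at least 10·k = {10 * k} pixels, got {n}")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(embedding)
    counts = np.bincount(labels, minlength=k)
    if np.any(counts == 0):
        raise EmptyClusterError(
            f"clusters {np.nonzero(counts == 0)[0].tolist()} are empty after {n_restarts} restarts"
        )
    centers_ts = np.empty((k, matrix.n_frames), dtype=np.float64)
    for j in range(k):
        centers_ts[j] = matrix.traces[labels == j].mean(axis=0)
    auc = centers_ts.sum(axis=1)
    return ClusteringResult(
        embedding=embedding,
        labels=labels,
        centers_ts=centers_ts,
        auc=auc,
        explained_variance_ratio=(
            np.asarray(explained_variance_ratio)
            if explained_variance_ratio is not None
            else np.array([])
        ),
    )


def select_chamber_clusters(result: ClusteringResult, n_select: int = 2) -> tuple[int, ...]:
    """Ids of the ``n_select`` clusters with highest accumulated fluorescence.

    Returned in descending AUC order; ties broken by lower cluster id.
    """
    if result.k < n_select:
        raise DomainError(f"need k >= {n_select} clusters, got {result.k}")
    # stable sort on -auc keeps lower ids first among ties
    order = np.argsort(-result.auc, kind="stable")
    return tuple(int(i) for i in order[:n_select])


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-length time-series.

    1/(T−1) · Σ ((a_t − ā)/s_a)·((b_t − b̄)/s_b) with sample (T−1) standard
    deviations.  Symmetric; invariant to positive affine rescaling of
    either argument; in [−1, 1].
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 1 or a.shape != b.shape:
        raise ValidationError(f"need equal-length 1-D signals, got {a.shape} vs {b.shape}")
    t = a.size
    if t < 2:
        raise DomainError("NCC needs T >= 2 samples")
    da = a - a.mean()
    db = b - b.mean()
    saa = da @ da  # (T-1)·s_a², the (T-1) factors cancel against the prefactor
    sbb = db @ db
    if saa == 0 or sbb == 0:
        raise UndefinedCorrelationError("NCC undefined for a zero-variance signal")
    val = float((da @ db) / np.sqrt(saa * sbb))
    return min(1.0, max(-1.0, val))  # clamp fp round-off at the bounds


def ncc_maps(
    matrix: PixelTimeSeriesMatrix,
    centers_ts: np.ndarray,
    frame_shape: tuple[int, int],
) -> NCCMaps:
    """Per-pixel NCC of every foreground trace against two cluster centers.

    Zero-variance pixel traces are marked missing (NaN) in all three maps
    rather than scored 0 — the NCC formula is undefined there and silent
    zeros would bias the difference map.
    """
    centers_ts = np.asarray(centers_ts, dtype=np.float64)
    if centers_ts.ndim != 2 or centers_ts.shape[0] != 2:
        raise ValidationError("exactly 2 selected cluster centers required")
    if centers_ts.shape[1] != matrix.n_frames:
        raise ValidationError("center length must match trace length")
    t = matrix.n_frames
    c = centers_ts - centers_ts.mean(axis=1, keepdims=True)
    c_sd = np.sqrt((c * c).sum(axis=1) / (t - 1))
    if np.any(c_sd == 0):
        raise UndefinedCorrelationError("a selected cluster center has zero variance")
    cz = c / c_sd[:, None]  # standardized centers

    traces = matrix.traces.astype(np.float32)
    d = traces - traces.mean(axis=1, keepdims=True)
    sd = np.sqrt((d * d).sum(axis=1) / (t - 1))
    valid = sd > 0
    vals = np.full((matrix.n_pixels, 2), np.nan, dtype=np.float64)
    if valid.any():
        z = d[valid] / sd[valid, None]
        vals[valid] = np.clip((z @ cz.T.astype(np.float32)) / (t - 1), -1.0, 1.0)

    m1 = matrix.to_map(frame_shape, vals[:, 0])
    m2 = matrix.to_map(frame_shape, vals[:, 1])
    return NCCMaps(ncc_c1=m1, ncc_c2=m2, ncc_diff=m1 - m2)


def _largest_component(grid: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(grid)  # 4-connectivity by default
    if n <= 1:
        return grid
    sizes = ndimage.sum_labels(grid, labeled, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return (labeled == keep).astype(np.uint8)


def marginate(
    maps: NCCMaps,
    epsilon: float = DEFAULT_EPSILON,
    largest_component_only: bool = False,
) -> MarginationResult:
    """Split the NCC-difference map into two regions and their margin.

    Region 1: ncc_diff > +epsilon; region 2: ncc_diff < −epsilon; margin:
    |ncc_diff| <= epsilon.  NaN (non-foreground / zero-variance) pixels
    belong to none.  ``largest_component_only`` optionally keeps only the
    largest 4-connected component of each region mask.
    """
    if epsilon < 0:
        raise DomainError(f"epsilon must be >= 0, got {epsilon}")
    diff = maps.ncc_diff
    defined = ~np.isnan(diff)
    c1 = (defined & (diff > epsilon)).astype(np.uint8)
    c2 = (defined & (diff < -epsilon)).astype(np.uint8)
    bound = (defined & (np.abs(diff) <= epsilon)).astype(np.uint8)
    if largest_component_only:
        c1 = _largest_component(c1)
        c2 = _largest_component(c2)
    return MarginationResult(
        chamber1_mask=BinaryMask(c1, label="chamber1"),
        chamber2_mask=BinaryMask(c2, label="chamber2"),
        boundary_mask=BinaryMask(bound, label="boundary"),
        epsilon=epsilon,
        maps=maps,
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineParams:
    """Knobs of the full margination pipeline, with the package defaults."""

    channel_strategy: str = "auto"
    channel: int | None = None
    threshold_fraction: float = 0.2
    threshold_statistic: str = "max"
    max_components: int = DEFAULT_MAX_COMPONENTS
    variance_target: float = DEFAULT_VARIANCE_TARGET
    k: int = DEFAULT_K
    seed: int = 0
    n_restarts: int = 10
    epsilon: float = DEFAULT_EPSILON
    largest_component_only: bool = False


def run_pipeline(
    stack: VideoStack,
    params: PipelineParams | None = None,
) -> tuple[MarginationResult, ClusteringResult, PixelTimeSeriesMatrix]:
    """Full video -> margination pipeline with the standard stage order.

    Channel isolation -> foreground thresholding -> trace extraction ->
    PCA -> k-means -> top-2 AUC cluster selection -> NCC maps ->
    epsilon margination.  Deterministic for a fixed seed and input.
    """
    p = params or PipelineParams()
    mono = isolate_fluorescence_channel(
        stack, strategy=p.channel_strategy, channel=p.channel
    )
    fg = threshold_foreground(
        mono, statistic=p.threshold_statistic, fraction=p.threshold_fraction
    )
    matrix = extract_timeseries(mono, fg)
    d = choose_n_components(matrix, p.max_components, p.variance_target)
    emb, pca = reduce_pca(matrix, d)
    clustering = cluster_kmeans(
        matrix,
        emb,
        k=p.k,
        seed=p.seed,
        n_restarts=p.n_restarts,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
    c1, c2 = select_chamber_clusters(clustering, n_select=2)
    maps = ncc_maps(matrix, clustering.centers_ts[[c1, c2]], mono.frame_shape)
    result = marginate(maps, epsilon=p.epsilon, largest_component_only=p.largest_component_only)
    return result, clustering, matrix
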