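"""Untargeted grouping of features into pseudo-spectra.

Under electron ionization each chemical fragments into many m/z features
that co-elute and co-vary in intensity across samples.  Features are
therefore grouped by a similarity that is the product of two Gaussians --
one in retention-time difference, one in (1 - correlation) across nonblank
samples:

    s_ij = exp(-(rt_i - rt_j)^2 / (2 sigma_rt^2))
         * exp(-(1 - r_ij)^2 / (2 sigma_corr^2))

with rank correlation by default (robust to the skewed intensity
distributions typical of population exposure data).  Average-linkage
agglomerative clustering on dissimilarity 1 - s is cut at ``cut_height``;
groups smaller than ``min_cluster_size`` (default 3) are discarded and
their members reported as unclustered, so the output is a partition of the
input features into clusters plus an unclustered set.

Each cluster is compiled into a pseudo-spectrum whose peak weights are the
feature's mean nonblank intensity times its mean correlation to the other
members; pseudo-spectra can be cosine-matched against reference spectra.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

from .io import BLANK_ROLES, Feature, FeatureTable, PseudoSpectrumRecord, ValidationError

__all__ = [
    "SimilarityParams",
    "SpectralCluster",
    "ClusterResult",
    "feature_similarity",
    "similarity_matrix",
    "cluster_features",
    "weighted_spectrum",
    "cosine_match",
    "sweep_cut_height",
]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityParams:
    """Tunables of the Gaussian-product similarity and the tree cut."""

    sigma_rt: float = 0.05  # minutes
    sigma_corr: float = 0.5
    correlation_kind: str = "spearman"  # or "pearson"
    cut_height: float = 0.5  # dissimilarity threshold in (0, 1)
    min_cluster_size: int = 3
    min_shared_samples: int = 3

    def __post_init__(self) -> None:
        if self.sigma_rt <= 0 or self.sigma_corr <= 0:
            raise ValidationError("similarity sigmas must be > 0")
        if not (0 < self.cut_height < 1):
            raise ValidationError("cut_height must lie in (0, 1)")
        if self.correlation_kind not in ("spearman", "pearson"):
            raise ValidationError(f"unknown correlation {self.correlation_kind!r}")


@dataclass
class SpectralCluster:
    cluster_id: str
    members: list[str]
    cluster_rt: float
    mean_internal_correlation: float


@dataclass
class ClusterResult:
    clusters: list[SpectralCluster]
    unclustered: list[str]

    @property
    def n_features(self) -> int:
        return sum(len(c.members) for c in self.clusters) + len(self.unclustered)


def _pair_correlation(
    a: pd.Series, b: pd.Series, kind: str, min_shared: int
) -> float:
    """Correlation over shared non-missing samples; NaN if overlap < min_shared
    or either side is constant."""
    shared = a.dropna().index.intersection(b.dropna().index)
    if len(shared) < min_shared:
        return float("nan")
    x = a[shared].to_numpy(dtype=float)
    y = b[shared].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "spearman":
            r = spearmanr(x, y).statistic
        else:
            r = pearsonr(x, y).statistic
    return float(r)


def feature_similarity(
    fi: Feature,
    fj: Feature,
    params: SimilarityParams | None = None,
    *,
    exclude_samples: Sequence[str] | set | None = None,
) -> float:
    """Gaussian-product similarity of two features in [0, 1].

    Defined as 0 when fewer than ``min_shared_samples`` samples carry both
    features (correlation is then meaningless)."""
    params = params or SimilarityParams()
    a, b = fi.intensities, fj.intensities
    if exclude_samples:
        keep = [s for s in a.index if s not in set(exclude_samples)]
        a = a[keep]
        b = b[[s for s in b.index if s not in set(exclude_samples)]]
    r = _pair_correlation(a, b, params.correlation_kind, params.min_shared_samples)
    if np.isnan(r):
        return 0.0
    s_rt = np.exp(-((fi.rt - fj.rt) ** 2) / (2.0 * params.sigma_rt**2))
    s_corr = np.exp(-((1.0 - r) ** 2) / (2.0 * params.sigma_corr**2))
    return float(s_rt * s_corr)


def similarity_matrix(
    table: FeatureTable, params: SimilarityParams | None = None
) -> tuple[list[str], np.ndarray]:
    """Symmetric similarity matrix with unit diagonal over all features of
    ``table``.  Blank samples are excluded from the correlations (they
    carry no biological covariation).

    Pairwise entries are computed with exactly the same scalar routine as
    :func:`feature_similarity`, so the matrix is its element-by-element
    equivalent by construction."""
    params = params or SimilarityParams()
    blank_samples = set(table.samples_with_role(BLANK_ROLES))
    feats = list(table.iter_features())
    n = len(feats)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = feature_similarity(
                feats[i], feats[j], params, exclude_samples=blank_samples
            )
            S[i, j] = S[j, i] = s
    return [f.feature_id for f in feats], S


def cluster_features(
    table: FeatureTable,
    params: SimilarityParams | None = None,
    rt_window: tuple[float, float] | None = None,
) -> ClusterResult:
    """Average-linkage agglomerative clustering of features on
    dissimilarity 1 - s, tree cut at ``params.cut_height``.

    Clusters smaller than ``min_cluster_size`` are discarded; their members
    are reported as unclustered.  The result partitions the (windowed)
    features."""
    params = params or SimilarityParams()
    if rt_window is not None:
        table = table.rt_window(*rt_window)
    ids = table.feature_ids
    if len(ids) == 0:
        warnings.warn("no features in the requested window", stacklevel=2)
        return ClusterResult(clusters=[], unclustered=[])
    if len(ids) == 1:
        return ClusterResult(clusters=[], unclustered=list(ids))

    ids, S = similarity_matrix(table, params)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = fcluster(Z, t=params.cut_height, criterion="distance")

    mean_int = (
        table.intensities[table.samples_with_role({"study", "srm_1957", "srm_1958"})]
        .mean(axis=1)
        .fillna(0.0)
    )
    clusters: list[SpectralCluster] = []
    unclustered: list[str] = []
    for lab in sorted(set(labels)):
        member_idx = [i for i, l in enumerate(labels) if l == lab]
        members = [ids[i] for i in member_idx]
        if len(members) < params.min_cluster_size:
            unclustered.extend(members)
            continue
        w = mean_int[members].to_numpy()
        rts = table.meta.loc[members, "rt"].to_numpy()
        cluster_rt = float(np.average(rts, weights=w)) if w.sum() > 0 else float(rts.mean())
        clusters.append(
            SpectralCluster(
                cluster_id=f"C{len(clusters) + 1:03d}",
                members=members,
                cluster_rt=cluster_rt,
                mean_internal_correlation=_mean_internal_correlation(
                    table, members, params
                ),
            )
        )
    logger.info(
        "cluster_features: %d features -> %d clusters, %d unclustered",
        len(ids), len(clusters), len(unclustered),
    )
    return ClusterResult(clusters=clusters, unclustered=unclustered)


def _member_correlations(
    table: FeatureTable, members: Sequence[str], params: SimilarityParams
) -> np.ndarray:
    """Pairwise correlation matrix among member features (nonblank samples)."""
    blank = set(table.samples_with_role(BLANK_ROLES))
    keep = [s for s in table.sample_ids if s not in blank]
    n = len(members)
    R = np.eye(n)
    series = [table.intensities.loc[m, keep] for m in members]
    for i in range(n):
        for j in range(i + 1, n):
            r = _pair_correlation(
                series[i], series[j], params.correlation_kind, params.min_shared_samples
            )
            R[i, j] = R[j, i] = 0.0 if np.isnan(r) else r
    return R


def _mean_internal_correlation(
    table: FeatureTable, members: Sequence[str], params: SimilarityParams
) -> float:
    R = _member_correlations(table, members, params)
    off = R[np.triu_indices(len(members), k=1)]
    return float(off.mean()) if len(off) else 1.0


def weighted_spectrum(
    cluster: SpectralCluster,
    table: FeatureTable,
    params: SimilarityParams | None = None,
) -> PseudoSpectrumRecord:
    """Compile a cluster into a pseudo-spectrum.

    Each member's weighted intensity is its mean intensity across nonblank
    samples times its mean correlation to the other members; peaks sort by
    descending weight.  Members with non-positive weight (uncorrelated or
    anti-correlated with the rest) are excluded and listed in
    ``record.excluded``."""
    params = params or SimilarityParams()
    members = cluster.members
    nonblank = table.samples_with_role({"study", "srm_1957", "srm_1958"})
    R = _member_correlations(table, members, params)
    n = len(members)
    peaks: list[tuple[float, float]] = []
    excluded: list[tuple[str, float]] = []
    for i, m in enumerate(members):
        mean_i = float(table.intensities.loc[m, nonblank].mean())
        if np.isnan(mean_i):
            mean_i = 0.0
        mean_r = float((R[i].sum() - 1.0) / (n - 1)) if n > 1 else 1.0
        w = mean_i * mean_r
        mz = float(table.meta.loc[m, "mz"])
        if w > 0:
            peaks.append((mz, w))
        else:
            excluded.append((m, w))
    peaks.sort(key=lambda p: -p[1])
    return PseudoSpectrumRecord(
        cluster_id=cluster.cluster_id,
        rt=cluster.cluster_rt,
        peaks=peaks,
        excluded=excluded,
    )


def cosine_match(
    query: PseudoSpectrumRecord,
    reference: PseudoSpectrumRecord,
    mz_tol_ppm: float = 10.0,
) -> float:
    """Normalized dot-product score in [0, 1] between two pseudo-spectra.

    Peaks pair greedily (most intense query peaks first, nearest unused
    reference peak within the ppm tolerance); the score is
    sum(sqrt(Iq * Ir)) over pairs, normalized by sqrt(sum Iq * sum Ir).
    Identical spectra score 1; spectra sharing no m/z score 0."""
    if not query.peaks or not reference.peaks:
        raise ValidationError("both spectra need >= 1 peak")
    q = sorted(query.peaks, key=lambda p: -p[1])
    ref = list(reference.peaks)
    used = [False] * len(ref)
    paired = 0.0
    for mzq, iq in q:
        best_j, best_dppm = -1, np.inf
        for j, (mzr, _ir) in enumerate(ref):
            if used[j]:
                continue
            dppm = abs(mzr - mzq) / mzq * 1e6
            if dppm <= mz_tol_ppm and dppm < best_dppm:
                best_j, best_dppm = j, dppm
        if best_j >= 0:
            used[best_j] = True
            paired += np.sqrt(iq * ref[best_j][1])
    norm = np.sqrt(sum(i for _, i in q) * sum(i for _, i in ref))
    return float(paired / norm) if norm > 0 else 0.0


def sweep_cut_height(
    table: FeatureTable,
    params: SimilarityParams,
    true_labels: dict[str, str],
    heights: Sequence[float] = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2)),
    rt_window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Sweep the tree-cut height and score each partition against known
    labels with the adjusted Rand index (unclustered features count as
    singletons).  Reports the interval of heights achieving the maximum
    ARI."""
    from sklearn.metrics import adjusted_rand_score

    rows = []
    for h in heights:
        p = SimilarityParams(
            sigma_rt=params.sigma_rt,
            sigma_corr=params.sigma_corr,
            correlation_kind=params.correlation_kind,
            cut_height=float(h),
            min_cluster_size=params.min_cluster_size,
            min_shared_samples=params.min_shared_samples,
        )
        result = cluster_features(table, p, rt_window=rt_window)
        pred: dict[str, str] = {}
        for c in result.clusters:
            for m in c.members:
                pred[m] = c.cluster_id
        for k, m in enumerate(result.unclustered):
            pred[m] = f"singleton_{k}"
        feats = list(pred)
        ari = adjusted_rand_score(
            [true_labels[f] for f in feats], [pred[f] for f in feats]
        )
        rows.append({"cut_height": float(h), "n_clusters": len(result.clusters), "ari": ari})
    return pd.DataFrame(rows)
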