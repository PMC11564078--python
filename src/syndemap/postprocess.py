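"""Co-regionalisation summaries and geographic clustering of risk patterns.

Two complementary correlation views of the fitted latent fields:

* *pairwise* — within each posterior draw, the Pearson correlation across
  areal units between two diseases' latent log-risk fields, summarised by
  the median over draws (a region-wide co-patterning measure);
* *local* — within each unit, the correlation across draws between the two
  diseases' latent values (where in the map the association holds).

Both are classified negative / none / positive against a +-0.3 threshold.
Clustering follows the study workflow: PCA of the (unit x disease) latent
mean matrix, then centroid-linkage agglomerative clustering of the leading
principal-component scores, cut at a requested number of clusters (centroid
linkage can produce dendrogram inversions, so the cut is on cluster count,
never on merge height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .joint_model import PosteriorSamples

__all__ = [
    "CorrelationSummary", "ClusterAssignment",
    "pairwise_coregionalisation", "local_coregionalisation", "pca_and_cluster",
    "classify_correlation", "latent_mean_matrix",
]


def classify_correlation(r: float, threshold: float = 0.3) -> str:
    if np.isnan(r):
        return "none"
    if r > threshold:
        return "positive"
    if r < -threshold:
        return "negative"
    return "none"


@dataclass
class CorrelationSummary:
    diseases: list[str]
    pairwise: np.ndarray           # (D, D) median across-unit correlations
    classification: np.ndarray     # (D, D) object array of labels
    flags: np.ndarray              # (D, D) True where correlation undefined

    def frame(self) -> pd.DataFrame:
        rows = []
        D = len(self.diseases)
        for a in range(D):
            for b in range(a + 1, D):
                rows.append((self.diseases[a], self.diseases[b],
                             self.pairwise[a, b], self.classification[a, b],
                             self.flags[a, b]))
        return pd.DataFrame(rows, columns=[
            "disease_a", "disease_b", "median_correlation", "classification", "undefined"])


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def pairwise_coregionalisation(
    samples: PosteriorSamples, threshold: float = 0.3
) -> CorrelationSummary:
    """Median across-draw Pearson correlation of latent fields, per pair."""
    D = len(samples.diseases)
    U = len(samples.units)
    if D < 2 or U < 2:
        raise ValueError("need at least 2 diseases and 2 units")
    S = samples.n_draws
    fields = np.stack([samples.latent_field(s) for s in range(S)])  # (S, U, D)
    med = np.eye(D)
    flags = np.zeros((D, D), dtype=bool)
    for a in range(D):
        for b in range(a + 1, D):
            rs = np.array([_corr(fields[s, :, a], fields[s, :, b]) for s in range(S)])
            if np.all(np.isnan(rs)):
                med[a, b] = med[b, a] = np.nan
                flags[a, b] = flags[b, a] = True
            else:
                m = float(np.nanmedian(rs))
                med[a, b] = med[b, a] = m
    cls = np.empty((D, D), dtype=object)
    for a in range(D):
        for b in range(D):
            cls[a, b] = "positive" if a == b else classify_correlation(med[a, b], threshold)
    return CorrelationSummary(list(samples.diseases), med, cls, flags)


def local_coregionalisation(
    samples: PosteriorSamples, pair: tuple[str, str], threshold: float = 0.3
) -> pd.DataFrame:
    """Per-unit correlation across posterior draws for one disease pair."""
    a = samples.diseases.index(pair[0])
    b = samples.diseases.index(pair[1])
    S = samples.n_draws
    fields = np.stack([samples.latent_field(s) for s in range(S)])  # (S, U, D)
    rows = []
    for i, uid in enumerate(samples.units):
        r = _corr(fields[:, i, a], fields[:, i, b])
        rows.append((uid, r, classify_correlation(r, threshold), np.isnan(r)))
    return pd.DataFrame(rows, columns=["unit_id", "correlation", "classification", "undefined"])


@dataclass
class ClusterAssignment:
    units: list[str]
    scores: np.ndarray              # (U, n_components)
    loadings: np.ndarray            # (D, n_components)
    variance_explained: np.ndarray  # fraction per component, all components
    labels: np.ndarray              # (U,) cluster ids 1..k
    linkage: np.ndarray             # scipy linkage record

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"unit_id": self.units, "cluster": self.labels})
        for j in range(self.scores.shape[1]):
            df[f"pc{j + 1}"] = self.scores[:, j]
        return df


def latent_mean_matrix(samples: PosteriorSamples, mode: str = "log_risk") -> np.ndarray:
    """(unit x disease) matrix to cluster on.

    ``"log_risk"``: posterior mean of period-averaged log relative risk (the
    default reading of "posterior predictions of the latent variable");
    ``"field"``: posterior mean of the latent spatial component only.
    """
    S = samples.n_draws
    if mode == "log_risk":
        acc = np.zeros((len(samples.units), len(samples.diseases)))
        for s in range(S):
            acc += samples.log_theta(s).mean(axis=2)
        return acc / S
    if mode == "field":
        return np.mean([samples.latent_field(s) for s in range(S)], axis=0)
    raise ValueError(f"unknown latent mode {mode!r}")


def pca_and_cluster(
    latent_means: np.ndarray,
    n_clusters: int,
    n_components: int = 2,
    unit_ids: list[str] | None = None,
) -> ClusterAssignment:
    """Column-centred PCA (via SVD) + centroid hierarchical clustering.

    Rows with any non-finite entry (units without usable latent values) must
    be excluded by the caller.  Deterministic: SVD sign convention fixes the
    component orientation by the largest-magnitude loading; scipy's ordered
    linkage breaks distance ties by observation order.
    """
    M = np.asarray(latent_means, float)
    if not np.all(np.isfinite(M)):
        raise ValueError("latent_means must be finite (drop no-case units first)")
    U, D = M.shape
    if n_clusters > U:
        raise ValueError(f"n_clusters={n_clusters} exceeds {U} units")
    n_components = min(n_components, min(U, D))
    Xc = M - M.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: make each component's largest-|loading| positive
    for j in range(len(s)):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u[:, :n_components] * s[:n_components]
    loadings = vt[:n_components].T
    if U > 1:
        Z = linkage(scores, method="centroid")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        Z = np.empty((0, 4))
        labels = np.array([1])
    ids = unit_ids if unit_ids is not None else [f"u{i}" for i in range(U)]
    return ClusterAssignment(list(ids), scores, loadings, var_frac, labels, Z)
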