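"""TAD-architecture subtyping: broad versus narrow TAD structure.

Samples are featurized by their TAD edge density (edges per Mb in 1-Mb
windows tiling the genome).  A two-class k-medoids partition on the
correlation distance between feature vectors defines the subtypes; the
cluster with the larger mean edge density is "narrow" (many boundaries
inside broad domains), the other "broad".  A 2-D t-SNE embedding is
produced for visualization only — the clustering never touches it, so
results do not inherit the embedding's seed sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .tads import TadSet, tad_edge_density

__all__ = [
    "SubtypeResult",
    "edge_density_matrix",
    "embed_and_cluster",
    "subtype_associations",
]


@dataclass
class SubtypeResult:
    samples: list[str]
    features: np.ndarray          # samples x windows edge densities
    embedding: np.ndarray         # samples x 2, presentation only
    labels: list[str]             # "broad" | "narrow" per sample
    mean_tad_size_bp: np.ndarray  # per sample
    degenerate: bool = False
    silhouette: dict[int, float] | None = None

    def cluster(self, label: str) -> list[str]:
        return [s for s, l in zip(self.samples, self.labels) if l == label]


def edge_density_matrix(cohort_tads: dict[str, TadSet],
                        window: int = 1_000_000) -> tuple[list[str], np.ndarray]:
    """Rows = samples (sorted by id), columns = 1-Mb windows in genome order."""
    samples = sorted(cohort_tads)
    if not samples:
        raise ValueError("empty cohort")
    frame = cohort_tads[samples[0]].bins
    rows = []
    for s in samples:
        t = cohort_tads[s]
        if not t.bins.same_frame(frame):
            raise ValueError(f"sample {s} is on a different assembly frame")
        rows.append(tad_edge_density(t, window))
    return samples, np.vstack(rows)


def _kmedoids_two(dist: np.ndarray, seed: int, n_init: int = 10,
                  max_iter: int = 100) -> np.ndarray:
    """Two-class PAM on a precomputed distance matrix, deterministic given
    seed; best of the farthest-pair init plus random restarts."""
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    inits = [tuple(np.unravel_index(np.argmax(dist), dist.shape))]
    for _ in range(n_init):
        inits.append(tuple(rng.choice(n, size=2, replace=False)))
    best_cost, best_assign = np.inf, None
    for m0, m1 in inits:
        if m0 == m1:
            continue
        medoids = [m0, m1]
        for _ in range(max_iter):
            assign = np.argmin(dist[:, medoids], axis=1)
            new = []
            for k in range(2):
                members = np.flatnonzero(assign == k)
                if members.size == 0:
                    new = medoids
                    break
                within = dist[np.ix_(members, members)].sum(axis=1)
                new.append(int(members[np.argmin(within)]))
            if new == medoids:
                break
            medoids = new
        assign = np.argmin(dist[:, medoids], axis=1)
        cost = dist[np.arange(n), np.array(medoids)[assign]].sum()
        if cost < best_cost - 1e-12:
            best_cost, best_assign = cost, assign
    return best_assign


def embed_and_cluster(samples: list[str], features: np.ndarray, seed: int,
                      cohort_tads: dict[str, TadSet] | None = None,
                      metric: str = "euclidean") -> SubtypeResult:
    """Subtype a cohort from its edge-density feature matrix.

    Clustering is 2-class k-medoids in feature space (never on the
    embedding); t-SNE provides the 2-D view for plotting only.  Labels map
    the denser cluster to "narrow".  All-identical feature rows are flagged
    degenerate (a single effective cluster).

    The default distance is Euclidean: the subtype signal lives in both the
    level and the positions of the edge density, and boundary-calling noise
    makes the sparse (broad) group mutually uncorrelated, so a scale-free
    correlation distance turns it into a diffuse cluster.  Correlation
    distance remains available via ``metric="correlation"``.
    """
    n = len(samples)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if features.shape[0] != n:
        raise ValueError("feature matrix rows != samples")
    degenerate = bool(np.allclose(features, features[0]))
    if degenerate:
        labels = ["broad"] * n
        assign = np.zeros(n, dtype=int)
    else:
        rows = features + 0.0
        if metric == "correlation":
            # correlation distance is undefined for zero-variance rows; nudge
            sd = rows.std(axis=1)
            rows[sd == 0, 0] += 1e-9
        dist = squareform(pdist(rows, metric=metric))
        assign = _kmedoids_two(dist, seed)
        dens = features.mean(axis=1)
        narrow_cluster = int(dens[assign == 1].mean() > dens[assign == 0].mean())
        labels = ["narrow" if a == narrow_cluster else "broad" for a in assign]
    if degenerate:
        emb = np.zeros((n, 2))
    else:
        perplexity = max(2.0, min(30.0, (n - 1) / 3.0))
        emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity,
                   init="pca").fit_transform(features)
    sizes = np.full(n, np.nan)
    if cohort_tads is not None:
        sizes = np.array([cohort_tads[s].mean_size_bp() for s in samples])
    sil = None
    if not degenerate and n >= 8:
        sil = {}
        for k in (2, 3, 4):
            try:
                from sklearn.cluster import AgglomerativeClustering
                lab_k = AgglomerativeClustering(n_clusters=k).fit_predict(features)
                sil[k] = float(silhouette_score(features, lab_k))
            except ValueError:
                sil[k] = float("nan")
    return SubtypeResult(list(samples), features, emb, labels, sizes,
                         degenerate, sil)


def subtype_associations(result: SubtypeResult,
                         covariates: dict[str, dict[str, float]],
                         alpha: float = 0.05,
                         max_missing: float = 0.5) -> pd.DataFrame:
    """Two-sided rank-sum (Mann-Whitney) comparison of per-sample covariates
    between subtypes, BH-corrected across covariates.

    ``covariates`` maps covariate name -> {sample id: value}; covariates
    missing for more than half the samples are dropped with a warning.
    """
    import warnings

    narrow = set(result.cluster("narrow"))
    broad = set(result.cluster("broad"))
    if len(narrow) < 2 or len(broad) < 2:
        raise ValueError("need >= 2 samples per subtype")
    rows = []
    for name, vals in covariates.items():
        have = [s for s in result.samples if s in vals and np.isfinite(vals[s])]
        if len(have) < (1 - max_missing) * len(result.samples):
            warnings.warn(f"covariate {name!r} missing for too many samples; dropped")
            continue
        x = np.array([vals[s] for s in have if s in narrow])
        y = np.array([vals[s] for s in have if s in broad])
        if x.size < 2 or y.size < 2:
            warnings.warn(f"covariate {name!r} has a degenerate group; dropped")
            continue
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        rows.append({
            "covariate": name,
            "n_narrow": x.size,
            "n_broad": y.size,
            "median_narrow": float(np.median(x)),
            "median_broad": float(np.median(y)),
            "direction": "narrow>broad" if np.median(x) > np.median(y) else "broad>narrow",
            "pvalue": float(res.pvalue),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["pvalue"], alpha=alpha, method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    return df
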