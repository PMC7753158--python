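"""Univariate clustering of per-genotype pollen sterility.

The screening panel reduces each genotype to one number — its average
sterile-pollen percentage — so cluster structure is sought in one dimension:

* exact optimal univariate k-means by dynamic programming over contiguous
  partitions of the sorted values (globally minimal within-cluster sum of
  squares, unlike Lloyd iterations),
* model selection by a normalised Bayesian Information Criterion (BIC/n) on
  the induced Gaussian mixture,
* agglomerative hierarchical clustering with the cluster count chosen by
  mean silhouette width or by the gap statistic against a uniform reference.

The DP recursion is the O(n²k) textbook form; panel sizes are at most a few
hundred values so the linear-time refinement is unnecessary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_score

from .impedance import RegressionFit, fit_linear, pearson

__all__ = [
    "ClusterResult",
    "ckmeans_1d",
    "bic_select",
    "hclust_1d",
    "hclust_cut",
    "silhouette_width",
    "gap_statistic",
    "GapResult",
    "build_panel",
    "sterility_size_correlation",
    "load_reference_panel",
]

LINKAGES = ("single", "complete", "average", "ward")


@dataclass(frozen=True)
class ClusterResult:
    """A k-cluster partition of univariate data.

    ``labels`` index clusters 0..k−1 in the original value order; cluster
    indices are sorted by ascending cluster mean, and each cluster is a
    contiguous interval of the sorted values.
    """

    k: int
    labels: np.ndarray
    means: np.ndarray
    sizes: np.ndarray
    withinss: np.ndarray

    @property
    def total_withinss(self) -> float:
        return float(self.withinss.sum())


def ckmeans_1d(values, k: int) -> ClusterResult:
    """Exact optimal univariate k-means via dynamic programming.

    Minimises the within-cluster sum of squares over all partitions of the
    sorted values into ``k`` contiguous intervals (the optimal univariate
    partition is always contiguous).  Deterministic; on exactly tied
    objectives the split placing fewer elements in higher clusters wins.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = x.size
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_ss(i: int, j: int) -> float:
        # within-ss of sorted slice [i, j] inclusive
        s = csum[j + 1] - csum[i]
        s2 = csum2[j + 1] - csum2[i]
        return max(s2 - s * s / (j - i + 1), 0.0)

    D = np.full((k + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    split = np.zeros((k + 1, n + 1), dtype=int)
    for q in range(1, k + 1):
        for j in range(q, n + 1):
            # candidate first indices i of the last cluster [i-1, j-1]
            i = np.arange(q, j + 1)
            s = csum[j] - csum[i - 1]
            s2 = csum2[j] - csum2[i - 1]
            ss = np.maximum(s2 - s * s / (j - i + 1), 0.0)
            v = D[q - 1, i - 1] + ss
            # ties (within 1e-12): prefer the largest split index, i.e. the
            # fewest elements in the higher cluster
            best = v.min()
            best_i = int(i[np.nonzero(v <= best + 1e-12)[0][-1]])
            D[q, j] = best
            split[q, j] = best_i
    bounds = []
    j = n
    for q in range(k, 0, -1):
        i = split[q, j]
        bounds.append((i - 1, j - 1))
        j = i - 1
    bounds.reverse()
    labels_sorted = np.empty(n, dtype=int)
    means = np.empty(k)
    sizes = np.empty(k, dtype=int)
    wss = np.empty(k)
    for c, (a, b) in enumerate(bounds):
        labels_sorted[a : b + 1] = c
        means[c] = xs[a : b + 1].mean()
        sizes[c] = b - a + 1
        wss[c] = seg_ss(a, b)
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return ClusterResult(k=k, labels=labels, means=means, sizes=sizes, withinss=wss)


def bic_select(values, k_max: int = 8, eps: float = 1e-4):
    """Choose the cluster count by normalised BIC over optimal partitions.

    For each k the optimal k-means partition induces a univariate Gaussian
    mixture (weights = cluster proportions, per-cluster mean and variance,
    variance floored at ``eps`` for near-singleton clusters); its score is
    ``BIC = 2 ln L − (3k − 1) ln n`` divided by n.  Returns ``(k_best,
    curve)`` where ``curve[k-1]`` is BIC/n at k.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 values, got {n}")
    k_max = min(k_max, n)
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        res = ckmeans_1d(x, k)
        ll = 0.0
        start = 0
        for c in range(k):
            m = res.sizes[c]
            seg = x[start : start + m]
            start += m
            var = max(float(seg.var()), eps)
            ll += -0.5 * m * np.log(2 * np.pi * var) - 0.5 * m + m * np.log(m / n)
        curve[k - 1] = (2.0 * ll - (3 * k - 1) * np.log(n)) / n
    return int(np.argmax(curve)) + 1, curve


def hclust_1d(values, linkage: str = "average") -> np.ndarray:
    """Agglomerative clustering of univariate values (scipy linkage matrix).

    Distances are absolute differences; ``linkage`` is one of single,
    complete, average or ward.  Merge order is deterministic (ties resolved
    by lowest observation index first, scipy's convention).
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    return hierarchy.linkage(x.reshape(-1, 1), method=linkage)


def hclust_cut(values, k: int, linkage: str = "average") -> ClusterResult:
    """Cut a hierarchical clustering at ``k`` clusters.

    Cluster indices are relabelled by ascending cluster mean so they are
    comparable with :func:`ckmeans_1d` output.
    """
    x = np.asarray(values, dtype=float)
    Z = hclust_1d(x, linkage)
    raw = hierarchy.fcluster(Z, k, criterion="maxclust")
    uniq = np.unique(raw)
    if uniq.size != k:
        raise ValueError(f"cut produced {uniq.size} clusters, wanted {k}")
    order = np.argsort([x[raw == c].mean() for c in uniq])
    remap = {int(uniq[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(c)] for c in raw])
    means = np.array([x[labels == c].mean() for c in range(k)])
    sizes = np.array([(labels == c).sum() for c in range(k)])
    wss = np.array([((x[labels == c] - means[c]) ** 2).sum() for c in range(k)])
    return ClusterResult(k=k, labels=labels, means=means, sizes=sizes, withinss=wss)


def silhouette_width(values, labels) -> float:
    """Mean silhouette width of a univariate partition (singletons score 0)."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels)
    k = np.unique(labels).size
    if k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_score(x, labels))


@dataclass(frozen=True)
class GapResult:
    k: int
    gaps: np.ndarray
    se: np.ndarray
    log_wk: np.ndarray


def gap_statistic(values, k_max: int = 6, b: int = 100, seed: int = 0) -> GapResult:
    """Gap statistic for the cluster count of univariate data.

    ``gap(k) = E*[log W_k] − log W_k`` with W_k the optimal within-cluster
    sum of squares and the expectation over ``b`` uniform reference draws on
    the observed data range.  The standard error carries the ``√(1 + 1/b)``
    factor, and the selected k is the smallest with
    ``gap(k) ≥ gap(k+1) − se(k+1)``.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate data range; gap statistic undefined")
    if b < 1:
        raise ValueError("need at least 1 reference draw")
    rng = np.random.default_rng(seed)
    ks = range(1, k_max + 1)
    log_wk = np.array([np.log(max(ckmeans_1d(x, k).total_withinss, 1e-300)) for k in ks])
    ref = np.empty((b, k_max))
    lo, hi = float(x.min()), float(x.max())
    for i in range(b):
        xb = rng.uniform(lo, hi, x.size)
        ref[i] = [np.log(max(ckmeans_1d(xb, k).total_withinss, 1e-300)) for k in ks]
    gaps = ref.mean(axis=0) - log_wk
    se = ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b)
    k_sel = k_max
    for k in range(1, k_max):
        if gaps[k - 1] >= gaps[k] - se[k]:
            k_sel = k
            break
    return GapResult(k=k_sel, gaps=gaps, se=se, log_wk=log_wk)


def build_panel(replica_stats: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replica-level population statistics into a genotype panel.

    ``replica_stats`` needs one row per (genotype, replica) with columns
    ``pct_viable``, ``pct_dead``, ``pct_sterile`` (percent of gated events,
    sterile included in the denominator) and optionally per-class 2 MHz
    amplitude means ``amp2_viable``/``amp2_dead``/``amp2_sterile``.  Returns
    one row per genotype with mean ± sample sd of sterility and viability
    and the averaged amplitude columns.
    """
    required = {"genotype", "pct_viable", "pct_dead", "pct_sterile"}
    missing = required - set(replica_stats.columns)
    if missing:
        raise ValueError(f"replica_stats missing columns {sorted(missing)}")
    rows = []
    for genotype, grp in replica_stats.groupby("genotype", sort=False):
        row = {
            "genotype": genotype,
            "n_replicas": len(grp),
            "sterility_mean": grp["pct_sterile"].mean(),
            "sterility_sd": grp["pct_sterile"].std(ddof=1) if len(grp) > 1 else 0.0,
            "viability_mean": grp["pct_viable"].mean(),
            "viability_sd": grp["pct_viable"].std(ddof=1) if len(grp) > 1 else 0.0,
            "dead_mean": grp["pct_dead"].mean(),
        }
        for col in ("amp2_viable", "amp2_dead", "amp2_sterile"):
            if col in grp.columns:
                row[col] = grp[col].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def sterility_size_correlation(
    panel: pd.DataFrame,
    cluster_labels=None,
    classes: tuple[str, ...] = ("viable", "dead", "sterile"),
) -> dict[str, dict]:
    """Correlate per-genotype sterility with per-class 2 MHz amplitude.

    For each pollen class with an ``amp2_<class>`` column, fits the global
    regression of amplitude on average sterility over all genotypes, plus
    within-cluster regressions when ``cluster_labels`` are given.  Returns
    ``{class: {"r": R, "fit": RegressionFit, "clusters": {label: ...}}}``;
    classes without a column are skipped.
    """
    out: dict[str, dict] = {}
    ster = np.asarray(panel["sterility_mean"], dtype=float)
    for cls in classes:
        col = f"amp2_{cls}"
        if col not in panel.columns:
            continue
        amp = np.asarray(panel[col], dtype=float)
        entry: dict = {
            "r": pearson(ster, amp),
            "fit": fit_linear(ster, amp),
            "clusters": {},
        }
        if cluster_labels is not None:
            labels = np.asarray(cluster_labels)
            for c in np.unique(labels):
                mask = labels == c
                if mask.sum() >= 3 and np.ptp(ster[mask]) > 0 and np.ptp(amp[mask]) > 0:
                    entry["clusters"][int(c)] = {
                        "r": pearson(ster[mask], amp[mask]),
                        "fit": fit_linear(ster[mask], amp[mask]),
                    }
        out[cls] = entry
    return out


def load_reference_panel() -> pd.DataFrame:
    """Packaged transcription of the 37-genotype hazelnut sterility panel.

    Columns: genotype, catkin amount/distribution, average sterility and
    viability (percent, mean ± sd over three 20 000-grain replicas) and the
    published k-means (``kmc``) and hierarchical (``hc``) cluster labels.
    """
    ref = importlib.resources.files("pollenifc.data") / "table1_hazelnut_panel.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def panel_cluster_report(values, k_kmeans: int = 5, k_hier: int = 2, linkage: str = "average"):
    """Convenience: k-means and hierarchical partitions of panel sterility.

    Returns ``(kmeans_result, hier_result)`` with cluster indices ordered by
    ascending mean sterility.
    """
    return ckmeans_1d(values, k_kmeans), hclust_cut(values, k_hier, linkage)
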