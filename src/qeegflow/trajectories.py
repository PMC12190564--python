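"""Trajectory clustering of subject-channel feature time courses.

For one metric x band, every subject-channel pair contributes an 8-point
trajectory: the feature value at each time point divided by that
subject-channel's baseline value (fold change), z-standardized across the
eight time points.  K-means (k = 5 by default) groups the standardized
trajectories; a cluster is flagged *distinct* when its mean profile is
monotone from baseline to day 1 and correlates with time (Spearman,
p < 0.05) in the same direction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .preprocess import TIMEPOINTS

log = logging.getLogger(__name__)


@dataclass
class TrajectoryMatrix:
    """Standardized fold-change trajectories; rows (subject, channel),
    columns the 8 ordered time points."""

    data: pd.DataFrame
    metric: str
    band: str
    eps: float = 1e-12

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class ClusterSolution:
    k: int
    assignments: pd.Series  # (subject, channel) -> cluster id
    mean_profiles: np.ndarray  # k x 8
    sem_profiles: np.ndarray  # k x 8
    inertia: float
    seed: int
    n_init: int
    spearman: list = field(default_factory=list)  # per cluster (rho, p)
    distinct: list = field(default_factory=list)  # per cluster bool
    timepoints: tuple = TIMEPOINTS


def build_trajectories(
    features: pd.DataFrame,
    metric: str,
    band: str,
    timepoints: tuple = TIMEPOINTS,
    baseline: str = "baseline",
    eps: float = 1e-12,
) -> TrajectoryMatrix:
    """Fold change vs baseline per subject-channel, z-standardized per row.

    Rows with a missing time point or a non-positive baseline are dropped
    (logged); constant trajectories standardize to all-zero rows.
    """
    sel = features[
        (features.metric == metric) & (features.band == band)
        & (features.channel != "GLOBAL")
    ]
    wide = sel.pivot_table(
        index=["subject", "channel"], columns="timepoint", values="value"
    )
    missing = [tp for tp in timepoints if tp not in wide.columns]
    if missing:
        raise ValueError(f"time points absent from feature table: {missing}")
    wide = wide[list(timepoints)]
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        log.warning("dropping %d incomplete trajectories (%s/%s)",
                    incomplete.sum(), metric, band)
        wide = wide[~incomplete]
    base = wide[baseline]
    bad_base = base <= 0
    if bad_base.any():
        log.warning("dropping %d rows with non-positive baseline (%s/%s)",
                    bad_base.sum(), metric, band)
        wide = wide[~bad_base]
        base = base[~bad_base]
    fold = wide.div(np.maximum(base, eps), axis=0)
    v = fold.to_numpy()
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (v - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return TrajectoryMatrix(
        data=pd.DataFrame(z, index=fold.index, columns=fold.columns),
        metric=metric, band=band, eps=eps,
    )


def spearman(x, y, exact: bool = False) -> tuple:
    """Spearman rho with a two-sided p-value.

    Default p from the t-approximation (t = rho * sqrt((n-2)/(1-rho^2));
    p reported as 0 at |rho| = 1, matching mainstream library behavior at
    these profile lengths).  ``exact=True`` enumerates all n! orderings
    (feasible for the 8-point profiles this package clusters).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    rho, p = sps.spearmanr(x, y)
    if exact:
        if x.size > 9:
            raise ValueError("exact permutation p limited to n <= 9")
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        null = np.array([
            np.corrcoef(rx[list(perm)], ry)[0, 1]
            for perm in itertools.permutations(range(x.size))
        ])
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    elif np.isclose(abs(rho), 1.0):
        p = 0.0
    return float(rho), float(p)


def kmeans_trajectories(
    tm: TrajectoryMatrix, k: int = 5, seed: int = 0, n_init: int = 50
) -> ClusterSolution:
    """Euclidean K-means on standardized trajectories, best of ``n_init``
    random initializations, deterministic given ``seed``."""
    v = tm.values
    if len(v) < k:
        raise ValueError(f"{len(v)} rows < k={k}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(v)
    means = np.empty((k, v.shape[1]))
    sems = np.empty((k, v.shape[1]))
    for c in range(k):
        grp = v[labels == c]
        means[c] = grp.mean(axis=0)
        sems[c] = grp.std(axis=0, ddof=0) / np.sqrt(len(grp)) if len(grp) else np.nan
    sol = ClusterSolution(
        k=k,
        assignments=pd.Series(labels, index=tm.data.index, name="cluster"),
        mean_profiles=means, sem_profiles=sems,
        inertia=float(km.inertia_), seed=seed, n_init=n_init,
        timepoints=tuple(tm.data.columns),
    )
    return flag_distinct(sol)


def _monotone_from_baseline(profile: np.ndarray, direction: float, tol_frac: float = 0.1) -> bool:
    """Successive differences from baseline (index 1) to day 1 (index 7)
    must not oppose ``direction`` by more than 10% of the profile range."""
    tol = tol_frac * (profile.max() - profile.min())
    diffs = np.diff(profile[1:])
    return bool(np.all(direction * diffs >= -tol))


def flag_distinct(sol: ClusterSolution, alpha: float = 0.05) -> ClusterSolution:
    """Distinct = significant Spearman trend over the 8 time points, sign
    matching the net baseline -> day-1 change, and monotone within
    tolerance."""
    t = np.arange(len(sol.timepoints))
    sol.spearman = []
    sol.distinct = []
    for profile in sol.mean_profiles:
        net = profile[-1] - profile[1]
        direction = np.sign(net)
        if profile.std() == 0 or direction == 0:
            sol.spearman.append((np.nan, np.nan))
            sol.distinct.append(False)
            continue
        rho, p = spearman(profile, t)
        sol.spearman.append((rho, p))
        ok = (
            p < alpha
            and np.sign(rho) == direction
            and _monotone_from_baseline(profile, direction)
        )
        sol.distinct.append(bool(ok))
    return sol


def cluster_summary(sol: ClusterSolution, tm: TrajectoryMatrix) -> pd.DataFrame:
    """Tidy per-cluster table: size, trend statistics and distinct flag."""
    sizes = sol.assignments.value_counts()
    rows = []
    for c in range(sol.k):
        rho, p = sol.spearman[c]
        rows.append(dict(
            metric=tm.metric, band=tm.band, cluster=c,
            n=int(sizes.get(c, 0)), spearman_rho=rho, spearman_p=p,
            distinct=sol.distinct[c],
            **{f"mean_{tp}": sol.mean_profiles[c, i]
               for i, tp in enumerate(sol.timepoints)},
        ))
    return pd.DataFrame(rows)


def silhouette_elbow_report(tm: TrajectoryMatrix, k_range=range(2, 9), seed: int = 0) -> pd.DataFrame:
    """Diagnostic sweep over k: within-cluster sum of squares (elbow) and
    silhouette score; k itself defaults to 5 in the main pipeline."""
    rows = []
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(tm.values)
        sil = silhouette_score(tm.values, km.labels_) if k < len(tm.values) else np.nan
        rows.append(dict(k=k, wcss=km.inertia_, silhouette=sil))
    return pd.DataFrame(rows)
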