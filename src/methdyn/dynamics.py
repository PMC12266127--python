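"""Temporal methylation dynamics: dynamic-bin selection and archetype clustering.

A 1-kb window is *dynamic* when its replicate-averaged methylation range
across the time course is at least ``min_delta`` (default 10 percentage
points, inclusive).  Dynamic windows are grouped by k-means on their
delta-from-baseline trajectories into four archetypes:

* C-I   — monotone gain
* C-II  — transient gain peaking mid-course
* C-III — transient/late loss
* C-IV  — monotone loss from the third timepoint onward

Cluster labels are assigned by matching each centroid to the canonical
template with which it is most correlated (one-to-one, Hungarian
assignment).  A separate two-group mode supports paired cell-type
comparisons (e.g. primary B cells versus macrophages) where only a single
between-group difference is needed.
"""

from __future__ import annotations

import logging
import warnings
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: tolerance for inclusive threshold comparisons on binary floats
EPS = 1e-12

#: Canonical delta-from-baseline templates on the default 4-timepoint design.
#: Used only to name clusters; shapes are a declared convention.
ARCHETYPE_TEMPLATES: dict[str, tuple[float, ...]] = {
    "C-I": (0.0, 0.2, 0.4, 0.4),
    "C-II": (0.0, 0.3, 0.3, 0.0),
    "C-III": (0.0, 0.0, -0.3, -0.1),
    "C-IV": (0.0, 0.0, -0.2, -0.4),
}


def _timepoint_means(
    profiles: pd.DataFrame, sample_timepoints: dict[str, float]
) -> tuple[pd.DataFrame, list[float]]:
    """Average replicate sample columns per timepoint, preserving time order."""
    tps = sorted(set(sample_timepoints.values()))
    cols = {}
    for tp in tps:
        samples = [s for s, t in sample_timepoints.items() if t == tp]
        missing = [s for s in samples if s not in profiles.columns]
        if missing:
            raise KeyError(f"profile table lacks sample columns {missing}")
        cols[f"t{tp:g}"] = profiles[samples].mean(axis=1)
    return pd.DataFrame(cols, index=profiles.index), tps


def select_dynamic_bins(
    profiles: pd.DataFrame,
    sample_timepoints: dict[str, float],
    min_delta: float = 0.10,
) -> pd.DataFrame:
    """Return windows whose methylation range across timepoints >= ``min_delta``.

    Output columns: chrom/start/end, one ``t<hours>`` column per timepoint
    (replicate-averaged), ``range``, ``net_delta`` (last - first) and
    ``direction`` in {loss, gain, transient}.  Windows with a missing mean at
    any timepoint are skipped (count logged).
    """
    if not 0 < min_delta < 1:
        raise ValueError("min_delta must be in (0, 1)")
    tmeans, tps = _timepoint_means(profiles, sample_timepoints)
    if len(tps) < 2:
        raise ValueError("need >= 2 timepoints")
    complete = tmeans.notna().all(axis=1)
    n_skipped = int((~complete).sum())
    if n_skipped:
        logger.info("skipping %d bins lacking methylation at some timepoint", n_skipped)
    tmeans = tmeans[complete]
    vals = tmeans.to_numpy()
    rng_ = vals.max(axis=1) - vals.min(axis=1)
    net = vals[:, -1] - vals[:, 0]
    keep = rng_ >= min_delta - EPS
    out = profiles.loc[tmeans.index[keep], ["chrom", "start", "end"]].copy()
    out = pd.concat([out, tmeans[keep]], axis=1)
    out["range"] = rng_[keep]
    out["net_delta"] = net[keep]
    out["direction"] = np.select(
        [net[keep] <= -(min_delta - EPS), net[keep] >= min_delta - EPS],
        ["loss", "gain"],
        default="transient",
    )
    return out.reset_index(drop=True)


def trajectory_matrix(trajectories: pd.DataFrame) -> np.ndarray:
    """Extract the ordered per-timepoint columns as a dense matrix."""
    tcols = [c for c in trajectories.columns if c.startswith("t") and
             c[1:].replace(".", "", 1).replace("-", "").isdigit()]
    tcols = sorted(tcols, key=lambda c: float(c[1:]))
    return trajectories[tcols].to_numpy(dtype=float)


def cluster_trajectories(
    trajectories: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    templates: dict[str, tuple[float, ...]] | None = None,
    n_init: int = 25,
) -> pd.DataFrame:
    """K-means cluster dynamic-bin trajectories and name clusters by archetype.

    Features are the trajectories minus their first-timepoint value, so every
    bin is anchored at 0 in the reference state.  With ``k`` equal to the
    number of templates, labels are assigned by maximizing total Pearson
    correlation between centroids and templates under a one-to-one matching;
    otherwise clusters are labelled ``cluster-1..k``.  Deterministic for a
    fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = trajectory_matrix(trajectories)
    if len(X) < k:
        raise ValueError(f"need >= {k} trajectories, got {len(X)}")
    feats = X - X[:, [0]]
    out = trajectories[["chrom", "start", "end"]].copy()
    if np.allclose(feats, feats[0]):
        warnings.warn("all trajectories identical; assigning a single cluster")
        out["cluster_label"] = "cluster-1"
        out["centroid_distance"] = 0.0
        return out
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(feats)
    centroids = km.cluster_centers_
    dists = np.linalg.norm(feats - centroids[km.labels_], axis=1)

    templates = ARCHETYPE_TEMPLATES if templates is None else templates
    names = list(templates)
    if k == len(templates) and len(next(iter(templates.values()))) == X.shape[1]:
        T = np.array([templates[n] for n in names], dtype=float)
        corr = np.zeros((k, len(names)))
        for i, c in enumerate(centroids):
            for j, t in enumerate(T):
                sc, st = c.std(), t.std()
                corr[i, j] = 0.0 if sc == 0 or st == 0 else np.corrcoef(c, t)[0, 1]
        rows, cols = linear_sum_assignment(-corr)
        label_of = {r: names[c] for r, c in zip(rows, cols)}
    else:
        label_of = {i: f"cluster-{i + 1}" for i in range(k)}
    out["cluster_label"] = [label_of[l] for l in km.labels_]
    out["centroid_distance"] = dists
    return out


def two_group_delta(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    min_delta: float = 0.10,
) -> pd.DataFrame:
    """Between-group methylation difference per shared window.

    ``delta`` = mean over group-b samples minus mean over group-a samples;
    windows with |delta| >= ``min_delta`` (inclusive) are flagged, with
    direction by sign.  Windows missing from either table are skipped.
    """
    if not 0 < min_delta < 1:
        raise ValueError("min_delta must be in (0, 1)")
    key = ["chrom", "start", "end"]
    meta = key + ["n_cpgs"]
    a_val = profiles_a.drop(columns=[c for c in meta if c in profiles_a], errors="ignore")
    b_val = profiles_b.drop(columns=[c for c in meta if c in profiles_b], errors="ignore")
    a = profiles_a[key].assign(mean_a=a_val.mean(axis=1))
    b = profiles_b[key].assign(mean_b=b_val.mean(axis=1))
    merged = a.merge(b, on=key, how="inner")
    n_skipped = len(profiles_a) + len(profiles_b) - 2 * len(merged)
    if n_skipped:
        logger.info("two_group_delta: %d unmatched windows skipped", n_skipped)
    merged["delta"] = merged["mean_b"] - merged["mean_a"]
    merged["flagged"] = merged["delta"].abs() >= min_delta - EPS
    merged["direction"] = np.select(
        [merged["delta"] <= -(min_delta - EPS), merged["delta"] >= min_delta - EPS],
        ["loss", "gain"],
        default="none",
    )
    return merged


def timepoint_delta(
    profiles: pd.DataFrame,
    sample_timepoints: dict[str, float],
    min_delta: float = 0.10,
) -> pd.DataFrame:
    """Last-versus-first-timepoint delta (the 'step change' across the course)."""
    tps = sorted(set(sample_timepoints.values()))
    first = [s for s, t in sample_timepoints.items() if t == tps[0]]
    last = [s for s, t in sample_timepoints.items() if t == tps[-1]]
    key = ["chrom", "start", "end"]
    a = profiles[key + first]
    b = profiles[key + last]
    return two_group_delta(a, b, min_delta=min_delta)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Adjusted Rand index from the pair-counting contingency-table formula."""
    a = pd.Categorical(labels_a).codes
    b = pd.Categorical(labels_b).codes
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    n = len(a)
    ct = pd.crosstab(a, b).to_numpy()
    sum_ij = sum(comb(int(x), 2) for x in ct.ravel())
    sum_a = sum(comb(int(x), 2) for x in ct.sum(axis=1))
    sum_b = sum(comb(int(x), 2) for x in ct.sum(axis=0))
    total = comb(n, 2)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
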