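"""Cross-session cluster matching, Poisson surrogate baselines, and
paired-preparation analyses.

Clusters found in different recordings are matched through their
exemplars: the distance D between the exemplar bursts of two clusters
measures how well a firing pattern discovered in one session recurs in
another.  To decide whether a small D reflects genuine spike-pattern
precision rather than merely similar firing-rate envelopes, each match is
compared against a rate-matched null: every burst is replaced by an
inhomogeneous Poisson surrogate whose rate profile is the cluster's
onset-aligned population PSTH, and the mean surrogate-to-surrogate
distance serves as the baseline.

The paired-preparation analyses quantify how similarly two simultaneously
recorded cells encode the same acoustic scene: nearest-burst distances
within versus across preparations, spike-level coincidence curves, and
the preparation composition of clusters computed on the pooled bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import Burst
from .metric import MetricParams, burst_shift_distance, distance_matrix
from .synth import generate_poisson_train

__all__ = [
    "MatchResult",
    "CoincidenceCurve",
    "match_clusters",
    "cluster_rate_profile",
    "poisson_baseline",
    "nearest_burst_analysis",
    "coincidence_analysis",
    "mix_clustering",
]

#: PSTH bin width (s) used for cluster rate profiles
PROFILE_BIN = 0.002


@dataclass
class MatchResult:
    """Best cross-session match of one source cluster."""

    source_cluster: int
    target_cluster: int
    distance: float
    baseline_mean: float | None = None
    baseline_sd: float | None = None


@dataclass
class CoincidenceCurve:
    """Fraction of burst spikes with a partner spike within +-window."""

    windows: np.ndarray
    frac_a_to_b: np.ndarray
    frac_b_to_a: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_s": self.windows, "a_to_b": self.frac_a_to_b,
             "b_to_a": self.frac_b_to_a}
        )


def match_clusters(
    clustering_a, bursts_a, clustering_b, bursts_b,
    params: MetricParams | None = None,
) -> list[MatchResult]:
    """Map every A-cluster to the B-cluster with the nearest exemplar.

    Many-to-one matches are allowed; argmin ties break toward the lower
    B-cluster id.
    """
    params = params or MetricParams()
    if clustering_a.n_clusters == 0 or clustering_b.n_clusters == 0:
        raise ValueError("both clusterings must be nonempty")
    ex_a = [bursts_a[i] for i in clustering_a.exemplars]
    ex_b = [bursts_b[i] for i in clustering_b.exemplars]
    D = distance_matrix(ex_a, ex_b, params)
    out = []
    for i in range(len(ex_a)):
        j = int(np.argmin(D.values[i]))  # argmin ties -> lowest index
        out.append(MatchResult(source_cluster=i, target_cluster=j,
                               distance=float(D.values[i, j])))
    return out


def cluster_rate_profile(bursts: list[Burst], bin: float = PROFILE_BIN) -> np.ndarray:
    """Onset-aligned population rate of a burst cluster (Hz per 2 ms bin).

    The raw PSTH of all onset-relative spike times, scaled to Hz and
    divided by the burst count; extends to the longest burst in the
    cluster.  No smoothing is applied.
    """
    if not bursts:
        raise ValueError("cluster must be nonempty")
    span = max(b.span for b in bursts)
    n_bins = max(int(np.ceil((span + 1e-9) / bin)), 1)
    edges = np.arange(n_bins + 1) * bin
    counts = np.zeros(n_bins)
    for b in bursts:
        c, _ = np.histogram(b.rel_times, bins=edges)
        counts += c
    return counts / (len(bursts) * bin)


def poisson_baseline(
    cluster_a: list[Burst], cluster_b: list[Burst],
    params: MetricParams | None = None, reps: int = 20, seed: int = 0,
) -> tuple[float, float]:
    """Rate-matched null distance between two clusters.

    Each cluster's bursts are replaced by ``reps`` inhomogeneous Poisson
    surrogates drawn from the cluster's population rate profile; returns
    the mean and SD of all cross-cluster surrogate distances under the
    same metric parameters as the exemplar match.
    """
    params = params or MetricParams()
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not cluster_a or not cluster_b:
        raise ValueError("clusters must be nonempty")
    rng = np.random.default_rng(seed)

    def surrogates(cluster):
        profile = cluster_rate_profile(cluster)
        out = []
        for _ in range(reps):
            t = generate_poisson_train(
                profile, bin_width=PROFILE_BIN,
                seed=int(rng.integers(2**31 - 1)),
            )
            out.append(t - t[0] if t.size else t)  # re-zero like detected bursts
        return out

    sa = surrogates(cluster_a)
    sb = surrogates(cluster_b)
    dists = np.array(
        [burst_shift_distance(x, y, q=params.q, n_max=params.n_max)
         for x in sa for y in sb]
    )
    return float(dists.mean()), float(dists.std(ddof=1))


def nearest_burst_analysis(
    bursts_a: list[Burst], bursts_b: list[Burst],
    params: MetricParams | None = None,
) -> pd.DataFrame:
    """Per-burst nearest-neighbour distances within and across preparations.

    Returns one row per burst (both preparations) with ``d_same``, the
    minimum distance to any other burst of its own set, and ``d_other``,
    the minimum distance to any burst of the other set.
    """
    params = params or MetricParams()
    if len(bursts_a) < 2 or len(bursts_b) < 2:
        raise ValueError("each set needs at least two bursts")
    daa = distance_matrix(bursts_a, params=params).values
    dbb = distance_matrix(bursts_b, params=params).values
    dab = distance_matrix(bursts_a, bursts_b, params).values
    np.fill_diagonal(daa, np.inf)
    np.fill_diagonal(dbb, np.inf)
    rows = []
    for i in range(len(bursts_a)):
        rows.append({"prep": 1, "index": i,
                     "d_same": float(daa[i].min()),
                     "d_other": float(dab[i].min())})
    for j in range(len(bursts_b)):
        rows.append({"prep": 2, "index": j,
                     "d_same": float(dbb[j].min()),
                     "d_other": float(dab[:, j].min())})
    return pd.DataFrame(rows)


def coincidence_analysis(
    spikes_a, spikes_b, windows=(0.001, 0.005, 0.010)
) -> CoincidenceCurve:
    """Spike-level coincidence between two preparations' burst spikes.

    For each half-width Delta, the fraction of burst spikes in one
    preparation with at least one burst spike of the other within
    [t - Delta, t + Delta]; reported in both directions.  Non-decreasing
    in Delta by construction.
    """
    a = np.sort(np.asarray(spikes_a, dtype=float))
    b = np.sort(np.asarray(spikes_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both burst-spike sets must be nonempty")
    windows = np.asarray(sorted(windows), dtype=float)

    def frac(x, y, delta):
        lo = np.searchsorted(y, x - delta, side="left")
        hi = np.searchsorted(y, x + delta, side="right")
        return float(np.mean(hi > lo))

    return CoincidenceCurve(
        windows=windows,
        frac_a_to_b=np.array([frac(a, b, w) for w in windows]),
        frac_b_to_a=np.array([frac(b, a, w) for w in windows]),
    )


def mix_clustering(prep_ids, clustering) -> pd.DataFrame:
    """Preparation composition of each cluster of a pooled clustering.

    ``prep_ids`` gives the preparation (1 or 2) of every burst in the
    aggregated set.  Returns per cluster the member count and the fraction
    contributed by each preparation.
    """
    preps = np.asarray(prep_ids)
    labels = np.asarray(getattr(clustering, "labels", clustering))
    if preps.size != labels.size:
        raise ValueError("prep_ids and clustering must have equal length")
    uniq_preps = sorted(np.unique(preps).tolist())
    rows = []
    for k in np.unique(labels):
        members = preps[labels == k]
        row = {"cluster": int(k), "size": int(members.size)}
        for p in uniq_preps:
            row[f"frac_prep{p}"] = float(np.mean(members == p))
        rows.append(row)
    return pd.DataFrame(rows)
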