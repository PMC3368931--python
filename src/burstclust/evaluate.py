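"""Cluster labeling, conditional-entropy homogeneity, and confusion matrices.

Clusters are labeled by class *over-representation*: the winning class
maximizes the ratio of its within-cluster frequency to its whole-dataset
frequency.  This avoids the bias toward the noise class, which typically
contributes several times more bursts than any stimulus class.

Homogeneity is measured per stimulus class c as the conditional entropy
H(X_c | L) of the binary variable "burst belongs to class c" given the
cluster identity L, restricted to clusters that contain at least one burst
of class c.  It is 0 exactly when every considered cluster is pure with
respect to c, and grows toward H(X_c) as class and cluster become
independent.  All entropies are in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import LABELS, NOISE_LABEL

__all__ = [
    "ClusterLabeling",
    "label_clusters",
    "conditional_entropy",
    "confusion_matrix",
]

#: tie-break order for cluster labels: stimulus classes first, noise last
_LABEL_ORDER = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class ClusterLabeling:
    """Per-cluster assigned labels with the winning over-representation ratio."""

    labels: dict          # cluster id -> assigned label
    ratios: dict          # cluster id -> f_X(c) / f_D(c) of the winning class
    class_counts: dict    # cluster id -> {class: member count}
    dataset_freq: dict    # class -> f_D(c)

    def frame(self) -> pd.DataFrame:
        rows = [
            {"cluster": k, "label": self.labels[k], "ratio": self.ratios[k],
             "size": sum(self.class_counts[k].values())}
            for k in sorted(self.labels)
        ]
        return pd.DataFrame(rows)


def _as_cluster_ids(clustering) -> np.ndarray:
    """Accept a Clustering object or a per-burst cluster-id array."""
    ids = getattr(clustering, "labels", clustering)
    return np.asarray(ids)


def label_clusters(clustering, burst_labels) -> ClusterLabeling:
    """Assign each cluster the most over-represented burst class.

    For cluster X: f_X(c) is the fraction of class-c bursts in X, f_D(c)
    the fraction in the whole dataset; the label is the class maximizing
    f_X(c)/f_D(c) among classes with f_D(c) > 0.  Ties break toward the
    larger f_X, then toward the lower class id (noise last).
    """
    cluster_ids = _as_cluster_ids(clustering)
    labels = np.asarray(burst_labels, dtype=object)
    if cluster_ids.size != labels.size:
        raise ValueError("clustering and burst_labels must have equal length")
    if cluster_ids.size == 0:
        raise ValueError("empty clustering")
    if any(lab not in LABELS for lab in labels):
        bad = sorted({str(lab) for lab in labels if lab not in LABELS})
        raise ValueError(f"burst labels outside alphabet {LABELS}: {bad}")
    n = labels.size
    f_d = {c: float(np.sum(labels == c)) / n for c in LABELS}
    out_labels, out_ratios, out_counts = {}, {}, {}
    for k in np.unique(cluster_ids):
        members = labels[cluster_ids == k]
        if members.size == 0:
            raise ValueError(f"cluster {k} is empty")
        counts = {c: int(np.sum(members == c)) for c in LABELS}
        candidates = []
        for c in LABELS:
            if f_d[c] <= 0:
                continue  # ratio undefined for classes absent from the dataset
            f_x = counts[c] / members.size
            candidates.append((f_x / f_d[c], f_x, -_LABEL_ORDER[c], c))
        ratio, _, _, winner = max(candidates)
        out_labels[k] = winner
        out_ratios[k] = ratio
        out_counts[k] = counts
    return ClusterLabeling(
        labels=out_labels, ratios=out_ratios, class_counts=out_counts,
        dataset_freq=f_d,
    )


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def conditional_entropy(c: str, clustering, burst_labels) -> float:
    """H(X_c | L) in bits over clusters containing >= 1 burst of class c.

    X_c indicates membership in class ``c``; L is the cluster identity.
    Computed as H(X_c, L) - H(L) with empirical probabilities and the
    convention 0 log 0 = 0.
    """
    cluster_ids = _as_cluster_ids(clustering)
    labels = np.asarray(burst_labels, dtype=object)
    if c not in set(labels.tolist()):
        raise ValueError(f"class {c!r} is absent from the dataset")
    is_c = labels == c
    keep_clusters = {k for k in np.unique(cluster_ids)
                     if np.any(is_c[cluster_ids == k])}
    mask = np.isin(cluster_ids, list(keep_clusters))
    sub_ids = cluster_ids[mask]
    sub_c = is_c[mask]
    n = sub_ids.size
    # joint distribution over (X_c, L)
    joint = []
    p_l = []
    for k in keep_clusters:
        in_k = sub_ids == k
        p_l.append(in_k.sum() / n)
        joint.append(np.sum(in_k & sub_c) / n)
        joint.append(np.sum(in_k & ~sub_c) / n)
    return _entropy(np.asarray(joint)) - _entropy(np.asarray(p_l))


def confusion_matrix(sessions) -> pd.DataFrame:
    """Average confusion matrix over recording sessions.

    ``sessions`` is an iterable of ``(clustering, burst_labels)`` pairs
    (or ``(clustering, burst_labels, ClusterLabeling)`` to reuse a
    labeling).  Per session, each assigned cluster label's row is the
    unweighted mean of the class-frequency vectors of the clusters bearing
    that label; rows are then averaged unweighted across the sessions in
    which they occur.  Rows with no cluster in any session are NaN.
    Occupied rows sum to 1.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("need at least one session")
    per_session = []
    for sess in sessions:
        if len(sess) == 3:
            clustering, burst_labels, labeling = sess
        else:
            clustering, burst_labels = sess
            labeling = label_clusters(clustering, burst_labels)
        cluster_ids = _as_cluster_ids(clustering)
        labels = np.asarray(burst_labels, dtype=object)
        rows = {}
        for assigned in LABELS:
            vecs = []
            for k, lab in labeling.labels.items():
                if lab != assigned:
                    continue
                members = labels[cluster_ids == k]
                vecs.append([np.mean(members == c) for c in LABELS])
            if vecs:
                rows[assigned] = np.mean(np.asarray(vecs), axis=0)
        per_session.append(rows)
    data = {}
    for assigned in LABELS:
        vecs = [s[assigned] for s in per_session if assigned in s]
        data[assigned] = (np.mean(np.asarray(vecs), axis=0) if vecs
                          else np.full(len(LABELS), np.nan))
    return pd.DataFrame.from_dict(data, orient="index", columns=list(LABELS))
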