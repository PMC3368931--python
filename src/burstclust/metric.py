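"""Victor-Purpura spike-time metric and its burst-shift extension.

The Victor-Purpura (VP) metric is the minimal total cost of editing one
spike train into another using three operations: insert a spike (cost 1),
delete a spike (cost 1), or shift a single spike by ``dt`` seconds (cost
``q * |dt|``).  The cost-rate parameter ``q`` (unit 1/s) sets the temporal
precision of the comparison: shifting beats delete+insert exactly when the
two spikes are closer than ``2/q`` seconds.

The burst-shift extension targets onset-aligned bursts contaminated by
occasional noise spikes immediately before the true burst onset: up to
``n_max`` initial spikes may be deleted from either train (cost 1 each),
after which the remaining spikes are re-zeroed to their new first spike and
compared with the plain VP metric.  Re-zeroing makes the comparison
translation-invariant in the way burst patterns (not absolute firing times)
require; it can break the triangle inequality, which the downstream
exemplar clustering does not need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from sklearn.base import BaseEstimator

__all__ = [
    "MetricParams",
    "DistanceMatrix",
    "VictorPurpuraDistance",
    "vp_distance",
    "burst_shift_distance",
    "distance_matrix",
    "q_separability",
]

#: default cost rate, 1/s.  Chosen so that one insertion/deletion costs the
#: same as shifting a spike by 16 ms (1/0.016 s = 62.5).
DEFAULT_Q = 62.5

#: default maximum number of initial deletions per burst.
DEFAULT_N_MAX = 2


@dataclass(frozen=True)
class MetricParams:
    """Parameters of the burst-shift Victor-Purpura metric.

    Parameters
    ----------
    q : float
        Shift cost rate in 1/s; must be >= 0.
    n_max : int
        Maximum number of initial spikes the burst-shift operator may
        delete from each train; must be >= 0.
    """

    q: float = DEFAULT_Q
    n_max: int = DEFAULT_N_MAX

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError(f"q must be >= 0, got {self.q}")
        if self.n_max < 0:
            raise ValueError(f"n_max must be >= 0, got {self.n_max}")


@dataclass
class DistanceMatrix:
    """Pairwise burst distances plus the ids and parameters that made them."""

    values: np.ndarray
    row_ids: list
    col_ids: list
    params: MetricParams = field(default_factory=MetricParams)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(fastmath=False)
def _vp_dp(a, b, q):  # pragma: no cover - exercised through vp_distance
    na = a.size
    nb = b.size
    if na == 0:
        return float(nb)
    if nb == 0:
        return float(na)
    prev = np.empty(nb + 1)
    cur = np.empty(nb + 1)
    for j in range(nb + 1):
        prev[j] = j
    for i in range(1, na + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, nb + 1):
            best = prev[j - 1] + q * abs(ai - b[j - 1])
            alt = prev[j] + 1.0
            if alt < best:
                best = alt
            alt = cur[j - 1] + 1.0
            if alt < best:
                best = alt
            cur[j] = best
        tmp = prev
        prev = cur
        cur = tmp
    return prev[nb]


@njit(fastmath=False)
def _bsd(a, b, q, n_max):  # pragma: no cover - exercised through wrappers
    best = np.inf
    ka_max = min(n_max, a.size)
    kb_max = min(n_max, b.size)
    for ka in range(ka_max + 1):
        aa = a[ka:]
        if aa.size > 0:
            aa = aa - aa[0]
        for kb in range(kb_max + 1):
            bb = b[kb:]
            if bb.size > 0:
                bb = bb - bb[0]
            c = ka + kb + _vp_dp(aa, bb, q)
            if c < best:
                best = c
    return best


@njit(fastmath=False)
def _pairwise(flat_a, offs_a, flat_b, offs_b, q, n_max, symmetric):
    n = offs_a.size - 1
    m = offs_b.size - 1
    out = np.zeros((n, m))
    for i in range(n):
        ai = flat_a[offs_a[i] : offs_a[i + 1]]
        j0 = i + 1 if symmetric else 0
        for j in range(j0, m):
            d = _bsd(ai, flat_b[offs_b[j] : offs_b[j + 1]], q, n_max)
            out[i, j] = d
            if symmetric:
                out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _as_times(x) -> np.ndarray:
    """Accept a Burst-like object (``rel_times`` attribute) or a sequence."""
    times = getattr(x, "rel_times", x)
    arr = np.asarray(times, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("spike times must be one-dimensional")
    return arr


def _check_sorted(arr: np.ndarray, name: str) -> None:
    if arr.size > 1 and np.any(np.diff(arr) < 0):
        raise ValueError(f"{name}: spike times must be sorted non-decreasing")


def vp_distance(a, b, q: float = DEFAULT_Q) -> float:
    """Plain Victor-Purpura spike-time distance between two trains.

    Satisfies the metric axioms; ``|n_a - n_b|`` is a lower bound and
    ``n_a + n_b`` an upper bound on the value.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    ta, tb = _as_times(a), _as_times(b)
    _check_sorted(ta, "a")
    _check_sorted(tb, "b")
    return float(_vp_dp(ta, tb, float(q)))


def burst_shift_distance(
    a, b, q: float = DEFAULT_Q, n_max: int = DEFAULT_N_MAX
) -> float:
    """Burst-shift Victor-Purpura distance between onset-aligned bursts.

    Minimum over deleting ``k_a <= n_max`` / ``k_b <= n_max`` initial spikes
    (cost 1 each), re-zeroing each remainder to its new first spike, and
    taking the plain VP distance; symmetric by construction and never larger
    than ``vp_distance`` (k_a = k_b = 0 is admissible).
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    if q < 0:
        raise ValueError("q must be >= 0")
    ta, tb = _as_times(a), _as_times(b)
    _check_sorted(ta, "a")
    _check_sorted(tb, "b")
    for name, arr in (("a", ta), ("b", tb)):
        if arr.size and abs(arr[0]) > 1e-9:
            raise ValueError(
                f"{name}: burst spike times must be onset-relative (first = 0)"
            )
    return float(_bsd(ta, tb, float(q), int(n_max)))


def _pack(bursts) -> tuple[np.ndarray, np.ndarray]:
    arrays = [_as_times(b) for b in bursts]
    offs = np.zeros(len(arrays) + 1, dtype=np.int64)
    offs[1:] = np.cumsum([a.size for a in arrays])
    flat = (
        np.concatenate(arrays) if arrays and offs[-1] else np.empty(0, dtype=np.float64)
    )
    return flat, offs


class VictorPurpuraDistance(BaseEstimator):
    """Pairwise burst-shift Victor-Purpura metric, estimator style.

    Parameters
    ----------
    q : float
        Shift cost rate (1/s).
    n_max : int
        Initial-deletion budget of the burst-shift operator.  ``n_max=0``
        reduces exactly to the plain metric.
    """

    def __init__(self, q: float = DEFAULT_Q, n_max: int = DEFAULT_N_MAX):
        self.q = q
        self.n_max = n_max

    @property
    def params_(self) -> MetricParams:
        return MetricParams(q=self.q, n_max=self.n_max)

    def __call__(self, a, b) -> float:
        return burst_shift_distance(a, b, q=self.q, n_max=self.n_max)

    def pairwise(self, bursts_a, bursts_b=None) -> DistanceMatrix:
        """All pairwise distances; exploits symmetry when one set is given."""
        params = self.params_  # validates
        bursts_a = list(bursts_a)
        if not bursts_a:
            raise ValueError("burst set must be nonempty")
        symmetric = bursts_b is None
        bursts_b = bursts_a if symmetric else list(bursts_b)
        if not bursts_b:
            raise ValueError("burst set must be nonempty")
        for name, bursts in (("set A", bursts_a), ("set B", bursts_b)):
            for k, b in enumerate(bursts):
                _check_sorted(_as_times(b), f"{name}[{k}]")
        flat_a, offs_a = _pack(bursts_a)
        flat_b, offs_b = (flat_a, offs_a) if symmetric else _pack(bursts_b)
        values = _pairwise(
            flat_a, offs_a, flat_b, offs_b, float(params.q), int(params.n_max), symmetric
        )

        def ids(bursts):
            out = []
            for i, b in enumerate(bursts):
                rid = getattr(b, "recording_id", "")
                out.append(f"{rid}:{i}" if rid else i)
            return out

        return DistanceMatrix(
            values=values,
            row_ids=ids(bursts_a),
            col_ids=ids(bursts_a) if symmetric else ids(bursts_b),
            params=params,
        )


def distance_matrix(set_a, set_b=None, params: MetricParams | None = None) -> DistanceMatrix:
    """Pairwise burst-shift distance matrix between two burst sets."""
    params = params or MetricParams()
    return VictorPurpuraDistance(q=params.q, n_max=params.n_max).pairwise(set_a, set_b)


# ---------------------------------------------------------------------------
# q-selection separability analysis
# ---------------------------------------------------------------------------

NOISE_LABEL = "N"


def _spike_counts(bursts) -> np.ndarray:
    return np.array([_as_times(b).size for b in bursts])


def q_separability(
    bursts,
    labels,
    q_grid,
    n_max: int = DEFAULT_N_MAX,
) -> pd.DataFrame:
    """Class-separability statistics of the metric as a function of ``q``.

    For every ``q`` in ``q_grid`` returns, over all labeled burst pairs:

    - ``sep_all``: mean between-class distance minus mean within-class
      distance over the full set;
    - ``sep_stimulus``: the same restricted to stimulus-labeled bursts
      (classes "1".."5");
    - ``sep_noise``: mean noise-vs-stimulus distance minus mean
      within-noise distance;
    - ``within_eq_stimulus`` / ``within_eq_noise``: mean within-class
      distance restricted to pairs with identical spike count (stimulus
      classes averaged per class, then across classes).

    Classes with fewer than two members contribute no within-class pairs.
    Raises if fewer than two classes are present or no within-class pair
    exists at all.
    """
    bursts = list(bursts)
    labels = np.asarray(labels, dtype=object)
    if len(bursts) != len(labels):
        raise ValueError("bursts and labels must have equal length")
    present = set(labels.tolist())
    if len(present) < 2:
        raise ValueError(
            "q_separability needs at least two classes; "
            f"found only {sorted(map(str, present))}"
        )
    counts = _spike_counts(bursts)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(bursts), k=1)
    within_mask = same[iu]
    if not within_mask.any():
        raise ValueError("all classes are singletons: no within-class pairs")
    stim = labels != NOISE_LABEL
    stim_pair = stim[iu[0]] & stim[iu[1]]
    noise_pair = ~stim[iu[0]] & ~stim[iu[1]]
    cross_pair = stim[iu[0]] != stim[iu[1]]
    eq_count = (counts[iu[0]] == counts[iu[1]]) & within_mask

    rows = []
    for q in q_grid:
        D = distance_matrix(bursts, params=MetricParams(q=float(q), n_max=n_max))
        d = D.values[iu]

        def mean_or_nan(mask):
            return float(d[mask].mean()) if mask.any() else np.nan

        sep_all = mean_or_nan(~within_mask) - mean_or_nan(within_mask)
        sep_stim = mean_or_nan(~within_mask & stim_pair) - mean_or_nan(
            within_mask & stim_pair
        )
        sep_noise = mean_or_nan(cross_pair) - mean_or_nan(within_mask & noise_pair)
        # per-class equal-count means for stimulus classes, then averaged
        stim_means = []
        for c in sorted(present - {NOISE_LABEL}, key=str):
            m = eq_count & (labels[iu[0]] == c) & (labels[iu[1]] == c)
            if m.any():
                stim_means.append(float(d[m].mean()))
        rows.append(
            {
                "q": float(q),
                "sep_all": sep_all,
                "sep_stimulus": sep_stim,
                "sep_noise": sep_noise,
                "within_eq_stimulus": float(np.mean(stim_means))
                if stim_means
                else np.nan,
                "within_eq_noise": mean_or_nan(eq_count & noise_pair),
            }
        )
    return pd.DataFrame(rows).set_index("q")


def equal_count_within_distances(
    bursts, labels, q: float = DEFAULT_Q, n_max: int = DEFAULT_N_MAX
) -> pd.DataFrame:
    """Within-class distances of equal-spike-count pairs at a single ``q``.

    Returns one row per qualifying pair with columns ``distance`` and
    ``group`` ("stimulus" or "noise"); the raw material for the histogram
    of within-class precision.
    """
    bursts = list(bursts)
    labels = np.asarray(labels, dtype=object)
    counts = _spike_counts(bursts)
    D = distance_matrix(bursts, params=MetricParams(q=q, n_max=n_max))
    iu = np.triu_indices(len(bursts), k=1)
    same = (labels[iu[0]] == labels[iu[1]]) & (counts[iu[0]] == counts[iu[1]])
    rows = []
    for i, j in zip(iu[0][same], iu[1][same]):
        rows.append(
            {
                "distance": float(D.values[i, j]),
                "group": "noise" if labels[i] == NOISE_LABEL else "stimulus",
            }
        )
    return pd.DataFrame(rows, columns=["distance", "group"])
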