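"""Seeded synthetic spike-train recordings with ground-truth burst labels.

Emulates the statistical structure of long field recordings from a single
auditory interneuron (the omega cell of a katydid) in a noisy nocturnal
habitat:

- baseline firing at 7-17 Hz with slow drift, modelled as a dead-time
  (refractory) renewal process whose instantaneous rate follows a
  20-minute sinusoid.  The dead time keeps the non-burst background free
  of burst-like spike runs, which in the recordings this pipeline targets
  always originate from acoustic events;
- noise bursts arriving with exponential inter-event intervals, each an
  instance of one of a fixed library of archetype patterns (a mixture of
  short precisely-patterned and long unstructured high-rate trains) with
  per-spike Gaussian jitter;
- stimulus-evoked bursts following every trigger with ~10 ms latency; the
  five stimulus classes are defined by their pulse envelopes;
- occasional noise spikes inserted shortly before a burst's first spike;
- a paired-preparation mode in which two recordings share one planted
  event sequence and the second preparation applies independent jitter
  plus per-spike thinning (emulating a 5 dB sensitivity offset).

Every planted burst satisfies the burst detector's acceptance rules by
construction, and the generator records each planted burst's onset, label,
archetype and preparation as ground truth for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import NOISE_LABEL, DetectorParams, SpikeTrain, StimulusEvent

__all__ = [
    "StimulusTemplate",
    "SynthConfig",
    "GroundTruth",
    "Recording",
    "make_stimulus_templates",
    "generate_poisson_train",
    "generate_recording",
    "generate_paired_recordings",
]

#: pulse epochs (s, relative to stimulus onset) of the five stimulus classes
_CLASS_EPOCHS = {
    1: [(0.0, 0.010)],
    2: [(0.0, 0.010), (0.020, 0.030)],
    3: [(0.0, 0.030)],
    4: [(0.0, 0.010), (0.020, 0.030), (0.040, 0.050), (0.060, 0.070)],
    5: [(0.0, 0.070)],
}

#: refractory gap below which the later of two spikes is dropped (s)
REFRACTORY = 0.0005

#: background guard zone around planted bursts: no background spike from
#: ``onset - PRE_GUARD`` to ``last spike + POST_GUARD``.
PRE_GUARD = 0.080
POST_GUARD = 0.050

#: sinusoidal drift period of the background rate (s); ~20 minutes
DRIFT_PERIOD = 1200.0


@dataclass(frozen=True)
class StimulusTemplate:
    """Pulse-envelope template of one stimulus class."""

    class_id: int
    pulse_epochs: tuple[tuple[float, float], ...]
    within_pulse_rate: float = 500.0
    jitter_sd: float = 0.0005
    latency_mean: float = 0.010
    latency_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.within_pulse_rate <= 0:
            raise ValueError("within_pulse_rate must be positive")
        last = -np.inf
        for s, e in self.pulse_epochs:
            if not (0.0 <= s < e <= 0.2):
                raise ValueError("pulse epochs must lie within [0, 0.2] s")
            if s < last:
                raise ValueError("pulse epochs must be sorted and non-overlapping")
            last = e

    @property
    def span(self) -> float:
        return self.pulse_epochs[-1][1] if self.pulse_epochs else 0.0

    def base_spikes(self) -> np.ndarray:
        """Deterministic spike grid: regular firing at ``within_pulse_rate``
        during each pulse epoch (endpoints included)."""
        step = 1.0 / self.within_pulse_rate
        out = []
        for s, e in self.pulse_epochs:
            out.append(np.arange(s, e + step / 2, step))
        return np.concatenate(out)


def make_stimulus_templates(classes) -> list[StimulusTemplate]:
    """One template per requested class id, sorted by class id."""
    templates = []
    for c in sorted(set(classes)):
        if c not in _CLASS_EPOCHS:
            raise ValueError(f"unknown stimulus class id: {c!r} (valid: 1..5)")
        templates.append(
            StimulusTemplate(class_id=int(c), pulse_epochs=tuple(_CLASS_EPOCHS[c]))
        )
    return templates


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of one synthetic recording session.

    Defaults mirror the field conditions the pipeline was designed for:
    baseline 12 Hz drifting between ~7 and ~17 Hz, stimulus triggers every
    10 s, and noise bursts four times as frequent as stimulus bursts.
    """

    duration: float = 600.0
    background_rate_mean: float = 12.0
    background_rate_drift: float = 0.4
    background_dead_time: float = 0.020
    stimulus_interval: float = 10.0
    stimulus_classes: tuple[int, ...] = (1, 2, 3, 4, 5)
    noise_burst_rate: float = 0.4
    noise_burst_archetypes: int = 8
    noise_archetype_jitter_sd: float = 0.0005
    pre_burst_noise_prob: float = 0.1
    paired_mode: bool = False
    sensitivity_offset: float = 0.1
    seed: int = 0
    archetype_seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("background_rate_mean", "noise_burst_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pre_burst_noise_prob", "sensitivity_offset"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.background_rate_drift < 1.0:
            raise ValueError("background_rate_drift must be in [0, 1)")
        if self.noise_burst_archetypes < 1:
            raise ValueError("need at least one noise-burst archetype")
        if self.stimulus_classes:
            span = max(_CLASS_EPOCHS[c][-1][1] for c in self.stimulus_classes
                       if c in _CLASS_EPOCHS) if all(
                c in _CLASS_EPOCHS for c in self.stimulus_classes
            ) else None
            if span is None:
                bad = [c for c in self.stimulus_classes if c not in _CLASS_EPOCHS]
                raise ValueError(f"unknown stimulus class id(s): {bad}")
            if self.stimulus_interval <= span + 0.2:
                raise ValueError(
                    "stimulus_interval must exceed the longest template span "
                    "(planted bursts would overlap adjacent triggers)"
                )


@dataclass
class GroundTruth:
    """Planted-burst records: onset_s, label, archetype (-1 = stimulus), prep."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"onset_s", "label", "archetype", "prep"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"ground truth needs columns {sorted(required)}")

    def __len__(self) -> int:
        return len(self.frame)

    def for_prep(self, prep: int) -> pd.DataFrame:
        return self.frame[self.frame["prep"] == prep].reset_index(drop=True)


@dataclass
class Recording:
    """A synthetic recording: the spike train plus its stimulus triggers.

    ``meta`` carries per-source spike counts (background / planted /
    pre_burst) for bookkeeping and superposition checks.
    """

    train: SpikeTrain
    triggers: list[StimulusEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# inhomogeneous Poisson sampling (used for recordings and surrogate baselines)
# ---------------------------------------------------------------------------


def generate_poisson_train(rate_profile, duration: float | None = None, seed=0,
                           bin_width: float | None = None) -> np.ndarray:
    """Inhomogeneous Poisson spike times on [0, T) by thinning.

    ``rate_profile`` is either a scalar rate (Hz; ``duration`` required) or
    a 1-D array of piecewise-constant rates over bins of ``bin_width``
    seconds (then T = len(profile) * bin_width).  Sampling thins a
    homogeneous process at the profile maximum; reproducible given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    profile = np.atleast_1d(np.asarray(rate_profile, dtype=float))
    if np.any(profile < 0):
        raise ValueError("rates must be >= 0")
    if profile.size == 1:
        if duration is None or duration <= 0:
            raise ValueError("scalar rate requires a positive duration")
        profile = np.full(1, profile[0])
        bin_width = float(duration)
    else:
        if bin_width is None or bin_width <= 0:
            raise ValueError("piecewise profile requires a positive bin_width")
        duration = profile.size * bin_width
    rmax = float(profile.max())
    if rmax == 0.0:
        return np.empty(0)
    n = rng.poisson(rmax * duration)
    t = np.sort(rng.uniform(0.0, duration, size=n))
    local = profile[np.minimum((t / bin_width).astype(int), profile.size - 1)]
    keep = rng.uniform(0.0, rmax, size=n) < local
    return t[keep]


# ---------------------------------------------------------------------------
# archetype library and burst instantiation
# ---------------------------------------------------------------------------


def _draw_archetypes(n: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Fixed library of noise-burst patterns (onset-relative spike times).

    Half short precisely-patterned trains (6-12 spikes, ISIs 2.5-8 ms,
    span >= 14 ms), half long unstructured high-rate trains (up to 40
    spikes, ~100-300 ms).  All satisfy the detector's interval rules.
    """
    out = []
    for _ in range(n):
        if rng.random() < 0.5:
            while True:
                k = int(rng.integers(6, 13))
                isis = rng.uniform(0.0025, 0.008, size=k - 1)
                if isis.sum() >= 0.014:
                    break
        else:
            mean_isi = rng.uniform(0.005, 0.012)
            dur = rng.uniform(0.10, 0.30)
            k = int(np.clip(round(dur / mean_isi), 10, 40))
            # ISIs capped at 14 ms so that losing any single spike (refractory
            # collision, paired-mode thinning) merges two ISIs to < 30 ms and
            # keeps every consecutive pair sum <= 45 ms: archetype
            # detectability is robust to single-spike deletions
            isis = np.clip(
                rng.uniform(0.6, 1.4, size=k - 1) * mean_isi, 0.0025, 0.014
            )
            # the first ISI must satisfy the detector's second-spike rule
            isis[0] = min(isis[0], 0.012)
        out.append(np.concatenate([[0.0], np.cumsum(isis)]))
    return out


def _resolve_collisions(times: np.ndarray) -> np.ndarray:
    """Drop the later spike of any pair closer than the refractory gap."""
    if times.size < 2:
        return times
    keep = [0]
    for i in range(1, times.size):
        if times[i] - times[keep[-1]] >= REFRACTORY:
            keep.append(i)
    return times[keep]


def _instance_valid(rel: np.ndarray, det: DetectorParams) -> bool:
    """Detector acceptance rules with a small safety margin."""
    if rel.size < det.min_spikes:
        return False
    isis = np.diff(rel)
    if rel.size >= 2 and isis[0] > det.second_spike_max - 0.001:
        return False
    if np.any(isis >= det.end_isi - 0.001):
        return False
    if isis.size >= 2 and np.any(isis[:-1] + isis[1:] > det.end_pair_sum - 0.001):
        return False
    return rel[-1] - rel[0] > det.min_duration + 0.0005


def _jitter_instance(
    base: np.ndarray, sd: float, rng: np.random.Generator,
    det: DetectorParams, retries: int = 200,
) -> np.ndarray:
    """Jittered copy of a base pattern, redrawn until it stays a valid burst.

    This is how planted bursts satisfy the detector's acceptance rules by
    construction.  Returns times relative to the base onset (first spike
    may carry a small offset from its own jitter).
    """
    if sd == 0.0:
        return base.copy()
    for _ in range(retries):
        cand = np.sort(base + rng.normal(0.0, sd, size=base.size))
        cand = _resolve_collisions(cand)
        if _instance_valid(cand - cand[0], det):
            return cand
    return base.copy()


# ---------------------------------------------------------------------------
# event planting
# ---------------------------------------------------------------------------


@dataclass
class _PlantedEvent:
    onset: float              # nominal onset (first base spike, absolute)
    base: np.ndarray          # base spike times relative to onset (first = 0)
    label: str
    archetype: int            # -1 for stimulus bursts
    jitter_sd: float
    pre_noise: bool           # insert a pre-burst noise spike?
    pre_noise_offset: float   # 5-15 ms before the first spike


def _plan_events(config: SynthConfig, rng_events: np.random.Generator
                 ) -> tuple[list[_PlantedEvent],
                            list[StimulusEvent],
                            list[np.ndarray]]:
    """Shared planted-event sequence (used by both single and paired modes)."""
    arch_seed = (config.archetype_seed if config.archetype_seed is not None
                 else config.seed + 101)
    rng_arch = np.random.default_rng([arch_seed, 7])
    archetypes = _draw_archetypes(config.noise_burst_archetypes, rng_arch)
    templates = {t.class_id: t for t in make_stimulus_templates(config.stimulus_classes)}

    events: list[_PlantedEvent] = []
    triggers: list[StimulusEvent] = []
    zones: list[tuple[float, float]] = []  # (start, end) of occupied intervals

    # stimulus triggers every stimulus_interval, classes drawn uniformly
    if templates:
        k = 0
        while True:
            t0 = k * config.stimulus_interval
            if t0 + 0.5 > config.duration:
                break
            cid = int(rng_events.choice(sorted(templates)))
            tpl = templates[cid]
            lat = float(np.clip(
                rng_events.normal(tpl.latency_mean, tpl.latency_sd), 0.002, 0.040
            ))
            base = tpl.base_spikes()
            base = base - base[0]
            onset = t0 + lat
            events.append(_PlantedEvent(
                onset=onset, base=base, label=str(cid), archetype=-1,
                jitter_sd=tpl.jitter_sd,
                pre_noise=bool(rng_events.random() < config.pre_burst_noise_prob),
                pre_noise_offset=float(rng_events.uniform(0.005, 0.015)),
            ))
            triggers.append(StimulusEvent(onset=float(t0), class_id=cid))
            zones.append((t0, onset + base[-1]))
            k += 1

    # noise bursts: exponential inter-event law, rejecting overlaps
    if config.noise_burst_rate > 0 and archetypes:
        t = 0.5
        while True:
            t += float(rng_events.exponential(1.0 / config.noise_burst_rate))
            if t + 0.5 > config.duration:
                break
            ai = int(rng_events.integers(len(archetypes)))
            base = archetypes[ai]
            lo, hi = t - 0.15, t + base[-1] + 0.15
            if any(lo < ze and zs < hi for zs, ze in zones):
                continue  # would overlap an existing planted burst or trigger
            events.append(_PlantedEvent(
                onset=t, base=base, label=NOISE_LABEL, archetype=ai,
                jitter_sd=config.noise_archetype_jitter_sd,
                pre_noise=bool(rng_events.random() < config.pre_burst_noise_prob),
                pre_noise_offset=float(rng_events.uniform(0.005, 0.015)),
            ))
            zones.append((t, t + base[-1]))
    events.sort(key=lambda e: e.onset)
    return events, triggers, archetypes


def _background(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Dead-time renewal background with slow sinusoidal rate drift."""
    r0 = config.background_rate_mean
    if r0 == 0:
        return np.empty(0)
    d = config.background_dead_time
    drift = config.background_rate_drift

    def rate(t):
        return r0 * (1.0 + drift * np.sin(2.0 * np.pi * t / DRIFT_PERIOD))

    rmax = r0 * (1.0 + drift)
    # effective hazard keeps the realized rate at the target despite the
    # dead time: lambda'(t) = r(t) / (1 - r(t) * d)
    hmax = rmax / (1.0 - rmax * d) if rmax * d < 1 else rmax * 10
    out = []
    t = float(rng.exponential(1.0 / max(rate(0.0), 1e-9)))
    while t < config.duration:
        h = rate(t) / max(1.0 - rate(t) * d, 1e-6)
        if rng.random() < h / hmax:
            out.append(t)
            t += d  # absolute dead time
        t += float(rng.exponential(1.0 / hmax))
    return np.asarray(out)


def _mask_zones(times: np.ndarray, zones: list[tuple[float, float]]) -> np.ndarray:
    if not zones or times.size == 0:
        return times
    keep = np.ones(times.size, dtype=bool)
    for lo, hi in zones:
        keep &= ~((times >= lo) & (times <= hi))
    return times[keep]


def _realize_prep(
    events: list[_PlantedEvent],
    background: np.ndarray,
    config: SynthConfig,
    rng_jitter: np.random.Generator,
    det: DetectorParams,
    prep: int,
    thin: float = 0.0,
    rng_thin: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame, int, int]:
    """Instantiate planted events for one preparation and assemble spikes.

    Returns (spike_times, ground-truth frame, planted spike count,
    pre-burst noise spike count).
    """
    planted_spikes = []
    pre_spikes = []
    gt_rows = []
    guard: list[tuple[float, float]] = []
    for ev in events:
        inst = _jitter_instance(ev.base, ev.jitter_sd, rng_jitter, det)
        abs_times = ev.onset + inst
        if thin > 0.0:
            keep = rng_thin.random(abs_times.size) >= thin
            abs_times = abs_times[keep]
        pre = None
        if ev.pre_noise and abs_times.size:
            pre = abs_times[0] - ev.pre_noise_offset
            if thin > 0.0 and rng_thin.random() < thin:
                pre = None
        if abs_times.size:
            planted_spikes.append(abs_times)
            gt_rows.append({
                "onset_s": float(abs_times[0]),
                "label": ev.label,
                "archetype": ev.archetype,
                "prep": prep,
            })
            lo = (pre if pre is not None else abs_times[0]) - PRE_GUARD
            guard.append((lo, abs_times[-1] + POST_GUARD))
        if pre is not None:
            pre_spikes.append(pre)
    bg = _mask_zones(background, guard)
    if thin > 0.0 and bg.size:
        bg = bg[rng_thin.random(bg.size) >= thin]
    n_planted = int(sum(a.size for a in planted_spikes))
    parts = [p for p in planted_spikes + [bg, np.asarray(pre_spikes)] if p.size]
    all_times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    all_times = _resolve_collisions(all_times)
    all_times = all_times[(all_times >= 0) & (all_times < config.duration)]
    gt = pd.DataFrame(gt_rows, columns=["onset_s", "label", "archetype", "prep"])
    gt = gt.sort_values("onset_s").reset_index(drop=True)
    counts = {
        "background": int(bg.size),
        "planted": n_planted,
        "pre_burst": len(pre_spikes),
    }
    return all_times, gt, counts


def generate_recording(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """One synthetic recording plus its planted-burst ground truth."""
    det = DetectorParams()
    rng_events = np.random.default_rng([config.seed, 1])
    rng_bg = np.random.default_rng([config.seed, 2])
    rng_jit = np.random.default_rng([config.seed, 3])
    events, triggers, _ = _plan_events(config, rng_events)
    background = _background(config, rng_bg)
    times, gt, counts = _realize_prep(
        events, background, config, rng_jit, det, prep=1
    )
    train = SpikeTrain(times=times, duration=config.duration,
                       id=f"synth-{config.seed}")
    return (Recording(train=train, triggers=triggers, meta=counts),
            GroundTruth(frame=gt))


def generate_paired_recordings(
    config: SynthConfig,
) -> tuple[Recording, Recording, GroundTruth]:
    """Two simultaneous recordings sharing one planted event sequence.

    Both preparations see the same acoustic events (identical base spike
    patterns and background stream); each applies its own per-spike jitter,
    and preparation 2 additionally thins every spike with probability
    ``sensitivity_offset``.
    """
    if not config.paired_mode:
        raise ValueError("generate_paired_recordings requires paired_mode=True")
    det = DetectorParams()
    rng_events = np.random.default_rng([config.seed, 1])
    rng_bg = np.random.default_rng([config.seed, 2])
    events, triggers, _ = _plan_events(config, rng_events)
    background = _background(config, rng_bg)
    t1, gt1, c1 = _realize_prep(
        events, background, config, np.random.default_rng([config.seed, 11]),
        det, prep=1,
    )
    t2, gt2, c2 = _realize_prep(
        events, background, config, np.random.default_rng([config.seed, 12]),
        det, prep=2, thin=config.sensitivity_offset,
        rng_thin=np.random.default_rng([config.seed, 13]),
    )
    gt = pd.concat([gt1, gt2], ignore_index=True)
    rec1 = Recording(
        train=SpikeTrain(t1, duration=config.duration, id=f"synth-{config.seed}-p1"),
        triggers=triggers, meta=c1,
    )
    rec2 = Recording(
        train=SpikeTrain(t2, duration=config.duration, id=f"synth-{config.seed}-p2"),
        triggers=list(triggers), meta=c2,
    )
    return rec1, rec2, GroundTruth(frame=gt)
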