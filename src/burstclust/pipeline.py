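"""End-to-end pipeline: detect -> associate -> distances -> cluster ->
dendrogram -> label -> homogeneity, with optional cross-session matching.

Every run writes a manifest recording all parameters and seeds; re-running
from the same configuration reproduces all artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as bio
from .cluster import BurstAffinityPropagation, build_dendrogram, silhouette_values
from .detect import DetectorParams, SpikeTrain, associate_stimuli, detect_bursts
from .evaluate import conditional_entropy, label_clusters
from .matching import match_clusters, poisson_baseline
from .metric import MetricParams, distance_matrix

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("burstclust")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Validated parameters of one end-to-end run."""

    spike_csv: str
    trigger_csv: str | None = None
    out_dir: str = "burstclust_out"
    duration: float | None = None
    detector: DetectorParams = field(default_factory=DetectorParams)
    metric: MetricParams = field(default_factory=MetricParams)
    association_window: float = 0.050
    damping: float = 0.5
    p_mult: float = 1.0
    noise_scale: float | None = None
    iters: int = 200
    seed: int = 0
    compute_entropy: bool = True
    match_spike_csv: str | None = None  # optional second session to match against

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = DetectorParams(**d["detector"])
        if "metric" in d and isinstance(d["metric"], dict):
            d["metric"] = MetricParams(**d["metric"])
        return cls(**d)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as err:
            raise PipelineError(f"stage '{name}' failed: {err}") from err
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
        return out
    return wrap


def _analyse_session(train: SpikeTrain, triggers, cfg: PipelineConfig):
    bursts = _stage("detect")(detect_bursts, train, cfg.detector)
    log.info("detected %d bursts", len(bursts))
    if triggers is not None:
        bursts = _stage("associate")(
            associate_stimuli, bursts, triggers, cfg.association_window
        )
    if not bursts:
        raise PipelineError("stage 'detect' failed: no bursts detected")
    D = _stage("distances")(distance_matrix, bursts, None, cfg.metric)
    ap = BurstAffinityPropagation(
        damping=cfg.damping, max_iter=cfg.iters, p_mult=cfg.p_mult,
        noise_scale=cfg.noise_scale, random_state=cfg.seed,
    )
    _stage("cluster")(ap.fit, D.values)
    clustering = ap.to_clustering()
    log.info("found %d clusters", clustering.n_clusters)
    ex = clustering.exemplars
    dend = _stage("dendrogram")(
        build_dendrogram, ex.tolist(), D.values[np.ix_(ex, ex)]
    )
    return bursts, D, clustering, dend


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write artifacts plus a manifest to ``out_dir``."""
    outdir = Path(cfg.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    train = _stage("read")(bio.read_spike_csv, cfg.spike_csv, cfg.duration)
    triggers = None
    if cfg.trigger_csv is not None:
        triggers = _stage("read")(bio.read_trigger_csv, cfg.trigger_csv)

    bursts, D, clustering, dend = _analyse_session(train, triggers, cfg)

    artifacts: dict = {}
    bio.write_bursts_csv(outdir / "bursts.csv", bursts)
    artifacts["bursts"] = "bursts.csv"
    D.to_frame().to_csv(outdir / "distances.csv", float_format="%.17g")
    artifacts["distances"] = "distances.csv"

    clustering_out = {
        "exemplars": clustering.exemplars.tolist(),
        "assignment": clustering.assignment.tolist(),
        "labels": clustering.labels.tolist(),
        "n_iter": clustering.n_iter,
        "damping": cfg.damping,
        "p_mult": cfg.p_mult,
        "noise_scale": cfg.noise_scale,
        "seed": cfg.seed,
        "dendrogram_newick": dend.to_newick(),
    }
    (outdir / "clustering.json").write_text(json.dumps(clustering_out, indent=1))
    artifacts["clustering"] = "clustering.json"

    results: dict = {"n_bursts": len(bursts),
                     "n_clusters": int(clustering.n_clusters)}
    if triggers is not None:
        burst_labels = [b.label for b in bursts]
        labeling = _stage("label")(label_clusters, clustering, burst_labels)
        labeling.frame().to_csv(outdir / "cluster_labels.csv", index=False)
        artifacts["cluster_labels"] = "cluster_labels.csv"
        if cfg.compute_entropy:
            ent = {}
            for c in sorted({lab for lab in burst_labels if lab != "N"}):
                ent[c] = _stage("entropy")(
                    conditional_entropy, c, clustering, burst_labels
                )
            results["conditional_entropy_bits"] = ent
        if clustering.n_clusters >= 2:
            sil = silhouette_values(D.values, clustering.labels)
            results["mean_silhouette"] = float(np.mean(sil))

    if cfg.match_spike_csv is not None:
        other = _stage("read")(bio.read_spike_csv, cfg.match_spike_csv)
        bursts_b, D_b, clustering_b, _ = _analyse_session(other, None, cfg)
        matches = _stage("match")(
            match_clusters, clustering, bursts, clustering_b, bursts_b, cfg.metric
        )
        match_rows = []
        for m in matches:
            mem_a = [bursts[i] for i in clustering.members(m.source_cluster)]
            mem_b = [bursts_b[i] for i in clustering_b.members(m.target_cluster)]
            mean, sd = _stage("baseline")(
                poisson_baseline, mem_a, mem_b, cfg.metric, 20, cfg.seed
            )
            match_rows.append({
                "source_cluster": m.source_cluster,
                "target_cluster": m.target_cluster,
                "distance": m.distance,
                "baseline_mean": mean,
                "baseline_sd": sd,
            })
        import pandas as pd

        pd.DataFrame(match_rows).to_csv(outdir / "matches.csv", index=False)
        artifacts["matches"] = "matches.csv"

    manifest = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items()
               if not isinstance(v, dict)},
            "detector": dataclasses.asdict(cfg.detector),
            "metric": dataclasses.asdict(cfg.metric),
        },
        "artifacts": artifacts,
        "results": results,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return manifest
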