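"""End-to-end orchestration: characterization and classification runs.

``run_characterization`` executes simulate -> preprocess -> features ->
cortical mapping -> repetition intersection in fixed order and emits the
behavioural score set plus the S, R and K activation maps.
``run_classification`` executes the session-split classification
protocol and emits the accuracy surface and windowed metrics.  Both
write a manifest (config hash, seeds, library versions, per-stage
counts) sufficient to reproduce every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from .behavior import aggregate_scores, score_log
from .classify import build_feature_matrix, run_comparison, window_means
from .mapping import (
    aggregate_to_ba,
    common_activation,
    source_band_power,
    test_activation,
    zscore_ba_to_ref,
)
from .preprocess import (
    FilterSpec,
    bandpass_filter,
    epoch_signal,
    regress_eog,
    reject_artifacts,
    select_channels,
)
from .simulate import CONDITIONS, SimulationConfig, simulate_session
from .spectral import band_power, compute_psd, define_bands, estimate_iaf, zscore_to_ref

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_subjects: int = 1
    effect_map: dict[str, float] = {}       # "cond|BA|band" -> z
    effect_space: str = "ba"                # "ba" | "channel" calibration space
    state_map: dict[str, float] = {}        # "cond|band" -> z (global shift)
    iaf_true: float = 10.0
    noise_level: float = 1.0
    blink_rate: float = 2.0
    gross_artifact_rate: float = 0.0
    segment_duration: float = 60.0
    eog_regression: bool = False
    filter_order: int = 5
    filter_band: tuple[float, float] = (2.0, 45.0)
    artifact_threshold: float = 80.0
    pca_variance: float = 0.90
    alpha: float = 0.05
    families: tuple[str, ...] = ("KNN",)
    windows: tuple[int, int] = (1, 35)
    out_dir: str | None = None

    def simulation_config(self, subject: int = 0) -> SimulationConfig:
        effect = {tuple(k.split("|")): v for k, v in self.effect_map.items()}
        cfg = SimulationConfig(
            seed=self.seed + 1000 * subject,
            iaf_true=self.iaf_true,
            noise_level=self.noise_level,
            blink_rate=self.blink_rate,
            gross_artifact_rate=self.gross_artifact_rate,
            effect_map=effect,
            effect_space=self.effect_space,
            state_map={tuple(k.split("|")): v
                       for k, v in self.state_map.items()},
        )
        for k in cfg.durations:
            cfg.durations[k] = self.segment_duration
        return cfg


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _manifest(cfg: RunConfig, stage_counts: dict) -> dict:
    import pandas
    import scipy
    import sklearn

    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return {
        "config": cfg.model_dump(),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "versions": {
            "srk": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "pandas": pandas.__version__,
        },
        "stage_counts": stage_counts,
    }


def preprocess_segment(rec, cfg: RunConfig):
    """filter -> (optional EOG regression) -> epoch -> artifact rejection."""
    spec = FilterSpec(order=cfg.filter_order, band=cfg.filter_band)
    rec = bandpass_filter(rec, spec)
    if cfg.eog_regression:
        rec = regress_eog(rec)
    ep = epoch_signal(rec)
    return reject_artifacts(ep, cfg.artifact_threshold)


def characterize_session(session, cfg: RunConfig):
    """Cortical characterization of one session: S, R, K activation maps.

    Returns ``(maps, per_condition_maps, iaf)`` where ``maps`` holds the
    repetition-intersected matrices for levels S, R and K.
    """
    epochs = {}
    for segment in ("rest", "REF") + CONDITIONS:
        if segment not in session.recordings:
            raise StageError(f"z-scoring stage: segment {segment!r} missing")
        epochs[segment] = preprocess_segment(session.recordings[segment], cfg)

    iaf = estimate_iaf(epochs["rest"])
    scheme = define_bands(iaf)

    sub = {seg: select_channels(ep) for seg, ep in epochs.items() if seg != "rest"}
    leadfield = session.leadfield.subset(sub["REF"].channel_labels)

    ba_power = {}
    for seg, ep in sub.items():
        sp = source_band_power(ep, leadfield, scheme)
        ba_power[seg] = aggregate_to_ba(sp, session.atlas)

    ref = ba_power["REF"]
    ref_z, _ = zscore_ba_to_ref(ref, ref)
    cond_maps = {}
    for cond in CONDITIONS:
        z, _ = zscore_ba_to_ref(ba_power[cond], ref)
        # two-sample condition-vs-REF contrast: the REF normalization's own
        # sampling error is shared by every condition epoch, so the one-sample
        # test of z against 0 would be anticonservative
        cond_maps[cond] = test_activation(
            z, session.atlas.labels, scheme.analysis_bands,
            condition=cond, alpha=cfg.alpha, ref_ba_z=ref_z,
        )
    maps = {
        level: common_activation(cond_maps[f"{level}1"], cond_maps[f"{level}2"])
        for level in ("S", "R", "K")
    }
    return maps, cond_maps, iaf


def score_session_behavior(session):
    """ScoreSet (condition + level accuracies and completion times)."""
    scores = {c: score_log(log) for c, log in session.logs.items()}
    times = {c: log.completion_time for c, log in session.logs.items()}
    return aggregate_scores(scores, times)


def run_characterization(cfg: RunConfig):
    """Simulate subjects and produce behavioural scores + S/R/K maps."""
    results = {"subjects": [], "manifest": None}
    for s in range(cfg.n_subjects):
        sim_cfg = cfg.simulation_config(s)
        try:
            session = simulate_session(sim_cfg)
        except Exception as e:  # pragma: no cover - defensive
            raise StageError(f"simulate stage: {e}") from e
        scores = score_session_behavior(session)
        maps, cond_maps, iaf = characterize_session(session, cfg)
        results["subjects"].append({
            "subject": s, "iaf": iaf, "scores": scores,
            "maps": maps, "condition_maps": cond_maps, "session": session,
        })
    counts = {"n_subjects": cfg.n_subjects,
              "n_significant_K": [r["maps"]["K"].n_significant()
                                  for r in results["subjects"]]}
    results["manifest"] = _manifest(cfg, counts)
    if cfg.out_dir:
        _write_characterization(results, cfg)
    return results


def classification_features(session, cfg: RunConfig):
    """Per-session-pair feature matrices (all 61 channels, z-scored to REF)."""
    epochs = {seg: preprocess_segment(session.recordings[seg], cfg)
              for seg in ("rest", "REF") + CONDITIONS}
    iaf = estimate_iaf(epochs["rest"])
    scheme = define_bands(iaf)

    def features(seg):
        return band_power(compute_psd(_clean(epochs[seg])), scheme)

    ref_table = features("REF")
    tables = {}
    for cond in CONDITIONS:
        z, _ = zscore_to_ref(features(cond), ref_table)
        tables[cond] = z
    pair1 = build_feature_matrix({c: tables[c] for c in ("S1", "R1", "K1")})
    pair2 = build_feature_matrix({c: tables[c] for c in ("S2", "R2", "K2")})
    return pair1, pair2


def _clean(ep):
    """Epochs with artifact-flagged entries dropped (mask reset)."""
    from .preprocess import EpochedEEG

    return EpochedEEG(epochs=ep.clean(), fs=ep.fs,
                      channel_labels=ep.channel_labels, condition=ep.condition)


def run_classification(cfg: RunConfig):
    """Session-split classification protocol over all subjects and families."""
    subjects = {}
    for s in range(cfg.n_subjects):
        session = simulate_session(cfg.simulation_config(s))
        subjects[f"subject{s + 1}"] = classification_features(session, cfg)
    lo, hi = cfg.windows
    surface = run_comparison(subjects, families=cfg.families,
                             windows=range(lo, hi + 1),
                             pca_threshold=cfg.pca_variance, seed=cfg.seed)
    means = window_means(surface)
    manifest = _manifest(cfg, {"n_subjects": cfg.n_subjects,
                               "n_rows": int(len(surface))})
    results = {"surface": surface, "window_means": means, "manifest": manifest}
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        surface.to_csv(out / "accuracy_surface.csv", index=False)
        means.to_csv(out / "window_means.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


def _write_characterization(results, cfg: RunConfig):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in results["subjects"]:
        tag = f"subject{r['subject'] + 1}"
        for level, amap in r["maps"].items():
            amap.to_dataframe().to_csv(out / f"{tag}_map_{level}.csv", index=False)
        scores = r["scores"]
        (out / f"{tag}_scores.json").write_text(json.dumps({
            "condition_scores": scores.condition_scores,
            "condition_times": scores.condition_times,
            "level_scores": scores.level_scores,
            "level_times": scores.level_times,
            "iaf": r["iaf"],
        }, indent=1))
    (out / "manifest.json").write_text(
        json.dumps(results["manifest"], indent=1, default=str))
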