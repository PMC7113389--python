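"""End-to-end orchestration of the rereading analysis.

``run_full_pipeline`` chains the stages on one dataset — features,
word-level gaze measures, questionnaire statistics, the mixed-model
rereading test, repeated cross-validated predictive modeling, and
total-effect feature importance — and writes each stage's output plus a
machine-readable manifest (package version, seeds, config, content
hashes) to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import bowker_test, describe_sessions, paired_binary_table, paired_t
from .gaze import (MEASURE_COLUMNS, aggregate_measures, assign_fixations,
                   compute_word_measures, measures_long_table, skipping_rate)
from .models import (CVConfig, NNSpec, correlation_table, fit_neural_net,
                     fit_least_squares, importance_report, lmm_session_test,
                     repeated_kfold, total_effect_importance)
from .synthgen import GeneratorConfig, gen_dataset
from .textfeatures import PREDICTOR_COLUMNS, zscore
from . import io as rio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_full_pipeline", "prepare_modeling_table"]

RESPONSES = ["ffd", "gd", "rt", "trt", "fixation_probability"]


@dataclass
class PipelineConfig:
    """Paths, stage options and seeds for one full run.

    With ``simulate=True`` the input files are generated by the synthetic
    module instead of being read from disk.
    """

    out_dir: str = "regaze_out"
    simulate: bool = True
    features_path: str | None = None
    fixations_path: str | None = None
    interest_areas_path: str | None = None
    ratings_path: str | None = None
    slack_px: float = 11.0           # half the inter-line gap of the layout
    min_fix_ms: float = 0.0
    seed: int = 0
    cv: CVConfig = field(default_factory=lambda: CVConfig(reps=10))
    generator: GeneratorConfig | None = None
    responses: list[str] = field(default_factory=lambda: list(RESPONSES))
    importance_n_mc: int = 2000


def prepare_modeling_table(long_table: pd.DataFrame, session: str,
                           response: str) -> tuple[pd.DataFrame, np.ndarray]:
    """Standardized predictors X and response y for one session.

    Rows with a missing response (words nobody fixated) are dropped;
    predictors and response are z-scored within the session, as done
    before predictive modeling.
    """
    sub = long_table[long_table["session"] == session].dropna(subset=[response])
    if sub.empty:
        raise ValueError(f"no rows for session {session!r}")
    X = pd.DataFrame({c: zscore(sub[c]) for c in PREDICTOR_COLUMNS},
                     index=sub.index)
    y = zscore(sub[response])
    return X, y


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write outputs plus a manifest to ``cfg.out_dir``.

    Returns the result bundle in memory; on disk each stage leaves one
    artifact, listed (with SHA-256 content hashes) in ``manifest.json``.
    """
    out = rio.ensure_dir(cfg.out_dir)
    stage_outputs: dict[str, str] = {}

    # --- stage 0: inputs ---------------------------------------------------
    if cfg.simulate:
        gen_cfg = cfg.generator or GeneratorConfig(seed=cfg.seed)
        data = gen_dataset(gen_cfg)
        features = data["features"]
        fixations = data["fixations"]
        areas = data["interest_areas"]
        ratings = data["ratings"]
        rio.write_features(features, out / "features.csv")
        rio.write_fixation_report(fixations, out / "fixations.tsv")
        rio.write_interest_areas(areas, out / "interest_areas.tsv")
        rio.write_ratings(ratings, out / "ratings.csv")
        data["truth_features"].to_json(out / "ground_truth.json")
        stage_outputs["inputs"] = "features.csv"
    else:
        for name in ("features_path", "fixations_path",
                     "interest_areas_path", "ratings_path"):
            if getattr(cfg, name) is None:
                raise ValueError(f"cfg.{name} is required when simulate=False")
        features = rio.read_features(cfg.features_path)
        fixations = rio.read_fixation_report(cfg.fixations_path)
        areas = rio.read_interest_areas(cfg.interest_areas_path)
        ratings = rio.read_ratings(cfg.ratings_path)

    # --- stage 1: gaze measures -------------------------------------------
    if cfg.min_fix_ms > 0:
        fixations = [f for f in fixations if f.duration >= cfg.min_fix_ms]
    assigned = assign_fixations(fixations, areas, slack_px=cfg.slack_px)
    all_keys = [(str(r.sonnet_id), int(r.line_no), int(r.word_no))
                for r in features.itertuples()]
    by_trial: dict[tuple[str, str], list] = {}
    for fix, key in assigned:
        by_trial.setdefault((fix.participant_id, fix.session), []).append((fix, key))
    word_measures = []
    for (pid, ses), seq in sorted(by_trial.items()):
        word_measures.extend(compute_word_measures(seq, all_keys))
    aggregated = aggregate_measures(word_measures)
    long_table = measures_long_table(aggregated, features)
    long_table.to_csv(out / "measures_long.csv", index=False)
    stage_outputs["measures"] = "measures_long.csv"

    # --- stage 2: questionnaire -------------------------------------------
    behavior_results = {"descriptives": describe_sessions(ratings).to_dict("records")}
    wide = ratings.pivot_table(index=["participant_id", "sonnet_id"],
                               columns="session",
                               values=["willingness", "appreciation",
                                       "topic_correct"], aggfunc="first")
    for q in ("willingness", "appreciation"):
        res = paired_t(wide[(q, "first")], wide[(q, "last")])
        behavior_results[q] = res.to_dict()
    table = paired_binary_table(wide[("topic_correct", "first")].astype(bool),
                                wide[("topic_correct", "last")].astype(bool))
    behavior_results["topic"] = bowker_test(table).to_dict()
    behavior_results["topic_table"] = table.tolist()
    (out / "behavior.json").write_text(json.dumps(behavior_results, indent=2))
    stage_outputs["behavior"] = "behavior.json"

    # --- stage 3: rereading LMM -------------------------------------------
    lmm_results = {}
    for resp in cfg.responses:
        try:
            lmm_results[resp] = lmm_session_test(long_table, resp).to_dict()
        except (RuntimeError, ValueError) as exc:
            raise RuntimeError(f"stage lmm[{resp}] failed: {exc}") from exc
    lmm_results["skipping_rate"] = skipping_rate(word_measures)
    (out / "lmm.json").write_text(json.dumps(lmm_results, indent=2))
    stage_outputs["rereading_test"] = "lmm.json"

    # --- stage 4: correlation tables --------------------------------------
    corr = {}
    for ses in ("first", "last"):
        sub = long_table[long_table["session"] == ses]
        corr[ses] = correlation_table(sub[MEASURE_COLUMNS]).round(4).to_dict()
    (out / "correlations.json").write_text(json.dumps(corr, indent=2))
    stage_outputs["correlations"] = "correlations.json"

    # --- stage 5: predictive modeling -------------------------------------
    fits = []
    for ses in ("first", "last"):
        for resp in cfg.responses:
            X, y = prepare_modeling_table(long_table, ses, resp)
            for family in ("neural_net", "least_squares"):
                fam_cfg = CVConfig(k=cfg.cv.k, reps=cfg.cv.reps,
                                   seed=cfg.cv.seed + cfg.seed, family=family,
                                   nn=cfg.cv.nn)
                summary = repeated_kfold(X.to_numpy(), y, fam_cfg)
                fits.append({"session": ses, "response": resp,
                             **summary.to_dict()})
    (out / "fits.json").write_text(json.dumps(fits, indent=2))
    stage_outputs["predict"] = "fits.json"

    # --- stage 6: feature importance --------------------------------------
    fi_frames = []
    for ses in ("first", "last"):
        for resp in cfg.responses:
            X, y = prepare_modeling_table(long_table, ses, resp)
            net = fit_neural_net(X.to_numpy(), y,
                                 NNSpec(seed=cfg.seed,
                                        hidden_units=cfg.cv.nn.hidden_units,
                                        weight_decay=cfg.cv.nn.weight_decay,
                                        restarts=cfg.cv.nn.restarts))
            imp = total_effect_importance(net, X, n_mc=cfg.importance_n_mc,
                                          seed=cfg.seed)
            rep = importance_report(imp)
            rep.insert(0, "response", resp)
            rep.insert(0, "session", ses)
            fi_frames.append(rep)
    fi_table = pd.concat(fi_frames, ignore_index=True)
    fi_table.to_csv(out / "importance.csv", index=False)
    stage_outputs["importance"] = "importance.csv"

    # --- manifest ----------------------------------------------------------
    manifest = {
        "package": "regaze",
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": json.loads(json.dumps(asdict(cfg), default=_json_default)),
        "stages": stage_outputs,
        "hashes": {name: _sha256(out / fname)
                   for name, fname in stage_outputs.items()
                   if (out / fname).exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "features": features,
        "long_table": long_table,
        "behavior": behavior_results,
        "lmm": lmm_results,
        "correlations": corr,
        "fits": fits,
        "importance": fi_table,
        "manifest": manifest,
    }


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
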