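"""End-to-end orchestration: config, stage execution, artifacts, report.

A run executes simulate -> extract -> label -> train -> rank -> ablate,
writing one artifact per stage plus a JSON report.  A single master seed
is fanned out to every random consumer through the documented derivation
in :mod:`eegfatigue._seeds`; timestamps never enter result files, so two
runs of the same config produce byte-identical reports.

Stages can be executed selectively; a stage whose prerequisites were not
run in-process loads them from the output directory (or, for the cheap
simulation stage, regenerates them deterministically from the config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from eegfatigue._seeds import child_seed
from eegfatigue.constants import CHANNELS
from eegfatigue.errors import ConfigurationError, EEGFatigueError
from eegfatigue.evaluation import (
    DEFAULT_WEIGHT,
    ablate_feature_groups,
    evaluate_all_combos,
    rank_combos,
    ranking_table,
    stratify_by_task,
)
from eegfatigue.features import FeatureParams, extract_feature_table
from eegfatigue.labelling import LabelPolicy, build_modelling_table, derive_policy
from eegfatigue.modelling import (
    DEFAULT_GRIDS,
    grid_search_loso,
    select_base_classifier,
)
from eegfatigue.synthetic import SessionPlan, default_plans, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "label", "train", "rank", "ablate")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    # cohort
    n_subjects: int = 12
    master_seed: int = 0
    s3_duration_s: int = 540
    event_durations: dict | None = None        # desk-scale override
    informative_channels: tuple = CHANNELS
    uninformative_gain: float = 0.1
    gain_physical_range: tuple = (0.8, 1.6)
    gain_mental_range: tuple = (0.8, 1.6)
    noise_scale: float = 0.3
    oscillation_mode: str = "narrowband"
    complementary: bool = False
    gain_bimodal: bool = False
    write_recordings: bool = False
    # features
    feature_params: FeatureParams = field(default_factory=FeatureParams)
    average: str = "features"
    # labelling: "derive" or {"physical": .., "mental": ..}
    label_policy: str | dict = "derive"
    # modelling
    grids: dict | None = None                  # None -> full default grids
    frozen_model: dict | None = None           # {"family": .., "params": ..} skips training
    objective: str = "score"
    k_neighbors: int = 5
    # evaluation
    w: float = DEFAULT_WEIGHT
    ablation_combo: tuple | None = None        # None -> top-ranked combo

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        if isinstance(raw.get("feature_params"), dict):
            raw["feature_params"] = FeatureParams(**raw["feature_params"])
        for key in ("informative_channels", "ablation_combo",
                    "gain_physical_range", "gain_mental_range"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["feature_params"] = self.feature_params.to_metadata()
        return out

    def plans(self) -> list[SessionPlan]:
        return default_plans(
            s3_duration_s=self.s3_duration_s, event_durations=self.event_durations
        )


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)


class PipelineRun:
    """Stage executor over one output directory."""

    def __init__(self, config: RunConfig, outdir) -> None:
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.cohort = None
        self.feature_table: pd.DataFrame | None = None
        self.modelling_table: pd.DataFrame | None = None
        self.policy: LabelPolicy | None = None
        self.selected: dict | None = None
        self.ranked = None
        self.ablation: pd.DataFrame | None = None

    # -- stage: simulate ---------------------------------------------------
    def simulate(self) -> None:
        cfg = self.config
        self.cohort = generate_cohort(
            n_subjects=cfg.n_subjects,
            plans=cfg.plans(),
            master_seed=cfg.master_seed,
            informative_channels=cfg.informative_channels,
            uninformative_gain=cfg.uninformative_gain,
            gain_physical_range=cfg.gain_physical_range,
            gain_mental_range=cfg.gain_mental_range,
            noise_scale=cfg.noise_scale,
            oscillation_mode=cfg.oscillation_mode,
            complementary=cfg.complementary,
            gain_bimodal=cfg.gain_bimodal,
        )
        _write_json(self.cohort.manifest, self.outdir / "manifest.json")
        self.cohort.scores.to_csv(self.outdir / "scores.csv", index=False)
        if cfg.write_recordings:
            write_cohort(self.cohort, self.outdir / "recordings")

    def _require_cohort(self):
        if self.cohort is None:
            logger.info("regenerating cohort deterministically from config")
            self.simulate()
        return self.cohort

    # -- stage: extract ----------------------------------------------------
    def extract(self) -> None:
        cohort = self._require_cohort()
        self.feature_table = extract_feature_table(
            cohort.iter_recordings(),
            params=self.config.feature_params,
            average=self.config.average,
        )
        self.feature_table.to_csv(self.outdir / "feature_table.csv", index=False)
        _write_json(
            self.config.feature_params.to_metadata(),
            self.outdir / "feature_params.json",
        )

    def _require_features(self) -> pd.DataFrame:
        if self.feature_table is None:
            path = self.outdir / "feature_table.csv"
            if path.exists():
                self.feature_table = pd.read_csv(path)
            else:
                self.extract()
        return self.feature_table

    # -- stage: label ------------------------------------------------------
    def label(self) -> None:
        cfg = self.config
        features = self._require_features()
        scores_path = self.outdir / "scores.csv"
        if scores_path.exists():
            scores = pd.read_csv(scores_path)
        else:
            scores = self._require_cohort().scores
        if cfg.label_policy == "derive":
            self.policy = derive_policy(scores)
        elif isinstance(cfg.label_policy, dict):
            self.policy = LabelPolicy(
                physical_threshold=float(cfg.label_policy["physical"]),
                mental_threshold=float(cfg.label_policy["mental"]),
            )
        else:
            raise ConfigurationError(
                f"label_policy must be 'derive' or a mapping, got {cfg.label_policy!r}"
            )
        self.modelling_table = build_modelling_table(features, scores, self.policy)
        self.modelling_table.to_csv(self.outdir / "modelling_table.csv", index=False)
        _write_json(self.policy.to_metadata(), self.outdir / "label_policy.json")

    def _require_table(self) -> pd.DataFrame:
        if self.modelling_table is None:
            path = self.outdir / "modelling_table.csv"
            if path.exists():
                self.modelling_table = pd.read_csv(path)
            else:
                self.label()
        return self.modelling_table

    # -- stage: train ------------------------------------------------------
    def train(self) -> None:
        cfg = self.config
        if cfg.frozen_model is not None:
            self.selected = dict(cfg.frozen_model)
            self.selected.setdefault("source", "frozen by config")
            _write_json(self.selected, self.outdir / "selected_model.json")
            return
        table = self._require_table()
        from eegfatigue.constants import feature_columns

        cols = feature_columns(CHANNELS)
        grids = cfg.grids or DEFAULT_GRIDS
        results = {}
        frames = []
        for family, grid in grids.items():
            res = grid_search_loso(
                family, grid, table, cols,
                w=cfg.w, objective=cfg.objective,
                seed=child_seed(cfg.master_seed, "gridsearch", family),
                k_neighbors=cfg.k_neighbors,
            )
            results[family] = res
            frames.append(res.candidates)
        family, params = select_base_classifier(results)
        pd.concat(frames, ignore_index=True).to_csv(
            self.outdir / "selection_candidates.csv", index=False
        )
        self.selected = {
            "family": family,
            "params": params,
            "summary": {
                f: r.best_metrics | {"params": r.best_params}
                for f, r in results.items()
            },
            "source": "grid search",
        }
        _write_json(self.selected, self.outdir / "selected_model.json")

    def _require_model(self) -> dict:
        if self.selected is None:
            path = self.outdir / "selected_model.json"
            if path.exists():
                with open(path) as fh:
                    self.selected = json.load(fh)
            else:
                self.train()
        return self.selected

    # -- stage: rank -------------------------------------------------------
    def rank(self) -> None:
        cfg = self.config
        table = self._require_table()
        model = self._require_model()
        results = evaluate_all_combos(
            table, model["family"], model["params"],
            w=cfg.w, seed=child_seed(cfg.master_seed, "rank"),
            k_neighbors=cfg.k_neighbors,
        )
        self.ranked = rank_combos(results)
        ranking_table(self.ranked).to_csv(self.outdir / "combo_metrics.csv", index=False)
        top = self.ranked[0]
        strata = stratify_by_task(top.predictions)
        _write_json(
            {
                "top_channels": list(top.channels),
                "confusion": {k: v.to_dict() for k, v in strata.items()},
            },
            self.outdir / "confusion.json",
        )

    # -- stage: ablate -----------------------------------------------------
    def ablate(self) -> None:
        cfg = self.config
        table = self._require_table()
        model = self._require_model()
        if cfg.ablation_combo is not None:
            combo = cfg.ablation_combo
        else:
            if self.ranked is None:
                self.rank()
            combo = self.ranked[0].channels
        self.ablation = ablate_feature_groups(
            combo, table, model["family"], model["params"],
            w=cfg.w, seed=child_seed(cfg.master_seed, "ablate"),
            k_neighbors=cfg.k_neighbors,
        )
        self.ablation.insert(0, "channels", "+".join(combo))
        self.ablation.to_csv(self.outdir / "ablation.csv", index=False)

    # -- report ------------------------------------------------------------
    def report(self) -> dict:
        payload: dict = {"config": self.config.to_dict()}
        if self.policy is not None:
            payload["label_policy"] = self.policy.to_metadata()
        if self.modelling_table is not None:
            payload["n_modelling_rows"] = int(len(self.modelling_table))
            payload["n_positive"] = int(self.modelling_table["label"].sum())
        if self.selected is not None:
            payload["selected_model"] = {
                k: v for k, v in self.selected.items() if k != "summary"
            }
        if self.ranked is not None:
            payload["ranking"] = ranking_table(self.ranked).to_dict(orient="records")
        if self.ablation is not None:
            payload["ablation"] = self.ablation.to_dict(orient="records")
        _write_json(payload, self.outdir / "report.json")
        return payload


def run_pipeline(config: RunConfig, outdir, stages=STAGES) -> dict:
    """Execute the requested stages in order and write the run report."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigurationError(f"unknown stage(s) {bad}; valid: {STAGES}")
    run = PipelineRun(config, outdir)
    for stage in STAGES:
        if stage in stages:
            logger.info("stage: %s", stage)
            try:
                getattr(run, stage)()
            except EEGFatigueError as exc:
                raise EEGFatigueError(f"stage {stage!r} failed: {exc}") from exc
    return run.report()
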