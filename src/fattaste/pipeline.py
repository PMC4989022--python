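"""End-to-end study pipeline driven by a YAML configuration.

``run_pipeline`` simulates (or loads) a detection-threshold cohort, runs
staircases, estimates and groups thresholds, analyses an optional 2-AFC
panel and rating table, and writes every output plus a run manifest
(seed, configuration hash, package version, rule choices) to the output
directory.  Reruns with the same configuration and seed are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .concentrations import OLEIC_ACID_MOLAR_MASS, DilutionSeries, build_series
from .staircase import StaircaseConfig
from .synthetic import CohortSpec, RatingEffects, simulate_2afc_panel, simulate_ratings, simulate_threshold_study
from .thresholds import assign_groups, threshold_from_log
from .discrimination import analyze_panel
from .ratings import cell_summary
from . import io as ftio

__all__ = ["StudyConfig", "run_pipeline"]


@dataclass(frozen=True)
class StudyConfig:
    """Validated pipeline configuration (see ``StudyConfig.from_yaml``)."""

    series: DilutionSeries
    staircase: StaircaseConfig
    seed: int
    out_dir: Path
    rule: str = "tail"
    alpha: float = 0.05
    panel_alpha: float = 0.05
    n_observers: int = 51
    sigma: float = 0.25
    lapse: float = 0.01
    panel_dprimes: dict = field(default_factory=dict)
    n_assessors: int = 51
    ratings: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        try:
            s = raw["series"]
            series = build_series(
                float(s["bottom"]),
                n_levels=int(s["n_levels"]),
                log_step=float(s.get("log_step", 0.25)),
                molar_mass=float(s.get("molar_mass", OLEIC_ACID_MOLAR_MASS)),
                bottom_unit=s.get("bottom_unit", "pct_wv"),
            )
        except KeyError as exc:
            raise ValueError(f"{path}: missing series definition key {exc}") from exc
        stair = StaircaseConfig(**raw.get("staircase", {}))
        cls_cfg = raw.get("classification", {})
        cohort = raw.get("cohort", {})
        panel = raw.get("panel", {})
        return cls(
            series=series,
            staircase=stair,
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "fattaste_out")),
            rule=cls_cfg.get("rule", "tail"),
            alpha=float(cls_cfg.get("alpha", 0.05)),
            panel_alpha=float(panel.get("alpha", 0.05)),
            n_observers=int(cohort.get("n_observers", 51)),
            sigma=float(cohort.get("sigma", 0.25)),
            lapse=float(cohort.get("lapse", 0.01)),
            panel_dprimes={str(k): float(v) for k, v in panel.get("dprimes", {}).items()},
            n_assessors=int(panel.get("n_assessors", 51)),
            ratings=raw.get("ratings", {}),
            raw=raw,
        )


def run_pipeline(config: StudyConfig) -> dict[str, Path]:
    """Execute simulate -> threshold estimate -> group -> discriminate -> rate.

    Returns a mapping of artefact names to written paths.  Stage failures
    propagate with the stage name; outputs written so far are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rng = np.random.default_rng(config.seed)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    # ladder
    paths["series"] = out / "series.csv"
    stage("series", lambda: ftio.write_series(config.series, paths["series"]))

    # simulate + estimate + group
    spec = CohortSpec(
        n_observers=config.n_observers,
        series=config.series,
        sigma=config.sigma,
        lapse=config.lapse,
    )
    logs, truth = stage(
        "simulate", lambda: simulate_threshold_study(spec, config.staircase, rng)
    )
    paths["trial_logs"] = out / "trial_logs.csv"
    ftio.write_trial_logs(logs, paths["trial_logs"])
    paths["truth"] = out / "observer_truth.csv"
    truth.to_csv(paths["truth"], index=False)

    results = stage(
        "threshold",
        lambda: [
            threshold_from_log(log, config.series, rule=config.rule, alpha=config.alpha)
            for log in logs
        ],
    )
    grouping = stage("group", lambda: assign_groups(results, config.series))
    paths["thresholds"] = out / "thresholds.csv"
    ftio.write_threshold_report(results, config.series, paths["thresholds"], grouping.labels)

    # optional 2-AFC panel
    if config.panel_dprimes:
        pairs = stage(
            "panel_simulate",
            lambda: simulate_2afc_panel(config.panel_dprimes, config.n_assessors, rng),
        )
        paths["panel"] = out / "panel.csv"
        ftio.write_panel(pairs, paths["panel"])
        table = stage("discriminate", lambda: analyze_panel(pairs, alpha=config.panel_alpha))
        paths["panel_stats"] = out / "panel_stats.csv"
        table.to_csv(paths["panel_stats"], index=False)

    # optional ratings
    if config.ratings:
        r = config.ratings
        effects = RatingEffects(**r.get("effects", {}))
        records, _ = stage(
            "ratings_simulate",
            lambda: simulate_ratings(
                int(r.get("n_participants", config.n_observers)),
                fat_levels=tuple(r.get("fat_levels", (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0))),
                modalities=tuple(r.get("modalities", ("taste", "overall"))),
                effects=effects,
                rng=rng,
            ),
        )
        paths["ratings"] = out / "ratings.csv"
        ftio.write_ratings(records, paths["ratings"])
        paths["rating_summary"] = out / "rating_summary.csv"
        cell_summary(records).to_csv(paths["rating_summary"], index=False)

    # manifest
    cfg_text = yaml.safe_dump(config.raw, sort_keys=True)
    manifest = {
        "package": "fattaste",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "classification_rule": config.rule,
        "alpha": config.alpha,
        "staircase": dataclasses.asdict(config.staircase),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
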