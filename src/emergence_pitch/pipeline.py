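"""End-to-end pipeline: simulate or load -> preprocess -> features -> Psi ->
event-locked and match-level analyses, driven by a single config.

The pipeline is a pure function of (config, seed): a single global seed
fans out to per-stage seeds through stable hashing of stage names, so
re-running an identical config reproduces every stochastic stage
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .emergence import EmergenceConfig, PsiSeries, concat_psi, sliding_window_psi
from .event_locked import align_shots, timepoint_significance, trend_regression
from .features import compute_feature_series
from .match_level import correlate_differences, half_summaries, paired_differences
from .synthetic import SyntheticParams, generate_match, season_params
from .tracking import (
    EventLog,
    MatchTracking,
    TEAMS,
    differentiate_positions,
    load_events,
    load_tracking,
    segment_halves,
    write_events,
    write_tracking,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31 from the global seed and stage name."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    mode: str = "synthetic"  # 'synthetic' or 'files'
    n_matches: int = 2
    synthetic: SyntheticParams = dataclasses.field(default_factory=SyntheticParams)
    possession_spread: float = 0.01
    tracking_paths: list[str] = dataclasses.field(default_factory=list)
    event_paths: list[str] = dataclasses.field(default_factory=list)
    features: list[str] = dataclasses.field(default_factory=lambda: ["com"])
    emergence: EmergenceConfig = dataclasses.field(default_factory=EmergenceConfig)
    duration_s: int = 60
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "pipeline_out"

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("synthetic", "files"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if not self.features:
            raise PipelineError("feature list must be non-empty")
        if self.mode == "files":
            if len(self.tracking_paths) != len(self.event_paths) or not self.tracking_paths:
                raise PipelineError("files mode needs matching tracking/event path lists")
            for p in [*self.tracking_paths, *self.event_paths]:
                if not Path(p).exists():
                    raise PipelineError(f"input path does not exist: {p}")
        return self

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        synth = SyntheticParams(**raw.pop("synthetic", {}))
        emrg = EmergenceConfig(**raw.pop("emergence", {}))
        return cls(synthetic=synth, emergence=emrg, **raw).validate()


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return enc(config)


def compute_match_psi(
    tracking: MatchTracking,
    events: EventLog,
    features: list[str],
    emergence_cfg: EmergenceConfig,
    *,
    reldist_variant: str = "com_to_center",
) -> dict[str, dict[str, PsiSeries]]:
    """Per-feature, per-team concatenated Psi series for one match.

    Preprocessing: segment into halves, finite-difference velocities within
    each half, then compute each feature's macro/micro series and its
    sliding-window Psi per half.
    """
    halves = [differentiate_positions(h) for h in segment_halves(tracking, events)]
    out: dict[str, dict[str, PsiSeries]] = {}
    for feature in features:
        out[feature] = {}
        for team in TEAMS:
            per_half = [
                sliding_window_psi(
                    compute_feature_series(h, team, feature, variant=reldist_variant),
                    emergence_cfg,
                )
                for h in halves
            ]
            out[feature][team] = concat_psi(per_half)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write artifacts under ``config.out_dir``, return the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": _config_echo(config),
        "seed": config.seed,
        "stage_seeds": {},
        "artifacts": [],
        "row_counts": {},
    }

    def record(path: Path, n_rows: int | None = None) -> None:
        manifest["artifacts"].append(str(path.relative_to(out_dir)))
        if n_rows is not None:
            manifest["row_counts"][str(path.relative_to(out_dir))] = n_rows

    # --- stage: inputs ------------------------------------------------------
    matches: list[tuple[MatchTracking, EventLog]] = []
    if config.mode == "synthetic":
        sim_seed = derive_seed(config.seed, "simulate")
        manifest["stage_seeds"]["simulate"] = sim_seed
        params = season_params(
            config.synthetic, config.n_matches, sim_seed, config.possession_spread
        )
        for i, p in enumerate(params):
            tracking, events = generate_match(p, seed=derive_seed(sim_seed, f"match:{i}"))
            t_path = out_dir / f"tracking_{i:03d}.csv"
            e_path = out_dir / f"events_{i:03d}.csv"
            p_path = out_dir / f"possession_{i:03d}.csv"
            write_tracking(tracking, t_path)
            write_events(events, e_path, p_path)
            record(t_path, tracking.n_frames * 2 * tracking.n_players)
            record(e_path, len(events.events))
            record(p_path)
            matches.append((tracking, events))
    else:
        for t_path, e_path in zip(config.tracking_paths, config.event_paths):
            matches.append((load_tracking(t_path), load_events(e_path)))

    # --- stage: features + Psi ---------------------------------------------
    psi_all: list[dict[str, dict[str, PsiSeries]]] = []
    for i, (tracking, events) in enumerate(matches):
        try:
            psi = compute_match_psi(tracking, events, config.features, config.emergence)
        except Exception as exc:  # noqa: BLE001 - stage-named abort
            raise PipelineError(f"stage 'emergence' failed on match {i}: {exc}") from exc
        psi_all.append(psi)
        for feature, by_team in psi.items():
            for team, series in by_team.items():
                path = out_dir / f"psi_{i:03d}_{team}_{feature}.csv"
                df = series.to_frame()
                df.to_csv(path, index=False)
                record(path, len(df))

    analyses: dict = {}
    for feature in config.features:
        # --- stage: event-locked analysis ----------------------------------
        ev_seed = derive_seed(config.seed, f"event:{feature}")
        manifest["stage_seeds"][f"event:{feature}"] = ev_seed
        curve_frames, trends_rows, masks = [], [], {}
        pooled = {"attacker": [], "defender": [], "baseline": []}
        for i, (tracking, events) in enumerate(matches):
            if events.shots().empty:
                continue
            try:
                curves = align_shots(
                    psi_all[i][feature], events, config.duration_s,
                    rng_seed=derive_seed(ev_seed, f"baseline:{i}"),
                )
            except Exception:  # no retainable shot in this match
                continue
            for g in pooled:
                pooled[g].append(curves.group(g))
        if pooled["attacker"]:
            groups = {g: np.concatenate(v, axis=0) for g, v in pooled.items()}
            rel_times = np.arange(-config.duration_s, 0, dtype=float)
            for g, arr in groups.items():
                curve_frames.append(
                    pd.DataFrame(
                        {
                            "relative_t": rel_times,
                            "group": g,
                            "mean": arr.mean(axis=0),
                            "sem": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]),
                        }
                    )
                )
                tr = trend_regression(arr.mean(axis=0), rel_times, label=g)
                trends_rows.append(
                    {
                        "feature": feature,
                        "group": g,
                        "slope": tr.slope,
                        "intercept": tr.intercept,
                        "r_squared": tr.r_squared,
                        "p_value": tr.p_value,
                        "n_events": arr.shape[0],
                    }
                )
            for a, b in (("attacker", "defender"), ("attacker", "baseline"), ("defender", "baseline")):
                if groups[a].shape[0] >= 2 and groups[b].shape[0] >= 2:
                    masks[f"{a}_vs_{b}"] = timepoint_significance(
                        groups[a], groups[b], config.alpha, config.duration_s
                    )
            curves_path = out_dir / f"curves_{feature}.csv"
            pd.concat(curve_frames, ignore_index=True).to_csv(curves_path, index=False)
            record(curves_path)
            trends_path = out_dir / f"trends_{feature}.csv"
            pd.DataFrame(trends_rows).to_csv(trends_path, index=False)
            record(trends_path, len(trends_rows))
            mask_path = out_dir / f"significance_{feature}.csv"
            mask_df = pd.DataFrame({"relative_t": rel_times, **masks})
            mask_df.to_csv(mask_path, index=False)
            record(mask_path)
            analyses[feature] = {"trends": trends_rows, "n_shots": int(groups["attacker"].shape[0])}

        # --- stage: match-level analysis ------------------------------------
        summaries = pd.concat(
            [half_summaries(i, psi_all[i][feature], ev) for i, (_, ev) in enumerate(matches)],
            ignore_index=True,
        )
        summary_path = out_dir / f"half_summaries_{feature}.csv"
        summaries.to_csv(summary_path, index=False)
        record(summary_path, len(summaries))
        pairs = paired_differences(summaries)
        corr: dict = {"feature": feature, "n_pairs": int(len(pairs))}
        if len(pairs) >= 3:
            r, p = correlate_differences(pairs)
            corr.update({"R": r, "p": p})
        corr_path = out_dir / f"correlation_{feature}.json"
        corr_path.write_text(json.dumps(corr, indent=2, sort_keys=True))
        record(corr_path)
        analyses.setdefault(feature, {})
        analyses[feature]["correlation"] = corr

    manifest["analyses"] = analyses
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
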