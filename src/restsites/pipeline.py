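"""End-to-end orchestration of the two-stage workflow.

Per deployment: validate -> truncate trailing failures -> apparent step
lengths -> fit HMM -> FFBS decode -> threshold assignment -> rest events ->
fit SSM -> simulation smoother -> credible ellipses -> diel summary ->
movement summaries.  Rest-location clustering and reuse detection pool the
95% ellipses of eligible events (>= 1 successful fix) across deployments.
Deployments are processed independently; a failure in one is recorded and
the rest continue.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .collar import (DeploymentSeries, apparent_step_lengths,
                     truncate_trailing_failures, write_observations)
from .diel import resting_by_category
from .hmm import (ActivityStepHMM, HmmPriors, extract_rest_events)
from .rest_sites import (cluster_rest_locations, clusters_to_frame,
                         detect_reuse, ellipses_to_geojson, rest_event_ellipse)
from .ssm import SwitchingSSM, movement_summaries

__all__ = ["PipelineConfig", "DeploymentResult", "run_pipeline", "summarize_run"]


@dataclass
class PipelineConfig:
    """Declarative settings for one pipeline run."""

    backend: str = "laplace"          # "laplace" or "emcee"
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    n_param_draws: int = 1000
    threshold: float = 0.95
    smoother_draws: int = 2000
    ellipse_levels: tuple = (0.5, 0.8, 0.95)
    min_event_duration_h: float = 1.0   # reporting filter for map export
    ref_lat: float = 42.4
    ref_lon: float = -122.3
    zone: str = "UTC"
    seed: int = 0
    hmm_priors: HmmPriors | None = None

    def __post_init__(self):
        if not 0.5 < self.threshold < 1:
            raise ValueError("threshold must lie in (0.5, 1)")
        if tuple(sorted(self.ellipse_levels)) != tuple(self.ellipse_levels):
            raise ValueError("ellipse levels must be sorted ascending")

    def config_hash(self) -> str:
        payload = {k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                   for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class DeploymentResult:
    deployment_id: str
    series: DeploymentSeries
    hmm_fit: object
    states: object
    events: list
    ssm_fit: object
    draws: object
    ellipses: dict              # level -> list[CredibleEllipse]
    diel: pd.DataFrame
    movement: dict
    seeds: dict


def _stage_seeds(seed: int, deployment_id: str) -> dict:
    """Per-stage seeds derived deterministically from the run seed."""
    base = int.from_bytes(
        hashlib.sha256(f"{seed}:{deployment_id}".encode()).digest()[:4], "big"
    )
    return {name: (base + k) % (2**31 - 1)
            for k, name in enumerate(["hmm", "decode", "ssm", "smooth"])}


def process_deployment(series: DeploymentSeries, config: PipelineConfig) -> DeploymentResult:
    seeds = _stage_seeds(config.seed, series.deployment_id)
    series = truncate_trailing_failures(series)
    obs = apparent_step_lengths(series)

    hmm = ActivityStepHMM(
        priors=config.hmm_priors, backend=config.backend,
        n_draws=config.n_param_draws, chains=config.chains,
        warmup=config.warmup, samples=config.samples,
        threshold=config.threshold, random_state=seeds["hmm"],
    ).fit(obs)
    if hmm.fit_.params is None:
        raise RuntimeError(f"HMM fit failed: {hmm.fit_.message}")
    states = hmm.decode(obs, seed=seeds["decode"])
    events = extract_rest_events(states, series)

    ssm = SwitchingSSM(
        backend=config.backend, n_draws=config.n_param_draws,
        chains=config.chains, warmup=config.warmup, samples=config.samples,
        random_state=seeds["ssm"],
    ).fit(series, states.s_star)
    draws = ssm.sample(n_draws=config.smoother_draws, seed=seeds["smooth"])

    ellipses = {
        level: [rest_event_ellipse(draws, ev, level) for ev in events]
        for level in config.ellipse_levels
    }
    diel = resting_by_category(
        states, series, (config.ref_lat, config.ref_lon), config.zone
    )
    movement = movement_summaries(draws, states.s_star, series.timestamps)
    return DeploymentResult(
        deployment_id=series.deployment_id, series=series, hmm_fit=hmm.fit_,
        states=states, events=events, ssm_fit=ssm.fit_, draws=draws,
        ellipses=ellipses, diel=diel, movement=movement, seeds=seeds,
    )


def run_pipeline(deployments, config: PipelineConfig | None = None,
                 output_dir=None) -> dict:
    """Run the two-stage workflow over a list of deployments.

    Returns a dict with per-deployment results, pooled rest-location
    clusters with reuse flags, per-deployment failures, and a run manifest.
    Writes the module CSV/GeoJSON artifacts when ``output_dir`` is given.
    """
    config = config or PipelineConfig()
    results: dict[str, DeploymentResult] = {}
    failures: dict[str, str] = {}
    for dep in deployments:
        try:
            results[dep.deployment_id] = process_deployment(dep, config)
        except Exception as exc:   # keep remaining deployments running
            failures[dep.deployment_id] = f"{type(exc).__name__}: {exc}"

    top = max(config.ellipse_levels)
    eligible = [
        e for r in results.values() for e in r.ellipses[top]
        if e.event.n_fixes >= 1
    ]
    clusters = detect_reuse(cluster_rest_locations(eligible))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_deployments": len(results),
        "failed": failures,
        "stage_seeds": {k: r.seeds for k, r in results.items()},
    }
    run = {"results": results, "clusters": clusters,
           "failures": failures, "manifest": manifest}
    if output_dir is not None:
        _write_artifacts(run, config, Path(output_dir))
    return run


def _write_artifacts(run, config, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for dep_id, r in run["results"].items():
        d = out / dep_id
        d.mkdir(exist_ok=True)
        obs = apparent_step_lengths(r.series)
        write_observations(r.series, obs, d / "observations.csv")
        r.hmm_fit.summary().to_csv(d / "hmm_summary.csv")
        r.hmm_fit.draws.to_csv(d / "hmm_draws.csv", index=False)
        r.ssm_fit.draws.to_csv(d / "ssm_draws.csv", index=False)
        pd.DataFrame({
            "timestamp": r.series.timestamps,
            "p_rest": r.states.p_rest,
            "s_star": r.states.s_star,
            "uncertain": r.states.uncertain,
        }).to_csv(d / "states.csv", index=False)
        pd.DataFrame([{
            "deployment_id": e.deployment_id, "animal_id": e.animal_id,
            "event_id": e.event_id, "start": e.start_time, "end": e.end_time,
            "duration_h": e.duration_h, "n_fixes": e.n_fixes,
        } for e in r.events]).to_csv(d / "rest_events.csv", index=False)
        r.ssm_fit.summary().to_csv(d / "ssm_summary.csv")
        mean, sd = r.draws.mean_path(), r.draws.sd_path()
        pd.DataFrame({
            "timestamp": r.series.timestamps,
            "easting_mean": mean[:, 0], "northing_mean": mean[:, 1],
            "easting_sd": sd[:, 0], "northing_sd": sd[:, 1],
            "n_draws": r.draws.n_draws,
        }).to_csv(d / "smoothed_path.csv", index=False)
        keep = [e for lv in config.ellipse_levels for e in r.ellipses[lv]
                if e.event.duration_h >= config.min_event_duration_h
                and e.event.n_fixes >= 1]
        ellipses_to_geojson(keep, d / "ellipses.geojson")
        r.diel.to_csv(d / "diel.csv", index=False)
        r.movement["daily"].to_csv(d / "distance_daily.csv", index=False)
        r.movement["bouts"].to_csv(d / "distance_bouts.csv", index=False)
    clusters_to_frame(run["clusters"]).to_csv(out / "rest_locations.csv", index=False)
    summarize_run(run).to_csv(out / "summary.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(run["manifest"], fh, indent=2, default=str)


def summarize_run(run) -> pd.DataFrame:
    """Study-style per-deployment summary table.

    Percent resting is reported under both conventions: out of all steps,
    and out of confidently assigned (non-uncertain) steps.
    """
    rows = []
    for dep_id, r in run["results"].items():
        s = r.states
        n = len(s)
        rest = int((s.s_star == 0).sum())
        unc = int(s.uncertain.sum())
        durations = np.array([e.duration_h for e in r.events])
        daily = r.movement["daily"]
        rows.append({
            "deployment_id": dep_id,
            "animal_id": r.series.animal_id,
            "n_steps": n,
            "percent_resting": 100.0 * rest / n,
            "percent_resting_of_confident": (
                100.0 * rest / (n - unc) if n > unc else np.nan
            ),
            "percent_uncertain": 100.0 * unc / n,
            "n_rest_events": len(r.events),
            "mean_duration_h": durations.mean() if len(durations) else np.nan,
            "sd_duration_h": durations.std(ddof=1) if len(durations) > 1 else np.nan,
            "km_per_day": daily["mean_m"].mean() / 1000.0 if len(daily) else np.nan,
        })
    return pd.DataFrame(rows)
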