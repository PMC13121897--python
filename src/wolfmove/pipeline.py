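"""End-to-end pipeline: simulate/load -> daily metrics -> covariates ->
hierarchical fits -> variable importance -> diagnostics.

Every stage writes its artifact under the output directory and logs record
counts into a manifest, so no filtering step drops data silently.  In
synthetic mode a truth-vs-estimate recovery table is added.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnostics import diagnose
from .inference import marginal_effects, pd_table, variance_partition
from .landscape import extract_covariates_for_track
from .model import (
    ModelSpec,
    assign_grid_cells,
    assign_period,
    fit_model,
    refuge_pca,
    subsample_two_thirds,
)
from .synthetic import (
    LandscapeConfig,
    SimConfig,
    SimulatedTracks,
    TruthTable,
    generate_landscape,
    simulate_tracks,
    write_landscape,
)
from .trajectories import filter_complete, segment_days, summarize_metrics, track_metrics


@dataclass
class RunConfig:
    outdir: str = "results/run"
    synthetic: dict | None = None  # {"landscape": {...}, "sim": {...}, "truth": {...}}
    fixes_csv: str | None = None
    attributes_csv: str | None = None
    buffer_radius_km: float = 1.0
    kernel_bandwidth_km: float = 1.0
    subsample_seed: int = 0
    fit_seed: int = 0
    responses: tuple[str, ...] = ("daily_distance", "net_displacement", "straightness")
    n_chains: int = 4
    n_iter: int = 4000
    n_warmup: int = 2000
    fast: bool = False  # reduced MCMC (2 chains x 1,000 iterations)
    diagnostics_reps: int = 200

    def __post_init__(self):
        if (self.synthetic is None) == (self.fixes_csv is None):
            raise ValueError("exactly one of a synthetic block or real fix paths must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def mcmc_settings(self) -> dict:
        if self.fast:
            return {"n_chains": 2, "n_iter": 1000, "n_warmup": 500}
        return {"n_chains": self.n_chains, "n_iter": self.n_iter, "n_warmup": self.n_warmup}


class StageError(RuntimeError):
    def __init__(self, stage: str, counts: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed after counts {counts}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the artifact directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "wolfmove_version": __version__,
        "python": platform.python_version(),
        "seeds": {"subsample": config.subsample_seed, "fit": config.fit_seed},
        "counts": {},
        "stages": [],
    }
    counts = manifest["counts"]

    def stage(name):
        manifest["stages"].append(name)

    try:
        stage("simulate")
        if config.synthetic is not None:
            lcfg = LandscapeConfig(**config.synthetic.get("landscape", {}))
            scfg_raw = dict(config.synthetic.get("sim", {}))
            if "days_per_individual" in scfg_raw and isinstance(scfg_raw["days_per_individual"], list):
                scfg_raw["days_per_individual"] = tuple(scfg_raw["days_per_individual"])
            scfg = SimConfig(**scfg_raw)
            truth = TruthTable(**config.synthetic.get("truth", {}))
            landscape = generate_landscape(lcfg)
            write_landscape(landscape, outdir / "landscape")
            simdata = simulate_tracks(landscape, scfg, truth)
            simdata.write(outdir / "synthetic")
            fixes, attributes = simdata.fixes, simdata.attributes
        else:
            landscape = None
            simdata = None
            fixes = pd.read_csv(config.fixes_csv)
            attributes = pd.read_csv(config.attributes_csv)
        counts["fixes"] = len(fixes)
        counts["individuals"] = fixes["individual_id"].nunique()
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", counts, e) from e

    try:
        stage("metrics")
        tracks = segment_days(fixes)
        counts["raw_daily_tracks"] = len(tracks)
        kept, filt = filter_complete(tracks)
        counts["tracks_retained"] = filt["n_retained"]
        counts["tracks_dropped_incomplete"] = filt["n_dropped"]
        metrics = track_metrics(kept)
        metrics.to_csv(outdir / "track_metrics.csv", index=False)
        summary = summarize_metrics(metrics)
        summary.to_csv(outdir / "metrics_summary.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("metrics", counts, e) from e

    try:
        stage("covariates")
        if landscape is None:
            raise NotImplementedError(
                "real-data covariate extraction requires landscape layer paths; "
                "provide a synthetic block or extract covariates upstream"
            )
        layers = landscape.to_layers(kernel_bandwidth_km=config.kernel_bandwidth_km)
        layers.prepare()
        cov_rows = []
        for t in kept:
            cov_rows.append(
                extract_covariates_for_track(
                    t.track_id, t.x, t.y, layers, buffer_radius_km=config.buffer_radius_km
                )
            )
        covariates = pd.DataFrame(cov_rows)
        pca = refuge_pca(covariates)
        covariates = pd.concat([covariates, pca.scores], axis=1)
        pd.DataFrame(
            {
                "component": pca.loadings.columns,
                "variance_explained": pca.variance_explained[: pca.loadings.shape[1]],
            }
        ).to_csv(outdir / "pca_variance.csv", index=False)
        pca.loadings.to_csv(outdir / "pca_loadings.csv")
        records = metrics.merge(covariates, on="track_id")
        records = records.merge(attributes, on="individual_id")
        records["period"] = [assign_period(d) for d in records["track_date"]]
        records["grid_cell_id"] = assign_grid_cells(records)
        records.to_csv(outdir / "covariate_records.csv", index=False)
        counts["covariate_records"] = len(records)
    except Exception as e:  # noqa: BLE001
        raise StageError("covariates", counts, e) from e

    try:
        stage("subsample")
        modeling = subsample_two_thirds(records, seed=config.subsample_seed)
        counts["modeling_records"] = len(modeling)
        modeling.to_csv(outdir / "modeling_records.csv", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("subsample", counts, e) from e

    mcmc = config.mcmc_settings()
    fits = {}
    for response in config.responses:
        try:
            stage(f"fit:{response}")
            spec = ModelSpec(response=response)
            fit = fit_model(spec, modeling, seed=config.fit_seed, **mcmc)
            fits[response] = fit
            summ = fit.summary()
            summ.to_csv(outdir / f"fit_{response}_summary.csv")
            pd_table(fit).to_csv(outdir / f"pd_{response}.csv")
            vp = variance_partition(fit, modeling)
            vp.table.to_csv(outdir / f"variance_partition_{response}.csv", index=False)
            json.dump(
                {"baseline_pseudo_r2": vp.baseline_pseudo_r2, "group_pct": vp.group_pct},
                open(outdir / f"variance_groups_{response}.json", "w"),
                indent=2,
            )
            me = marginal_effects(fit, ("pop_density", "settlement_density"), modeling)
            me.to_csv(outdir / f"marginal_{response}_pop_x_settlement.csv", index=False)
            diag = diagnose(fit, modeling, n_reps=config.diagnostics_reps, seed=config.fit_seed)
            (outdir / f"diagnostics_{response}.json").write_text(json.dumps(diag.to_dict(), indent=2))
            counts[f"rhat_max_{response}"] = diag.rhat_max
        except Exception as e:  # noqa: BLE001
            raise StageError(f"fit:{response}", counts, e) from e

    if simdata is not None and "daily_distance" in fits:
        stage("recovery")
        recov = _recovery_table(fits["daily_distance"], simdata)
        recov.to_csv(outdir / "recovery_daily_distance.csv", index=False)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir


def _recovery_table(fit, simdata: SimulatedTracks) -> pd.DataFrame:
    """Truth-vs-posterior comparison for coefficients named in the truth table.

    The pipeline's covariates are re-extracted (not the simulator's own
    surfaces), so agreement is qualitative: matching signs and overlapping
    intervals, not exact equality.
    """
    rows = []
    eff = fit.fixed_effect_draws()
    truth = simdata.truth
    for name, draws in eff.items():
        true_val = truth.beta.get(name)
        if name == "intercept":
            true_val = truth.intercept
        if true_val is None:
            continue
        rows.append(
            {
                "term": name,
                "truth": true_val,
                "posterior_mean": float(np.mean(draws)),
                "q2.5": float(np.quantile(draws, 0.025)),
                "q97.5": float(np.quantile(draws, 0.975)),
            }
        )
    return pd.DataFrame(rows)
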