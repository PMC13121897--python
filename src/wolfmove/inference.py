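"""Variable importance: Probability of Direction, credible intervals,
predictive pseudo-R^2 variance partitioning, and marginal effects.

The importance measure is predictive: pseudo-R^2 is the squared Pearson
correlation between observed responses and median posterior predictions.
Each predictor's contribution is the drop in pseudo-R^2 when that predictor
is neutralized — continuous terms held at their mean (0 on the standardized
scale), categorical terms fixed to each level in turn (drops averaged),
interaction columns held at their training mean, and random effects replaced
by a novel level.  Contributions are expressed as percentages of the
baseline pseudo-R^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import CATEGORICAL_LEVELS, CONTINUOUS_TERMS, PosteriorFit, build_design
from .model import _factorize  # shared level coding

DEFAULT_GROUPS = {
    "age": "intrinsic",
    "sex": "intrinsic",
    "status": "intrinsic",
    "period": "intrinsic",
    "diet": "trophic",
    "pop_density": "anthropogenic",
    "settlement_density": "anthropogenic",
    "primary_road": "anthropogenic",
    "secondary_road": "anthropogenic",
    "tri": "landscape",
    "refuge_dim1": "refuge",
    "refuge_dim2": "refuge",
    "sex x period": "intrinsic",
    "status x period": "intrinsic",
    "pop_density x settlement_density": "anthropogenic",
    "primary_road x refuge_dim1": "anthropogenic",
    "primary_road x refuge_dim2": "anthropogenic",
    "secondary_road x refuge_dim1": "anthropogenic",
    "secondary_road x refuge_dim2": "anthropogenic",
    "refuge_dim1 x refuge_dim2": "refuge",
    "individual_id": "random",
    "grid_cell_id": "random",
}


@dataclass
class PDResult:
    parameter: str
    pd: float
    ci95: tuple[float, float]
    significant: bool  # 95% CI excludes zero
    credible_direction: bool  # pd > 0.9


def probability_of_direction(draws: np.ndarray, parameter: str = "") -> PDResult:
    """PD = posterior mass of the dominant sign, in [0.5, 1].

    Draws that are exactly zero count toward neither sign; an all-zero
    posterior degenerates to pd = 0.5.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a stable PD")
    frac_pos = np.mean(draws > 0)
    frac_neg = np.mean(draws < 0)
    pd_val = max(frac_pos, frac_neg)
    if frac_pos == 0 and frac_neg == 0:
        pd_val = 0.5
    lo, hi = np.quantile(draws, [0.025, 0.975])
    return PDResult(
        parameter=parameter,
        pd=float(max(0.5, pd_val)),
        ci95=(float(lo), float(hi)),
        significant=bool(lo > 0 or hi < 0),
        credible_direction=bool(pd_val > 0.9),
    )


def pd_table(fit: PosteriorFit) -> pd.DataFrame:
    """PD / CI table for every fixed-effect coefficient (intercept excluded)."""
    rows = []
    for name, d in fit.fixed_effect_draws().items():
        if name == "intercept":
            continue
        r = probability_of_direction(d, name)
        rows.append(
            {
                "parameter": name,
                "pd": r.pd,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "significant": r.significant,
                "credible_direction": r.credible_direction,
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def pseudo_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Squared Pearson correlation of observed vs median posterior prediction."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.size != predicted.size:
        raise ValueError("length mismatch")
    if observed.size < 3:
        raise ValueError("need at least 3 points")
    if observed.std() == 0 or predicted.std() == 0:
        raise ValueError("zero-variance input to pseudo_r2")
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r**2)


def _predict_draws(
    fit: PosteriorFit,
    records: pd.DataFrame,
    overrides: dict | None = None,
    neutral_columns: dict | None = None,
    scale: str = "natural",
) -> np.ndarray:
    """(n_draws_total, n_records) conditional-expectation predictions."""
    overrides = dict(overrides or {})
    new_ind = overrides.pop("individual_id", None) is not None
    new_cell = overrides.pop("grid_cell_id", None) is not None
    records = records.reset_index(drop=True)
    X, _ = build_design(records, fit.spec, meta=fit.meta, overrides=overrides)
    if neutral_columns:
        for col, val in neutral_columns.items():
            X[:, fit.meta.column_names.index(col)] = val
    ind_idx = (
        np.full(len(records), -1)
        if new_ind
        else _factorize(records["individual_id"], fit.meta.individual_levels)[0]
    )
    cell_idx = (
        np.full(len(records), -1)
        if new_cell
        else _factorize(records["grid_cell_id"], fit.meta.cell_levels)[0]
    )
    eta = fit.linear_predictor_draws(X, ind_idx, cell_idx)
    if fit.spec.family == "gaussian":
        return eta**2 if scale == "natural" else eta
    mu = expit(eta)
    return (1.0 - fit.pi_draws.reshape(-1, 1)) * mu


@dataclass
class VariancePartition:
    baseline_pseudo_r2: float
    table: pd.DataFrame  # term, raw_drop, pct_contribution, group
    group_pct: dict[str, float] = field(default_factory=dict)


def variance_partition(
    fit: PosteriorFit,
    records: pd.DataFrame,
    groups: dict[str, str] | None = None,
    scale: str = "natural",
    level_weighting: str = "unweighted",
) -> VariancePartition:
    """Predictive pseudo-R^2 drop per predictor, as percent of baseline.

    Negative drops (possible by chance) are floored at 0 for the percentage
    column but retained raw.  ``level_weighting='frequency'`` weights the
    categorical per-level drops by observed level frequencies instead of the
    unweighted mean.
    """
    groups = groups or DEFAULT_GROUPS
    records = records.reset_index(drop=True)
    obs = records[fit.spec.response_column].to_numpy(dtype=float)
    finite = np.isfinite(obs)
    records = records.loc[finite].reset_index(drop=True)
    obs = obs[finite]

    def r2_for(overrides=None, neutral_columns=None):
        pred = np.median(
            _predict_draws(fit, records, overrides=overrides, neutral_columns=neutral_columns, scale=scale),
            axis=0,
        )
        return pseudo_r2(obs, pred)

    baseline = r2_for()
    rows = []
    for term in fit.spec.fixed_terms:
        if term in CONTINUOUS_TERMS:
            drop = baseline - r2_for(overrides={term: 0.0})
        else:
            levels = CATEGORICAL_LEVELS[term]
            level_drops = [baseline - r2_for(overrides={term: lev}) for lev in levels]
            if level_weighting == "frequency":
                freqs = records[term].value_counts(normalize=True)
                w = np.array([freqs.get(lev, 0.0) for lev in levels])
                drop = float(np.average(level_drops, weights=w)) if w.sum() > 0 else float(np.mean(level_drops))
            else:
                drop = float(np.mean(level_drops))
        rows.append({"term": term, "raw_drop": drop})
    for inter in fit.spec.interactions:
        a, b = inter.split(" x ")
        cols = [
            name
            for name in fit.meta.column_names
            if " x " in name
            and name.split(" x ")[0].split(":")[0] == a
            and name.split(" x ")[1].split(":")[0] == b
        ]
        neutral = {c: float(fit.X[:, fit.meta.column_names.index(c)].mean()) for c in cols}
        rows.append({"term": inter, "raw_drop": baseline - r2_for(neutral_columns=neutral)})
    for re_name in fit.spec.random_intercepts:
        rows.append({"term": re_name, "raw_drop": baseline - r2_for(overrides={re_name: "__new__"})})

    table = pd.DataFrame(rows)
    table["pct_contribution"] = 100.0 * np.maximum(table["raw_drop"], 0.0) / baseline
    table["group"] = [groups.get(t, "other") for t in table["term"]]
    group_pct = table.groupby("group")["pct_contribution"].sum().to_dict()
    return VariancePartition(baseline_pseudo_r2=baseline, table=table, group_pct=group_pct)


def marginal_effects(
    fit: PosteriorFit,
    focal: str | tuple[str, str],
    records: pd.DataFrame,
    n_grid: int = 25,
    scale: str = "natural",
) -> pd.DataFrame:
    """Predicted response over a grid of a focal predictor.

    Non-focal continuous terms sit at their mean (0 standardized) and
    categoricals at their reference level; random effects at the population
    level.  For a pair (focal, moderator) the moderator is evaluated at its
    observed first and third quartiles, the convention used for the
    interaction figures.  Returns median and equal-tailed 95% band per grid
    point.
    """
    if isinstance(focal, str):
        focal_term, moderator = focal, None
    else:
        focal_term, moderator = focal
    for t in filter(None, (focal_term, moderator)):
        if t not in fit.meta.fixed_terms:
            raise KeyError(f"focal term {t!r} not in the model")
        if t not in CONTINUOUS_TERMS:
            raise KeyError(f"marginal-effect grids are for continuous terms, got {t!r}")

    def std_col(term):
        raw = records[term].to_numpy(dtype=float)
        m, s = fit.meta.cont_means[term], fit.meta.cont_sds[term]
        return (raw - m) / (s if s != 0 else 1.0)

    zf = std_col(focal_term)
    grid = np.linspace(np.quantile(zf, 0.02), np.quantile(zf, 0.98), n_grid)
    mod_values = [None]
    if moderator is not None:
        zm = std_col(moderator)
        mod_values = list(np.quantile(zm, [0.25, 0.75]))

    base_row = {}
    for term in fit.meta.fixed_terms:
        if term in CONTINUOUS_TERMS:
            base_row[term] = fit.meta.cont_means[term]  # standardizes to 0
        else:
            base_row[term] = CATEGORICAL_LEVELS[term][0]
    rows = []
    for mv in mod_values:
        for g in grid:
            row = dict(base_row)
            m, s = fit.meta.cont_means[focal_term], fit.meta.cont_sds[focal_term]
            row[focal_term] = m + g * (s if s != 0 else 1.0)
            if moderator is not None:
                mm, ms = fit.meta.cont_means[moderator], fit.meta.cont_sds[moderator]
                row[moderator] = mm + mv * (ms if ms != 0 else 1.0)
            row["individual_id"] = "__new__"
            row["grid_cell_id"] = "__new__"
            rows.append(row)
    grid_records = pd.DataFrame(rows)
    preds = _predict_draws(
        fit,
        grid_records,
        overrides={"individual_id": "__new__", "grid_cell_id": "__new__"},
        scale=scale,
    )
    med = np.median(preds, axis=0)
    lo, hi = np.quantile(preds, [0.025, 0.975], axis=0)
    out = []
    k = 0
    for mv in mod_values:
        for g in grid:
            out.append(
                {
                    "focal": focal_term,
                    "focal_z": g,
                    "moderator": moderator,
                    "moderator_z": mv,
                    "median": med[k],
                    "lo95": lo[k],
                    "hi95": hi[k],
                }
            )
            k += 1
    return pd.DataFrame(out)
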