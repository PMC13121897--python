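"""Model diagnostics: residual autocorrelation (temporal and spatial) and
posterior predictive checks.

Residuals for the Gaussian models are taken on the sqrt (fitting) scale,
where the error model holds.  Temporal structure is checked with a
within-individual ACF over day lags (subsampled-out days break lag chains
rather than being bridged), spatial structure with Moran's I over track
mid-points (inverse-distance weights with a 5-km cutoff by default), and
calibration with posterior predictive replicates of summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .model import PosteriorFit


def residual_acf(residuals: pd.DataFrame, max_lag: int = 10) -> pd.DataFrame:
    """Within-individual residual ACF at day lags 0..max_lag.

    ``residuals`` needs columns individual_id, track_date, residual.  For
    each individual the residuals are placed on a day-indexed axis; the
    lag-k correlation uses only pairs of days both present (gaps from the
    temporal subsampling are never bridged).  Per-lag values are averaged
    across individuals, weighted by the number of contributing pairs.
    Individuals with fewer than 3 residuals are skipped.
    """
    acc = {k: [] for k in range(max_lag + 1)}
    series_lengths = []
    for _, grp in residuals.groupby("individual_id"):
        if len(grp) < 3:
            continue
        series_lengths.append(len(grp))
        dates = pd.to_datetime(grp["track_date"])
        day = (dates - dates.min()).dt.days.to_numpy()
        r = grp["residual"].to_numpy(dtype=float)
        r = r - r.mean()
        denom = np.sum(r**2)
        if denom == 0:
            continue
        series = {}
        for d, v in zip(day, r):
            series[d] = v
        for k in range(max_lag + 1):
            num, npairs = 0.0, 0
            for d, v in series.items():
                if d + k in series:
                    num += v * series[d + k]
                    npairs += 1
            if npairs > 0:
                # normalize by the per-individual variance (lag-0 value is 1)
                acc[k].append((num / denom * len(r) / npairs, npairs))
    # small-sample expectation of the sample autocorrelation under white
    # noise (Anderson): about -1/n per series; significance tests should be
    # centered there rather than at zero
    wn_mean = float(np.mean([-1.0 / n for n in series_lengths])) if series_lengths else float("nan")
    rows = []
    for k in range(max_lag + 1):
        if acc[k]:
            vals = np.array([v for v, _ in acc[k]])
            wts = np.array([w for _, w in acc[k]], dtype=float)
            rows.append(
                {
                    "lag": k,
                    "acf": float(np.average(vals, weights=wts)),
                    "n_pairs": int(wts.sum()),
                    "white_noise_mean": 0.0 if k == 0 else wn_mean,
                }
            )
        else:
            rows.append({"lag": k, "acf": float("nan"), "n_pairs": 0, "white_noise_mean": float("nan")})
    return pd.DataFrame(rows)


@dataclass
class MoranResult:
    statistic: float
    expectation: float
    variance: float
    z: float
    p_value: float
    n: int


def inverse_distance_weights(xy: np.ndarray, cutoff_km: float = 5.0) -> np.ndarray:
    """Inverse-distance spatial weights, zero beyond the cutoff and on the
    diagonal."""
    xy = np.asarray(xy, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    w[~np.isfinite(w)] = 0.0
    w[d > cutoff_km] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def morans_i(values: np.ndarray, weights: np.ndarray) -> MoranResult:
    """Moran's I with expectation, normality-based variance, z and p.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with E[I] = -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 points for Moran's I")
    xc = x - x.mean()
    denom = np.sum(xc**2)
    if denom == 0:
        raise ValueError("zero residual variance")
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("all spatial weights are zero")
    num = xc @ w @ xc
    stat = (n / s0) * num / denom
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z = (stat - e_i) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return MoranResult(
        statistic=float(stat), expectation=e_i, variance=float(var), z=float(z), p_value=float(p), n=n
    )


@dataclass
class PPCSummary:
    stats: pd.DataFrame  # statistic, observed, rep_mean, tail_prob

    def to_dict(self) -> dict:
        return self.stats.to_dict(orient="records")


def posterior_predictive_check(fit: PosteriorFit, n_reps: int = 200, seed: int = 0) -> PPCSummary:
    """Simulate replicate response vectors from posterior draws and compare
    observed summary statistics (mean, SD, and the zero fraction for the
    straightness model) with their replicate distributions.

    The tail probability is the fraction of replicates with a statistic at
    least as large as observed; values near 0 or 1 flag misfit.
    """
    rng = np.random.default_rng(seed)
    nc, nd, _ = fit.draws.shape
    total = nc * nd
    take = rng.choice(total, size=min(n_reps, total), replace=False)
    flat = fit.draws.reshape(total, -1)

    if fit.spec.family == "gaussian":
        ind_idx, cell_idx, X, y = fit.ind_idx, fit.cell_idx, fit.X, fit.y
    else:
        pos = fit.y > 0
        X, ind_idx, cell_idx = fit.X[pos], fit.ind_idx[pos], fit.cell_idx[pos]
        y = fit.y

    stats = {"mean": [], "sd": []}
    if fit.spec.family == "zib":
        stats["zero_fraction"] = []
    for t in take:
        theta = flat[t]
        beta = theta[fit.slices["beta"]]
        eta = X @ beta
        for z_name, s_name, idx in (("z_ind", "log_sigma_ind", ind_idx), ("z_cell", "log_sigma_cell", cell_idx)):
            if z_name in fit.slices:
                eta = eta + np.exp(theta[fit.slices[s_name]])[0] * theta[fit.slices[z_name]][idx]
        if fit.spec.family == "gaussian":
            s_r = np.exp(theta[fit.slices["log_sigma_resid"]])[0]
            rep = eta + rng.normal(0.0, s_r, size=eta.size)
        else:
            phi = np.exp(theta[fit.slices["log_phi"]])[0]
            mu = expit(eta)
            pi = fit.pi_draws.reshape(-1)[t]
            n_total = fit.y.size
            take_mu = mu[rng.integers(0, mu.size, size=n_total)]
            rep = rng.beta(np.maximum(take_mu * phi, 1e-6), np.maximum((1 - take_mu) * phi, 1e-6))
            rep[rng.random(n_total) < pi] = 0.0
            stats["zero_fraction"].append(float(np.mean(rep == 0)))
        stats["mean"].append(float(rep.mean()))
        stats["sd"].append(float(rep.std(ddof=1)))

    obs = {"mean": float(np.mean(y)), "sd": float(np.std(y, ddof=1))}
    if fit.spec.family == "zib":
        obs["zero_fraction"] = float(np.mean(y == 0))
    rows = []
    for name, reps in stats.items():
        reps = np.asarray(reps)
        rows.append(
            {
                "statistic": name,
                "observed": obs[name],
                "rep_mean": float(reps.mean()),
                "rep_sd": float(reps.std(ddof=1)),
                "tail_prob": float(np.mean(reps >= obs[name])),
            }
        )
    return PPCSummary(stats=pd.DataFrame(rows))


@dataclass
class DiagnosticsReport:
    acf: pd.DataFrame
    moran: MoranResult
    ppc: PPCSummary
    rhat_max: float

    def to_dict(self) -> dict:
        return {
            "acf": self.acf.to_dict(orient="records"),
            "moran": {
                "statistic": self.moran.statistic,
                "expectation": self.moran.expectation,
                "variance": self.moran.variance,
                "z": self.moran.z,
                "p_value": self.moran.p_value,
                "n": self.moran.n,
            },
            "ppc": self.ppc.to_dict(),
            "rhat_max": self.rhat_max,
        }


def diagnose(
    fit: PosteriorFit,
    records: pd.DataFrame,
    max_lag: int = 10,
    cutoff_km: float = 5.0,
    n_reps: int = 200,
    seed: int = 0,
) -> DiagnosticsReport:
    """Full diagnostics for one fitted movement model.

    Residuals: observed minus median fitted value on the fitting scale
    (sqrt for the distance models, the (0,1) response for straightness).
    """
    records = records.reset_index(drop=True)
    obs_col = fit.spec.response_column
    obs = records[obs_col].to_numpy(dtype=float)
    finite = np.isfinite(obs)
    recs = records.loc[finite].reset_index(drop=True)
    from .inference import _predict_draws

    scale = "sqrt" if fit.spec.family == "gaussian" else "natural"
    pred = np.median(_predict_draws(fit, recs, scale=scale), axis=0)
    obs_fit_scale = np.sqrt(obs[finite]) if fit.spec.family == "gaussian" else obs[finite]
    resid = obs_fit_scale - pred
    resid_df = pd.DataFrame(
        {
            "individual_id": recs["individual_id"],
            "track_date": recs["track_date"],
            "residual": resid,
        }
    )
    acf = residual_acf(resid_df, max_lag=max_lag)
    xy = recs[["mid_x_km", "mid_y_km"]].to_numpy(dtype=float)
    # jitter exact duplicates so inverse-distance weights stay finite
    w = inverse_distance_weights(xy + 1e-9, cutoff_km=cutoff_km)
    moran = morans_i(resid, w)
    ppc = posterior_predictive_check(fit, n_reps=n_reps, seed=seed)
    rhat_max = float(fit.rhat().max())
    return DiagnosticsReport(acf=acf, moran=moran, ppc=ppc, rhat_max=rhat_max)
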