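"""Bayesian hierarchical regressions for the three daily movement metrics.

One comprehensive model per response, with fixed and random structure set a
priori:

* daily distance and net displacement: square-root transformed response,
  Gaussian errors;
* straightness index: zero-inflated Beta — a point mass pi at 0 plus
  Beta(mu*phi, (1-mu)*phi) on (0, 1) with a logit link on mu.

Fixed effects: age, sex, social status, reproductive period, diet category,
human population density, settlement density, primary/secondary road density,
terrain ruggedness, and the first two refuge-cover PCA dimensions, plus a
fixed set of interactions (sex/status with period, population x settlement,
roads x refuge dimensions, refuge dim1 x dim2).  Random intercepts for the
individual and for the 1x1-km grid cell of the track midpoint.  Priors are
Normal(0, 10) on the intercept and Normal(0, 1) on slopes; half-Normal(2.5)
on random-effect and residual SDs.  Continuous predictors are standardized
to mean 0, SD 1 before fitting.

Posteriors are sampled by Hamiltonian Monte Carlo (non-centered random
effects); the zero-inflation probability has a conjugate Beta posterior and
is drawn exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from .sampler import sample_posterior

CONTINUOUS_TERMS = (
    "pop_density",
    "settlement_density",
    "primary_road",
    "secondary_road",
    "tri",
    "refuge_dim1",
    "refuge_dim2",
)
CATEGORICAL_LEVELS = {
    "age": ("subadult", "adult"),
    "sex": ("female", "male"),
    "status": ("pack", "nonpack"),
    "period": ("mating", "breeding", "nonreproductive"),
    "diet": ("wild", "livestock", "horses"),
}
DEFAULT_FIXED_TERMS = (
    "age",
    "sex",
    "status",
    "period",
    "diet",
    "pop_density",
    "settlement_density",
    "primary_road",
    "secondary_road",
    "tri",
    "refuge_dim1",
    "refuge_dim2",
)
DEFAULT_INTERACTIONS = (
    "sex x period",
    "status x period",
    "pop_density x settlement_density",
    "primary_road x refuge_dim1",
    "primary_road x refuge_dim2",
    "secondary_road x refuge_dim1",
    "secondary_road x refuge_dim2",
    "refuge_dim1 x refuge_dim2",
)
RESPONSE_COLUMNS = {
    "daily_distance": "daily_distance_km",
    "net_displacement": "net_displacement_km",
    "straightness": "straightness",
}
REFUGE_METRIC_COLUMNS = (
    "refuge_cover_pct",
    "patch_density",
    "mean_patch_size",
    "mean_cohesion",
    "mean_fdi",
)


@dataclass
class ModelSpec:
    response: str
    fixed_terms: tuple[str, ...] = DEFAULT_FIXED_TERMS
    interactions: tuple[str, ...] = DEFAULT_INTERACTIONS
    random_intercepts: tuple[str, ...] = ("individual_id", "grid_cell_id")
    prior_intercept_sd: float = 10.0
    prior_slope_sd: float = 1.0
    prior_sigma_sd: float = 2.5
    n_chains: int = 4
    n_iter: int = 4000  # total iterations per chain
    n_warmup: int = 2000

    def __post_init__(self):
        if self.response not in RESPONSE_COLUMNS:
            raise ValueError(f"unknown response {self.response!r}")
        parents = set(self.fixed_terms)
        for inter in self.interactions:
            for part in inter.split(" x "):
                if part not in parents:
                    raise ValueError(f"interaction parent {part!r} not in fixed_terms")

    @property
    def transform(self) -> str:
        return "sqrt" if self.response in ("daily_distance", "net_displacement") else "none"

    @property
    def family(self) -> str:
        return "gaussian" if self.response in ("daily_distance", "net_displacement") else "zib"

    @property
    def response_column(self) -> str:
        return RESPONSE_COLUMNS[self.response]


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # metrics x components
    scores: pd.DataFrame  # tracks x components (refuge_dim1, refuge_dim2, ...)
    variance_explained: np.ndarray
    means: pd.Series
    sds: pd.Series


def refuge_pca(covariates: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of the five refuge metrics on the correlation structure.

    Zero-patch areas (flagged NaN metrics) are imputed at their limiting
    values (patch size 0, cohesion 0, FDI 1) so they stay in the analysis.
    The sign convention fixes dim1 to load positively on percent refuge
    cover and dim2 positively on mean fractal dimension.
    """
    from sklearn.decomposition import PCA

    mat = covariates.loc[:, list(REFUGE_METRIC_COLUMNS)].copy()
    mat["mean_patch_size"] = mat["mean_patch_size"].fillna(0.0)
    mat["mean_cohesion"] = mat["mean_cohesion"].fillna(0.0)
    mat["mean_fdi"] = mat["mean_fdi"].fillna(1.0)
    means = mat.mean()
    sds = mat.std(ddof=0)
    if (sds == 0).any():
        bad = sds[sds == 0].index.tolist()
        raise ValueError(f"refuge metrics with zero variance: {bad}")
    z = (mat - means) / sds
    pca = PCA(n_components=min(n_components, z.shape[1]))
    scores = pca.fit_transform(z.to_numpy())
    loadings = pca.components_.T.copy()  # metrics x comps
    for k, anchor in enumerate(["refuge_cover_pct", "mean_fdi"][: loadings.shape[1]]):
        a = list(REFUGE_METRIC_COLUMNS).index(anchor)
        if loadings[a, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"refuge_dim{k + 1}" for k in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=list(REFUGE_METRIC_COLUMNS), columns=comp_names),
        scores=pd.DataFrame(scores, index=covariates.index, columns=comp_names),
        variance_explained=pca.explained_variance_ratio_,
        means=means,
        sds=sds,
    )


def assign_period(d: date | pd.Timestamp) -> str:
    """Reproductive period from the calendar month: mating Feb-Apr,
    breeding May-Oct, nonreproductive Nov-Jan."""
    m = pd.Timestamp(d).month
    if m in (2, 3, 4):
        return "mating"
    if 5 <= m <= 10:
        return "breeding"
    return "nonreproductive"


def assign_grid_cells(df: pd.DataFrame, cell_km: float = 1.0, x_col: str = "mid_x_km", y_col: str = "mid_y_km") -> pd.Series:
    """1x1-km lattice cell id from the track's mid-coordinates."""
    ix = np.floor(df[x_col].to_numpy() / cell_km).astype(int)
    iy = np.floor(df[y_col].to_numpy() / cell_km).astype(int)
    return pd.Series([f"c{a}_{b}" for a, b in zip(ix, iy)], index=df.index, name="grid_cell_id")


def subsample_two_thirds(records: pd.DataFrame, seed: int, date_col: str = "track_date") -> pd.DataFrame:
    """Random 2/3 subsample stratified by individual x calendar month.

    Each stratum keeps floor(2n/3) rows without replacement (strata of one
    row keep nothing under the floor rule); deterministic under the seed.
    Breaking the day-to-day sequence this way removes the serial dependence
    that motivates the subsampling.
    """
    rng = np.random.default_rng(seed)
    months = pd.to_datetime(records[date_col]).dt.month
    keep_idx: list = []
    for (_, _), grp in records.groupby([records["individual_id"], months], sort=True):
        k = (2 * len(grp)) // 3
        if k == 0:
            continue
        chosen = rng.choice(len(grp), size=k, replace=False)
        keep_idx.extend(grp.index[np.sort(chosen)])
    return records.loc[keep_idx]


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMeta:
    fixed_terms: tuple[str, ...]
    interactions: tuple[str, ...]
    column_names: list[str]
    cont_means: dict[str, float]
    cont_sds: dict[str, float]
    individual_levels: list[str]
    cell_levels: list[str]
    standardize: bool


def _term_columns(term: str, values: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Columns contributed by one main-effect term."""
    if term in CONTINUOUS_TERMS:
        return {term: values[term]}
    levels = CATEGORICAL_LEVELS[term]
    codes = values[term]
    return {f"{term}:{lev}": (codes == lev).astype(float) for lev in levels[1:]}


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    meta: DesignMeta | None = None,
    standardize: bool = True,
    overrides: dict | None = None,
) -> tuple[np.ndarray, DesignMeta]:
    """Fixed-effects design matrix (intercept first).

    ``overrides`` neutralizes terms before interaction columns are formed:
    a continuous term maps to a scalar on the standardized scale (0 = its
    mean), a categorical term to a single level name.  Interactions are
    recomputed from the neutralized values, keeping the design internally
    consistent.
    """
    overrides = overrides or {}
    values: dict[str, np.ndarray] = {}
    n = len(records)
    cont_means: dict[str, float] = {}
    cont_sds: dict[str, float] = {}
    for term in spec.fixed_terms:
        if term in CONTINUOUS_TERMS:
            raw = records[term].to_numpy(dtype=float)
            if meta is not None:
                m, s = meta.cont_means[term], meta.cont_sds[term]
            elif standardize:
                m, s = float(raw.mean()), float(raw.std(ddof=0))
                if s == 0:
                    raise ValueError(f"continuous predictor {term!r} has zero variance")
            else:
                m, s = 0.0, 1.0
            cont_means[term], cont_sds[term] = m, s
            z = (raw - m) / s if s != 0 else raw - m
            if term in overrides:
                z = np.full(n, float(overrides[term]))
            values[term] = z
        elif term in CATEGORICAL_LEVELS:
            codes = records[term].astype(str).to_numpy()
            levels = CATEGORICAL_LEVELS[term]
            unknown = set(np.unique(codes)) - set(levels)
            if unknown:
                raise ValueError(f"unknown levels {unknown} for {term!r}")
            if term in overrides:
                codes = np.full(n, str(overrides[term]))
            values[term] = codes
        else:
            raise ValueError(f"unknown fixed term {term!r}")

    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    for term in spec.fixed_terms:
        cols.update(_term_columns(term, values))
    for inter in spec.interactions:
        a, b = inter.split(" x ")
        for na, va in _term_columns(a, values).items():
            for nb, vb in _term_columns(b, values).items():
                cols[f"{na} x {nb}"] = va * vb

    if meta is not None:
        # align to the training column order
        X = np.column_stack([cols[name] for name in meta.column_names])
        return X, meta
    names = list(cols)
    X = np.column_stack([cols[name] for name in names])
    new_meta = DesignMeta(
        fixed_terms=spec.fixed_terms,
        interactions=spec.interactions,
        column_names=names,
        cont_means=cont_means,
        cont_sds=cont_sds,
        individual_levels=[],
        cell_levels=[],
        standardize=standardize,
    )
    return X, new_meta


def _factorize(values: pd.Series, levels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    vals = values.astype(str)
    if levels is None:
        levels = sorted(vals.unique())
    lookup = {lev: k for k, lev in enumerate(levels)}
    idx = np.array([lookup.get(v, -1) for v in vals])
    return idx, levels


# ---------------------------------------------------------------------------
# posterior fit container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    spec: ModelSpec
    meta: DesignMeta
    param_names: list[str]
    draws: np.ndarray  # (chains, draws, dim)
    slices: dict[str, slice]
    pi_draws: np.ndarray | None  # (chains, draws) for ZIB
    y: np.ndarray  # response on the fitting scale
    X: np.ndarray
    ind_idx: np.ndarray
    cell_idx: np.ndarray
    records_index: pd.Index
    sampler_info: dict = field(default_factory=dict)

    @property
    def n_fixed(self) -> int:
        return len(self.meta.column_names)

    def beta_draws(self) -> np.ndarray:
        """(total draws, n fixed) fixed-effect draws, chains stacked."""
        sl = self.slices["beta"]
        return self.draws[:, :, sl].reshape(-1, self.n_fixed)

    def fixed_effect_draws(self) -> dict[str, np.ndarray]:
        b = self.beta_draws()
        return {name: b[:, k] for k, name in enumerate(self.meta.column_names)}

    def scalar_draws(self, name: str) -> np.ndarray:
        sl = self.slices[name]
        return self.draws[:, :, sl].reshape(-1)

    def sd_draws(self) -> dict[str, np.ndarray]:
        out = {}
        for name in ("log_sigma_ind", "log_sigma_cell", "log_sigma_resid", "log_phi"):
            if name in self.slices:
                out[name.replace("log_", "")] = np.exp(self.scalar_draws(name))
        return out

    def to_inference_data(self):
        import arviz as az

        sl = self.slices["beta"]
        data = {"beta": self.draws[:, :, sl]}
        for name in ("log_sigma_ind", "log_sigma_cell", "log_sigma_resid", "log_phi"):
            if name in self.slices:
                data[name] = self.draws[:, :, self.slices[name]][:, :, 0]
        if self.pi_draws is not None:
            data["pi"] = self.pi_draws
        return az.from_dict(
            posterior=data, coords={"coef": self.meta.column_names}, dims={"beta": ["coef"]}
        )

    def rhat(self) -> pd.Series:
        """Split-R-hat for every fixed effect and variance parameter."""
        import arviz as az

        idata = self.to_inference_data()
        rh = az.rhat(idata)
        out = {}
        for k, name in enumerate(self.meta.column_names):
            out[name] = float(rh["beta"].values[k])
        for name in ("log_sigma_ind", "log_sigma_cell", "log_sigma_resid", "log_phi"):
            if name in self.slices:
                out[name.replace("log_", "")] = float(rh[name].values)
        if self.pi_draws is not None:
            out["pi"] = float(rh["pi"].values)
        return pd.Series(out)

    def summary(self) -> pd.DataFrame:
        rows = {}
        for name, d in self.fixed_effect_draws().items():
            rows[name] = {
                "mean": d.mean(),
                "sd": d.std(),
                "q2.5": np.quantile(d, 0.025),
                "q97.5": np.quantile(d, 0.975),
            }
        for name, d in self.sd_draws().items():
            rows[name] = {
                "mean": d.mean(),
                "sd": d.std(),
                "q2.5": np.quantile(d, 0.025),
                "q97.5": np.quantile(d, 0.975),
            }
        if self.pi_draws is not None:
            d = self.pi_draws.reshape(-1)
            rows["pi"] = {
                "mean": d.mean(),
                "sd": d.std(),
                "q2.5": np.quantile(d, 0.025),
                "q97.5": np.quantile(d, 0.975),
            }
        df = pd.DataFrame(rows).T
        rh = self.rhat()
        df["rhat"] = rh.reindex(df.index)
        return df

    def save(self, path) -> None:
        """Serialize draws + design metadata to a .npz with embedded JSON.

        Enough to reload for prediction, partitioning and diagnostics without
        refitting.
        """
        import json
        from dataclasses import asdict
        from pathlib import Path

        meta_json = json.dumps(
            {
                "spec": asdict(self.spec),
                "meta": asdict(self.meta),
                "slices": {k: [v.start, v.stop] for k, v in self.slices.items()},
                "param_names": self.param_names,
                "records_index": list(map(int, self.records_index)),
                "sampler_info": {
                    k: (list(map(float, v)) if isinstance(v, list) else v)
                    for k, v in self.sampler_info.items()
                },
            }
        )
        np.savez_compressed(
            Path(path),
            draws=self.draws,
            pi_draws=self.pi_draws if self.pi_draws is not None else np.empty(0),
            y=self.y,
            X=self.X,
            ind_idx=self.ind_idx,
            cell_idx=self.cell_idx,
            meta_json=np.array(meta_json),
        )

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        import json

        data = np.load(path, allow_pickle=False)
        info = json.loads(str(data["meta_json"]))
        spec_kwargs = info["spec"]
        for key in ("fixed_terms", "interactions", "random_intercepts"):
            spec_kwargs[key] = tuple(spec_kwargs[key])
        spec = ModelSpec(**spec_kwargs)
        meta_kwargs = info["meta"]
        meta_kwargs["fixed_terms"] = tuple(meta_kwargs["fixed_terms"])
        meta_kwargs["interactions"] = tuple(meta_kwargs["interactions"])
        meta = DesignMeta(**meta_kwargs)
        pi = data["pi_draws"]
        return cls(
            spec=spec,
            meta=meta,
            param_names=info["param_names"],
            draws=data["draws"],
            slices={k: slice(a, b) for k, (a, b) in info["slices"].items()},
            pi_draws=pi if pi.size else None,
            y=data["y"],
            X=data["X"],
            ind_idx=data["ind_idx"],
            cell_idx=data["cell_idx"],
            records_index=pd.Index(info["records_index"]),
            sampler_info=info["sampler_info"],
        )

    def linear_predictor_draws(
        self, X: np.ndarray, ind_idx: np.ndarray, cell_idx: np.ndarray
    ) -> np.ndarray:
        """(total draws, n records) linear predictor; unseen levels (idx -1)
        contribute the population-level effect 0."""
        nc, nd, _ = self.draws.shape
        flat = self.draws.reshape(nc * nd, -1)
        beta = flat[:, self.slices["beta"]]
        eta = beta @ X.T
        for name, idx, sig_name in (
            ("z_ind", ind_idx, "log_sigma_ind"),
            ("z_cell", cell_idx, "log_sigma_cell"),
        ):
            if name not in self.slices:
                continue
            z = flat[:, self.slices[name]]
            sig = np.exp(flat[:, self.slices[sig_name]]).reshape(-1, 1)
            eff = np.where(idx[None, :] >= 0, z[:, np.clip(idx, 0, None)], 0.0)
            eta += sig * eff
        return eta


# ---------------------------------------------------------------------------
# log posteriors
# ---------------------------------------------------------------------------


def _make_layout(p: int, n_ind: int, n_cell: int, tail_name: str) -> dict[str, slice]:
    """Parameter-vector layout; random-effect blocks with <2 levels are
    dropped (a one-level intercept is not identifiable beside the global
    intercept)."""
    slices: dict[str, slice] = {"beta": slice(0, p)}
    o = p
    if n_ind >= 2:
        slices["z_ind"] = slice(o, o + n_ind)
        o += n_ind
    if n_cell >= 2:
        slices["z_cell"] = slice(o, o + n_cell)
        o += n_cell
    if n_ind >= 2:
        slices["log_sigma_ind"] = slice(o, o + 1)
        o += 1
    if n_cell >= 2:
        slices["log_sigma_cell"] = slice(o, o + 1)
        o += 1
    slices[tail_name] = slice(o, o + 1)
    slices["__dim__"] = slice(0, o + 1)
    return slices


def _random_effect_terms(theta, grad, slices, ind_idx, cell_idx, sigma_prior_sd):
    """Shared non-centered random-effect machinery.

    Adds the z ~ N(0,1) and half-Normal SD priors (with log-Jacobian) to
    (lp, grad) and returns the random-effect contribution to eta together
    with closures that accumulate the likelihood gradient chain terms.
    """
    lp = 0.0
    eta_re = 0.0
    parts = []
    for z_name, s_name, idx in (("z_ind", "log_sigma_ind", ind_idx), ("z_cell", "log_sigma_cell", cell_idx)):
        if z_name not in slices:
            continue
        z = theta[slices[z_name]]
        ls = theta[slices[s_name]][0]
        s = np.exp(ls)
        lp += -0.5 * np.sum(z**2)
        grad[slices[z_name]] = -z
        lp += -(s**2) / (2 * sigma_prior_sd**2) + ls
        grad[slices[s_name]] = -(s**2) / sigma_prior_sd**2 + 1.0
        eta_re = eta_re + s * z[idx]
        parts.append((z_name, s_name, idx, z, s))
    return lp, eta_re, parts


def _accumulate_re_grad(grad, slices, parts, dl_deta):
    for z_name, s_name, idx, z, s in parts:
        n_lev = slices[z_name].stop - slices[z_name].start
        grad[slices[z_name]] += s * np.bincount(idx, weights=dl_deta, minlength=n_lev)
        grad[slices[s_name]] += s * np.sum(dl_deta * z[idx])


def _gaussian_logp_grad_factory(
    X, y, ind_idx, cell_idx, slices, prior_sd, sigma_prior_sd, prior_only=False
):
    n, p = X.shape
    prior_prec = 1.0 / prior_sd**2
    dim = slices["__dim__"].stop

    def logp_grad(theta):
        grad = np.zeros(dim)
        beta = theta[slices["beta"]]
        ls_r = theta[slices["log_sigma_resid"]][0]
        s_r = np.exp(ls_r)
        lp = -0.5 * np.sum(prior_prec * beta**2)
        grad[slices["beta"]] = -prior_prec * beta
        lp_re, eta_re, parts = _random_effect_terms(theta, grad, slices, ind_idx, cell_idx, sigma_prior_sd)
        lp += lp_re
        lp += -(s_r**2) / (2 * sigma_prior_sd**2) + ls_r
        grad[slices["log_sigma_resid"]] = -(s_r**2) / sigma_prior_sd**2 + 1.0

        if not prior_only:
            r = y - (X @ beta + eta_re)
            inv_var = 1.0 / s_r**2
            lp += -0.5 * np.sum(r**2) * inv_var - n * ls_r
            dl_deta = r * inv_var
            grad[slices["beta"]] += X.T @ dl_deta
            _accumulate_re_grad(grad, slices, parts, dl_deta)
            grad[slices["log_sigma_resid"]] += np.sum(r**2) * inv_var - n
        return lp, grad

    return logp_grad


def _zib_logp_grad_factory(
    X, y, ind_idx, cell_idx, slices, prior_sd, sigma_prior_sd, log_phi_loc=np.log(10.0), log_phi_sd=1.5
):
    """Log posterior of the Beta part (y strictly inside (0, 1))."""
    n, p = X.shape
    prior_prec = 1.0 / prior_sd**2
    log_y = np.log(y)
    log_1my = np.log1p(-y)
    dim = slices["__dim__"].stop

    def logp_grad(theta):
        grad = np.zeros(dim)
        beta = theta[slices["beta"]]
        lphi = theta[slices["log_phi"]][0]
        phi = np.exp(lphi)
        lp = -0.5 * np.sum(prior_prec * beta**2)
        grad[slices["beta"]] = -prior_prec * beta
        lp_re, eta_re, parts = _random_effect_terms(theta, grad, slices, ind_idx, cell_idx, sigma_prior_sd)
        lp += lp_re
        lp += -0.5 * (lphi - log_phi_loc) ** 2 / log_phi_sd**2
        grad[slices["log_phi"]] = -(lphi - log_phi_loc) / log_phi_sd**2

        eta = X @ beta + eta_re
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        lp += np.sum(gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * log_y + (b - 1) * log_1my)
        dl_deta = phi * mu * (1.0 - mu) * (digamma(b) - digamma(a) + log_y - log_1my)
        grad[slices["beta"]] += X.T @ dl_deta
        _accumulate_re_grad(grad, slices, parts, dl_deta)
        dlphi = phi * np.sum(
            digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b) + mu * log_y + (1.0 - mu) * log_1my
        )
        grad[slices["log_phi"]] += dlphi
        return lp, grad

    return logp_grad


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def compress_boundary_ones(y: np.ndarray) -> np.ndarray:
    """Shrink exact 1s of a proportion to (y*(n-1)+0.5)/n, applied only to
    boundary values — the zero-inflated Beta likelihood excludes 1."""
    y = np.asarray(y, dtype=float).copy()
    n = y.size
    y[y >= 1.0] = (1.0 * (n - 1) + 0.5) / n
    return y


def fit_model(
    spec: ModelSpec,
    records: pd.DataFrame,
    seed: int = 0,
    n_chains: int | None = None,
    n_iter: int | None = None,
    n_warmup: int | None = None,
    standardize: bool = True,
    prior_only: bool = False,
) -> PosteriorFit:
    """Fit one movement-metric model by HMC and return labelled draws.

    ``n_chains``/``n_iter``/``n_warmup`` override the spec's MCMC settings
    (the full 4 chains x 4,000 iterations with 2,000 warmup stays the spec
    default; tests use reduced runs).
    """
    n_chains = n_chains or spec.n_chains
    n_iter = n_iter or spec.n_iter
    n_warmup = n_warmup if n_warmup is not None else min(spec.n_warmup, n_iter // 2)
    n_draws = n_iter - n_warmup

    records = records.reset_index(drop=True)
    y_raw = records[spec.response_column].to_numpy(dtype=float)
    if spec.family == "zib":
        keep = np.isfinite(y_raw)
        records = records.loc[keep].reset_index(drop=True)
        y_raw = y_raw[keep]
        y_all = compress_boundary_ones(y_raw)
        if np.any((y_all < 0) | (y_all >= 1)):
            raise ValueError("straightness values must lie in [0, 1]")
    else:
        if not np.all(np.isfinite(y_raw)):
            raise ValueError(f"non-finite {spec.response} responses")
        if np.any(y_raw < 0):
            raise ValueError("distance responses must be nonnegative")
        y_all = np.sqrt(y_raw)

    X, meta = build_design(records, spec, standardize=standardize)
    ind_idx, ind_levels = _factorize(records["individual_id"])
    cell_idx, cell_levels = _factorize(records["grid_cell_id"])
    meta.individual_levels = ind_levels
    meta.cell_levels = cell_levels
    n_ind, n_cell = len(ind_levels), len(cell_levels)
    p = X.shape[1]

    prior_sd = np.full(p, spec.prior_slope_sd)
    prior_sd[0] = spec.prior_intercept_sd

    tail = "log_sigma_resid" if spec.family == "gaussian" else "log_phi"
    slices = _make_layout(p, n_ind, n_cell, tail)
    dim = slices["__dim__"].stop
    init = np.zeros(dim)
    for name in ("log_sigma_ind", "log_sigma_cell"):
        if name in slices:
            init[slices[name]] = np.log(0.3)

    pi_draws = None
    if spec.family == "gaussian":
        init[0] = y_all.mean()
        init[slices[tail]] = np.log(max(y_all.std(), 0.1))
        logp_grad = _gaussian_logp_grad_factory(
            X, y_all, ind_idx, cell_idx, slices, prior_sd, spec.prior_sigma_sd, prior_only=prior_only
        )
        fit_rows = records.index
    else:
        pos = y_all > 0
        n0 = int(np.sum(~pos))
        n_pos = int(np.sum(pos))
        X_fit, ind_fit, cell_fit = X[pos], ind_idx[pos], cell_idx[pos]
        y_fit = y_all[pos]
        ybar = y_fit.mean() if n_pos else 0.5
        init[0] = np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0
        init[slices[tail]] = np.log(8.0)
        logp_grad = _zib_logp_grad_factory(
            X_fit, y_fit, ind_fit, cell_fit, slices, prior_sd, spec.prior_sigma_sd
        )
        # conjugate exact posterior for the zero-inflation probability
        rng_pi = np.random.default_rng(seed + 99)
        pi_draws = rng_pi.beta(1.0 + n0, 1.0 + n_pos, size=(n_chains, n_draws))
        fit_rows = records.index

    draws, info = sample_posterior(
        logp_grad,
        init,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        seed=seed,
        jitter=0.1,
    )
    param_names = list(meta.column_names)
    slices = {k: v for k, v in slices.items() if k != "__dim__"}
    return PosteriorFit(
        spec=spec,
        meta=meta,
        param_names=param_names,
        draws=draws,
        slices=slices,
        pi_draws=pi_draws,
        y=y_all,
        X=X,
        ind_idx=ind_idx,
        cell_idx=cell_idx,
        records_index=fit_rows,
        sampler_info=info,
    )


def posterior_predict(
    fit: PosteriorFit,
    records: pd.DataFrame,
    overrides: dict | None = None,
    scale: str = "natural",
) -> np.ndarray:
    """Per-record median posterior prediction of the conditional expectation.

    Gaussian models: the linear predictor is on the sqrt scale and is squared
    for ``scale='natural'`` (the default) or returned as-is for
    ``scale='sqrt'``.  ZIB models: (1 - pi) * mu.  Overrides neutralize
    named terms (see build_design); ``{'individual_id': '__new__'}`` or
    ``{'grid_cell_id': '__new__'}`` replace every level of that random effect
    with a novel one, whose effect is the population level, 0.
    """
    overrides = dict(overrides or {})
    new_ind = overrides.pop("individual_id", None) is not None
    new_cell = overrides.pop("grid_cell_id", None) is not None
    for term in overrides:
        if term not in fit.meta.fixed_terms:
            raise KeyError(f"override of unknown term {term!r}")
    records = records.reset_index(drop=True)
    X, _ = build_design(records, fit.spec, meta=fit.meta, overrides=overrides)
    if new_ind:
        ind_idx = np.full(len(records), -1)
    else:
        ind_idx, _ = _factorize(records["individual_id"], fit.meta.individual_levels)
    if new_cell:
        cell_idx = np.full(len(records), -1)
    else:
        cell_idx, _ = _factorize(records["grid_cell_id"], fit.meta.cell_levels)
    eta = fit.linear_predictor_draws(X, ind_idx, cell_idx)
    if fit.spec.family == "gaussian":
        pred = eta**2 if scale == "natural" else eta
    else:
        mu = expit(eta)
        pi = fit.pi_draws.reshape(-1, 1)
        pred = (1.0 - pi) * mu
    return np.median(pred, axis=0)
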