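"""Model fitting, diagnostics, holdout evaluation and posterior prediction.

``fit`` composes a joint log posterior (likelihood from the count/size
modules plus the sparsity and spatiotemporal priors) and samples it with
the package's NUTS engine — the default configuration is four chains of
1,000 iterations with the first 500 discarded as warmup — or, for quick
count-family screening, a mean-field variational approximation trained by
stochastic gradient ascent on the ELBO.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fire_extremes import count_models, size_models
from fire_extremes.design import DesignMatrix
from fire_extremes.inference.nuts import NutsConfig, nuts_chain
from fire_extremes.inference.posteriors import CountPosterior, SizePosterior


@dataclass
class PosteriorDraws:
    """Named posterior draws indexed (chain, iteration, ...)."""

    params: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.params.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite draws for parameter {name!r}")

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def stacked(self, name: str) -> np.ndarray:
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def subset(self, names) -> "PosteriorDraws":
        return PosteriorDraws({n: self.params[n] for n in names}, dict(self.meta))

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, arr in self.params.items():
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            pd.DataFrame(flat).to_csv(d / f"{name}.csv", index=False)
        shapes = {n: list(a.shape) for n, a in self.params.items()}
        with open(d / "meta.json", "w") as fh:
            json.dump({"shapes": shapes, "meta": _jsonable(self.meta)}, fh, indent=1)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        d = Path(directory)
        with open(d / "meta.json") as fh:
            payload = json.load(fh)
        params = {}
        for name, shape in payload["shapes"].items():
            flat = pd.read_csv(d / f"{name}.csv").to_numpy()
            params[name] = flat.reshape(shape)
        return cls(params, payload["meta"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def build_posterior(model_spec: dict, data: pd.DataFrame, design: DesignMatrix):
    """Construct the joint posterior object for a model specification.

    ``model_spec`` needs ``kind`` ('count' or 'size') and ``family``;
    optional keys: ``include_spacetime``, ``hierarchy``, and prior
    hyperparameters (p0, alpha_sd, delta_scale/aux_scale, y0).
    """
    spec = dict(model_spec)
    kind = spec.pop("kind")
    family = spec.pop("family")
    if kind == "count":
        include_st = spec.pop("include_spacetime", False)
        hierarchy = spec.pop("hierarchy", None)
        kwargs = {}
        if include_st:
            months = np.array(sorted(data["t"].unique()))
            kwargs["cell_region_index"] = np.array(
                [hierarchy.index_of(int(r)) for r in data["region"]]
            )
            kwargs["cell_time_index"] = np.searchsorted(months, data["t"].to_numpy())
        return CountPosterior(
            family,
            design,
            data["count"].to_numpy(),
            np.log(data["area_km2"].to_numpy()),
            hierarchy=hierarchy,
            include_spacetime=include_st,
            **kwargs,
            **spec,
        )
    if kind == "size":
        spec.pop("hierarchy", None)
        spec.pop("include_spacetime", None)
        return SizePosterior(family, design, data["exceedance_ha"].to_numpy(), **spec)
    raise ValueError(f"unknown model kind {kind!r}")


def fit(
    model_spec: dict,
    data: pd.DataFrame,
    design: DesignMatrix,
    method: str = "nuts",
    chains: int = 4,
    iterations: int = 1000,
    warmup: int = 500,
    seed: int = 0,
    target_accept: float = 0.9,
    max_treedepth: int = 10,
) -> PosteriorDraws:
    """Fit a count or size model; returns named posterior draws.

    ``iterations`` counts total transitions per chain, of which the first
    ``warmup`` are discarded (and used for adaptation).
    """
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    post = build_posterior(model_spec, data, design)
    kept = iterations - warmup
    seeds = np.random.SeedSequence(seed).spawn(chains)
    chains_out: list[list[dict]] = []
    sampler_stats = []
    if method == "nuts":
        cfg = NutsConfig(target_accept=target_accept, max_treedepth=max_treedepth)
        for ss in seeds:
            rng = np.random.default_rng(ss)
            x0 = post.initial(rng)
            draws_unc, stats = nuts_chain(post.logp_grad, x0, kept, warmup, rng, cfg)
            chains_out.append([post.unpack(x) for x in draws_unc])
            sampler_stats.append(
                {"divergences": stats.divergences, "step_size": stats.step_size}
            )
    elif method == "variational":
        rng = np.random.default_rng(seeds[0])
        m, log_s = _advi(post, rng)
        for ss in seeds:
            rng_c = np.random.default_rng(ss)
            eps = rng_c.normal(size=(kept, post.dim))
            chains_out.append([post.unpack(m + np.exp(log_s) * e) for e in eps])
        sampler_stats.append({"method": "advi"})
    else:
        raise ValueError(f"unknown method {method!r}; use 'nuts' or 'variational'")

    names = chains_out[0][0].keys()
    params = {
        name: np.stack(
            [np.stack([np.asarray(d[name]) for d in chain]) for chain in chains_out]
        )
        for name in names
    }
    meta = {
        "kind": model_spec["kind"],
        "family": model_spec["family"],
        "include_spacetime": bool(model_spec.get("include_spacetime", False)),
        "method": method,
        "seed": seed,
        "chains": chains,
        "iterations": iterations,
        "warmup": warmup,
        "sampler_stats": sampler_stats,
    }
    return PosteriorDraws(params, meta)


def _advi(post, rng, n_steps: int = 2000, n_mc: int = 4, lr: float = 0.02):
    """Mean-field Gaussian variational approximation (reparameterized)."""
    m = post.initial(rng)
    log_s = np.full(post.dim, -2.0)
    mom1 = np.zeros((2, post.dim))
    mom2 = np.zeros((2, post.dim))
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    for step in range(1, n_steps + 1):
        gm = np.zeros(post.dim)
        gs = np.zeros(post.dim)
        for _ in range(n_mc):
            e = rng.normal(size=post.dim)
            lp, g = post.logp_grad(m + np.exp(log_s) * e)
            if not np.isfinite(lp):
                continue
            gm += g
            gs += g * np.exp(log_s) * e
        gm /= n_mc
        gs = gs / n_mc + 1.0  # entropy gradient
        for i, grad in enumerate((gm, gs)):
            mom1[i] = b1 * mom1[i] + (1 - b1) * grad
            mom2[i] = b2 * mom2[i] + (1 - b2) * grad**2
        mhat = mom1 / (1 - b1**step)
        vhat = mom2 / (1 - b2**step)
        m = m + lr * mhat[0] / (np.sqrt(vhat[0]) + eps_adam)
        log_s = log_s + lr * mhat[1] / (np.sqrt(vhat[1]) + eps_adam)
    return m, log_s


# -- diagnostics -------------------------------------------------------------


def compute_rhat(draws: PosteriorDraws, names=None) -> dict[str, np.ndarray]:
    """Split-chain potential scale reduction statistic per scalar parameter.

    Each chain is split in half; R-hat is sqrt of (weighted within +
    between variance) over within variance. Values >= 1.1 (or undefined
    values from zero-variance chains, returned as NaN) indicate
    convergence failure.
    """
    if draws.n_chains < 2:
        raise ValueError("R-hat needs at least 2 chains")
    out = {}
    for name in names or draws.params:
        arr = draws.get(name)
        c, d = arr.shape[:2]
        half = d // 2
        split = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
        flat = split.reshape(2 * c, half, -1)
        with np.errstate(divide="ignore", invalid="ignore"):
            chain_means = flat.mean(axis=1)
            chain_vars = flat.var(axis=1, ddof=1)
            w = chain_vars.mean(axis=0)
            b = half * chain_means.var(axis=0, ddof=1)
            var_plus = (half - 1) / half * w + b / half
            rhat = np.sqrt(var_plus / w)
        out[name] = rhat.reshape(arr.shape[2:]) if arr.ndim > 2 else float(rhat[0])
    return out


def rhat_flags(rhats: dict[str, np.ndarray], threshold: float = 1.1) -> dict[str, bool]:
    """True where any component fails (R-hat >= threshold or undefined)."""
    out = {}
    for name, r in rhats.items():
        r = np.atleast_1d(np.asarray(r, dtype=float))
        out[name] = bool(np.any(~np.isfinite(r) | (r >= threshold)))
    return out


# -- holdout evaluation and posterior prediction -----------------------------


def _count_draw_predictors(draws, i, X, log_offset, st_extrapolate=None):
    family = draws.meta["family"]
    beta_mu = draws.stacked("beta_mu")[i]
    eta_mu = draws.stacked("alpha_mu")[i] + X @ beta_mu + log_offset
    if st_extrapolate is not None:
        eta_mu = eta_mu + st_extrapolate[i]
    mu = np.exp(eta_mu)
    pi = None
    if family in ("zip", "zinb"):
        from scipy.special import expit

        eta_pi = draws.stacked("alpha_pi")[i] + X @ draws.stacked("beta_pi")[i]
        pi = expit(eta_pi)
    delta = draws.stacked("delta")[i] if family in ("nb", "zinb") else None
    return mu, pi, delta


def holdout_loglik(
    draws: PosteriorDraws,
    test_data: pd.DataFrame,
    design_test: DesignMatrix,
) -> tuple[float, float]:
    """Posterior mean and sd of the summed test-set log likelihood."""
    kind = draws.meta["kind"]
    family = draws.meta["family"]
    X = design_test.X
    n_total = draws.n_chains * draws.n_draws
    lls = np.empty(n_total)
    if kind == "count":
        if draws.meta.get("include_spacetime"):
            raise NotImplementedError(
                "holdout evaluation with spatiotemporal effects requires "
                "AR extrapolation; fit with include_spacetime=False for "
                "holdout comparison"
            )
        n = test_data["count"].to_numpy()
        log_offset = np.log(test_data["area_km2"].to_numpy())
        for i in range(n_total):
            mu, pi, delta = _count_draw_predictors(draws, i, X, log_offset)
            lls[i] = float(np.sum(count_models.count_logpmf(family, n, mu, delta, pi)))
    elif kind == "size":
        y = test_data["exceedance_ha"].to_numpy()
        for i in range(n_total):
            eta = draws.stacked("alpha")[i] + X @ draws.stacked("beta")[i]
            loc = size_models.size_location(family, eta)
            aux = _aux_dict(family, draws.stacked("aux")[i])
            lls[i] = float(np.sum(size_models.size_logpdf(family, y, loc, aux)))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    sd = float(lls.std(ddof=1)) if n_total > 1 else 0.0
    return float(lls.mean()), sd


def _aux_dict(family: str, aux_value: float) -> dict[str, float]:
    key = {"lognormal": "sigma", "gamma": "shape", "weibull": "shape",
           "gpd_lomax": "shape", "tapered_pareto": "theta"}[family]
    return {key: float(aux_value)}


def posterior_predict(
    draws: PosteriorDraws,
    design: DesignMatrix,
    data: pd.DataFrame,
    seed: int = 0,
) -> np.ndarray:
    """Replicated data, one row per retained draw.

    Counts: an (n_draws_total, n_cells) integer array. Sizes: an
    (n_draws_total, n_events) array of exceedances for the given rows.
    """
    rng = np.random.default_rng(seed)
    kind = draws.meta["kind"]
    family = draws.meta["family"]
    X = design.X
    n_total = draws.n_chains * draws.n_draws
    if kind == "count":
        log_offset = np.log(data["area_km2"].to_numpy())
        out = np.empty((n_total, X.shape[0]), dtype=int)
        for i in range(n_total):
            mu, pi, delta = _count_draw_predictors(draws, i, X, log_offset)
            out[i] = count_models.count_rng(family, mu, delta, pi, seed=rng)
        return out
    if kind == "size":
        out = np.empty((n_total, X.shape[0]))
        for i in range(n_total):
            eta = draws.stacked("alpha")[i] + X @ draws.stacked("beta")[i]
            loc = size_models.size_location(family, eta)
            aux = _aux_dict(family, draws.stacked("aux")[i])
            out[i] = size_models.size_rng(family, loc, aux, seed=rng)
        return out
    raise ValueError(f"unknown model kind {kind!r}")


def size_location_draws(
    draws: PosteriorDraws, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw size-model location parameters for given rows.

    Returns (loc, aux) with loc of shape (n_draws_total, n_rows) — the
    bridge between a fitted size model and the extremes module.
    """
    family = draws.meta["family"]
    X = design.X
    n_total = draws.n_chains * draws.n_draws
    loc = np.empty((n_total, X.shape[0]))
    for i in range(n_total):
        eta = draws.stacked("alpha")[i] + X @ draws.stacked("beta")[i]
        loc[i] = size_models.size_location(family, eta)
    return loc, draws.stacked("aux")
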