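"""Exact samplers for the latent traits and for (accuracy, time) under each
model; the package's synthetic-data source.

Latents come either from the normal kernel or from the Kac-type distribution
g (grid-based inverse-CDF in one dimension; marginal-then-conditional
inverse-CDF on a tensor grid in two).  Observables are sampled from the
model-specific conditional laws: Bernoulli 2PL accuracies everywhere;
lognormal times (HM), truncated-exponential pseudo-times mapped back through
the pseudo-time involution (SM), and first-passage decision times by inverse
CDF of the gridded conditional time distribution (DM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .dm import (DMItem, SeriesSpec, dm_accuracy_marginal,
                 dm_curved_decomposition, wiener_series_factor_vec)
from .expfam import KernelSpec, LatentModel
from .hm import HMItem, HMKernel, hm_expfam_decomposition
from .quadrature import laplace_center
from .sm import SMItem, pseudo_inverse, sm_expfam_decomposition

__all__ = [
    "SimulationConfig",
    "ResponseTable",
    "sample_latents",
    "sample_hm",
    "sample_sm",
    "sample_dm",
    "dm_time_sampler_grid",
    "generate_dataset",
]

_GRID_NODES = 2048  # inverse-CDF latent grid nodes per dimension
_UNIFORM_RADIUS = 1e-4  # |theta + beta| below which the SM pseudo-time is uniform


@dataclass(frozen=True)
class SimulationConfig:
    model: str  # "hm" | "sm" | "dm"
    items: tuple
    kernel: object  # HMKernel for hm, KernelSpec for sm/dm
    n_persons: int
    seed: int
    latent_source: str = "kernel"  # "kernel" | "g"
    series: SeriesSpec = field(default_factory=SeriesSpec)

    def __post_init__(self):
        if self.model not in ("hm", "sm", "dm"):
            raise ValueError("model must be one of 'hm', 'sm', 'dm'")
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if self.latent_source not in ("kernel", "g"):
            raise ValueError("latent_source must be 'kernel' or 'g'")
        object.__setattr__(self, "items", tuple(self.items))

    def latent_model(self) -> LatentModel:
        if self.model == "hm":
            return hm_expfam_decomposition(self.items, self.kernel)
        if self.model == "sm":
            return sm_expfam_decomposition(self.items, self.kernel)
        return dm_curved_decomposition(self.items, self.kernel, self.series)


@dataclass
class ResponseTable:
    """Long-format responses: one row per person x item."""

    data: pd.DataFrame  # columns person_id, item_id, accuracy, time
    metadata: dict
    latents: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.9f")


def sample_latents(model: LatentModel, n: int, rng: np.random.Generator,
                   source: str = "kernel", grid_nodes: int = _GRID_NODES) -> np.ndarray:
    """Draw n latent vectors from the kernel or from g (grid inverse-CDF).

    For source="g" the grid spans the Laplace mode of g plus/minus 8 local
    SDs; an improper g raises ImproperLatentDistributionError before any
    draw is produced.
    """
    if source == "kernel":
        return model.kernel.rvs(n, rng)
    if source != "g":
        raise ValueError("source must be 'kernel' or 'g'")
    if not model.items:
        # g reduces exactly to the kernel when there are no items
        return model.kernel.rvs(n, rng)
    mode, cov = laplace_center(model.log_g_unnormalized, model.kernel.mean)
    sd = np.sqrt(np.diag(cov))
    if model.latent_dim == 1:
        grid = np.linspace(mode[0] - 8 * sd[0], mode[0] + 8 * sd[0], grid_nodes)
        logg = model.log_g_unnormalized(grid[:, None])
        pdf = np.exp(logg - logg.max())
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2)])
        cdf /= cdf[-1]
        u = rng.random(n)
        return np.interp(u, cdf, grid)[:, None]
    if model.latent_dim != 2:
        raise ValueError("g sampling is implemented for 1 or 2 latent dimensions")
    g0 = np.linspace(mode[0] - 8 * sd[0], mode[0] + 8 * sd[0], grid_nodes)
    g1 = np.linspace(mode[1] - 8 * sd[1], mode[1] + 8 * sd[1], grid_nodes)
    pts = np.column_stack([np.repeat(g0, grid_nodes), np.tile(g1, grid_nodes)])
    logg = model.log_g_unnormalized(pts).reshape(grid_nodes, grid_nodes)
    W = np.exp(logg - logg.max())
    # marginal of the first coordinate, then the conditional within its row
    marg0 = np.trapezoid(W, g1, axis=1)
    cdf0 = np.concatenate([[0.0], np.cumsum((marg0[1:] + marg0[:-1]) / 2)])
    cdf0 /= cdf0[-1]
    u0 = rng.random(n)
    z0 = np.interp(u0, cdf0, g0)
    rows = np.clip(np.searchsorted(g0, z0), 0, grid_nodes - 1)
    cdf1 = np.concatenate(
        [np.zeros((grid_nodes, 1)),
         np.cumsum((W[:, 1:] + W[:, :-1]) / 2, axis=1)], axis=1)
    cdf1 /= cdf1[:, -1][:, None]
    u1 = rng.random(n)
    z1 = np.empty(n)
    for row in np.unique(rows):
        sel = rows == row
        z1[sel] = np.interp(u1[sel], cdf1[row], g1)
    return np.column_stack([z0, z1])


def sample_hm(theta: float, eta: float, items: Sequence[HMItem],
              rng: np.random.Generator):
    """One person's (x, t): x ~ 2PL(theta) and ln t ~ N(xi - eta, 1/phi),
    independently given the latents."""
    a = np.array([it.alpha for it in items])
    b = np.array([it.beta for it in items])
    phi = np.array([it.phi for it in items])
    xi = np.array([it.xi for it in items])
    x = (rng.random(len(items)) < expit(a * (theta + b))).astype(int)
    u = rng.normal(xi - eta, 1.0 / np.sqrt(phi))
    return x, np.exp(u)


def _sm_pseudo_draw(lam: float, d: float, u: float) -> float:
    """Inverse CDF of the truncated exponential on (0, d) with rate lam."""
    if abs(lam) < _UNIFORM_RADIUS:
        return u * d
    return float(-np.log1p(-u * (-np.expm1(-d * lam))) / lam)


def sample_sm(theta: float, items: Sequence[SMItem], rng: np.random.Generator):
    """One person's (x, t): 2PL accuracy with discrimination d, truncated-
    exponential pseudo-time, then the pseudo-time involution back to t."""
    p = len(items)
    d = np.array([it.d for it in items])
    b = np.array([it.beta for it in items])
    x = (rng.random(p) < expit(d * (theta + b))).astype(int)
    u = rng.random(p)
    t_star = np.array([_sm_pseudo_draw(theta + bi, di, ui)
                       for bi, di, ui in zip(b, d, u)])
    # the involution maps boundary draws t*=0 back inside by a nudge
    t_star = np.clip(t_star, 1e-12 * d, (1 - 1e-12) * d)
    return x, pseudo_inverse(x, t_star, items)


@lru_cache(maxsize=64)
def _dm_grid_cached(theta: float, item: DMItem, spec: SeriesSpec, n_grid: int):
    lam = theta + item.beta
    rate = 0.5 * lam**2 + np.pi**2 / (2.0 * item.alpha**2)
    tau_min = 2e-4 * item.alpha**2  # below this the mass is ~exp(-alpha^2/8 tau)
    tau_max = max(60.0 / rate, 10.0 * tau_min)
    tau = np.linspace(tau_min, tau_max, n_grid)
    dens = np.exp(-0.5 * tau * lam**2) * wiener_series_factor_vec(tau, item.alpha, spec)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
    cdf /= cdf[-1]
    times = item.t_er + tau
    times.setflags(write=False)
    cdf.setflags(write=False)
    return times, cdf


def dm_time_sampler_grid(x: int, theta: float, item: DMItem,
                         spec: SeriesSpec | None = None, n_grid: int = 4096):
    """Gridded conditional time CDF for the DM given accuracy and ability.

    Returns (times, cdf) on a grid covering essentially all of the
    conditional mass; draws are produced by monotone-interpolation inversion
    (the root of the interpolated CDF).  The conditional density of the
    decision time is proportional to exp(-tau lam^2 / 2) * series(tau), the
    same for both accuracies, so the grid is cached on (theta, item).
    """
    spec = spec or SeriesSpec()
    return _dm_grid_cached(float(theta), item, spec, n_grid)


def sample_dm(theta: float, items: Sequence[DMItem], rng: np.random.Generator,
              spec: SeriesSpec | None = None):
    """One person's (x, t): Bernoulli 2PL accuracy, then the decision time
    from the inverse of the gridded conditional time CDF."""
    p = len(items)
    x = np.array([int(rng.random() < dm_accuracy_marginal(1, theta, it))
                  for it in items])
    t = np.empty(p)
    for j, it in enumerate(items):
        times, cdf = dm_time_sampler_grid(int(x[j]), theta, it, spec)
        t[j] = np.interp(rng.random(), cdf, times)
    return x, t


def generate_dataset(config: SimulationConfig) -> ResponseTable:
    """n_persons x n_items long-format dataset, deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    model = config.latent_model()
    latents = sample_latents(model, config.n_persons, rng,
                             source=config.latent_source)
    rows = []
    for pid in range(config.n_persons):
        if config.model == "hm":
            x, t = sample_hm(latents[pid, 0], latents[pid, 1], config.items, rng)
        elif config.model == "sm":
            x, t = sample_sm(latents[pid, 0], config.items, rng)
        else:
            x, t = sample_dm(latents[pid, 0], config.items, rng, config.series)
        for iid in range(len(config.items)):
            rows.append((pid, iid, int(x[iid]), float(t[iid])))
    data = pd.DataFrame(rows, columns=["person_id", "item_id", "accuracy", "time"])
    latent_cols = ["theta", "eta"] if config.model == "hm" else ["theta"]
    latent_df = pd.DataFrame(latents, columns=latent_cols)
    latent_df.insert(0, "person_id", np.arange(config.n_persons))
    metadata = {
        "model": config.model,
        "n_persons": config.n_persons,
        "n_items": len(config.items),
        "seed": config.seed,
        "latent_source": config.latent_source,
    }
    return ResponseTable(data=data, metadata=metadata, latents=latent_df)
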