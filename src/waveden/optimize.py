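"""Gaussian-process Bayesian optimization of the bilateral-filter triple.

The objective is the negative PSNR of the bilateral-filtered wavelet output
against the clean reference; minimizing it maximizes PSNR.  The loop follows
the classic design: a Latin-hypercube initial design, a GP surrogate with an
anisotropic Matern-5/2 kernel refit after every evaluation, and an
expected-improvement acquisition maximized by dense random candidate search.
The window diameter d is treated as a continuous surrogate dimension and
rounded to an integer at evaluation time; evaluated triples are cached so a
re-proposed duplicate never spends a second expensive objective computation.

Objective evaluations are the expensive unit (each one runs a full bilateral
filter), so the budget is exact: a run performs n_initial + iterations trace
steps and never computes the objective more often than that.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .bilateral import BilateralParams, bilateral
from .image import GrayImage
from .metrics import psnr
from .wavelet import WaveletSpec, wavelet_denoise

__all__ = [
    "SearchSpace",
    "OptimizationTrace",
    "SurrogateModel",
    "objective",
    "expected_improvement",
    "fit_surrogate",
    "propose_next",
    "minimize",
    "optimize",
]

# finite stand-in for -PSNR when the filtered image matches the reference exactly
PSNR_CAP_DB = 200.0

_N_CANDIDATES = 2048


@dataclass(frozen=True)
class SearchSpace:
    """Box bounds for (d, sigma_color, sigma_space).

    Defaults cover the operating range of the method on 8-bit medical
    images: window diameters 3-9 px, colour sigma 10-150 (8-bit intensity
    units), spatial sigma 1-15 px.
    """

    d_range: tuple[int, int] = (3, 9)
    sigma_color_range: tuple[float, float] = (10.0, 150.0)
    sigma_space_range: tuple[float, float] = (1.0, 15.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.d_range, self.sigma_color_range, self.sigma_space_range):
            if not lo < hi:
                raise ValueError("each range must satisfy lower < upper")

    @property
    def _bounds(self) -> np.ndarray:
        return np.array([self.d_range, self.sigma_color_range, self.sigma_space_range], dtype=float)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map points in [0,1]^3 to (d, sigma_color, sigma_space) coordinates."""
        b = self._bounds
        return b[:, 0] + np.asarray(u) * (b[:, 1] - b[:, 0])

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        b = self._bounds
        return (np.asarray(x, dtype=float) - b[:, 0]) / (b[:, 1] - b[:, 0])

    def params_at(self, u: np.ndarray) -> BilateralParams:
        """Concrete parameters at a unit-cube point, with d rounded."""
        d, sc, ss = self.from_unit(u)
        return BilateralParams(d=int(round(d)), sigma_color=float(sc), sigma_space=float(ss))


@dataclass
class OptimizationTrace:
    """Every evaluation in order, plus the best-so-far after each step."""

    evaluations: list[tuple[BilateralParams, float]] = field(default_factory=list)
    incumbents: list[tuple[BilateralParams, float]] = field(default_factory=list)
    n_initial: int = 0
    seed: int = 0
    space: SearchSpace = field(default_factory=SearchSpace)
    #: continuous unit-cube coordinates of each evaluation (surrogate inputs)
    unit_coords: list[np.ndarray] = field(default_factory=list)

    def record(self, u: np.ndarray, params: BilateralParams, value: float) -> None:
        self.evaluations.append((params, value))
        self.unit_coords.append(np.asarray(u, dtype=float))
        if not self.incumbents or value < self.incumbents[-1][1]:
            self.incumbents.append((params, value))
        else:
            self.incumbents.append(self.incumbents[-1])

    @property
    def best_params(self) -> BilateralParams:
        return self.incumbents[-1][0]

    @property
    def best_value(self) -> float:
        return self.incumbents[-1][1]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_initial": self.n_initial,
            "evaluations": [
                {"d": p.d, "sigma_color": p.sigma_color, "sigma_space": p.sigma_space, "objective": v}
                for p, v in self.evaluations
            ],
            "incumbent": {
                "d": self.best_params.d,
                "sigma_color": self.best_params.sigma_color,
                "sigma_space": self.best_params.sigma_space,
                "objective": self.best_value,
            },
        }


@dataclass
class SurrogateModel:
    """Fitted GP over the unit cube together with its training targets."""

    gp: GaussianProcessRegressor
    space: SearchSpace
    y_train: np.ndarray

    @property
    def f_best(self) -> float:
        return float(np.min(self.y_train))

    def predict(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mu, sd = self.gp.predict(np.atleast_2d(u), return_std=True)
        return mu, sd


def objective(clean: GrayImage, wavelet_out: GrayImage, p: BilateralParams) -> float:
    """Negative PSNR of the bilateral-filtered image against the reference.

    A perfect match (infinite PSNR) is mapped to -PSNR_CAP_DB so the value
    stays finite for the surrogate.
    """
    val = psnr(clean, bilateral(wavelet_out, p))
    if math.isinf(val):
        return -PSNR_CAP_DB
    return -val


def expected_improvement(
    mu: np.ndarray | float, sd: np.ndarray | float, f_best: float
) -> np.ndarray | float:
    """Closed-form EI for minimization: E[max(f_best - f(x), 0)].

    (f_best - mu) Phi(z) + sd phi(z) with z = (f_best - mu)/sd for sd > 0;
    max(f_best - mu, 0) at sd = 0.  Always non-negative.
    """
    mu_arr = np.asarray(mu, dtype=float)
    sd_arr = np.asarray(sd, dtype=float)
    if np.any(sd_arr < 0):
        raise ValueError("sd must be non-negative")
    imp = f_best - mu_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd_arr > 0, imp / np.where(sd_arr > 0, sd_arr, 1.0), 0.0)
        ei = np.where(
            sd_arr > 0,
            imp * norm.cdf(z) + sd_arr * norm.pdf(z),
            np.maximum(imp, 0.0),
        )
    ei = np.maximum(ei, 0.0)
    return float(ei) if np.isscalar(mu) and np.isscalar(sd) else ei


def fit_surrogate(trace: OptimizationTrace, random_state: int = 0) -> SurrogateModel:
    """Fit the GP surrogate to every evaluation in the trace.

    Kernel: constant * anisotropic Matern(nu=2.5) with per-dimension length
    scales, hyperparameters by marginal-likelihood maximization with one
    restart; targets are normalized and a 1e-6 diagonal jitter keeps the
    Cholesky well conditioned (the objective itself is deterministic).
    """
    if len(trace.evaluations) < 2:
        raise ValueError("need at least 2 evaluations to fit a surrogate")
    X = np.vstack(trace.unit_coords)
    y = np.array([v for _, v in trace.evaluations], dtype=float)
    if np.allclose(X, X[0]):
        raise ValueError(
            "all surrogate inputs are identical; evaluate at least two distinct "
            "parameter settings before fitting"
        )
    kernel = ConstantKernel(1.0, (1e-4, 1e6)) * Matern(
        length_scale=[0.3, 0.3, 0.3], length_scale_bounds=(1e-2, 1e2), nu=2.5
    )
    gp = GaussianProcessRegressor(
        kernel=kernel,
        alpha=1e-6,
        normalize_y=True,
        n_restarts_optimizer=1,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gp.fit(X, y)
    return SurrogateModel(gp=gp, space=trace.space, y_train=y)


def propose_next(model: SurrogateModel, space: SearchSpace, seed: int) -> BilateralParams:
    """Maximize EI over a dense random candidate set; deterministic per seed.

    If EI vanishes everywhere (a fully exploited surrogate), fall back to
    the candidate with the largest predictive standard deviation so the
    search keeps exploring.
    """
    u = _propose_unit(model, seed)
    return space.params_at(u)


def _propose_unit(model: SurrogateModel, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    cand = rng.uniform(size=(_N_CANDIDATES, 3))
    mu, sd = model.predict(cand)
    ei = expected_improvement(mu, sd, model.f_best)
    if np.max(ei) <= 1e-12:
        return cand[int(np.argmax(sd))]
    return cand[int(np.argmax(ei))]


def minimize(
    func: Callable[[BilateralParams], float],
    space: SearchSpace,
    iterations: int,
    n_initial: int = 10,
    seed: int = 0,
    early_stop: bool = False,
    early_stop_tol: float = 1e-3,
    early_stop_patience: int = 15,
) -> OptimizationTrace:
    """Run the init -> fit -> acquire -> evaluate loop on an arbitrary objective.

    ``func`` maps a :class:`BilateralParams` triple to the value to minimize.
    The trace contains exactly n_initial + iterations evaluations (fewer only
    if early stopping is enabled and triggers).  Duplicate triples are served
    from a cache; they still occupy a trace slot but cost no recomputation.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if n_initial < 2:
        raise ValueError("n_initial must be >= 2")
    trace = OptimizationTrace(n_initial=n_initial, seed=seed, space=space)
    cache: dict[tuple[int, float, float], float] = {}

    def spend(u: np.ndarray) -> None:
        p = space.params_at(u)
        key = (p.d, round(p.sigma_color, 12), round(p.sigma_space, 12))
        if key not in cache:
            cache[key] = float(func(p))
        trace.record(u, p, cache[key])

    sampler = qmc.LatinHypercube(d=3, seed=seed)
    for u in sampler.random(n_initial):
        spend(u)

    stall = 0
    for it in range(iterations):
        model = fit_surrogate(trace, random_state=seed)
        before = trace.best_value
        u = _propose_unit(model, seed=seed + 1 + it)
        spend(u)
        if early_stop:
            stall = stall + 1 if before - trace.best_value < early_stop_tol else 0
            if stall >= early_stop_patience:
                break
    return trace


def optimize(
    clean: GrayImage,
    noisy: GrayImage,
    space: SearchSpace = SearchSpace(),
    iterations: int = 100,
    n_initial: int = 10,
    seed: int = 0,
    wavelet_spec: WaveletSpec = WaveletSpec(),
    early_stop: bool = False,
) -> OptimizationTrace:
    """Tune the bilateral triple for one image against its clean reference.

    The wavelet stage runs once on the noisy image; every objective
    evaluation then filters that fixed intermediate with candidate
    parameters and scores -PSNR against the clean reference.
    """
    wavelet_out, _ = wavelet_denoise(noisy, wavelet_spec)

    def func(p: BilateralParams) -> float:
        return objective(clean, wavelet_out, p)

    return minimize(
        func, space, iterations=iterations, n_initial=n_initial, seed=seed, early_stop=early_stop
    )
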