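"""Gaussian-process Bayesian optimization of model/training hyper-parameters.

The search space covers, at minimum, the number of graph-convolution layers,
the number of post-gather dense layers, the dropout rate, and the learning
rate.  Optimization proceeds as ``n_initial`` quasi-random (Sobol) seeded
evaluations followed by ``n_iterations`` acquisition-driven evaluations: a
GP surrogate (Matern 5/2 kernel) is fitted to the observed objective values
in the unit cube and the next point maximizes expected improvement over a
random candidate set.  Integer and categorical dimensions are handled by
continuous relaxation and rounding.  Failed trials are recorded and enter
the surrogate at a penalty value (worst observed minus one margin); the
``penalized`` flag distinguishes real from penalty objectives.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .chemio import GraphDataset
from .errors import OptimizationError, SpecError
from .gcncore import ModelSpec, TrainConfig, default_model_spec, run_cross_validation


@dataclass
class Dimension:
    """One axis of the search space."""

    name: str
    kind: str  # integer | real | log-real | categorical
    bounds: tuple[float, float] | None = None
    choices: list | None = None

    def __post_init__(self):
        if self.kind in ("integer", "real", "log-real"):
            if self.bounds is None or not (self.bounds[0] < self.bounds[1]):
                raise SpecError(f"dimension {self.name!r} needs finite ordered bounds")
            if self.kind == "log-real" and self.bounds[0] <= 0:
                raise SpecError(f"log-real dimension {self.name!r} needs positive bounds")
        elif self.kind == "categorical":
            if not self.choices:
                raise SpecError(f"categorical dimension {self.name!r} needs choices")
        else:
            raise SpecError(f"unknown dimension kind {self.kind!r}")

    def from_unit(self, u: float):
        """Map a unit-interval coordinate to a point on this axis."""
        u = min(max(u, 0.0), 1.0)
        if self.kind == "real":
            lo, hi = self.bounds
            return lo + u * (hi - lo)
        if self.kind == "log-real":
            lo, hi = math.log(self.bounds[0]), math.log(self.bounds[1])
            return math.exp(lo + u * (hi - lo))
        if self.kind == "integer":
            lo, hi = self.bounds
            return int(min(hi, math.floor(lo + u * (hi - lo + 1))))
        idx = int(min(len(self.choices) - 1, math.floor(u * len(self.choices))))
        return self.choices[idx]


@dataclass
class HyperparamSpace:
    dimensions: list[Dimension]

    def __post_init__(self):
        if not self.dimensions:
            raise SpecError("search space needs at least one dimension")

    def decode(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(float(u[i])) for i, d in enumerate(self.dimensions)}

    @classmethod
    def default(cls) -> "HyperparamSpace":
        return cls([
            Dimension("n_conv_layers", "integer", (1, 3)),
            Dimension("n_dense_layers", "integer", (0, 2)),
            Dimension("dropout_rate", "real", (0.0, 0.5)),
            Dimension("learning_rate", "log-real", (1e-4, 1e-1)),
        ])

    @classmethod
    def from_dict(cls, d: dict) -> "HyperparamSpace":
        dims = []
        for spec in d["dimensions"]:
            dims.append(Dimension(
                name=spec["name"], kind=spec["kind"],
                bounds=tuple(spec["bounds"]) if spec.get("bounds") else None,
                choices=spec.get("choices"),
            ))
        return cls(dims)


@dataclass
class TrialRecord:
    """One evaluated configuration in the optimization history."""

    params: dict
    objective: float | None
    status: str  # ok | failed
    seed: int
    unit_point: list[float] = field(default_factory=list)
    penalized: bool = False

    def to_dict(self) -> dict:
        return {
            "params": self.params,
            "objective": self.objective,
            "status": self.status,
            "seed": self.seed,
            "penalized": self.penalized,
        }


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float,
                          jitter: float = 0.01) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    imp = mu - best - jitter
    z = imp / sigma
    return imp * norm.cdf(z) + sigma * norm.pdf(z)


def bayesian_optimize(
    objective,
    space: HyperparamSpace,
    n_initial: int = 5,
    n_iterations: int = 15,
    seed: int = 0,
    n_candidates: int = 512,
) -> tuple[TrialRecord, list[TrialRecord]]:
    """Maximize ``objective`` over ``space``; returns (best trial, history).

    ``objective`` receives a decoded parameter dict; raising an exception or
    returning a non-finite value marks the trial failed.  The whole run is
    deterministic given ``seed``.
    """
    if n_initial < 2:
        raise SpecError("n_initial must be >= 2")
    if n_iterations < 0:
        raise SpecError("n_iterations must be >= 0")
    rng = np.random.default_rng(seed)
    d = len(space.dimensions)
    sobol = qmc.Sobol(d, scramble=True, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-2 draw is fine here
        unit_points = list(sobol.random(n_initial))

    history: list[TrialRecord] = []

    def run_trial(u: np.ndarray) -> TrialRecord:
        params = space.decode(u)
        try:
            val = float(objective(params))
            if not np.isfinite(val):
                raise ValueError("non-finite objective")
            rec = TrialRecord(params, val, "ok", seed, [float(x) for x in u])
        except Exception:
            rec = TrialRecord(params, None, "failed", seed, [float(x) for x in u])
        history.append(rec)
        return rec

    for u in unit_points:
        run_trial(np.asarray(u))

    for _ in range(n_iterations):
        ok = [t for t in history if t.status == "ok"]
        if ok:
            worst = min(t.objective for t in ok)
            best = max(t.objective for t in ok)
            xs = np.array([t.unit_point for t in history])
            ys = np.array([t.objective if t.status == "ok" else worst - 1.0 for t in history])
            kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                      * Matern(length_scale=np.full(d, 0.3), nu=2.5,
                               length_scale_bounds=(1e-2, 1e2))
                      + WhiteKernel(1e-6, (1e-10, 1e-1)))
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          n_restarts_optimizer=1, random_state=seed)
            with warnings.catch_warnings():
                # hyper-parameters at a bound are acceptable for the surrogate
                warnings.simplefilter("ignore")
                gp.fit(xs, ys)
            cand = rng.random((n_candidates, d))
            # densify around the incumbent
            inc = np.array(max(ok, key=lambda t: t.objective).unit_point)
            local = np.clip(inc + rng.normal(0, 0.05, (n_candidates // 4, d)), 0, 1)
            cand = np.vstack([cand, local])
            mu, sigma = gp.predict(cand, return_std=True)
            next_u = cand[int(np.argmax(_expected_improvement(mu, sigma, best)))]
        else:
            next_u = rng.random(d)
        run_trial(next_u)

    ok = [t for t in history if t.status == "ok"]
    if not ok:
        raise OptimizationError("all trials failed")
    return max(ok, key=lambda t: t.objective), history


def make_cv_objective(
    spec_template,
    data: GraphDataset,
    k: int = 5,
    config: TrainConfig | None = None,
    seed: int = 0,
):
    """Bind a hyper-parameter point to a cross-validated mean ROC-AUC.

    ``spec_template`` is either a callable ``params -> (ModelSpec,
    TrainConfig)`` or None, in which case the default architecture template
    is used: ``n_conv_layers`` / ``n_dense_layers`` shape the spec and
    ``dropout_rate`` / ``learning_rate`` enter the training config.
    """
    base = config or TrainConfig()

    def default_template(params: dict) -> tuple[ModelSpec, TrainConfig]:
        spec = default_model_spec(
            n_tasks=data.n_tasks,
            n_conv_layers=int(params.get("n_conv_layers", 1)),
            n_dense_layers=int(params.get("n_dense_layers", 0)),
            seed=seed,
        )
        cfg = TrainConfig(
            epochs=base.epochs,
            batch_size=base.batch_size,
            learning_rate=float(params.get("learning_rate", base.learning_rate)),
            dropout_rate=float(params.get("dropout_rate", base.dropout_rate)),
            seed=base.seed,
        )
        return spec, cfg

    template = spec_template or default_template

    def objective(params: dict) -> float:
        spec, cfg = template(params)
        report = run_cross_validation(spec, data, k, cfg, seed=seed)
        if report["mean_auc"] is None:
            raise OptimizationError("AUC undefined for every task")
        return float(report["mean_auc"])

    return objective
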