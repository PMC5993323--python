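"""Benchmark orchestration: method registry, condition grid and reports.

The benchmark runs every registered TVC estimator on every configured
simulation condition and scores them (Simulation 1 by method similarity,
Simulations 2-4 by the Bayesian tracking model and WAIC).  User methods
plug in through :func:`register_method` with the contract

    callable(values: (T, 2) ndarray, **params) -> TVCSeries
                                               | (estimate, valid_mask)

and are benchmarked alongside the built-ins.
"""

from __future__ import annotations

import traceback
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import simgen
from .evalstats import (
    ModelComparison,
    SimilarityMatrix,
    TrackingModelSpec,
    compare_models,
    fit_tracking_model,
    method_similarity,
    posterior_summary,
)
from .methods import (
    TVCSeries,
    WindowSpec,
    common_valid_mask,
    fisher_transform,
    jackknife_correlation,
    mtd,
    sliding_window,
    spatial_distance_tvc,
    standardize,
    tapered_sliding_window,
)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkReport",
    "ConditionResult",
    "ContractViolationError",
    "register_method",
    "registered_methods",
    "get_method",
    "run_method",
    "run_benchmark",
    "scale_config",
    "DEFAULT_METHODS",
    "VERSION_TAG",
]

VERSION_TAG = "simulation routine V1.0"

#: Taper width (Gaussian SD, in time points) of the built-in tapered windows.
DEFAULT_TAPER_STD = 10.0


class ContractViolationError(ValueError):
    """A candidate method failed the plugin smoke test; the message names
    the failing check."""


@dataclass(frozen=True)
class _MethodEntry:
    name: str
    func: object
    params: dict
    builtin: bool = False


_REGISTRY: dict[str, _MethodEntry] = {}


def _smoke_fixture() -> np.ndarray:
    rng = np.random.default_rng(0)
    return rng.standard_normal((100, 2))


def _coerce_series(result, T: int, name: str) -> TVCSeries:
    if isinstance(result, TVCSeries):
        series = result
    else:
        try:
            estimate, valid = result
        except Exception:
            raise ContractViolationError(
                f"{name}: result is neither a TVCSeries nor an "
                "(estimate, valid) pair")
        series = TVCSeries(np.asarray(estimate, float),
                           np.asarray(valid, bool), method=name)
    if series.T != T:
        raise ContractViolationError(
            f"{name}: estimate length {series.T} != series length {T}")
    if not series.valid.any():
        raise ContractViolationError(f"{name}: no valid time points")
    return series


def register_method(name: str, func, params: dict | None = None,
                    overwrite: bool = False, _builtin: bool = False) -> None:
    """Register a TVC method; it is smoke-tested on a 100-point fixture."""
    if name in _REGISTRY and not overwrite:
        raise ValueError(f"method name '{name}' already registered")
    params = dict(params or {})
    fixture = _smoke_fixture()
    try:
        result = func(fixture, **params)
    except Exception as exc:
        raise ContractViolationError(
            f"{name}: raised {type(exc).__name__} on the smoke fixture: {exc}"
        ) from exc
    _coerce_series(result, fixture.shape[0], name)
    _REGISTRY[name] = _MethodEntry(name=name, func=func, params=params,
                                   builtin=_builtin)


def registered_methods() -> list[str]:
    return list(_REGISTRY)


def get_method(name: str) -> _MethodEntry:
    if name not in _REGISTRY:
        raise KeyError(f"unknown method '{name}'; registered: {registered_methods()}")
    return _REGISTRY[name]


def run_method(name: str, values: np.ndarray) -> TVCSeries:
    """Apply a registered method to a (T, 2) matrix."""
    entry = get_method(name)
    result = entry.func(np.asarray(values, float), **entry.params)
    series = _coerce_series(result, values.shape[0], name)
    if series.method != name:
        series = replace(series, method=name)
    return series


# Built-in estimators ------------------------------------------------------

def _register_builtins() -> None:
    register_method("SW-15", lambda v: sliding_window(v, WindowSpec(15)),
                    _builtin=True)
    register_method("SW-29", lambda v: sliding_window(v, WindowSpec(29)),
                    _builtin=True)
    register_method(
        "TSW-15",
        lambda v: tapered_sliding_window(v, WindowSpec(15, taper_std=DEFAULT_TAPER_STD)),
        _builtin=True)
    register_method(
        "TSW-29",
        lambda v: tapered_sliding_window(v, WindowSpec(29, taper_std=DEFAULT_TAPER_STD)),
        _builtin=True)
    register_method("SD", lambda v: spatial_distance_tvc(v, mode="bivariate"),
                    _builtin=True)
    register_method("JC", jackknife_correlation, _builtin=True)
    register_method("MTD-7", lambda v: mtd(v, smooth_window=7), _builtin=True)


_register_builtins()

DEFAULT_METHODS = ("SW-15", "SW-29", "TSW-15", "TSW-29", "SD", "JC", "MTD-7")


# Configuration ------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkConfig:
    """Full benchmark condition grid (defaults are the study conditions)."""

    simulations: tuple = (1, 2, 3, 4)
    T: int = 10_000
    master_seed: int = 0
    methods: tuple = DEFAULT_METHODS
    sim1_alpha: float = 0.8
    sim1_cov: float = 0.5
    sim2_alphas: tuple = (0.0, 0.25, 0.5)
    sim2_sigmas: tuple = (0.08, 0.1, 0.12)
    sim3_alphas: tuple = (0.0, 0.25, 0.5)
    sim3_sigma: float = 0.1
    sim4_conditions: tuple = ("fast", "slow")
    sim4_sigma: float = 0.1
    mcmc: TrackingModelSpec = field(default_factory=TrackingModelSpec)

    def __post_init__(self):
        if not set(self.simulations) <= {1, 2, 3, 4}:
            raise ValueError("simulations must be a subset of {1, 2, 3, 4}")
        if not self.methods:
            raise ValueError("need at least one method")
        for m in self.methods:
            get_method(m)

    def conditions(self) -> list[dict]:
        out = []
        if 1 in self.simulations:
            out.append({"sim": 1, "alpha": self.sim1_alpha, "cov": self.sim1_cov})
        if 2 in self.simulations:
            for a in self.sim2_alphas:
                for s in self.sim2_sigmas:
                    out.append({"sim": 2, "alpha_r": a, "sigma_r": s})
        if 3 in self.simulations:
            for a in self.sim3_alphas:
                out.append({"sim": 3, "alpha_r": a, "sigma_r": self.sim3_sigma})
        if 4 in self.simulations:
            for c in self.sim4_conditions:
                out.append({"sim": 4, "condition": c, "sigma_r": self.sim4_sigma})
        return out

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mcmc = raw.pop("mcmc", None)
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        if mcmc is not None:
            kwargs["mcmc"] = TrackingModelSpec(**mcmc)
        return cls(**kwargs)


def scale_config(config: BenchmarkConfig, T_small: int,
                 draws_small: int | None = None) -> BenchmarkConfig:
    """Reduced-size copy of a configuration for quick runs.

    Window edges and masks are recomputed consistently downstream; only
    the problem sizes change, never the grids or the method set.
    """
    if T_small < 200:
        raise ValueError("T_small must be >= 200")
    largest = max((get_method(m).params.get("length", 0) for m in config.methods),
                  default=0)
    largest = max(largest, 29)
    if T_small <= largest:
        raise ValueError("T_small must exceed the largest window")
    mcmc = config.mcmc
    if draws_small is not None:
        burn = max(100, draws_small // 5)
        if burn >= draws_small:
            raise ValueError("draws_small too small")
        mcmc = replace(mcmc, draws=draws_small, burn=burn)
    return replace(config, T=T_small, mcmc=mcmc)


# Running ------------------------------------------------------------------


@dataclass
class ConditionResult:
    sim: int
    params: dict
    seed_entropy: list
    n_mask: int = 0
    similarity: SimilarityMatrix | None = None
    comparison: ModelComparison | None = None
    posterior: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    failures: dict = field(default_factory=dict)


@dataclass
class BenchmarkReport:
    version: str
    config: BenchmarkConfig
    conditions: list

    def to_dict(self) -> dict:
        out = {"version": self.version,
               "config": _config_dict(self.config),
               "conditions": []}
        for cond in self.conditions:
            entry = {
                "sim": cond.sim,
                "params": cond.params,
                "seed_entropy": cond.seed_entropy,
                "n_mask": int(cond.n_mask),
                "similarity": None,
                "waic_table": None,
                "posterior": [
                    {"method": m, **vars(s)} for m, s in cond.posterior.items()
                ],
                "diagnostics": cond.diagnostics,
                "failures": cond.failures,
            }
            if cond.similarity is not None:
                entry["similarity"] = {
                    "methods": list(cond.similarity.table.index),
                    "matrix": cond.similarity.table.to_numpy().tolist(),
                }
            if cond.comparison is not None:
                df = cond.comparison.table
                entry["waic_table"] = [
                    {"method": m,
                     "waic": float(row["waic"]),
                     "waic_se": float(row["waic_se"]),
                     "delta_waic": float(row["delta_waic"])}
                    for m, row in df.iterrows()
                ]
            out["conditions"].append(entry)
        return out


def _config_dict(config: BenchmarkConfig) -> dict:
    d = {k: v for k, v in vars(config).items() if k != "mcmc"}
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    d["mcmc"] = {k: v for k, v in vars(config.mcmc).items()}
    return d


def _condition_seed(config: BenchmarkConfig, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=config.master_seed, spawn_key=(index,))


def generate_condition(config: BenchmarkConfig, cond: dict,
                       seed) -> simgen.SimulatedDataset:
    sim = cond["sim"]
    if sim == 1:
        return simgen.simulate_sim1(config.T, cond["alpha"], cond["cov"], seed)
    if sim == 2:
        return simgen.simulate_sim2(config.T, sigma_r=cond["sigma_r"],
                                    alpha_r=cond["alpha_r"], seed=seed)
    if sim == 3:
        return simgen.simulate_sim3(config.T, sigma_r=cond["sigma_r"],
                                    alpha_r=cond["alpha_r"], seed=seed)
    if sim == 4:
        return simgen.simulate_sim4(config.T, condition=cond["condition"],
                                    sigma_r=cond["sigma_r"], seed=seed)
    raise ValueError(f"unknown simulation id {sim}")


def run_condition(config: BenchmarkConfig, cond: dict, index: int) -> ConditionResult:
    seed_seq = _condition_seed(config, index)
    data_rng = np.random.default_rng(seed_seq)
    ds = generate_condition(config, cond, data_rng)
    result = ConditionResult(sim=cond["sim"],
                             params={k: v for k, v in cond.items() if k != "sim"},
                             seed_entropy=[config.master_seed, index])

    series: dict[str, TVCSeries] = {}
    for name in config.methods:
        try:
            series[name] = run_method(name, ds.pair.values)
        except Exception as exc:
            result.failures[name] = f"{type(exc).__name__}: {exc}"
    if not series:
        return result

    mask = common_valid_mask(series.values())
    result.n_mask = int(mask.sum())

    transformed = {
        name: (fisher_transform(s) if s.correlation_scale else s)
        for name, s in series.items()
    }

    if cond["sim"] == 1:
        # raw (unstandardized) series; Spearman is rank-invariant anyway
        result.similarity = method_similarity(transformed, mask)
        return result

    y_raw = ds.truth.r[mask]
    y = (y_raw - y_raw.mean()) / y_raw.std()
    fits = {}
    mcmc_seed_root = np.random.SeedSequence(entropy=config.master_seed,
                                            spawn_key=(index, 1))
    mcmc_seeds = mcmc_seed_root.spawn(len(transformed))
    for k, (name, s) in enumerate(transformed.items()):
        try:
            zs = standardize(s, mask)
            x = zs.masked(mask)
            spec = replace(config.mcmc,
                           seed=int(mcmc_seeds[k].generate_state(1)[0] // 2))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = fit_tracking_model(x, y, spec)
            fits[name] = fit
            result.posterior[name] = posterior_summary(fit)
            result.diagnostics[name] = {
                **{k2: v for k2, v in fit.diagnostics.items() if k2 != "step_sizes"},
                "warnings": [str(w.message) for w in caught],
            }
        except Exception as exc:
            result.failures[name] = f"{type(exc).__name__}: {exc}"
            if __debug__:
                result.diagnostics.setdefault("_tracebacks", {})[name] = (
                    traceback.format_exc(limit=3))
    if len(fits) >= 2:
        result.comparison = compare_models(fits)
    return result


def run_benchmark(config: BenchmarkConfig | None = None) -> BenchmarkReport:
    """Run every configured condition; deterministic given the master seed.

    Per-method failures are isolated into the report's ``failures`` field
    rather than aborting the run.
    """
    config = config or BenchmarkConfig()
    results = [run_condition(config, cond, i)
               for i, cond in enumerate(config.conditions())]
    return BenchmarkReport(version=VERSION_TAG, config=config, conditions=results)
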