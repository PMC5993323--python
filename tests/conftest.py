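import numpy as np
import pytest

import tvcbench
from tvcbench.bench import run_method
from tvcbench.evalstats import TrackingModelSpec, fit_tracking_model, waic
from tvcbench.methods import common_valid_mask, fisher_transform, standardize


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sim1_small():
    """A short constant-covariance AR(1) pair shared across method tests."""
    return tvcbench.simulate_sim1(T=2000, seed=7)


def tracking_waic(ds, method_name, mcmc_spec=None, mask_methods=("SW-29",)):
    """End-to-end score of one method on one dataset: run the estimator,
    Fisher-transform if applicable, standardize over the common mask set by
    the widest window, fit the tracking model and return (waic, fit)."""
    series = run_method(method_name, ds.pair.values)
    maskers = [series] + [run_method(m, ds.pair.values) for m in mask_methods]
    mask = common_valid_mask(maskers)
    z = fisher_transform(series) if series.correlation_scale else series
    x = standardize(z, mask).masked(mask)
    y = ds.truth.r[mask]
    y = (y - y.mean()) / y.std()
    spec = mcmc_spec or TrackingModelSpec(seed=0)
    fit = fit_tracking_model(x, y, spec)
    return waic(fit), fit


def condition_waics(ds, methods, mcmc_spec):
    """WAIC per method for one dataset, sharing the common mask and y."""
    series = {m: run_method(m, ds.pair.values) for m in methods}
    mask = common_valid_mask(series.values())
    y = ds.truth.r[mask]
    y = (y - y.mean()) / y.std()
    out = {}
    for name, s in series.items():
        z = fisher_transform(s) if s.correlation_scale else s
        x = standardize(z, mask).masked(mask)
        fit = fit_tracking_model(x, y, mcmc_spec)
        out[name] = waic(fit)
    return out
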