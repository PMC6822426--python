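import numpy as np
import pandas as pd
import pytest

from basketpls import curation
from basketpls.datatypes import FeatureMatrix, ResponseVector
from basketpls.opls import fit_opls
from basketpls.simulate import default_spec, generate_rppa_like


def curate(x, y, detection=0.25):
    """Standard curation chain used across tests."""
    x, y = curation.intersect_datasets(x, y)
    x = curation.filter_by_detection(x, detection)
    x = curation.impute_missing(x)
    scaled, params = curation.autoscale(x)
    return scaled, params, y


def make_linear_dataset(n=21, p=5, seed=0, noise_sd=0.0, latent=False):
    """Linear response on a random matrix, rescaled into the AUC range.

    With ``latent=True`` the matrix carries a single latent direction
    (X = t v' + noise, y affine in t), the regime a one-component
    projection model captures exactly. The affine rescaling of y keeps
    linear-model comparisons intact.
    """
    rng = np.random.default_rng(seed)
    if latent:
        t = rng.standard_normal(n)
        v = rng.uniform(0.5, 1.5, size=p) * rng.choice([-1, 1], size=p)
        X = np.outer(t, v) + noise_sd * rng.standard_normal((n, p))
        beta = v
        y_raw = t.copy()
    else:
        X = rng.standard_normal((n, p))
        beta = rng.uniform(0.5, 1.5, size=p) * rng.choice([-1, 1], size=p)
        y_raw = X @ beta + noise_sd * rng.standard_normal(n)
    lo, hi = y_raw.min(), y_raw.max()
    y_raw = 0.02 + 0.96 * (y_raw - lo) / (hi - lo)
    ids = [f"S{i}" for i in range(n)]
    feats = [f"F{j}" for j in range(p)]
    x = FeatureMatrix(pd.DataFrame(X, index=ids, columns=feats))
    y = ResponseVector(pd.Series(y_raw, index=ids))
    return x, y, beta


@pytest.fixture(scope="session")
def default_dataset():
    """One curated draw from the generator's benchmark regime."""
    x, y, truth = generate_rppa_like(default_spec(seed=11))
    scaled, params, y = curate(x, y)
    return {"raw": x, "scaled": scaled, "params": params, "y": y, "truth": truth}


@pytest.fixture(scope="session")
def default_model(default_dataset):
    d = default_dataset
    return fit_opls(d["scaled"], d["y"], scaling=d["params"], seed=0)
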