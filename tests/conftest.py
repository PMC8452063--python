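import numpy as np
import pandas as pd
import pytest

import twistpg as tw


def make_data(G, T, Y=None, Z=None, outcome_type="continuous", time=None, event=None,
              extra=None, derive=True):
    """Build a PGDataset from plain sequences (covariate column named Z)."""
    df = pd.DataFrame({"G": np.asarray(G, float), "T": np.asarray(T, float)})
    covs = []
    if Y is not None:
        df["Y"] = np.asarray(Y, float)
    if time is not None:
        df["time"] = np.asarray(time, float)
        df["event"] = np.asarray(event, float)
    if Z is not None:
        df["Z"] = np.asarray(Z, float)
        covs.append("Z")
    for name, vals in (extra or {}).items():
        df[name] = np.asarray(vals, float)
        covs.append(name)
    data = tw.PGDataset(df=df, outcome_type=outcome_type, covariates=tuple(covs))
    return tw.build_derived(data) if derive else data


def random_dataset(rng, n=60, with_covariate=False, p_g=0.4, p_t=0.5):
    """Small random cohort guaranteed to populate all four (G, T) strata."""
    while True:
        G = (rng.random(n) < p_g).astype(float)
        T = (rng.random(n) < p_t).astype(float)
        if min(((G == g) & (T == t)).sum() for g in (0, 1) for t in (0, 1)) >= 2:
            break
    Z = rng.normal(size=n) if with_covariate else None
    Y = 1.0 + 0.4 * T - 0.8 * T * G + 0.3 * G + rng.normal(size=n)
    if Z is not None:
        Y = Y + 0.5 * Z
    return make_data(G, T, Y, Z=Z)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
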