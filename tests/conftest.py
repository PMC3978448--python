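import numpy as np
import pandas as pd
import pytest

from cytorisk import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, genes, sites=None, platform="rtpcr"):
    """Helper: build an ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    idx = [f"s{i+1}" for i in range(values.shape[0])]
    sites = sites if sites is not None else ["siteA"] * values.shape[0]
    return ExpressionMatrix(
        pd.DataFrame(values, index=idx, columns=list(genes)),
        pd.Series(sites, index=idx),
        platform=platform,
    )


def random_survival(rng, n, hazard=0.3, censor_scale=5.0, score_effect=0.0):
    """Small random censored dataset for oracle comparisons."""
    score = rng.standard_normal(n)
    t_event = rng.exponential(1.0 / (hazard * np.exp(score_effect * score)))
    t_cens = rng.uniform(0.1, censor_scale, n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    idx = [f"p{i}" for i in range(n)]
    outcome = pd.DataFrame({"time": np.maximum(time, 1e-4), "event": event}, index=idx)
    return pd.Series(score, index=idx), outcome


@pytest.fixture
def small_cohort():
    """Deterministic default-config synthetic cohort."""
    from cytorisk import default_ffpe_config, generate_cohort

    return generate_cohort(default_ffpe_config(seed=7))
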