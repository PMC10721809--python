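import numpy as np
import pandas as pd
import pytest

from careshift.synthgen import ClusterSpec, ShockProfile, SimConfig, generate_panel


def degenerate_config(n_entities=1, *, mean=100.0, amplitude=0.0, trend=0.0,
                      family="poisson", theta=5.0, shock=None, seed=0,
                      mean_floor=None):
    """A panel config with all parameter ranges collapsed to a point, so the
    generating mean is known exactly."""
    spec = ClusterSpec(
        cluster_id=0, weight=1.0,
        shock=shock or ShockProfile.none(),
        base_log_mean=(np.log(mean), np.log(mean)),
        trend_per_year=(trend, trend),
        amplitude_12=(amplitude, amplitude),
        poisson_fraction=1.0 if family == "poisson" else 0.0,
        negbin_size=(theta, theta),
        shock_jitter_sd=0.0,
    )
    kwargs = {}
    if mean_floor is not None:
        kwargs["mean_floor"] = mean_floor
    return SimConfig(n_entities=n_entities, clusters=(spec,),
                     severity_fraction=0.0, seed=seed, **kwargs)


@pytest.fixture(scope="session")
def small_panel():
    """Six-entity default-style panel for pipeline-level tests."""
    from careshift.pipeline_io import MonthlyPanel
    cfg = SimConfig(n_entities=6, seed=42)
    long_df, truths = generate_panel(cfg)
    return MonthlyPanel.from_long(long_df), truths
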