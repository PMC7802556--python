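import numpy as np
import pytest

from maillard_kinetics.panel import TimeSeries
from maillard_kinetics.synthetic_data import load_registry


def make_series(
    times,
    concentrations,
    system="glucose_only",
    compound="3-deoxyglucosone",
    temperature=90.0,
    censored=None,
    n_replicates=1,
):
    """Build a TimeSeries from per-time concentrations, optionally replicated."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if censored is None:
        censored = np.zeros_like(conc, dtype=bool)
    else:
        censored = np.asarray(censored, dtype=bool)
    t_all, rep_all, c_all, cens_all = [], [], [], []
    for r in range(n_replicates):
        t_all.append(times)
        rep_all.append(np.full(times.size, r))
        c_all.append(conc)
        cens_all.append(censored)
    conc_out = np.concatenate(c_all)
    cens_out = np.concatenate(cens_all)
    conc_out = conc_out.copy()
    conc_out[cens_out] = np.nan
    return TimeSeries(
        system=system,
        compound=compound,
        temperature=temperature,
        time_h=np.concatenate(t_all),
        replicate=np.concatenate(rep_all),
        concentration=conc_out,
        censored=cens_out,
    )


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def registry_by_key(registry):
    return {e.key: e for e in registry}
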