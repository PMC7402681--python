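"""Shared fixtures.

The expensive network simulations are session-scoped and shared across the
spectral-trend, forward-model and acceptance tests: a six-point g sweep and
the two chemogenetic-like sweeps, all on the reduced (500-neuron) preset
with 10-s traces as in the full-scale protocol.
"""

import numpy as np
import pytest

from eispec import (
    SweepSpec,
    aggregate_lfp,
    design_hpf,
    extrapolate_low_freq,
    lfp_to_bold,
    make_hrf,
    run_dreadd_sweep,
    run_g_sweep,
)

G_GRID = [4.0, 5.6, 8.0, 11.3, 13.5, 16.0]
REFERENCE_G = 11.3


@pytest.fixture(scope="session")
def g_sweep():
    """Six-point g sweep, 3 repetitions, with LFP traces retained."""
    spec = SweepSpec(g_grid=G_GRID, nu0_levels=(1.5,), n_reps=3, seed0=0)
    df, traces = run_g_sweep(spec, keep_lfp=True)
    return df, traces


@pytest.fixture(scope="session")
def g_sweep_df(g_sweep):
    return g_sweep[0]


@pytest.fixture(scope="session")
def ref_traces(g_sweep):
    _, traces = g_sweep
    return [t for t in traces if abs(t.meta["g"] - REFERENCE_G) < 0.05]


@pytest.fixture(scope="session")
def excite_sweep():
    spec = SweepSpec(nu0_levels=(1.5,), n_reps=3, seed0=0)
    return run_dreadd_sweep(spec, "excite_vth", [-52.0, -53.0], keep_lfp=True)


@pytest.fixture(scope="session")
def silence_sweep():
    spec = SweepSpec(nu0_levels=(1.5,), n_reps=3, seed0=0)
    return run_dreadd_sweep(spec, "silence_el", [-70.0, -75.0], keep_lfp=True)


@pytest.fixture(scope="session")
def hpf():
    return design_hpf()


@pytest.fixture(scope="session")
def hrf():
    return make_hrf(rate=1000.0)


def bold_series_from_traces(traces, slope_low, hpf, hrf, n_reps=6, seed=0,
                            n_concat=20, eta=None, group=None):
    """Helper: aggregate a homogeneous set of traces and forward-model BOLD."""
    groups = None if group is None else [group]
    aggs = aggregate_lfp(traces, n_concat=n_concat, n_reps=n_reps, seed=seed,
                         groups=groups)
    out = []
    for i, agg in enumerate(aggs):
        ext = extrapolate_low_freq(agg, slope_low, seed=seed + 1000 + i)
        out.append(lfp_to_bold(ext, hpf, hrf, eta_amplitude=eta, seed=seed + 2000 + i))
    return out
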