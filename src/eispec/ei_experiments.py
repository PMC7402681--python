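"""Orchestration of the in-silico experiments.

Runs grids of network conditions — the inhibition/excitation conductance
ratio g, or chemogenetic-like single-parameter manipulations (spike
threshold of excitatory cells; resting potential of both populations) —
and collects per-condition spectral readouts into tidy tables: aperiodic
slopes of the LFP spectrum, the Hurst exponent of the LFP, firing rates,
and (optionally, through the forward model) the Hurst exponent of
simulated BOLD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lif_network import (
    LFPTrace,
    NetworkConfig,
    SimulationDivergenceError,
    apply_excitatory_dreadd,
    apply_silencing_dreadd,
    compute_lfp,
    configure_ei_ratio,
    default_config,
    reduced_config,
    simulate_network,
)
from .spectral import fit_piecewise_slopes, welch_psd
from .hurst_fip import EstimatorConfig, estimate_hurst_fip

__all__ = [
    "SweepSpec",
    "GroupedH",
    "full_preset",
    "reduced_preset",
    "run_g_sweep",
    "run_dreadd_sweep",
    "group_h_by_g",
    "default_g_grid",
]


def default_g_grid(n: int = 12, lo: float = 4.0, hi: float = 16.0) -> np.ndarray:
    """Log-spaced g grid spanning the explored range around the reference."""
    return np.geomspace(lo, hi, n)


def full_preset(**overrides) -> NetworkConfig:
    return default_config(**overrides)


def reduced_preset(**overrides) -> NetworkConfig:
    return reduced_config(**overrides)


@dataclass
class SweepSpec:
    """A sweep: conditions x thalamic-input levels x repetitions.

    ``g_grid`` holds g values for ratio sweeps or the manipulated parameter
    values for chemogenetic-like sweeps.  Each repetition r of a condition
    uses seed = seed0 + r (simulation randomness only; the per-condition
    pipeline is otherwise deterministic).
    """

    g_grid: Sequence[float] = field(default_factory=lambda: default_g_grid())
    nu0_levels: Sequence[float] = (1.5, 2.0)
    n_reps: int = 5
    base: NetworkConfig = field(default_factory=reduced_preset)
    seed0: int = 0

    def validate(self) -> None:
        if len(self.g_grid) == 0:
            raise ValueError("empty condition grid")
        if any(nu <= 0 for nu in self.nu0_levels):
            raise ValueError("nu0 levels must be positive")


@dataclass
class GroupedH:
    labels: List[str]
    member_g: List[List[float]]
    h_samples: List[np.ndarray]


_COLUMNS = [
    "param", "value", "g", "nu0", "seed", "rate_e", "rate_i",
    "slope_low", "slope_high", "h_lfp", "ok",
]


def _condition_row(config: NetworkConfig, param: str, value: float,
                   hurst_cfg: Optional[EstimatorConfig],
                   keep_lfp: bool) -> Tuple[dict, Optional[LFPTrace]]:
    row = {
        "param": param,
        "value": value,
        "g": config.g,
        "nu0": config.nu0,
        "seed": config.seed,
        "ok": True,
    }
    try:
        sim = simulate_network(config)
        lfp = compute_lfp(sim)
        psd = welch_psd(lfp.samples, lfp.rate)
        fit = fit_piecewise_slopes(psd)
        est = estimate_hurst_fip(lfp.samples, hurst_cfg)
        row.update(
            rate_e=sim.rates["E"],
            rate_i=sim.rates["I"],
            slope_low=fit.slope_low,
            slope_high=fit.slope_high,
            h_lfp=est.h,
        )
    except SimulationDivergenceError as exc:
        row.update(
            rate_e=np.nan, rate_i=np.nan, slope_low=np.nan, slope_high=np.nan,
            h_lfp=np.nan, ok=False,
        )
        row["error"] = str(exc)
        lfp = None
    return row, (lfp if keep_lfp else None)


def _run_sweep(
    spec: SweepSpec,
    configs: Iterable[Tuple[str, float, NetworkConfig]],
    hurst_cfg: Optional[EstimatorConfig],
    existing: Optional[pd.DataFrame],
    keep_lfp: bool,
):
    rows: List[dict] = [] if existing is None else existing.to_dict("records")
    done = {
        (r["param"], r["value"], r["nu0"], r["seed"]) for r in rows
    }
    traces: List[LFPTrace] = []
    for param, value, cfg in configs:
        for rep in range(spec.n_reps):
            seed = spec.seed0 + rep
            key = (param, value, cfg.nu0, seed)
            if key in done:
                continue
            row, lfp = _condition_row(
                replace(cfg, seed=seed), param, value, hurst_cfg, keep_lfp
            )
            rows.append(row)
            if lfp is not None:
                lfp.meta["condition"] = f"{param}={value}"
                traces.append(lfp)
    df = pd.DataFrame(rows)
    order = [c for c in _COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in _COLUMNS
    ]
    df = df[order].reset_index(drop=True)
    return (df, traces) if keep_lfp else df


def run_g_sweep(
    spec: SweepSpec,
    hurst_cfg: Optional[EstimatorConfig] = None,
    existing: Optional[pd.DataFrame] = None,
    keep_lfp: bool = False,
):
    """Per (g, nu0, repetition): simulate, compute the LFP, fit the
    piecewise 1/f slopes and estimate H.  Returns a tidy DataFrame (and the
    LFP traces when ``keep_lfp``); rows already present in ``existing`` are
    skipped, so interrupted sweeps resume."""
    spec.validate()
    configs = (
        ("g", float(g), configure_ei_ratio(replace(spec.base, nu0=nu0), float(g)))
        for nu0 in spec.nu0_levels
        for g in spec.g_grid
    )
    return _run_sweep(spec, configs, hurst_cfg, existing, keep_lfp)


def run_dreadd_sweep(
    spec: SweepSpec,
    mode: str,
    values: Sequence[float],
    hurst_cfg: Optional[EstimatorConfig] = None,
    existing: Optional[pd.DataFrame] = None,
    keep_lfp: bool = False,
):
    """Chemogenetic-mimicking sweeps.

    mode "excite_vth": lower the excitatory spike threshold (enhanced
    excitability, hM3Dq-like).  mode "silence_el": lower the resting
    potential of both populations (pan-neuronal silencing, hM4Di-like).
    """
    spec.validate()
    if mode == "excite_vth":
        make = apply_excitatory_dreadd
    elif mode == "silence_el":
        make = apply_silencing_dreadd
    else:
        raise ValueError(f"unknown sweep mode: {mode!r}")
    configs = (
        (mode, float(v), make(replace(spec.base, nu0=nu0), float(v)))
        for nu0 in spec.nu0_levels
        for v in values
    )
    return _run_sweep(spec, configs, hurst_cfg, existing, keep_lfp)


def group_h_by_g(result: pd.DataFrame, n_groups: int = 3) -> GroupedH:
    """Split the distinct g values of a sweep into equal-size ordered groups
    (low/medium/high) and pool the H samples per group."""
    df = result[result["ok"]] if "ok" in result.columns else result
    gs = np.sort(df["g"].unique())
    if gs.size < n_groups:
        raise ValueError("need at least n_groups distinct g values")
    base, rem = divmod(gs.size, n_groups)
    if rem:
        import warnings

        warnings.warn(
            f"{gs.size} g values not divisible into {n_groups} groups; "
            "using largest-remainder sizes"
        )
    sizes = [base + (1 if i < rem else 0) for i in range(n_groups)]
    names = (
        ["low g", "medium g", "high g"]
        if n_groups == 3
        else [f"group {i + 1}" for i in range(n_groups)]
    )
    labels, member_g, h_samples = [], [], []
    start = 0
    for name, size in zip(names, sizes):
        members = gs[start : start + size]
        start += size
        labels.append(name)
        member_g.append([float(g) for g in members])
        h_samples.append(df.loc[df["g"].isin(members), "h_lfp"].to_numpy())
    return GroupedH(labels=labels, member_g=member_g, h_samples=h_samples)
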