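"""Conductance-based leaky integrate-and-fire network of excitatory and
inhibitory populations, with an LFP proxy computed from synaptic currents.

The circuit is a standard two-population recurrent cortical model: N_E
excitatory (AMPA-forming) and N_I inhibitory (GABA-forming) point neurons,
randomly connected with probability ``p_conn``, driven by two external
excitatory inputs per neuron — a constant-rate thalamic Poisson input and an
"intracortical" input whose rate follows a zero-mean Ornstein-Uhlenbeck
process rectified at zero.

The local field potential is modelled as the sum of the absolute values of
the total AMPA and total GABA postsynaptic currents onto excitatory cells
(external plus recurrent): AMPA synapses are apical and GABA synapses
peri-somatic, so their current dipoles add with the same sign.

Internal units: mV, ms, nS, pF (hence currents in pA: nS * mV = pA).
Public time stamps are in seconds; LFP/current traces in nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "PopulationParams",
    "SynapseParams",
    "NetworkConfig",
    "SimOutput",
    "LFPTrace",
    "SimulationDivergenceError",
    "default_config",
    "reduced_config",
    "simulate_network",
    "compute_lfp",
    "configure_ei_ratio",
    "apply_excitatory_dreadd",
    "apply_silencing_dreadd",
    "read_config_file",
    "write_config_file",
]


class SimulationDivergenceError(RuntimeError):
    """Raised when the membrane integration produces non-finite voltages."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParams:
    """Single-neuron parameters of one population.

    v_leak/v_threshold/v_reset in mV, tau_refractory in ms, g_leak in nS,
    c_m in pF.  The membrane time constant tau_m = c_m / g_leak (ms) is
    derived, not stored.
    """

    v_leak: float
    v_threshold: float
    v_reset: float
    tau_refractory: float
    g_leak: float
    c_m: float

    @property
    def tau_m(self) -> float:
        return self.c_m / self.g_leak

    def validate(self) -> None:
        if not self.v_reset < self.v_threshold:
            raise ValueError("v_reset must lie below v_threshold")
        if self.tau_refractory <= 0 or self.g_leak <= 0 or self.c_m <= 0:
            raise ValueError("time constants and conductances must be positive")


@dataclass(frozen=True)
class SynapseParams:
    """Synaptic reversal potentials, kinetics and peak conductances.

    Field names carry an ``_e`` / ``_i`` suffix for the *target* population.
    Conductance transients are difference-of-exponentials, peak-normalized so
    that a single presynaptic spike produces a conductance excursion whose
    maximum equals the listed peak conductance.
    """

    e_ampa: float = 0.0
    e_gaba: float = -80.0
    # rise / decay time constants (ms), per receptor, per target population
    tau_r_ampa_e: float = 0.4
    tau_d_ampa_e: float = 2.0
    tau_r_ampa_i: float = 0.2
    tau_d_ampa_i: float = 1.0
    tau_r_gaba_e: float = 0.25
    tau_d_gaba_e: float = 5.0
    tau_r_gaba_i: float = 0.25
    tau_d_gaba_i: float = 5.0
    latency: float = 0.0
    # peak conductances (nS), per source pathway, per target population
    g_ampa_rec_e: float = 0.178
    g_ampa_rec_i: float = 0.233
    g_ampa_tha_e: float = 0.234
    g_ampa_tha_i: float = 0.317
    g_ampa_cort_e: float = 0.187
    g_ampa_cort_i: float = 0.254
    g_gaba_e: float = 2.01
    g_gaba_i: float = 2.7

    def validate(self) -> None:
        for tgt in ("e", "i"):
            for rec in ("ampa", "gaba"):
                tr = getattr(self, f"tau_r_{rec}_{tgt}")
                td = getattr(self, f"tau_d_{rec}_{tgt}")
                if not (td > tr > 0):
                    raise ValueError(
                        f"tau_decay > tau_rise > 0 violated for {rec} onto {tgt}"
                    )
        if not self.e_gaba < self.e_ampa:
            raise ValueError("E_GABA must be below E_AMPA")
        for name in (
            "g_ampa_rec_e", "g_ampa_rec_i", "g_ampa_tha_e", "g_ampa_tha_i",
            "g_ampa_cort_e", "g_ampa_cort_i", "g_gaba_e", "g_gaba_i",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class NetworkConfig:
    """Full network + stimulation configuration.

    nu0 is the thalamic rate per external synapse (spikes/s); each neuron
    receives ``n_ext`` independent external synapses per pathway.  The
    intracortical pathway rate per synapse is max(0, x(t)) with x a
    zero-mean OU process of time constant ``ou_tau`` (ms) and stationary
    standard deviation ``ou_sigma`` (spikes/s); the process is shared
    network-wide, which is what produces slow coherent LFP fluctuations.
    """

    n_e: int = 4000
    n_i: int = 1000
    p_conn: float = 0.2
    pop_e: PopulationParams = field(
        default_factory=lambda: PopulationParams(-70.0, -52.0, -59.0, 2.0, 25.0, 500.0)
    )
    pop_i: PopulationParams = field(
        default_factory=lambda: PopulationParams(-70.0, -52.0, -59.0, 1.0, 20.0, 200.0)
    )
    syn: SynapseParams = field(default_factory=SynapseParams)
    nu0: float = 1.5
    n_ext: int = 8200
    ou_tau: float = 16.0
    ou_sigma: Optional[float] = None  # defaults to 0.2 * nu0
    ou_shared: bool = True  # one OU rate for the whole network vs per-neuron
    dt: float = 0.05
    duration: float = 10.0
    lfp_rate: float = 1000.0
    seed: int = 0

    @property
    def g(self) -> float:
        """Inhibition/excitation conductance ratio, from synapses onto E."""
        return self.syn.g_gaba_e / self.syn.g_ampa_rec_e

    @property
    def ou_sigma_eff(self) -> float:
        return 0.2 * self.nu0 if self.ou_sigma is None else self.ou_sigma

    def validate(self) -> None:
        self.pop_e.validate()
        self.pop_i.validate()
        self.syn.validate()
        if not 0.0 <= self.p_conn <= 1.0:
            raise ValueError("p_conn must lie in [0, 1]")
        if self.nu0 < 0:
            raise ValueError("nu0 must be non-negative")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.dt <= 0 or self.lfp_rate <= 0:
            raise ValueError("dt and lfp_rate must be positive")
        if self.syn.g_ampa_rec_e > 0 and self.g < 0:
            raise ValueError("derived g must be non-negative")


@dataclass
class SimOutput:
    """Spikes, population-summed synaptic currents on E cells, mean rates.

    ``currents`` holds 1-D arrays sampled at ``rate`` Hz: keys ``"ampa"``
    (recurrent + external) and ``"gaba"``, in nA, plus optionally
    ``"per_cell"`` with per-neuron, per-pathway current arrays for small
    diagnostic runs.
    """

    spike_ids: np.ndarray
    spike_times: np.ndarray  # seconds
    currents: Dict[str, np.ndarray]
    rate: float
    rates: Dict[str, float]
    config: NetworkConfig
    per_cell: Optional[Dict[str, np.ndarray]] = None


@dataclass
class LFPTrace:
    samples: np.ndarray
    rate: float
    duration: float
    meta: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Configuration helpers
# ---------------------------------------------------------------------------

def default_config(**overrides) -> NetworkConfig:
    """Baseline full-size (5000-neuron) configuration."""
    return replace(NetworkConfig(), **overrides)


def reduced_config(n_total: int = 500, **overrides) -> NetworkConfig:
    """Desk-scale preset: a 10x smaller network made fully connected so the
    recurrent in-degree stays as close as possible to full scale, with
    single-synapse conductances kept at their baseline values.

    Keeping per-event conductances at baseline (rather than upscaling them
    to compensate the remaining in-degree shortfall) keeps single-synapse
    fluctuations realistic; the shortfall in mean drive is absorbed by the
    external-input calibration, which is shared with the full preset.
    """
    base = NetworkConfig()
    frac = n_total / (base.n_e + base.n_i)
    cfg = replace(
        base,
        n_e=int(round(base.n_e * frac)),
        n_i=int(round(base.n_i * frac)),
        p_conn=1.0,
    )
    return replace(cfg, **overrides)


def configure_ei_ratio(base: NetworkConfig, g: float) -> NetworkConfig:
    """Return a config whose GABA/AMPA conductance ratio onto E cells is g.

    Both GABA conductances (onto E and onto I) are scaled by one common
    factor; AMPA conductances are left at baseline, so conditions are
    indexed by g alone.
    """
    if g <= 0:
        raise ValueError("g must be positive")
    factor = g * base.syn.g_ampa_rec_e / base.syn.g_gaba_e
    syn = replace(
        base.syn,
        g_gaba_e=base.syn.g_gaba_e * factor,
        g_gaba_i=base.syn.g_gaba_i * factor,
    )
    return replace(base, syn=syn)


def apply_excitatory_dreadd(config: NetworkConfig, v_th_new: float) -> NetworkConfig:
    """Lower (or raise) the spike threshold of excitatory cells only —
    the in-silico analogue of hM3Dq-mediated enhanced excitability."""
    if v_th_new <= config.pop_e.v_reset:
        raise ValueError(
            f"new threshold {v_th_new} mV must exceed the reset "
            f"potential {config.pop_e.v_reset} mV"
        )
    return replace(config, pop_e=replace(config.pop_e, v_threshold=v_th_new))


def apply_silencing_dreadd(config: NetworkConfig, e_l_new: float) -> NetworkConfig:
    """Lower the resting (leak) potential of BOTH populations — the
    in-silico analogue of pan-neuronal hM4Di silencing."""
    if e_l_new > min(config.pop_e.v_threshold, config.pop_i.v_threshold):
        raise ValueError("new leak potential lies above spike threshold")
    return replace(
        config,
        pop_e=replace(config.pop_e, v_leak=e_l_new),
        pop_i=replace(config.pop_i, v_leak=e_l_new),
    )


# ---------------------------------------------------------------------------
# Flat key-value config files
# ---------------------------------------------------------------------------

_POP_KEYS = ("v_leak", "v_threshold", "v_reset", "tau_refractory", "g_leak", "c_m")
_TOP_KEYS = (
    "n_e", "n_i", "p_conn", "nu0", "n_ext", "ou_tau", "ou_sigma",
    "dt", "duration", "lfp_rate", "seed",
)


def write_config_file(config: NetworkConfig, path) -> None:
    lines = []
    for key in _TOP_KEYS:
        val = getattr(config, key)
        if val is None:
            continue
        lines.append(f"{key} = {val}")
    for tag, pop in (("e", config.pop_e), ("i", config.pop_i)):
        for key in _POP_KEYS:
            lines.append(f"{key}_{tag} = {getattr(pop, key)}")
    for f_ in SynapseParams.__dataclass_fields__:
        lines.append(f"{f_} = {getattr(config.syn, f_)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config_file(path) -> NetworkConfig:
    """Read a flat ``key = value`` text config; unlisted keys keep defaults."""
    kv: Dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = float(val.strip())
    cfg = NetworkConfig()
    pops = {}
    for tag, pop in (("e", cfg.pop_e), ("i", cfg.pop_i)):
        updates = {
            key: kv.pop(f"{key}_{tag}") for key in _POP_KEYS if f"{key}_{tag}" in kv
        }
        pops[tag] = replace(pop, **updates)
    syn_updates = {
        f_: kv.pop(f_) for f_ in list(kv) if f_ in SynapseParams.__dataclass_fields__
    }
    top_updates = {k: kv.pop(k) for k in list(kv) if k in _TOP_KEYS}
    for key in ("n_e", "n_i", "n_ext", "seed"):
        if key in top_updates:
            top_updates[key] = int(top_updates[key])
    unknown = set(kv)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return replace(
        cfg,
        pop_e=pops["e"],
        pop_i=pops["i"],
        syn=replace(cfg.syn, **syn_updates),
        **top_updates,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _dexp_norm(tau_r: float, tau_d: float) -> float:
    """Peak-normalization for a difference-of-exponentials transient."""
    tp = tau_d * tau_r / (tau_d - tau_r) * math.log(tau_d / tau_r)
    peak = math.exp(-tp / tau_d) - math.exp(-tp / tau_r)
    return 1.0 / peak


class _Channel:
    """One difference-of-exponentials conductance pathway onto a population.

    State per target neuron: decay gate ``a`` (tau_d) and rise gate ``b``
    (tau_r); the conductance is norm * (a - b).  Gates decay exactly
    (exponential Euler) and are incremented by the peak conductance per
    incoming spike.
    """

    def __init__(self, n: int, tau_r: float, tau_d: float, dt: float):
        self.a = np.zeros(n)
        self.b = np.zeros(n)
        self.decay_a = math.exp(-dt / tau_d)
        self.decay_b = math.exp(-dt / tau_r)
        self.norm = _dexp_norm(tau_r, tau_d)

    def step(self) -> None:
        self.a *= self.decay_a
        self.b *= self.decay_b

    def add(self, increments: np.ndarray) -> None:
        self.a += increments
        self.b += increments

    @property
    def g(self) -> np.ndarray:
        return self.norm * (self.a - self.b)


def _bin_spike_times(times_s: Sequence[np.ndarray], n_steps: int, dt_ms: float) -> np.ndarray:
    """Bin per-neuron spike-time arrays (s) into a (n_steps, n) count matrix."""
    counts = np.zeros((n_steps, len(times_s)), dtype=np.int32)
    for i, tt in enumerate(times_s):
        idx = np.floor(np.asarray(tt, dtype=float) * 1000.0 / dt_ms).astype(int)
        idx = idx[(idx >= 0) & (idx < n_steps)]
        np.add.at(counts[:, i], idx, 1)
    return counts


def simulate_network(
    config: NetworkConfig,
    thalamic_spike_times: Optional[Sequence[np.ndarray]] = None,
    record_per_cell: bool = False,
    connectivity: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    v_init: Optional[np.ndarray] = None,
) -> SimOutput:
    """Integrate the network and return spikes, E-cell synaptic currents
    (sampled at ``config.lfp_rate``) and mean population rates.

    ``thalamic_spike_times`` optionally injects a fixed external thalamic
    spike train per neuron (list of arrays of times in seconds, length
    n_e + n_i, E cells first); when given, the internal thalamic Poisson
    generator is bypassed.  ``connectivity`` and ``v_init`` override the
    seeded random structure (boolean E->all and I->all matrices; initial
    voltages), which pins down every source of variability for comparisons
    against reference integrators.  Identical (config, seed) gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt = config.dt
    n_e, n_i = config.n_e, config.n_i
    n = n_e + n_i
    n_steps = int(round(config.duration * 1000.0 / dt))
    rec_every = max(1, int(round(1000.0 / (config.lfp_rate * dt))))
    n_rec = int(round(config.duration * config.lfp_rate))
    if config.duration > 0 and n_rec < 1:
        raise ValueError("duration shorter than one LFP sample")

    syn = config.syn
    pops = (config.pop_e, config.pop_i)
    slices = (slice(0, n_e), slice(n_e, n))

    # connectivity: Bernoulli(p_conn) per ordered pair, no autapses
    if connectivity is not None:
        w_e, w_i = (np.asarray(w, dtype=bool) for w in connectivity)
        if w_e.shape != (n_e, n) or w_i.shape != (n_i, n):
            raise ValueError("connectivity matrices have wrong shapes")
    else:
        w_e = rng.random((n_e, n)) < config.p_conn  # E -> all
        w_i = rng.random((n_i, n)) < config.p_conn  # I -> all
        np.fill_diagonal(w_e[:, :n_e], False)
        np.fill_diagonal(w_i[:, n_e:], False)

    # channels per target population: AMPA(rec, tha, cort) share AMPA taus
    chans = {}
    for tag, sl, npop in (("e", slices[0], n_e), ("i", slices[1], n_i)):
        tr_a = getattr(syn, f"tau_r_ampa_{tag}")
        td_a = getattr(syn, f"tau_d_ampa_{tag}")
        tr_g = getattr(syn, f"tau_r_gaba_{tag}")
        td_g = getattr(syn, f"tau_d_gaba_{tag}")
        chans[tag] = {
            "rec": _Channel(npop, tr_a, td_a, dt),
            "tha": _Channel(npop, tr_a, td_a, dt),
            "cort": _Channel(npop, tr_a, td_a, dt),
            "gaba": _Channel(npop, tr_g, td_g, dt),
        }

    if v_init is not None:
        v = np.array(v_init, dtype=float)
        if v.shape != (n,):
            raise ValueError("v_init must have one entry per neuron")
    else:
        v = np.concatenate([
            np.full(n_e, config.pop_e.v_leak), np.full(n_i, config.pop_i.v_leak)
        ])
        # small random offsets desynchronize onset transients
        v += rng.uniform(0.0, 1.0, n) * np.concatenate([
            np.full(n_e, config.pop_e.v_threshold - config.pop_e.v_leak),
            np.full(n_i, config.pop_i.v_threshold - config.pop_i.v_leak),
        ]) * 0.5
    refr = np.zeros(n, dtype=np.int64)
    refr_steps = np.concatenate([
        np.full(n_e, int(round(config.pop_e.tau_refractory / dt))),
        np.full(n_i, int(round(config.pop_i.tau_refractory / dt))),
    ])
    v_th = np.concatenate([
        np.full(n_e, config.pop_e.v_threshold), np.full(n_i, config.pop_i.v_threshold)
    ])
    v_reset = np.concatenate([
        np.full(n_e, config.pop_e.v_reset), np.full(n_i, config.pop_i.v_reset)
    ])
    v_leak = np.concatenate([
        np.full(n_e, config.pop_e.v_leak), np.full(n_i, config.pop_i.v_leak)
    ])
    g_leak = np.concatenate([
        np.full(n_e, config.pop_e.g_leak), np.full(n_i, config.pop_i.g_leak)
    ])
    c_m = np.concatenate([
        np.full(n_e, config.pop_e.c_m), np.full(n_i, config.pop_i.c_m)
    ])

    if thalamic_spike_times is not None:
        if len(thalamic_spike_times) != n:
            raise ValueError("need one thalamic spike-time array per neuron")
        tha_counts = _bin_spike_times(thalamic_spike_times, n_steps, dt)
    else:
        tha_counts = None
    lam_tha = config.n_ext * config.nu0 * dt / 1000.0

    ou_sigma = config.ou_sigma_eff
    ou_decay = math.exp(-dt / config.ou_tau)
    ou_jump = ou_sigma * math.sqrt(1.0 - ou_decay**2)
    ou = 0.0 if config.ou_shared else np.zeros(n)

    spike_ids: list = []
    spike_times: list = []
    i_ampa = np.zeros(n_rec)
    i_gaba = np.zeros(n_rec)
    per_cell = None
    if record_per_cell:
        per_cell = {
            key: np.zeros((n_rec, n_e))
            for key in ("ampa_rec", "ampa_tha", "ampa_cort", "gaba")
        }
    rec_idx = 0

    g_rec = {"e": syn.g_ampa_rec_e, "i": syn.g_ampa_rec_i}
    g_tha = {"e": syn.g_ampa_tha_e, "i": syn.g_ampa_tha_i}
    g_cort = {"e": syn.g_ampa_cort_e, "i": syn.g_ampa_cort_i}
    g_gab = {"e": syn.g_gaba_e, "i": syn.g_gaba_i}

    for step in range(n_steps):
        for tag in ("e", "i"):
            for ch in chans[tag].values():
                ch.step()

        # external drives
        if tha_counts is not None:
            counts = tha_counts[step].astype(float)
        else:
            counts = rng.poisson(lam_tha, n).astype(float)
        if config.ou_shared:
            ou = ou * ou_decay + ou_jump * rng.standard_normal()
            lam_cort = config.n_ext * max(0.0, ou) * dt / 1000.0
            cort_counts = (
                rng.poisson(lam_cort, n).astype(float) if lam_cort > 0 else None
            )
        else:
            ou = ou * ou_decay + ou_jump * rng.standard_normal(n)
            lam_cort = config.n_ext * np.maximum(0.0, ou) * dt / 1000.0
            cort_counts = (
                rng.poisson(lam_cort).astype(float) if lam_cort.any() else None
            )
        for tag, sl in (("e", slices[0]), ("i", slices[1])):
            chans[tag]["tha"].add(counts[sl] * g_tha[tag])
            if cort_counts is not None:
                chans[tag]["cort"].add(cort_counts[sl] * g_cort[tag])

        # membrane update (forward Euler); conductances in nS, V in mV -> pA
        g_ampa_e = chans["e"]["rec"].g + chans["e"]["tha"].g + chans["e"]["cort"].g
        g_gaba_e = chans["e"]["gaba"].g
        g_ampa_i = chans["i"]["rec"].g + chans["i"]["tha"].g + chans["i"]["cort"].g
        g_gaba_i = chans["i"]["gaba"].g
        g_ampa = np.concatenate([g_ampa_e, g_ampa_i])
        g_gaba_all = np.concatenate([g_gaba_e, g_gaba_i])
        i_syn = g_ampa * (v - syn.e_ampa) + g_gaba_all * (v - syn.e_gaba)
        dv = dt * (-(g_leak * (v - v_leak)) - i_syn) / c_m
        active = refr <= 0
        v = np.where(active, v + dv, v_reset)
        refr = np.maximum(refr - 1, 0)

        if not np.all(np.isfinite(v)):
            raise SimulationDivergenceError(
                f"membrane potential diverged at t={step * dt:.3f} ms; "
                f"reduce dt (currently {dt} ms)"
            )

        spiking = active & (v >= v_th)
        if np.any(spiking):
            ids = np.nonzero(spiking)[0]
            spike_ids.append(ids)
            spike_times.append(np.full(ids.size, (step + 1) * dt / 1000.0))
            v[ids] = v_reset[ids]
            refr[ids] = refr_steps[ids]
            spk_e = ids[ids < n_e]
            spk_i = ids[ids >= n_e] - n_e
            if spk_e.size:
                inc = w_e[spk_e].sum(axis=0).astype(float)
                chans["e"]["rec"].add(inc[:n_e] * g_rec["e"])
                chans["i"]["rec"].add(inc[n_e:] * g_rec["i"])
            if spk_i.size:
                inc = w_i[spk_i].sum(axis=0).astype(float)
                chans["e"]["gaba"].add(inc[:n_e] * g_gab["e"])
                chans["i"]["gaba"].add(inc[n_e:] * g_gab["i"])

        if (step + 1) % rec_every == 0 and rec_idx < n_rec:
            v_e = v[:n_e]
            amp = g_ampa_e * (v_e - syn.e_ampa)
            gab = g_gaba_e * (v_e - syn.e_gaba)
            i_ampa[rec_idx] = amp.sum() / 1000.0  # pA -> nA
            i_gaba[rec_idx] = gab.sum() / 1000.0
            if per_cell is not None:
                per_cell["ampa_rec"][rec_idx] = (
                    chans["e"]["rec"].g * (v_e - syn.e_ampa) / 1000.0
                )
                per_cell["ampa_tha"][rec_idx] = (
                    chans["e"]["tha"].g * (v_e - syn.e_ampa) / 1000.0
                )
                per_cell["ampa_cort"][rec_idx] = (
                    chans["e"]["cort"].g * (v_e - syn.e_ampa) / 1000.0
                )
                per_cell["gaba"][rec_idx] = gab / 1000.0
            rec_idx += 1

    ids = np.concatenate(spike_ids) if spike_ids else np.array([], dtype=int)
    times = np.concatenate(spike_times) if spike_times else np.array([])
    dur = config.duration if config.duration > 0 else 1.0
    rates = {
        "E": float((ids < n_e).sum()) / (n_e * dur),
        "I": float((ids >= n_e).sum()) / (n_i * dur),
    }
    return SimOutput(
        spike_ids=ids,
        spike_times=times,
        currents={"ampa": i_ampa, "gaba": i_gaba},
        rate=config.lfp_rate,
        rates=rates,
        config=config,
        per_cell=per_cell,
    )


def compute_lfp(sim: SimOutput, rate: Optional[float] = None) -> LFPTrace:
    """LFP proxy: |total AMPA current| + |total GABA current| on E cells.

    The absolute values of the two population-summed currents are added,
    so the trace is non-negative by construction.
    """
    if "ampa" not in sim.currents or "gaba" not in sim.currents:
        raise ValueError("simulation output lacks current traces")
    if rate is not None and rate != sim.rate:
        raise ValueError(
            f"currents were recorded at {sim.rate} Hz; re-run the simulation "
            f"with lfp_rate={rate} to obtain a different sampling rate"
        )
    samples = np.abs(sim.currents["ampa"]) + np.abs(sim.currents["gaba"])
    cfg = sim.config
    return LFPTrace(
        samples=samples,
        rate=sim.rate,
        duration=cfg.duration,
        meta={"g": cfg.g, "nu0": cfg.nu0, "condition": "baseline", "seed": cfg.seed},
    )
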