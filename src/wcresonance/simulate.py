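"""Stochastic delay-network integration.

The coupled system is integrated with a fixed-step Euler-Maruyama scheme at
dt = 1 ms.  Two conventions matter and are part of the numerical contract
(see docs/methods.md for the rationale):

* **Sequential population update.**  Within each step the E populations are
  updated first and the *updated* E enters the intra-unit term of the I
  equation (a Gauss-Seidel sweep).  Inter-unit inputs always come from the
  delay history, i.e. pre-update activity.
* **Delay history.**  Delayed inter-unit inputs read the excitatory
  activity ``delay_steps`` integration steps in the past from a circular
  buffer; pre-history values (t < 0) equal the initial state.  A delay of
  0 reads the pre-update activity of the current step.

Noise is Gaussian white noise shared by all units of a macrocolumn, drawn
independently per macrocolumn per step, scaled by ``z`` and added inside
the sigmoid argument of the E equation, exactly where the model places it.

The production integrator (:func:`simulate_trial`, batched
:func:`run_trials_mask_mean`) is a numba kernel; ``simulate_trial_reference``
is a deliberately naive full-history NumPy implementation used as an
independent oracle — the two must agree to ~1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .connectivity import Network, SubnetworkMask
from .model import UnitParams, uncoupled_fixed_point

__all__ = [
    "NoiseConfig",
    "SimulationConfig",
    "TrialOutput",
    "simulate_trial",
    "simulate_trial_reference",
    "run_trials",
    "run_trials_mask_mean",
    "run_conditions_mask_mean",
    "mask_average",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Noise SD multiplier ``z`` and the seed of the noise stream."""

    z: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z < 0:
            raise ValueError("noise multiplier z must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Integration plan.

    ``n_steps`` samples are integrated and returned; ``burn_in_steps``
    extra steps are integrated *before* them and discarded, so analysis
    sees the steady state rather than the trial-onset transient.
    """

    dt: float = 0.001
    n_steps: int = 2000
    burn_in_steps: int = 0
    initial_state: str = "fixed_point"  # or "zeros"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be >= 0")
        if self.initial_state not in ("fixed_point", "zeros"):
            raise ValueError("initial_state must be 'fixed_point' or 'zeros'")


@dataclass
class TrialOutput:
    """Excitatory activity of one stochastic trial, time x units."""

    e_series: np.ndarray
    dt: float
    drive_freq: float | None = None
    mask: SubnetworkMask | None = None


@njit(cache=True)
def _sig(x: float, gain: float, offset: float) -> float:
    z = gain * (x - offset)
    if z > 500.0:
        z = 500.0
    elif z < -500.0:
        z = -500.0
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def _integrate(
    E,
    I,
    hist,
    n_steps,
    dt,
    tau_e,
    tau_i,
    w_ee,
    w_ie,
    w_ei,
    w_ii,
    bg_e,
    bg_i,
    gain,
    offset,
    esrc,
    edst,
    ew,
    edel,
    isrc,
    idst,
    iw,
    idel,
    drive,
    has_drive,
    drive_mask,
    z,
    noise,
    mcol,
    rec_mode,
    rec_idx,
    out,
):
    """Euler-Maruyama sweep over ``n_steps``; returns -1 or failing step.

    Shapes: E, I (units, batch); hist (L, units, batch) pre-filled with the
    initial E; noise (n_steps, n_macrocolumns, batch); out is
    (n_steps, units) for rec_mode 0 (batch must be 1) or (n_steps, batch)
    for rec_mode 1 (mean over ``rec_idx``).
    """
    U, B = E.shape
    L = hist.shape[0]
    net_e = np.empty((U, B))
    net_i = np.empty((U, B))
    for t in range(n_steps):
        row = t % L
        for u in range(U):
            for b in range(B):
                hist[row, u, b] = E[u, b]
                net_e[u, b] = 0.0
                net_i[u, b] = 0.0
        for k in range(esrc.shape[0]):
            r = (t - edel[k]) % L
            s = esrc[k]
            d = edst[k]
            w = ew[k]
            for b in range(B):
                net_e[d, b] += w * hist[r, s, b]
        for k in range(isrc.shape[0]):
            r = (t - idel[k]) % L
            s = isrc[k]
            d = idst[k]
            w = iw[k]
            for b in range(B):
                net_i[d, b] += w * hist[r, s, b]
        for u in range(U):
            driven = has_drive and drive_mask[u]
            mc = mcol[u]
            for b in range(B):
                drv = drive[t, b] if driven else 0.0
                x = (
                    w_ee * E[u, b]
                    + w_ie * I[u, b]
                    + bg_e
                    + net_e[u, b]
                    + drv
                    + z * noise[t, mc, b]
                )
                e_new = E[u, b] + dt * (-E[u, b] + _sig(x, gain, offset)) / tau_e
                xi = w_ei * e_new + w_ii * I[u, b] + bg_i + net_i[u, b]
                i_new = I[u, b] + dt * (-I[u, b] + _sig(xi, gain, offset)) / tau_i
                if not (np.isfinite(e_new) and np.isfinite(i_new)):
                    return t
                E[u, b] = e_new
                I[u, b] = i_new
        if rec_mode == 0:
            for u in range(U):
                out[t, u] = E[u, 0]
        else:
            for b in range(B):
                acc = 0.0
                for j in range(rec_idx.shape[0]):
                    acc += E[rec_idx[j], b]
                out[t, b] = acc / rec_idx.shape[0]
    return -1


def _initial_state(p: UnitParams, how: str):
    if how == "zeros":
        return 0.0, 0.0
    try:
        return uncoupled_fixed_point(p)
    except RuntimeError:
        return 0.0, 0.0


def _noise_block(seed: int, n_steps: int, n_macro: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return rng.standard_normal((n_steps, n_macro))


def _max_delay(network: Network) -> int:
    md = 0
    for edges in (network.exc, network.inh):
        if len(edges):
            md = max(md, int(edges.delay_steps.max()))
    return md


def _run_batch(
    network: Network,
    p: UnitParams,
    z: float,
    noise: np.ndarray,
    drive: np.ndarray | None,
    drive_mask: SubnetworkMask | None,
    sim: SimulationConfig,
    rec_mode: int,
    rec_idx: np.ndarray,
) -> np.ndarray:
    U = network.n_units
    B = noise.shape[2]
    total = sim.burn_in_steps + sim.n_steps
    e0, i0 = _initial_state(p, sim.initial_state)
    E = np.full((U, B), e0)
    I = np.full((U, B), i0)
    L = _max_delay(network) + 1
    hist = np.full((L, U, B), e0)
    has_drive = drive is not None
    if has_drive:
        drive = np.asarray(drive, dtype=float)
        if drive.ndim == 1:
            drive = np.broadcast_to(drive[:, None], (len(drive), B))
        if drive.shape != (total, B):
            raise ValueError(
                "drive must have length burn_in_steps + n_steps "
                "(optionally one column per batch member)"
            )
        drive_arr = np.ascontiguousarray(drive)
        dmask = drive_mask.member
    else:
        drive_arr = np.zeros((1, B))
        dmask = np.zeros(U, dtype=bool)
    out = np.empty((total, U) if rec_mode == 0 else (total, B))
    bad = _integrate(
        E,
        I,
        hist,
        total,
        sim.dt,
        p.tau_e,
        p.tau_i,
        p.w_ee,
        p.w_ie,
        p.w_ei,
        p.w_ii,
        p.e0,
        p.i0,
        p.sigmoid_gain,
        p.sigmoid_offset,
        network.exc.src,
        network.exc.dst,
        network.exc.weight,
        network.exc.delay_steps,
        network.inh.src,
        network.inh.dst,
        network.inh.weight,
        network.inh.delay_steps,
        drive_arr,
        has_drive,
        dmask,
        z,
        np.ascontiguousarray(noise),
        network.macrocolumn_of.astype(np.int64),
        rec_mode,
        rec_idx.astype(np.int64),
        out,
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite state at integration step {bad}")
    return out[sim.burn_in_steps :]


def simulate_trial(
    network: Network,
    p: UnitParams,
    noise: NoiseConfig,
    drive: np.ndarray | None = None,
    mask: SubnetworkMask | None = None,
    sim: SimulationConfig = SimulationConfig(),
) -> TrialOutput:
    """Integrate one stochastic trial and return the full E time series.

    ``drive`` (a sampled pulse train of length ``n_steps``) is applied to
    the E populations of units in ``mask`` only; both must be given
    together.  Deterministic given the seeds.
    """
    if (drive is None) != (mask is None):
        raise ValueError("drive and mask must be given together")
    n_macro = int(network.macrocolumn_of.max()) + 1
    total = sim.burn_in_steps + sim.n_steps
    noise_block = _noise_block(noise.seed, total, n_macro)[:, :, None]
    out = _run_batch(
        network,
        p,
        noise.z,
        noise_block,
        drive,
        mask,
        sim,
        rec_mode=0,
        rec_idx=np.arange(network.n_units),
    )
    freq = None
    return TrialOutput(out, sim.dt, drive_freq=freq, mask=mask)


def simulate_trial_reference(
    network: Network,
    p: UnitParams,
    noise: NoiseConfig,
    drive: np.ndarray | None = None,
    mask: SubnetworkMask | None = None,
    sim: SimulationConfig = SimulationConfig(),
) -> TrialOutput:
    """Naive full-history reference integrator (independent oracle).

    Keeps the entire E history in a (n_steps+1, units) array and gathers
    delayed inputs edge by edge with plain NumPy indexing.  Slow; used in
    tests to certify the circular-buffer kernel.
    """
    if (drive is None) != (mask is None):
        raise ValueError("drive and mask must be given together")
    from .model import sigmoid

    U = network.n_units
    total = sim.burn_in_steps + sim.n_steps
    e0, i0 = _initial_state(p, sim.initial_state)
    E = np.full(U, e0)
    I = np.full(U, i0)
    n_macro = int(network.macrocolumn_of.max()) + 1
    xi = _noise_block(noise.seed, total, n_macro)
    hist = np.full((total + 1, U), e0)  # hist[t] = E entering step t
    out = np.empty((total, U))
    mcol = network.macrocolumn_of
    dmask = mask.member if mask is not None else np.zeros(U, dtype=bool)
    if drive is not None and len(drive) != total:
        raise ValueError("drive length must equal burn_in_steps + n_steps")
    for t in range(total):
        hist[t] = E
        net_e = np.zeros(U)
        net_i = np.zeros(U)
        for s, d, w, dl in zip(
            network.exc.src, network.exc.dst, network.exc.weight, network.exc.delay_steps
        ):
            past = hist[t - dl] if t - dl >= 0 else hist[0]
            net_e[d] += w * past[s]
        for s, d, w, dl in zip(
            network.inh.src, network.inh.dst, network.inh.weight, network.inh.delay_steps
        ):
            past = hist[t - dl] if t - dl >= 0 else hist[0]
            net_i[d] += w * past[s]
        drv = np.where(dmask, drive[t], 0.0) if drive is not None else np.zeros(U)
        g, n = p.sigmoid_gain, p.sigmoid_offset
        # term order mirrors the production kernel so results agree bitwise
        arg_e = p.w_ee * E + p.w_ie * I + p.e0 + net_e + drv + noise.z * xi[t, mcol]
        E_new = E + sim.dt * (-E + sigmoid(arg_e, g, n)) / p.tau_e
        arg_i = p.w_ei * E_new + p.w_ii * I + p.i0 + net_i
        I_new = I + sim.dt * (-I + sigmoid(arg_i, g, n)) / p.tau_i
        if not (np.all(np.isfinite(E_new)) and np.all(np.isfinite(I_new))):
            raise FloatingPointError(f"non-finite state at integration step {t}")
        E, I = E_new, I_new
        out[t] = E
    return TrialOutput(out[sim.burn_in_steps :], sim.dt, mask=mask)


def trial_seed(base_seed: int, k: int) -> int:
    """Noise seed of trial ``k`` derived from ``base_seed`` (stable)."""
    ss = np.random.SeedSequence((base_seed, k))
    return int(ss.generate_state(1, np.uint32)[0])


def run_trials(
    n_trials: int,
    network: Network,
    p: UnitParams,
    z: float,
    base_seed: int,
    drive: np.ndarray | None = None,
    mask: SubnetworkMask | None = None,
    sim: SimulationConfig = SimulationConfig(),
) -> list[TrialOutput]:
    """Run ``n_trials`` independent trials (full per-unit output each)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return [
        simulate_trial(
            network, p, NoiseConfig(z, trial_seed(base_seed, k)), drive, mask, sim
        )
        for k in range(n_trials)
    ]


def run_trials_mask_mean(
    n_trials: int,
    network: Network,
    p: UnitParams,
    z: float,
    base_seed: int,
    drive: np.ndarray | None = None,
    mask: SubnetworkMask | None = None,
    sim: SimulationConfig = SimulationConfig(),
    record_mask: SubnetworkMask | None = None,
) -> np.ndarray:
    """Batched fast path: (n_steps, n_trials) mask-averaged E series.

    All trials share the network and drive; trial ``k`` uses the noise
    stream derived from ``(base_seed, k)``, identical to
    :func:`run_trials`.  ``record_mask`` defaults to the drive mask, or to
    the whole lattice for spontaneous runs.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if (drive is None) != (mask is None):
        raise ValueError("drive and mask must be given together")
    if record_mask is None:
        record_mask = mask if mask is not None else SubnetworkMask.full(network.spec)
    n_macro = int(network.macrocolumn_of.max()) + 1
    total = sim.burn_in_steps + sim.n_steps
    noise = np.stack(
        [
            _noise_block(trial_seed(base_seed, k), total, n_macro)
            for k in range(n_trials)
        ],
        axis=2,
    )
    return _run_batch(
        network,
        p,
        z,
        noise,
        drive,
        mask,
        sim,
        rec_mode=1,
        rec_idx=record_mask.indices,
    )


def run_conditions_mask_mean(
    conditions,
    network: Network,
    p: UnitParams,
    z: float,
    n_trials: int,
    mask: SubnetworkMask | None,
    sim: SimulationConfig,
    record_mask: SubnetworkMask | None = None,
    max_hist_bytes: float = 6e8,
) -> list[np.ndarray]:
    """Run several driven conditions in one (or few) batched kernel calls.

    ``conditions`` is a sequence of ``(drive, base_seed)`` pairs sharing
    the drive mask and trial count; drives may be ``None`` for spontaneous
    conditions.  Per condition the result equals
    :func:`run_trials_mask_mean` exactly — conditions and trials map onto
    batch columns, each with its own drive column and noise stream.
    Conditions are chunked so the delay history buffer stays under
    ``max_hist_bytes``.

    Returns one ``(n_steps, n_trials)`` array per condition.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    conditions = list(conditions)
    if record_mask is None:
        record_mask = mask if mask is not None else SubnetworkMask.full(network.spec)
    U = network.n_units
    total = sim.burn_in_steps + sim.n_steps
    n_macro = int(network.macrocolumn_of.max()) + 1
    L = _max_delay(network) + 1
    cap_cols = max(n_trials, int(max_hist_bytes // (L * U * 8)))
    per_chunk = max(1, cap_cols // n_trials)
    has_drive = any(d is not None for d, _ in conditions)
    if has_drive and mask is None:
        raise ValueError("driven conditions need a drive mask")
    results: list[np.ndarray] = []
    for start in range(0, len(conditions), per_chunk):
        chunk = conditions[start : start + per_chunk]
        B = len(chunk) * n_trials
        noise = np.empty((total, n_macro, B))
        for ci, (_, base_seed) in enumerate(chunk):
            for k in range(n_trials):
                noise[:, :, ci * n_trials + k] = _noise_block(
                    trial_seed(base_seed, k), total, n_macro
                )
        drive_mat = None
        if has_drive:
            drive_mat = np.zeros((total, B))
            for ci, (d, _) in enumerate(chunk):
                if d is None:
                    raise ValueError("cannot mix driven and spontaneous conditions")
                drive_mat[:, ci * n_trials : (ci + 1) * n_trials] = np.asarray(d)[
                    :, None
                ]
        out = _run_batch(
            network,
            p,
            z,
            noise,
            drive_mat,
            mask,
            sim,
            rec_mode=1,
            rec_idx=record_mask.indices,
        )
        for ci in range(len(chunk)):
            results.append(out[:, ci * n_trials : (ci + 1) * n_trials])
    return results


def mask_average(trial: TrialOutput, mask: SubnetworkMask | None = None) -> np.ndarray:
    """Arithmetic mean of the E series over masked units per time step.

    Falls back to the trial's own mask, then to the whole lattice.
    """
    if mask is None:
        mask = trial.mask
    if mask is None:
        return trial.e_series.mean(axis=1)
    return trial.e_series[:, mask.member].mean(axis=1)
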