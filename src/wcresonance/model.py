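"""Single Wilson-Cowan unit: dynamics, response function, and stimulus kernel.

A Wilson-Cowan (WC) unit is a two-variable mean-field model of an excitatory
(E) and an inhibitory (I) neural population.  The unit's output is the
activity of the excitatory population.  Everything in this module is
network-independent: coupling to other units enters only through the
aggregate external-input arguments of :func:`unit_derivatives`.

The dynamics are

.. math::

    \\tau_E \\dot E = -E + \\sigma(W_{EE} E + W_{IE} I + E_0 + u_E)

    \\tau_I \\dot I = -I + \\sigma(W_{EI} E + W_{II} I + I_0 + u_I)

with the sigmoid response function
:math:`\\sigma(x) = 1 / (1 + e^{-m (x - n)})`, where ``u_E`` aggregates
inter-unit excitation, the periodic drive and the noise term, and ``u_I``
aggregates inter-unit inhibition (excitatory activity of other units
projecting onto the I population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "UnitParams",
    "StimulusKernelParams",
    "sigmoid",
    "unit_derivatives",
    "uncoupled_fixed_point",
    "stimulus_kernel",
    "periodic_drive",
]

#: Clamp for the sigmoid exponent argument; far outside the model's operating
#: range, prevents overflow in exp without affecting results.
_EXP_CLAMP = 500.0


@dataclass(frozen=True)
class UnitParams:
    """Parameters of a single Wilson-Cowan unit.

    Attributes
    ----------
    w_ee, w_ie, w_ei, w_ii :
        Intra-unit coupling weights.  ``w_ie`` is the I->E weight (appears
        in the E equation, negative for inhibition); ``w_ei`` is the E->I
        weight (appears in the I equation).
    e0, i0 :
        Background input levels of the two populations.
    tau_e, tau_i :
        Time constants in **seconds** (defaults 14 ms and 13 ms).
    sigmoid_gain, sigmoid_offset :
        Steepness ``m`` and offset ``n`` of the sigmoid response function.
    """

    w_ee: float = 23.0
    w_ie: float = -15.0
    w_ei: float = 35.0
    w_ii: float = 0.0
    e0: float = 0.5
    i0: float = -5.0
    tau_e: float = 0.014
    tau_i: float = 0.013
    sigmoid_gain: float = 1.0
    sigmoid_offset: float = 4.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.sigmoid_gain <= 0:
            raise ValueError("sigmoid gain must be positive")


@dataclass(frozen=True)
class StimulusKernelParams:
    """Shape of the repetitive ("spiking") stimulus kernel.

    The kernel is a gamma-like pulse ``f(t) = q (t/w)^shape exp(-t/w)``
    with ``t`` and ``w`` in milliseconds.  With the defaults the pulse
    peaks ``shape * w = 11.1`` ms after onset.
    """

    q: float = 0.5
    shape: float = 3.0
    w: float = 3.7

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("amplitude q must be non-negative")
        if self.shape <= 0 or self.w <= 0:
            raise ValueError("kernel shape and time scale must be positive")


def sigmoid(x, gain: float = 1.0, offset: float = 4.0):
    """Sigmoid response function ``1 / (1 + exp(-gain * (x - offset)))``.

    Strictly increasing with values in (0, 1).  The exponent argument is
    clamped so the function saturates instead of overflowing.  Accepts
    scalars or arrays.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    z = np.clip(gain * (np.asarray(x, dtype=float) - offset), -_EXP_CLAMP, _EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(-z))
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def unit_derivatives(e, i, ext_e, ext_i, p: UnitParams):
    """Time derivatives ``(dE/dt, dI/dt)`` of one WC unit.

    Parameters
    ----------
    e, i :
        Current population activities.
    ext_e :
        Aggregate external input to the E population: delayed inter-unit
        excitation plus drive plus noise.
    ext_i :
        Aggregate external input to the I population: delayed inter-unit
        excitatory activity targeting I.
    p :
        Unit parameters.

    Raises
    ------
    FloatingPointError
        If any input is non-finite (signals numerical blow-up upstream).
    """
    vals = np.asarray([e, i, ext_e, ext_i], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError("non-finite state or input in unit_derivatives")
    g, n = p.sigmoid_gain, p.sigmoid_offset
    de = (-e + sigmoid(p.w_ee * e + p.w_ie * i + p.e0 + ext_e, g, n)) / p.tau_e
    di = (-i + sigmoid(p.w_ei * e + p.w_ii * i + p.i0 + ext_i, g, n)) / p.tau_i
    return de, di


def _inner_i_fixed_point(e: float, p: UnitParams, tol: float = 1e-14) -> float:
    """Solve ``i = sigma(w_ei e + w_ii i + i0)`` for i at fixed e.

    For the default parameters ``w_ii = 0`` and this is a closed form; the
    Picard iteration below converges for any ``|w_ii| * sigma' < 1`` which
    holds throughout the model's operating range (sigma' <= gain/4).
    """
    g, n = p.sigmoid_gain, p.sigmoid_offset
    i = 0.5
    for _ in range(200):
        i_new = sigmoid(p.w_ei * e + p.w_ii * i + p.i0, g, n)
        if abs(i_new - i) < tol:
            return i_new
        i = i_new
    return i


def uncoupled_fixed_point(p: UnitParams, residual_tol: float = 1e-10):
    """Equilibrium ``(e*, i*)`` of an isolated unit with zero external input.

    The E nullcline is reduced to a one-dimensional root problem
    ``F(e) = sigma(w_ee e + w_ie i(e) + e0) - e`` and bracketed roots are
    located on a fine grid.  When several equilibria exist (the default
    weights give three: a low-activity spiral, a saddle and a saturated
    high-activity node) the **lowest-E** root is returned — that is the
    branch around which the model oscillates and the state all simulations
    start from.

    Raises
    ------
    RuntimeError
        If no root is found or the residual exceeds ``residual_tol``.
    """
    from scipy.optimize import brentq

    g, n = p.sigmoid_gain, p.sigmoid_offset

    def f_res(e: float) -> float:
        i = _inner_i_fixed_point(e, p)
        return sigmoid(p.w_ee * e + p.w_ie * i + p.e0, g, n) - e

    grid = np.linspace(0.0, 1.0, 2001)
    vals = np.array([f_res(e) for e in grid])
    roots = []
    for k in range(len(grid) - 1):
        if vals[k] == 0.0:
            roots.append(grid[k])
        elif vals[k] * vals[k + 1] < 0:
            roots.append(brentq(f_res, grid[k], grid[k + 1], xtol=1e-14))
    if not roots:
        raise RuntimeError("no equilibrium found for these unit parameters")
    e_star = min(roots)
    i_star = _inner_i_fixed_point(e_star, p)
    de, di = unit_derivatives(e_star, i_star, 0.0, 0.0, p)
    if max(abs(de), abs(di)) * min(p.tau_e, p.tau_i) > residual_tol:
        raise RuntimeError(
            f"fixed point residual {max(abs(de), abs(di)):.3e} exceeds tolerance"
        )
    return float(e_star), float(i_star)


def stimulus_kernel(t, k: StimulusKernelParams = StimulusKernelParams()):
    """Stimulus kernel ``f(t) = q (t/w)^shape exp(-t/w)`` with ``t`` in ms.

    Causal: returns 0 for ``t < 0``.  Accepts scalars or arrays.
    """
    t_arr = np.asarray(t, dtype=float)
    with np.errstate(invalid="ignore"):
        ratio = np.where(t_arr > 0, t_arr / k.w, 0.0)
        out = k.q * ratio**k.shape * np.exp(-ratio)
    out = np.where(t_arr > 0, out, 0.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out


def periodic_drive(
    freq: float,
    n_steps: int,
    dt: float,
    k: StimulusKernelParams = StimulusKernelParams(),
) -> np.ndarray:
    """Sampled periodic pulse train at driving frequency ``freq`` (Hz).

    The kernel is restarted at each cycle onset; onsets fall at multiples
    of ``1/freq`` rounded to the integration grid.  Restarting (rather than
    summing overlapping kernels) keeps the construction deterministic; at
    the driving frequencies used here the kernel has decayed to below 2 %
    of its peak by the end of a cycle, so the two constructions nearly
    coincide.

    Parameters
    ----------
    freq :
        Driving frequency in Hz; must be below Nyquist ``1/(2 dt)``.
    n_steps :
        Number of samples to generate.
    dt :
        Sampling step in seconds.
    """
    if freq <= 0 or freq >= 0.5 / dt:
        raise ValueError(f"drive frequency {freq} Hz outside (0, Nyquist)")
    steps = np.arange(n_steps)
    period_steps = 1.0 / (freq * dt)
    # index of the most recent onset (onsets at multiples of 1/freq, rounded)
    cycle = np.floor(steps / period_steps + 1e-12)
    onset = np.rint(cycle * period_steps)
    late = onset > steps  # rounding pushed the onset past the sample
    onset[late] = np.rint((cycle[late] - 1) * period_steps)
    elapsed_ms = (steps - onset) * dt * 1000.0
    return stimulus_kernel(elapsed_ms, k)
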