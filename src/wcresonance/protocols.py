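"""Runnable, seeded reproductions of the simulation experiments.

Each ``run_*`` function reproduces one in-silico experiment end to end:
build a network, drive it (or not), simulate trials, score spectra, and
bootstrap the resonance statistic.  Every protocol is fully reproducible
from its configuration: all randomness derives from ``seed`` through named
sub-streams, and ``scale`` shrinks only the trial and bootstrap counts —
never model parameters — so reduced desk-scale runs probe the same model.

The default configurations are the published operating points:

========  =======  ====  ======================  ==========================
protocol  lattice  z     delay (steps/unit)      drive grid (Hz)
========  =======  ====  ======================  ==========================
fig2      50x50    0.05  10                      10.0-15.0 step 0.5
fig3a     100x100  —     10                      none (connectivity census)
fig3b     30x30    0.05  10-100 step 10 (scan)   12.0-14.0 step 0.2
fig3c/d   30x30    0.07  0                       12.0-17.0 step 0.2
s1        single   0.05  —                       6.0-13.0 step 0.2
s2        30x30    scan  10                      none (spontaneous)
========  =======  ====  ======================  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import (
    ConnectivityConfig,
    LatticeSpec,
    Network,
    SubnetworkMask,
    apply_lateral_inhibition,
    build_network,
    subnetwork_connectivity_stats,
)
from .model import StimulusKernelParams, UnitParams, periodic_drive
from .simulate import SimulationConfig, run_conditions_mask_mean, run_trials_mask_mean
from .spectra import (
    BootstrapConfig,
    FitResult,
    PowerSpectrum,
    ResonanceCurve,
    bootstrap_peak_frequency,
    bootstrap_response_power,
    bootstrap_spectrum_peak,
    linear_fit,
    peak_driving_frequency,
    power_spectrum,
)

__all__ = [
    "ProtocolConfig",
    "ScanResult",
    "SizeResonanceResult",
    "run_size_resonance",
    "run_connectivity_profile",
    "run_delay_scan",
    "run_degree_scan",
    "run_single_unit_tau_scan",
    "run_noise_strength_scan",
]


def _substream_seed(base: int, *key: int) -> int:
    """Stable 32-bit seed for a named sub-stream of ``base``."""
    return int(np.random.SeedSequence((base, *key)).generate_state(1, np.uint32)[0])


@dataclass
class ProtocolConfig:
    """Everything needed to run (and re-run) one protocol."""

    name: str
    lattice: LatticeSpec
    connectivity: ConnectivityConfig
    unit: UnitParams = UnitParams()
    kernel: StimulusKernelParams = StimulusKernelParams()
    z: float = 0.05
    delay_per_step: float = 10.0
    n_steps: int = 2000
    burn_in_steps: int = 500
    dt: float = 0.001
    drive_freqs: np.ndarray | None = None
    scan_values: np.ndarray | None = None
    n_trials: int = 100
    n_boot: int = 1000
    scale: float = 1.0
    seed: int = 0
    regenerate_connectivity_per_trial: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        if round(self.n_trials * self.scale) < 5:
            raise ValueError("scale * n_trials must be >= 5")

    @property
    def n_trials_eff(self) -> int:
        return max(5, int(round(self.n_trials * self.scale)))

    @property
    def n_boot_eff(self) -> int:
        return max(100, int(round(self.n_boot * self.scale)))

    # ---- factory presets ---------------------------------------------

    @classmethod
    def fig2(cls, scale: float = 1.0, seed: int = 0) -> "ProtocolConfig":
        return cls(
            name="fig2",
            lattice=LatticeSpec(side=50),
            connectivity=ConnectivityConfig(),
            z=0.05,
            delay_per_step=10.0,
            n_steps=2000,
            drive_freqs=np.round(np.arange(10.0, 15.0 + 1e-9, 0.5), 2),
            n_trials=100,
            scale=scale,
            seed=seed,
        )

    @classmethod
    def fig3a(cls, seed: int = 0) -> "ProtocolConfig":
        return cls(
            name="fig3a",
            lattice=LatticeSpec(side=100),
            connectivity=ConnectivityConfig(),
            delay_per_step=10.0,
            scan_values=np.arange(2, 101, 2),
            seed=seed,
        )

    @classmethod
    def fig3b(cls, scale: float = 1.0, seed: int = 0) -> "ProtocolConfig":
        return cls(
            name="fig3b",
            lattice=LatticeSpec(side=30),
            connectivity=ConnectivityConfig(),
            z=0.05,
            n_steps=5000,
            drive_freqs=np.round(np.arange(12.0, 14.0 + 1e-9, 0.2), 2),
            scan_values=np.arange(10, 101, 10),
            n_trials=100,
            scale=scale,
            seed=seed,
        )

    @classmethod
    def fig3c(cls, scale: float = 1.0, seed: int = 0) -> "ProtocolConfig":
        # varied inhibitory degree, excitatory fixed at 5
        return cls(
            name="fig3c",
            lattice=LatticeSpec(side=30),
            connectivity=ConnectivityConfig(),
            z=0.07,
            delay_per_step=0.0,
            n_steps=5000,
            drive_freqs=np.round(np.arange(12.0, 17.0 + 1e-9, 0.2), 2),
            scan_values=np.arange(0, 10),
            n_trials=1000,
            scale=scale,
            seed=seed,
        )

    @classmethod
    def fig3d(cls, scale: float = 1.0, seed: int = 0) -> "ProtocolConfig":
        cfg = cls.fig3c(scale=scale, seed=seed)
        cfg.name = "fig3d"
        return cfg

    @classmethod
    def s1(cls, scale: float = 1.0, seed: int = 0) -> "ProtocolConfig":
        return cls(
            name="s1",
            lattice=LatticeSpec(side=2, macrocolumn_side=1),
            connectivity=ConnectivityConfig(k_exc=0, k_inh=0, long_range_fraction=0.0),
            z=0.05,
            delay_per_step=0.0,
            n_steps=5000,
            drive_freqs=np.round(np.arange(6.0, 13.0 + 1e-9, 0.2), 2),
            scan_values=np.array([0.017, 0.016, 0.015, 0.014, 0.013]),
            n_trials=100,
            scale=scale,
            seed=seed,
        )

    @classmethod
    def s2(cls, scale: float = 1.0, seed: int = 0) -> "ProtocolConfig":
        return cls(
            name="s2",
            lattice=LatticeSpec(side=30),
            connectivity=ConnectivityConfig(),
            z=0.05,
            delay_per_step=10.0,
            n_steps=5000,
            n_trials=100,
            scale=scale,
            seed=seed,
        )


@dataclass
class ScanResult:
    """Resonance frequency (bootstrap mean +/- SD) per scanned value."""

    parameter: str
    values: np.ndarray
    resonance_mean: np.ndarray
    resonance_sd: np.ndarray
    fit: FitResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter: self.values,
                "resonance_hz": self.resonance_mean,
                "resonance_sd_hz": self.resonance_sd,
            }
        )


@dataclass
class SizeResonanceResult:
    curves: dict  # mask side -> ResonanceCurve
    peaks: dict  # mask side -> Hz


def _driven_grid_spectra(
    cfg: ProtocolConfig,
    network: Network,
    mask: SubnetworkMask,
    seed_key: tuple[int, ...],
) -> list[tuple[float, list[PowerSpectrum]]]:
    """Per-trial spectra of the mask mean for every drive frequency.

    All (frequency, trial) combinations run as one batched integration;
    results are identical to running each frequency separately.
    """
    sim = SimulationConfig(
        dt=cfg.dt, n_steps=cfg.n_steps, burn_in_steps=cfg.burn_in_steps
    )
    total = cfg.burn_in_steps + cfg.n_steps
    conditions = [
        (
            periodic_drive(float(f), total, cfg.dt, cfg.kernel),
            _substream_seed(cfg.seed, *seed_key, fi),
        )
        for fi, f in enumerate(cfg.drive_freqs)
    ]
    series_list = run_conditions_mask_mean(
        conditions, network, cfg.unit, cfg.z, cfg.n_trials_eff, mask, sim
    )
    out = []
    for f, series in zip(cfg.drive_freqs, series_list):
        out.append(
            (
                float(f),
                [power_spectrum(series[:, k], cfg.dt) for k in range(series.shape[1])],
            )
        )
    return out


def _spontaneous_spectra(
    cfg: ProtocolConfig,
    network: Network,
    record_mask: SubnetworkMask,
    trial_seed_base: int,
) -> list[PowerSpectrum]:
    sim = SimulationConfig(
        dt=cfg.dt, n_steps=cfg.n_steps, burn_in_steps=cfg.burn_in_steps
    )
    series = run_trials_mask_mean(
        cfg.n_trials_eff,
        network,
        cfg.unit,
        cfg.z,
        trial_seed_base,
        sim=sim,
        record_mask=record_mask,
    )
    return [power_spectrum(series[:, k], cfg.dt) for k in range(series.shape[1])]


def run_size_resonance(cfg: ProtocolConfig | None = None) -> SizeResonanceResult:
    """Drive centred 10x10 and 30x30 patches of a 50x50 lattice.

    For each mask, one connectivity realization with lateral inhibition of
    the surround; the pulse-train drive sweeps the frequency grid and the
    bootstrap of normalized response power at the drive bin gives a
    resonance curve whose peak is the patch's resonance frequency.
    """
    if cfg is None:
        cfg = ProtocolConfig.fig2()
    curves: dict[int, ResonanceCurve] = {}
    peaks: dict[int, float] = {}
    for ci, mask_side in enumerate((10, 30)):
        conn = replace(cfg.connectivity, seed=_substream_seed(cfg.seed, 1, ci))
        network = build_network(cfg.lattice, conn, cfg.delay_per_step)
        mask = SubnetworkMask.centred_square(cfg.lattice, mask_side)
        apply_lateral_inhibition(network, mask)
        means, sds = [], []
        by_freq = _driven_grid_spectra(cfg, network, mask, (2, ci))
        for fi, (f, spectra) in enumerate(by_freq):
            m, s = bootstrap_response_power(
                spectra,
                f,
                BootstrapConfig(cfg.n_boot_eff, seed=_substream_seed(cfg.seed, 3, ci, fi)),
            )
            means.append(m)
            sds.append(s)
        curve = ResonanceCurve(
            np.asarray(cfg.drive_freqs, float), np.array(means), np.array(sds)
        )
        curves[mask_side] = curve
        peaks[mask_side] = peak_driving_frequency(curve)
    return SizeResonanceResult(curves, peaks)


def run_connectivity_profile(cfg: ProtocolConfig | None = None) -> pd.DataFrame:
    """Mean node degree and mean delay of growing centred sub-networks."""
    if cfg is None:
        cfg = ProtocolConfig.fig3a()
    conn = replace(cfg.connectivity, seed=_substream_seed(cfg.seed, 1))
    network = build_network(cfg.lattice, conn, cfg.delay_per_step)
    rows = []
    for side in cfg.scan_values:
        mask = SubnetworkMask.centred_square(cfg.lattice, int(side))
        deg, dly = subnetwork_connectivity_stats(network, mask)
        rows.append({"side": int(side), "mean_degree": deg, "mean_delay_steps": dly})
    return pd.DataFrame(rows)


def _peak_freq_scan(
    cfg: ProtocolConfig,
    networks: Sequence[Network],
    mask: SubnetworkMask,
    parameter: str,
) -> ScanResult:
    """Shared machinery of the delay and degree scans."""
    means, sds = [], []
    for vi, network in enumerate(networks):
        by_freq = _driven_grid_spectra(cfg, network, mask, (2, vi))
        m, s = bootstrap_peak_frequency(
            by_freq,
            BootstrapConfig(cfg.n_boot_eff, seed=_substream_seed(cfg.seed, 3, vi)),
        )
        means.append(m)
        sds.append(s)
    fit = linear_fit(cfg.scan_values, means)
    return ScanResult(
        parameter, np.asarray(cfg.scan_values), np.array(means), np.array(sds), fit
    )


def run_delay_scan(cfg: ProtocolConfig | None = None) -> ScanResult:
    """Resonance of a fully driven 30x30 network vs transmission delay."""
    if cfg is None:
        cfg = ProtocolConfig.fig3b()
    mask = SubnetworkMask.full(cfg.lattice)
    networks = []
    for vi, delay in enumerate(cfg.scan_values):
        conn = replace(cfg.connectivity, seed=_substream_seed(cfg.seed, 1, vi))
        networks.append(build_network(cfg.lattice, conn, float(delay)))
    return _peak_freq_scan(cfg, networks, mask, "delay_per_unit_distance")


def run_degree_scan(
    cfg: ProtocolConfig | None = None, varied: str = "inh"
) -> ScanResult:
    """Resonance vs local node degree at instantaneous transmission.

    ``varied`` selects which local degree sweeps 0..9 while the other
    stays at 5.  The long-range edge count is held fixed at its mid-value
    (the count implied by local degree 5) across the whole scan.
    """
    if varied not in ("exc", "inh"):
        raise ValueError("varied must be 'exc' or 'inh'")
    if cfg is None:
        cfg = ProtocolConfig.fig3c() if varied == "inh" else ProtocolConfig.fig3d()
    mask = SubnetworkMask.full(cfg.lattice)
    n_lr = int(
        round(cfg.connectivity.long_range_fraction * cfg.lattice.n_units * 5)
    )
    networks = []
    for vi, k in enumerate(cfg.scan_values):
        conn = replace(
            cfg.connectivity,
            k_exc=int(k) if varied == "exc" else 5,
            k_inh=int(k) if varied == "inh" else 5,
            seed=_substream_seed(cfg.seed, 1, vi),
        )
        networks.append(
            build_network(cfg.lattice, conn, cfg.delay_per_step, n_long_range=n_lr)
        )
    return _peak_freq_scan(cfg, networks, mask, f"local_{varied}_degree")


def run_single_unit_tau_scan(cfg: ProtocolConfig | None = None) -> pd.DataFrame:
    """Spontaneous peak and entrainment curve of an isolated unit per tau_i.

    The "network" is edgeless with per-unit noise, so each unit is an
    independent single Wilson-Cowan oscillator; activity of one unit is
    recorded.  For each inhibitory time constant the table holds the
    bootstrap peak of the spontaneous spectrum and, over the entrainment
    grid, the driving frequency of maximal response.
    """
    if cfg is None:
        cfg = ProtocolConfig.s1()
    mask = SubnetworkMask.centred_square(cfg.lattice, 1)
    rows = []
    for ti_idx, tau_i in enumerate(cfg.scan_values):
        unit = replace(cfg.unit, tau_e=0.018, tau_i=float(tau_i))
        ccfg = replace(cfg.connectivity, seed=_substream_seed(cfg.seed, 1, ti_idx))
        network = build_network(cfg.lattice, ccfg, 0.0)
        sub = replace(cfg, unit=unit)
        spectra = _spontaneous_spectra(
            sub, network, mask, _substream_seed(cfg.seed, 2, ti_idx)
        )
        pf, pf_sd, pp = bootstrap_spectrum_peak(
            spectra,
            BootstrapConfig(cfg.n_boot_eff, seed=_substream_seed(cfg.seed, 3, ti_idx)),
        )
        by_freq = []
        for fi, (f, dsp) in enumerate(
            _driven_grid_spectra(sub, network, mask, (4, ti_idx))
        ):
            m, _ = bootstrap_response_power(
                dsp,
                f,
                BootstrapConfig(
                    cfg.n_boot_eff, seed=_substream_seed(cfg.seed, 5, ti_idx, fi)
                ),
            )
            by_freq.append(m)
        curve = ResonanceCurve(
            np.asarray(cfg.drive_freqs, float),
            np.array(by_freq),
            np.zeros(len(by_freq)),
        )
        rows.append(
            {
                "tau_i": float(tau_i),
                "spontaneous_peak_hz": pf,
                "spontaneous_peak_sd_hz": pf_sd,
                "spontaneous_peak_power": pp,
                "entrainment_peak_hz": peak_driving_frequency(curve),
            }
        )
    return pd.DataFrame(rows)


def run_noise_strength_scan(cfg: ProtocolConfig | None = None):
    """Spontaneous spectral peak vs noise level and connection strengths.

    Returns ``(noise_table, strength_table)``.  A degenerate z = 0 run
    (no fluctuations to normalize) yields NaN rather than an error.
    """
    if cfg is None:
        cfg = ProtocolConfig.s2()
    record = SubnetworkMask.full(cfg.lattice)

    def peak_for(conn_seed_key, z, ce, ci, trial_key):
        conn = replace(
            cfg.connectivity,
            ce_strength=ce,
            ci_strength=ci,
            seed=_substream_seed(cfg.seed, *conn_seed_key),
        )
        network = build_network(cfg.lattice, conn, cfg.delay_per_step)
        sub = replace(cfg, z=z)
        try:
            spectra = _spontaneous_spectra(
                sub, network, record, _substream_seed(cfg.seed, *trial_key)
            )
        except ValueError:
            return float("nan"), float("nan")
        pf, _, pp = bootstrap_spectrum_peak(
            spectra, BootstrapConfig(cfg.n_boot_eff, seed=_substream_seed(cfg.seed, 9, *trial_key))
        )
        return pf, pp

    noise_rows = []
    for zi, z in enumerate([0.0, 0.01, 0.03, 0.05, 0.07, 0.09]):
        pf, pp = peak_for((1, zi), z, 0.15, 0.10, (2, zi))
        noise_rows.append({"z": z, "peak_hz": pf, "peak_power": pp})

    strength_rows = []
    grid = [0.05, 0.10, 0.15, 0.20, 0.25, 0.30]
    for si, cs in enumerate(grid):
        pf, _ = peak_for((3, si), cfg.z, cs, 0.10, (4, si))
        strength_rows.append({"varied": "cs_e", "strength": cs, "peak_hz": pf})
    for si, cs in enumerate(grid):
        pf, _ = peak_for((5, si), cfg.z, 0.15, cs, (6, si))
        strength_rows.append({"varied": "cs_i", "strength": cs, "peak_hz": pf})

    return pd.DataFrame(noise_rows), pd.DataFrame(strength_rows)
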