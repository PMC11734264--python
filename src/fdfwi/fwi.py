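"""Frequency-domain full-waveform inversion with adjoint-state gradients.

The misfit at a single frequency is

    E(w, s) = 1/2 sum_i || p_i(w, s) - p_obs,i(w) ||^2

over transmits i, where ``p_i = a_i R u_i`` is the simulated receive vector
(``u_i`` the unit-source Helmholtz field, ``R`` bilinear receiver sampling,
``a_i`` a per-transmit complex source amplitude estimated by least squares),
and ``p_obs,i`` the observed channel vector. Exactly the same code path runs
on measured spectra and on frequency-differenced spectra — the engine never
inspects provenance, only the data object differs — which is what makes the
difference-frequency objective "identical to the original" by construction.

Gradients are discretize-then-optimize adjoint state: one extra solve per
transmit with the receiver-injected conjugated residuals, reusing the same LU
factors (the discrete system is complex symmetric). Model updates use
nonlinear Polak-Ribiere+ conjugate gradient with a parabolic line search and
physical clipping.

Reconstruction protocols:

* :func:`run_fd_kickstart` — single ascending sweep over the
  difference-frequency grid, sound speed only, 2 CG iterations per frequency
  (attenuation is never updated from frequency-differenced data).
* :func:`run_two_pass_fwi` — pass 1 sweeps its frequency list updating sound
  speed only; pass 2 sweeps a staggered list alternating a sound-speed block
  then an attenuation block per frequency; 3 CG iterations per block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .data import ChannelSpectra
from .exceptions import DegenerateSourceError
from .freqdiff import FDBand
from .helmholtz import (
    PMLConfig,
    assemble_helmholtz,
    bilinear_weights,
    source_vector,
)
from .phantom import AcousticModel

__all__ = [
    "FrequencySchedule",
    "InversionConfig",
    "ReconstructionResult",
    "objective",
    "estimate_source",
    "gradient",
    "cg_update_block",
    "run_fd_kickstart",
    "run_two_pass_fwi",
    "receiver_mask",
]

log = logging.getLogger(__name__)

Parameter = Literal["sound_speed", "attenuation"]


@dataclass(frozen=True)
class FrequencySchedule:
    """Frequency lists and iteration counts for the reconstruction protocols."""

    pass1_frequencies: tuple[float, ...]
    pass2_frequencies: tuple[float, ...]
    fd_band: FDBand | None = None
    cg_iterations_main: int = 3
    cg_iterations_fd: int = 2

    def __post_init__(self) -> None:
        for name in ("pass1_frequencies", "pass2_frequencies"):
            fl = tuple(float(f) for f in getattr(self, name))
            object.__setattr__(self, name, fl)
            if len(fl) > 1 and not all(b > a for a, b in zip(fl, fl[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.cg_iterations_main < 1 or self.cg_iterations_fd < 1:
            raise ValueError("CG iteration counts must be at least 1")


@dataclass
class InversionConfig:
    """Tunables shared by every inversion entry point.

    ``self_receive_exclusion`` masks receivers within +/- that many element
    indices (circularly) of the transmitter: the coincident channel is
    singular in a point-source model and near-neighbors are dominated by it.
    Sound-speed updates are clipped to ``sound_speed_bounds`` (widen for
    transcranial work); attenuation is clipped to be nonnegative. ``step0_*``
    set the largest pointwise change attempted by the first line-search trial.
    """

    pml: PMLConfig = field(default_factory=PMLConfig)
    self_receive_exclusion: int = 5
    sound_speed_bounds: tuple[float, float] = (1300.0, 1800.0)
    attenuation_max: float = 10.0
    source_stencil: str = "nearest"
    precondition: bool = True
    precondition_eps: float = 1e-3
    step0_sound_speed: float = 10.0  # m/s
    step0_attenuation: float = 0.05  # dB/(cm MHz)
    max_backtracks: int = 5
    update_radius_fraction: float = 0.97  # restrict updates inside this ring fraction

    def snapshot(self) -> dict:
        d = asdict(self)
        d["pml"] = asdict(self.pml)
        return d


@dataclass
class ReconstructionResult:
    """Recovered model plus the per-frequency objective history."""

    model: AcousticModel
    objective_history: list[tuple[float, str, int, float]]  # (freq, pass id, iter, E)
    config: dict


def receiver_mask(n_elements: int, exclusion: int) -> np.ndarray:
    """(n_tx, n_rx) boolean mask, False within +/- ``exclusion`` of the diagonal
    (circular distance)."""
    i = np.arange(n_elements)
    d = np.abs(i[:, None] - i[None, :])
    d = np.minimum(d, n_elements - d)
    return d > exclusion


def estimate_source(sim_unit: np.ndarray, obs: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-transmit complex source amplitude minimizing ||a * sim - obs||^2.

    ``sim_unit`` and ``obs`` have shape (n_tx, n_rx); the optimum is the
    complex projection ``a_i = <sim_i, obs_i> / ||sim_i||^2`` over unmasked
    receivers.
    """
    sim_unit = np.asarray(sim_unit)
    obs = np.asarray(obs)
    if mask is None:
        mask = np.ones(sim_unit.shape, dtype=bool)
    num = np.sum(np.conj(sim_unit) * obs * mask, axis=1)
    den = np.sum(np.abs(sim_unit) ** 2 * mask, axis=1)
    if np.any(den == 0):
        bad = np.nonzero(den == 0)[0]
        raise DegenerateSourceError(
            f"all-zero simulated channel for transmit(s) {bad.tolist()[:10]}"
        )
    return num / den


class _FrequencyWorkspace:
    """Forward solves, sampling and misfit at one (model, frequency) pair.

    One factorization; transmit fields and adjoint solves share it.
    """

    def __init__(self, model: AcousticModel, observed: ChannelSpectra, frequency: float,
                 config: InversionConfig):
        self.model = model
        self.observed = observed
        self.frequency = frequency
        self.config = config
        self.array = observed.array
        self.obs = observed.at_frequency(frequency)
        self.mask = receiver_mask(self.array.n_elements, config.self_receive_exclusion)
        if not self.mask.any(axis=1).all():
            raise ValueError(
                f"self_receive_exclusion={config.self_receive_exclusion} leaves no "
                f"usable receivers on a {self.array.n_elements}-element ring; "
                "reduce the exclusion"
            )
        self.op = assemble_helmholtz(model, frequency, pml=config.pml)
        grid = model.grid
        n = grid.nx * grid.ny
        n_el = self.array.n_elements
        # receiver sampling matrix entries, shared by sampling and adjoint injection
        self._rx_idx: list[np.ndarray] = []
        self._rx_w: list[np.ndarray] = []
        for pos in self.array.element_positions:
            idx, w = bilinear_weights(grid, pos)
            self._rx_idx.append(idx)
            self._rx_w.append(w)
        B = np.zeros((n, n_el), dtype=complex)
        for j, pos in enumerate(self.array.element_positions):
            B[:, j] = source_vector(self.op, tuple(pos), 1.0, stencil=config.source_stencil)
        self.U = self.op.solve(B)  # (n, n_tx) unit-source fields
        self.sim_unit = self._sample(self.U)  # (n_tx, n_rx)
        self.sources = estimate_source(self.sim_unit, self.obs, self.mask)
        self.residual = (self.sources[:, None] * self.sim_unit - self.obs) * self.mask
        self.E = 0.5 * float(np.sum(np.abs(self.residual) ** 2))

    def _sample(self, U: np.ndarray) -> np.ndarray:
        n_el = self.array.n_elements
        out = np.empty((U.shape[1], n_el), dtype=complex)
        for r in range(n_el):
            out[:, r] = (self._rx_w[r] @ U[self._rx_idx[r], :])
        return out

    def gradient(self, parameter: Parameter) -> np.ndarray:
        """Adjoint-state gradient of E w.r.t. the chosen parameter map."""
        grid = self.model.grid
        n = grid.nx * grid.ny
        n_tx = self.array.n_elements
        V = np.zeros((n, n_tx), dtype=complex)
        conj_r = np.conj(self.residual)
        for r in range(n_tx):
            idx, w = self._rx_idx[r], self._rx_w[r]
            # scatter a_i * w * conj(residual_i_r) into column i
            V[idx, :] += w[:, None] * (self.sources[None, :] * conj_r[:, r][None, :])
        W = self.op.solve(V)  # A symmetric: A^-T = A^-1
        dD = self._dD_dparam(parameter)
        g = -np.real(dD[:, None] * self.U * W).sum(axis=1)
        return g.reshape(grid.shape)

    def illumination(self) -> np.ndarray:
        return (np.abs(self.U) ** 2).sum(axis=1).reshape(self.model.grid.shape)

    def _dD_dparam(self, parameter: Parameter) -> np.ndarray:
        """Derivative of the system's diagonal mass term D = S * k^2 * gamma.

        gamma is the dispersion-correction factor 1 - beta * (w h / c)^2 with
        beta = 0.75/12, a function of sound speed only.
        """
        op = self.op
        omega = op.omega
        h = self.model.grid.spacing
        c = self.model.sound_speed.ravel()
        k = op.k
        gamma = op.gamma
        S = op.stretch_diag
        if parameter == "sound_speed":
            dk_dc = -omega / c**2
            d = 2.0 * k * dk_dc * gamma
            if op.dispersion_correction:
                beta = 0.75 / 12.0
                dgamma_dc = 2.0 * beta * (omega * h) ** 2 / c**3
                d = d + k**2 * dgamma_dc
            return S * d
        elif parameter == "attenuation":
            from .helmholtz import _DB_CM_TO_NP_M

            dk_da = 1j * _DB_CM_TO_NP_M * (self.frequency / 1e6)
            return S * 2.0 * k * dk_da * gamma
        raise ValueError(f"unknown parameter {parameter!r}")


def objective(
    model: AcousticModel,
    observed: ChannelSpectra,
    frequency: float,
    sources: np.ndarray | None = None,
    config: InversionConfig | None = None,
) -> float:
    """Misfit E = 1/2 sum_i ||a_i sim_i - obs_i||^2 over unmasked receivers.

    When ``sources`` is None the per-transmit amplitudes are estimated by
    least squares (variable projection); passing fixed amplitudes evaluates
    the raw objective at those sources.
    """
    config = config or InversionConfig()
    ws = _FrequencyWorkspace(model, observed, frequency, config)
    if sources is None:
        return ws.E
    residual = (np.asarray(sources)[:, None] * ws.sim_unit - ws.obs) * ws.mask
    return 0.5 * float(np.sum(np.abs(residual) ** 2))


def gradient(
    model: AcousticModel,
    observed: ChannelSpectra,
    frequency: float,
    parameter: Parameter,
    config: InversionConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Objective value and adjoint-state gradient map at one frequency.

    Sources are re-estimated at the current model before the gradient is
    formed (the variable-projection optimum, so the reduced-objective gradient
    equals the fixed-source gradient by the envelope theorem).
    """
    config = config or InversionConfig()
    ws = _FrequencyWorkspace(model, observed, frequency, config)
    return ws.E, ws.gradient(parameter)


def _update_mask(model: AcousticModel, observed: ChannelSpectra, fraction: float) -> np.ndarray:
    arr = observed.array
    X, Y = model.grid.meshgrid()
    r2 = (X - arr.center[0]) ** 2 + (Y - arr.center[1]) ** 2
    return (r2 < (fraction * arr.radius) ** 2).astype(float)


def _apply_step(model: AcousticModel, parameter: Parameter, step: np.ndarray,
                config: InversionConfig) -> AcousticModel:
    new = model.copy()
    if parameter == "sound_speed":
        lo, hi = config.sound_speed_bounds
        new.sound_speed = np.clip(model.sound_speed + step, lo, hi)
    else:
        new.attenuation = np.clip(model.attenuation + step, 0.0, config.attenuation_max)
    return new


def cg_update_block(
    model: AcousticModel,
    observed: ChannelSpectra,
    frequency: float,
    parameter: Parameter,
    n_iters: int,
    config: InversionConfig | None = None,
    history: list | None = None,
    pass_id: str = "",
) -> AcousticModel:
    """``n_iters`` nonlinear CG iterations on one parameter at one frequency.

    Polak-Ribiere+ directions with restart on non-descent; parabolic line
    search seeded by the directional derivative, with backtracking (cap
    ``config.max_backtracks``); steps are accepted only if they decrease E, so
    the objective is nonincreasing across the block. Updates are clipped to
    physical bounds and restricted to the ring interior.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be at least 1")
    config = config or InversionConfig()
    mask = _update_mask(model, observed, config.update_radius_fraction)
    step0 = (
        config.step0_sound_speed if parameter == "sound_speed" else config.step0_attenuation
    )
    g_prev = None
    pg_prev = None
    d = None
    E_last = np.nan
    for it in range(n_iters):
        ws = _FrequencyWorkspace(model, observed, frequency, config)
        E0 = ws.E
        g = ws.gradient(parameter)
        if history is not None:
            history.append((frequency, pass_id, it, E0))
        if config.precondition:
            illum = ws.illumination()
            P = 1.0 / (illum + config.precondition_eps * float(illum.max()) + 1e-300)
        else:
            P = 1.0
        pg = g * P * mask
        if g_prev is None:
            d = -pg
        else:
            denom = float(np.sum(pg_prev * g_prev))
            beta = max(0.0, float(np.sum(pg * (g - g_prev))) / denom) if denom > 0 else 0.0
            d = -pg + beta * d
            if float(np.sum(d * g)) >= 0:  # not a descent direction: restart
                d = -pg
        slope = float(np.sum(d * g))  # dE/dalpha at alpha=0
        dmax = float(np.max(np.abs(d)))
        if dmax == 0 or slope >= 0:
            log.info("cg block %s f=%.3g: zero/ascent direction, stopping", pass_id, frequency)
            break
        alpha0 = step0 / dmax
        accepted = False
        for bt in range(config.max_backtracks + 1):
            trial = _apply_step(model, parameter, alpha0 * d, config)
            E1 = objective(trial, observed, frequency, config=config)
            if E1 < E0:
                # parabola through E(0), E'(0), E(alpha0)
                curv = (E1 - E0 - slope * alpha0) / alpha0**2
                best_model, best_E = trial, E1
                if curv > 0:
                    alpha_star = float(np.clip(-slope / (2 * curv), 0.1 * alpha0, 3.0 * alpha0))
                    if not np.isclose(alpha_star, alpha0, rtol=0.05):
                        cand = _apply_step(model, parameter, alpha_star * d, config)
                        E2 = objective(cand, observed, frequency, config=config)
                        if E2 < best_E:
                            best_model, best_E = cand, E2
                model, E_last = best_model, best_E
                accepted = True
                break
            alpha0 *= 0.5
        if not accepted:
            warnings.warn(
                f"line search failed after {config.max_backtracks} backtracks at "
                f"{frequency/1e6:.3g} MHz ({parameter}); ending block early",
                stacklevel=2,
            )
            break
        g_prev, pg_prev = g, pg
    if history is not None and np.isfinite(E_last):
        history.append((frequency, pass_id, n_iters, E_last))
    return model


def run_fd_kickstart(
    fd_data: ChannelSpectra,
    schedule: FrequencySchedule,
    start: AcousticModel,
    config: InversionConfig | None = None,
    history: list | None = None,
) -> AcousticModel:
    """Single-pass sound-speed-only FWI on frequency-differenced data.

    Sweeps the difference frequencies ascending, ``cg_iterations_fd``
    (default 2) CG iterations each; attenuation is never touched. The result
    is the *kickstart model* handed to :func:`run_two_pass_fwi` in place of a
    homogeneous start.
    """
    if fd_data.provenance != "frequency_differenced":
        raise ValueError(
            f"run_fd_kickstart expects frequency_differenced data, got {fd_data.provenance!r}"
        )
    config = config or InversionConfig()
    model = start.copy()
    for f in np.sort(fd_data.frequencies):
        model = cg_update_block(
            model, fd_data, float(f), "sound_speed", schedule.cg_iterations_fd,
            config, history, pass_id="fd",
        )
    return model


def run_two_pass_fwi(
    data: ChannelSpectra,
    schedule: FrequencySchedule,
    start: AcousticModel,
    config: InversionConfig | None = None,
) -> ReconstructionResult:
    """The two-pass reconstruction protocol.

    Pass 1 sweeps ``pass1_frequencies`` ascending updating sound speed only;
    pass 2 sweeps ``pass2_frequencies`` ascending, at each frequency running a
    sound-speed block then an attenuation block. Every block uses
    ``cg_iterations_main`` (default 3) CG iterations. Empty frequency lists
    return the start model unchanged.
    """
    config = config or InversionConfig()
    history: list[tuple[float, str, int, float]] = []
    model = start.copy()
    for f in schedule.pass1_frequencies:
        model = cg_update_block(
            model, data, f, "sound_speed", schedule.cg_iterations_main,
            config, history, pass_id="pass1",
        )
    for f in schedule.pass2_frequencies:
        model = cg_update_block(
            model, data, f, "sound_speed", schedule.cg_iterations_main,
            config, history, pass_id="pass2-c",
        )
        model = cg_update_block(
            model, data, f, "attenuation", schedule.cg_iterations_main,
            config, history, pass_id="pass2-a",
        )
    return ReconstructionResult(model=model, objective_history=history, config=config.snapshot())
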