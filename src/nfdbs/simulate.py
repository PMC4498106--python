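"""Forward-Euler integration of the closed-loop delayed neural fields.

The integrator keeps a ring buffer of past population states so that each
synaptic connection can read the presynaptic rate at its own axonal lag
z_j(r', t - d_j(r, r')).  Exogenous drive is stochastic: cortical input to the
STN and (sign-inverted) striatal input to the GPe, white in time and space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from .control import StimulationPolicy, averaged_term, delayed_term, proportional_term
from .model import NeuralFieldModel, sigmoid

__all__ = ["SimConfig", "HistoryBuffer", "SimulationResult", "sample_inputs", "simulate"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Temporal and input configuration of one simulation run.

    Times in ms, rates in spk/s.  The exogenous inputs are
    I1 = cortical_weight * (cortical_rate + eta) to the STN and
    I2 = striatal_sign * striatal_weight * (striatal_rate + eta') to the GPe,
    with eta, eta' Gaussian, variance ``noise_variance``, drawn independently
    per node and per step (per population per step when ``noise_shared``).

    ``stimulation_weight`` converts the controller's stimulation *rate* into
    input units, mirroring how afferent rates are weighted (default: the
    cortical input weight 12.5, i.e. the actuator behaves like a regulatable
    afferent population).  Set it to 1 to add the raw controller rate to the
    activation argument instead.
    """

    tau1: float = 6.0
    tau2: float = 14.0
    dt: float = 1.0
    t_f: float = 1000.0
    stim_onset: float = 500.0
    cortical_rate: float = 27.0
    striatal_rate: float = 2.0
    noise_variance: float = 0.05
    cortical_weight: float = 12.5
    striatal_weight: float = 110.0
    striatal_sign: float = -1.0
    stimulation_weight: float = 12.5
    noise_shared: bool = False
    initial_history: Literal["zeros", "baseline", "random"] = "zeros"
    seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.dt >= min(self.tau1, self.tau2):
            raise ValueError(
                f"Euler stability requires dt < min(tau1, tau2); got dt={self.dt}, "
                f"tau1={self.tau1}, tau2={self.tau2}"
            )
        if not 0 <= self.stim_onset <= self.t_f:
            raise ValueError(
                f"need 0 <= stim_onset <= t_f, got onset={self.stim_onset}, t_f={self.t_f}"
            )
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_f / self.dt))


class HistoryBuffer:
    """Ring buffer over the last ``n_lags`` state vectors of one population.

    ``read(lags)`` with an integer array of lags (in steps) returns the state
    that many steps ago; before the simulation has run that long it returns
    the initial history value.  Lag 0 is the current state.
    """

    def __init__(self, n_lags: int, initial: np.ndarray):
        self.n_slots = n_lags + 1
        self.buf = np.tile(np.asarray(initial, dtype=float), (self.n_slots, 1))
        self.cursor = 0
        self._cols = np.broadcast_to(
            np.arange(self.buf.shape[1])[None, :], (1, self.buf.shape[1])
        )

    def push(self, state: np.ndarray) -> None:
        self.cursor = (self.cursor + 1) % self.n_slots
        self.buf[self.cursor] = state

    def read(self, lags: np.ndarray) -> np.ndarray:
        """Gather per-connection lagged states; lags shaped (n_post, n_pre)."""
        rows = (self.cursor - lags) % self.n_slots
        cols = np.broadcast_to(np.arange(self.buf.shape[1])[None, :], lags.shape)
        return self.buf[rows, cols]

    def read_lag(self, lag: int) -> np.ndarray:
        """Whole state vector ``lag`` steps ago."""
        return self.buf[(self.cursor - lag) % self.n_slots]


@dataclass
class SimulationResult:
    """Trajectories of one run: rates per node per step plus the stimulation.

    ``z1``/``z2``: (n_steps, n_pop) rates in spk/s; ``u``: the raw controller
    rate u(r, t) per STN node; ``u_applied``: the alpha-weighted,
    synaptically weighted term actually added to the STN activation argument.
    ``times`` are the ends of each Euler step (ms).
    """

    times: np.ndarray
    z1: np.ndarray
    z2: np.ndarray
    u: np.ndarray
    u_applied: np.ndarray
    config: SimConfig
    seed: int | None

    def mean_stn_rate(self) -> np.ndarray:
        return self.z1.mean(axis=1)

    def mean_gpe_rate(self) -> np.ndarray:
        return self.z2.mean(axis=1)

    def to_frame(self):
        """Long-format table: time_ms, population, node, rate_spk_s."""
        import pandas as pd

        frames = []
        for name, arr in (("STN", self.z1), ("GPe", self.z2)):
            n = arr.shape[1]
            frames.append(
                pd.DataFrame(
                    {
                        "time_ms": np.repeat(self.times, n),
                        "population": name,
                        "node": np.tile(np.arange(n), arr.shape[0]),
                        "rate_spk_s": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def sample_inputs(
    rng: np.random.Generator, n_stn: int, n_gpe: int, cfg: SimConfig = SimConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """One step of exogenous input: (I1 per STN node, I2 per GPe node).

    I1 = w_ctx * (r_ctx + eta), I2 = -w_str * (r_str + eta'); eta i.i.d.
    Gaussian with variance ``cfg.noise_variance``.  With zero variance this
    is the constant pair (337.5, -220.0) at nominal parameters.
    """
    sd = float(np.sqrt(cfg.noise_variance))
    if cfg.noise_shared:
        eta1 = np.full(n_stn, rng.normal(0.0, sd)) if sd else np.zeros(n_stn)
        eta2 = np.full(n_gpe, rng.normal(0.0, sd)) if sd else np.zeros(n_gpe)
    else:
        eta1 = rng.normal(0.0, sd, n_stn) if sd else np.zeros(n_stn)
        eta2 = rng.normal(0.0, sd, n_gpe) if sd else np.zeros(n_gpe)
    I1 = cfg.cortical_weight * (cfg.cortical_rate + eta1)
    I2 = cfg.striatal_sign * cfg.striatal_weight * (cfg.striatal_rate + eta2)
    return I1, I2


def _initial_state(cfg: SimConfig, model: NeuralFieldModel, rng: np.random.Generator):
    n1, n2 = model.grid.n_stn, model.grid.n_gpe
    if cfg.initial_history == "zeros":
        return np.zeros(n1), np.zeros(n2)
    if cfg.initial_history == "baseline":
        return (
            np.full(n1, model.act1.base_rate),
            np.full(n2, model.act2.base_rate),
        )
    return (
        rng.uniform(0.0, model.act1.base_rate, n1),
        rng.uniform(0.0, model.act2.base_rate, n2),
    )


def simulate(
    model: NeuralFieldModel,
    cfg: SimConfig = SimConfig(),
    policy: StimulationPolicy | None = None,
) -> SimulationResult:
    """Integrate the closed-loop delayed neural fields over [0, t_f].

    The policy is inactive before ``cfg.stim_onset`` (u recorded as 0).  Runs
    with equal seeds and configurations produce bit-identical results.
    Raises ``FloatingPointError`` if the state stops being finite.
    """
    if policy is None:
        policy = StimulationPolicy()
    grid = model.grid
    n1, n2 = grid.n_stn, grid.n_gpe
    dt = cfg.dt
    D12, D21, D22 = model.delay_blocks()
    control_lag = int(np.floor(policy.T / dt + 0.5))
    n_lags = int(max(D12.max(), D21.max(), D22.max(), control_lag))

    rng = np.random.default_rng(cfg.seed)
    z1, z2 = _initial_state(cfg, model, rng)
    h1 = HistoryBuffer(n_lags, z1)
    h2 = HistoryBuffer(n_lags, z2)

    W12, W21, W22 = model.kernels.W12, model.kernels.W21, model.kernels.W22
    # precomputed gather columns: rows vary with the cursor, columns do not
    cols12 = np.broadcast_to(np.arange(n2)[None, :], D12.shape)
    cols21 = np.broadcast_to(np.arange(n1)[None, :], D21.shape)
    cols22 = np.broadcast_to(np.arange(n2)[None, :], D22.shape)
    n_slots = n_lags + 1
    n_steps = cfg.n_steps
    Z1 = np.empty((n_steps, n1))
    Z2 = np.empty((n_steps, n2))
    U = np.zeros((n_steps, n1))
    UA = np.zeros((n_steps, n1))
    e1 = dt / cfg.tau1
    e2 = dt / cfg.tau2
    variant = policy.variant if policy.kc > 0 else "none"

    buf1, buf2 = h1.buf, h2.buf
    for k in range(n_steps):
        t = k * dt
        cur = h1.cursor  # h1 and h2 advance in lockstep
        syn1 = (W12 * buf2[(cur - D12) % n_slots, cols12]).sum(axis=1)
        syn2 = (W21 * buf1[(cur - D21) % n_slots, cols21]).sum(axis=1) + (
            W22 * buf2[(cur - D22) % n_slots, cols22]
        ).sum(axis=1)
        I1, I2 = sample_inputs(rng, n1, n2, cfg)

        stim = 0.0
        if variant != "none" and t >= cfg.stim_onset:
            if variant == "proportional":
                u_raw, term = proportional_term(z1, policy)
            elif variant == "averaged":
                u_raw, term = averaged_term(z1, policy, grid)
            elif variant == "delayed_proportional":
                u_raw, term = delayed_term(h1.read_lag(control_lag), policy)
            else:  # pragma: no cover - guarded by StimulationPolicy typing
                raise ValueError(f"unknown policy variant {variant!r}")
            stim = cfg.stimulation_weight * term
            U[k] = u_raw
            UA[k] = stim

        z1 = z1 + e1 * (-z1 + sigmoid(syn1 + I1 + stim, model.act1))
        z2 = z2 + e2 * (-z2 + sigmoid(syn2 + I2, model.act2))
        if not (np.all(np.isfinite(z1)) and np.all(np.isfinite(z2))):
            raise FloatingPointError(
                f"state diverged at t={t + dt:.1f} ms (non-finite rates); "
                "check dt/tau and kernel amplitudes"
            )
        h1.push(z1)
        h2.push(z2)
        Z1[k] = z1
        Z2[k] = z2

    logger.info(
        "simulated %d steps (m=%d, seed=%s, policy=%s, kc=%g)",
        n_steps, grid.n_nodes, cfg.seed, policy.variant, policy.kc,
    )
    return SimulationResult(
        times=(np.arange(n_steps) + 1) * dt,
        z1=Z1,
        z2=Z2,
        u=U,
        u_applied=UA,
        config=cfg,
        seed=cfg.seed,
    )
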