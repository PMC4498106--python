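import numpy as np
import pytest

from nfdbs import SimConfig, build_model
from nfdbs.control import StimulationPolicy, averaged_term, delayed_term, proportional_term
from nfdbs.model import NeuralFieldModel, sigmoid
from nfdbs.simulate import sample_inputs


@pytest.fixture(scope="session")
def nominal_model() -> NeuralFieldModel:
    return build_model()


@pytest.fixture(scope="session")
def tiny_model() -> NeuralFieldModel:
    """Smallest legal grid: one STN node, one GPe node, four silent spacers."""
    return build_model(m=6)


def oracle_simulate(model, cfg: SimConfig, policy: StimulationPolicy | None = None):
    """Reference integrator: store the whole trajectory, index t - d directly.

    Same model and noise stream as :func:`nfdbs.simulate.simulate` but without
    any ring buffer: the delayed presynaptic state is looked up in the full
    per-step state history (clamped to the initial history before t = 0).
    Used to validate the ring-buffer implementation.
    """
    grid = model.grid
    n1, n2 = grid.n_stn, grid.n_gpe
    D12, D21, D22 = model.delay_blocks()
    rng = np.random.default_rng(cfg.seed)
    assert cfg.initial_history == "zeros"
    z1 = np.zeros(n1)
    z2 = np.zeros(n2)
    states1 = [z1.copy()]
    states2 = [z2.copy()]
    n_steps = cfg.n_steps
    control_lag = 0
    if policy is not None:
        control_lag = int(np.floor(policy.T / cfg.dt + 0.5))
    Z1 = np.empty((n_steps, n1))
    Z2 = np.empty((n_steps, n2))
    U = np.zeros((n_steps, n1))
    for k in range(n_steps):
        t = k * cfg.dt
        syn1 = np.zeros(n1)
        for i in range(n1):
            for j in range(n2):
                syn1[i] += model.kernels.W12[i, j] * states2[max(k - D12[i, j], 0)][j]
        syn2 = np.zeros(n2)
        for i in range(n2):
            for j in range(n1):
                syn2[i] += model.kernels.W21[i, j] * states1[max(k - D21[i, j], 0)][j]
            for j in range(n2):
                syn2[i] += model.kernels.W22[i, j] * states2[max(k - D22[i, j], 0)][j]
        I1, I2 = sample_inputs(rng, n1, n2, cfg)
        stim = 0.0
        if policy is not None and policy.kc > 0 and t >= cfg.stim_onset:
            if policy.variant == "proportional":
                u_raw, term = proportional_term(z1, policy)
            elif policy.variant == "averaged":
                u_raw, term = averaged_term(z1, policy, grid)
            else:
                u_raw, term = delayed_term(states1[max(k - control_lag, 0)], policy)
            stim = cfg.stimulation_weight * term
            U[k] = u_raw
        z1 = z1 + cfg.dt / cfg.tau1 * (-z1 + sigmoid(syn1 + I1 + stim, model.act1))
        z2 = z2 + cfg.dt / cfg.tau2 * (-z2 + sigmoid(syn2 + I2, model.act2))
        states1.append(z1.copy())
        states2.append(z2.copy())
        Z1[k] = z1
        Z2[k] = z2
    return Z1, Z2, U
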