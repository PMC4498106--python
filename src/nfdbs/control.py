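"""Closed-loop stimulation policies for the STN.

All controllers compute a stimulation *rate* u from the measured STN activity:

* proportional:          u(r, t) = -kc (z1(r, t) - zref(r))
* averaged (one source): u(t)    = -kc integral_STN (z1(r, t) - zref(r)) dr
* delayed proportional:  u(r, t) = -kc (z1(r, t - T) - zref(r))

The rate acts on each STN node through the photosensitization gain alpha(r)
(zero where gene transfer or illumination failed), and enters the STN input
like any other afferent rate — weighted by the uniform input synaptic weight
(see :class:`nfdbs.simulate.SimConfig.stimulation_weight`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .model import AlphaProfile, SpaceGrid

__all__ = ["StimulationPolicy", "proportional_term", "averaged_term", "delayed_term"]

Variant = Literal["none", "proportional", "averaged", "delayed_proportional"]


@dataclass(frozen=True)
class StimulationPolicy:
    """Controller variant with gain, target pattern and actuation profile.

    ``kc`` is the non-negative feedback gain; ``zref`` the target STN rate
    pattern (spk/s, scalar or per-STN-node); ``alpha`` the photosensitization
    profile; ``T`` the acquisition/processing delay in ms (delayed variant
    only).  ``averaged_mode`` selects how the single-light-source signal
    aggregates space: "integral" (default, the spatial integral over the STN
    subdomain with the node measure dr), "mean" (node average) or "sum"
    (plain node sum).
    """

    variant: Variant = "none"
    kc: float = 0.0
    zref: float | np.ndarray = 0.0
    alpha: AlphaProfile | None = None
    T: float = 0.0
    averaged_mode: Literal["integral", "mean", "sum"] = "integral"

    def __post_init__(self):
        if self.kc < 0:
            raise ValueError(f"feedback gain kc must be >= 0, got {self.kc}")
        if self.T < 0:
            raise ValueError(f"acquisition delay T must be >= 0, got {self.T}")
        if not np.all(np.isfinite(np.asarray(self.zref, dtype=float))):
            raise ValueError("zref must be finite")

    def zref_array(self, n_stn: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.zref, dtype=float), (n_stn,)).copy()

    def alpha_values(self, n_stn: int) -> np.ndarray:
        if self.alpha is None:
            return np.ones(n_stn)
        return self.alpha.values


def proportional_term(z1_now: np.ndarray, policy: StimulationPolicy):
    """Per-node stimulation from the instantaneous proportional law.

    Returns ``(u_raw, term)``: the raw controller rate u(r, t) per STN node
    and the alpha-weighted term alpha(r) * u(r, t) that enters the STN input.
    Nodes with alpha = 0 receive nothing regardless of their error.
    """
    n = z1_now.shape[0]
    u_raw = -policy.kc * (z1_now - policy.zref_array(n))
    return u_raw, policy.alpha_values(n) * u_raw


def averaged_term(z1_now: np.ndarray, policy: StimulationPolicy, grid: SpaceGrid):
    """Single-light-source stimulation: one scalar rate for the whole STN.

    The scalar u(t) aggregates the STN activity error over space (spatial
    integral by default); every node receives alpha(r) * u(t).  Returns
    ``(u_raw, term)`` with ``u_raw`` the scalar broadcast per node.
    """
    n = z1_now.shape[0]
    err = z1_now - policy.zref_array(n)
    if policy.averaged_mode == "integral":
        agg = err.sum() * grid.dr
    elif policy.averaged_mode == "mean":
        agg = err.mean()
    else:  # "sum"
        agg = err.sum()
    u = -policy.kc * float(agg)
    u_raw = np.full(n, u)
    return u_raw, policy.alpha_values(n) * u_raw


def delayed_term(z1_lagged: np.ndarray, policy: StimulationPolicy):
    """Proportional law on the STN activity measured T ms ago.

    ``z1_lagged`` is z1(t - T) as read from the history buffer (the initial
    history before t = T).  With T = 0 this reproduces
    :func:`proportional_term` exactly.
    """
    n = z1_lagged.shape[0]
    u_raw = -policy.kc * (z1_lagged - policy.zref_array(n))
    return u_raw, policy.alpha_values(n) * u_raw
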