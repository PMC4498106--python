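"""Static ingredients of the STN-GPe delayed neural-field model.

The model lives on the 1-D domain Omega = [0, L] mm (default L = 15 mm, the
extent of the STN-GPe zone in the adult human brain), normalized to [0, 1] for
simulation.  The STN occupies the leftmost sixth of the nodes, the GPe the
rightmost sixth; the nodes in between are "silent" and only provide the
physical separation that generates axonal conduction delays.

Populations are indexed 1 (STN, glutamatergic) and 2 (GPe, GABAergic).
Activity ``z_i(r, t)`` evolves as

    tau_i dz_i/dt = -z_i + S_i( sum_j integral w_ij(r, r') z_j(r', t - d_j(r, r')) dr'
                                + I_i^ext(r, t) )

with sigmoid activations ``S_i`` bounded by a baseline ``b_i`` and a
saturation ``m_i``, Gaussian synaptic kernels ``w_ij``, and distance/velocity
axonal delays ``d_j = |r - r'| / c_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SpaceGrid",
    "ActivationParams",
    "KernelParams",
    "KernelSet",
    "AlphaProfile",
    "DelayTable",
    "NeuralFieldModel",
    "build_grid",
    "sigmoid",
    "sigmoid_slope",
    "build_kernels",
    "build_alpha",
    "build_delays",
    "build_model",
    "mm_to_normalized",
    "velocity_to_normalized",
]

DEFAULT_SCALE_MM = 15.0


def mm_to_normalized(x_mm: float | np.ndarray, scale_mm: float = DEFAULT_SCALE_MM):
    """Convert a position or length in mm to normalized domain units."""
    if scale_mm <= 0:
        raise ValueError(f"scale_mm must be positive, got {scale_mm}")
    return np.asarray(x_mm, dtype=float) / scale_mm if np.ndim(x_mm) else float(x_mm) / scale_mm


def velocity_to_normalized(v_m_per_s: float, scale_mm: float = DEFAULT_SCALE_MM) -> float:
    """Convert an axonal conduction velocity in m/s to normalized length per ms.

    1 m/s equals 1 mm/ms, so the conversion divides by the physical domain
    length in mm (2.5 m/s on a 15 mm domain -> 0.1667 normalized/ms).
    """
    if scale_mm <= 0:
        raise ValueError(f"scale_mm must be positive, got {scale_mm}")
    return float(v_m_per_s) / scale_mm


@dataclass(frozen=True)
class SpaceGrid:
    """Cell-centered discretization of the normalized domain [0, 1].

    ``m`` nodes sit at positions (i + 1/2)/m.  The first m/6 nodes are STN,
    the last m/6 are GPe, the remainder are silent spacer nodes.
    """

    n_nodes: int
    positions: np.ndarray
    stn_indices: np.ndarray
    gpe_indices: np.ndarray
    silent_indices: np.ndarray
    dr: float
    scale_mm: float = DEFAULT_SCALE_MM

    @property
    def n_stn(self) -> int:
        return self.stn_indices.size

    @property
    def n_gpe(self) -> int:
        return self.gpe_indices.size

    @property
    def stn_positions(self) -> np.ndarray:
        return self.positions[self.stn_indices]

    @property
    def gpe_positions(self) -> np.ndarray:
        return self.positions[self.gpe_indices]

    @property
    def stn_center(self) -> float:
        """Mean STN node position (normalized units)."""
        return float(self.stn_positions.mean())

    @property
    def gpe_center(self) -> float:
        return float(self.gpe_positions.mean())

    def positions_mm(self) -> np.ndarray:
        return self.positions * self.scale_mm

    def mm_to_normalized(self, x_mm: float) -> float:
        return mm_to_normalized(x_mm, self.scale_mm)

    def velocity_to_normalized(self, v_m_per_s: float) -> float:
        return velocity_to_normalized(v_m_per_s, self.scale_mm)


def build_grid(m: int, scale_mm: float = DEFAULT_SCALE_MM) -> SpaceGrid:
    """Build the discretized domain with m/6 STN, m/6 GPe and silent spacers."""
    if m < 6 or m % 6 != 0:
        raise ValueError(
            f"node count m must be a multiple of 6 (m/6 STN + m/6 GPe + silent spacers); got m={m}"
        )
    if scale_mm <= 0:
        raise ValueError(f"scale_mm must be positive, got {scale_mm}")
    positions = (np.arange(m) + 0.5) / m
    n_pop = m // 6
    stn = np.arange(0, n_pop)
    gpe = np.arange(m - n_pop, m)
    silent = np.arange(n_pop, m - n_pop)
    return SpaceGrid(
        n_nodes=m,
        positions=positions,
        stn_indices=stn,
        gpe_indices=gpe,
        silent_indices=silent,
        dr=1.0 / m,
        scale_mm=scale_mm,
    )


@dataclass(frozen=True)
class ActivationParams:
    """Sigmoid activation parameters for one population.

    ``max_rate`` is the saturation rate m_i and ``base_rate`` the baseline b_i
    (both spk/s).  The sigmoid

        S(x) = m b / (b + (m - b) exp(-4 x / m))

    satisfies S(0) = b, S(+inf) = m, S(-inf) = 0, and its maximum slope is
    exactly 1 for any admissible (m, b) — the 4/m exponent normalizes the gain.
    """

    max_rate: float
    base_rate: float

    def __post_init__(self):
        if not (0 < self.base_rate < self.max_rate):
            raise ValueError(
                f"need 0 < base_rate < max_rate, got b={self.base_rate}, m={self.max_rate}"
            )


# nominal parameters: STN (m1=300, b1=17), GPe (m2=400, b2=75) spk/s
STN_ACTIVATION = ActivationParams(max_rate=300.0, base_rate=17.0)
GPE_ACTIVATION = ActivationParams(max_rate=400.0, base_rate=75.0)


def sigmoid(x, p: ActivationParams):
    """Population activation S(x), bounded in (0, max_rate), in spk/s."""
    m, b = p.max_rate, p.base_rate
    # clip the exponent so saturated inputs cannot overflow
    expo = np.clip(-4.0 * np.asarray(x, dtype=float) / m, -700.0, 700.0)
    out = m * b / (b + (m - b) * np.exp(expo))
    return out if np.ndim(x) else float(out)


def sigmoid_slope(x, p: ActivationParams):
    """dS/dx.  Peaks at exactly 1 at x* = (m/4) ln((m-b)/b)."""
    m, b = p.max_rate, p.base_rate
    expo = np.clip(-4.0 * np.asarray(x, dtype=float) / m, -700.0, 700.0)
    y = np.exp(expo)
    out = 4.0 * b * (m - b) * y / (b + (m - b) * y) ** 2
    return out if np.ndim(x) else float(out)


@dataclass(frozen=True)
class KernelParams:
    """Gaussian synaptic kernel parameters (normalized-length units).

    Amplitudes K_ij are dimensionless synaptic gains; sigma_ij are the
    variances of the Gaussian profiles g_ij(x) = K_ij exp(-x^2 / (2 sigma_ij))
    in normalized-length^2.  mu1/mu2 are the population centers used for the
    topographic alignment of the cross-population kernels; when None they
    default to the mean STN / GPe node positions.
    """

    K12: float = 30.0
    K21: float = 38.0
    K22: float = 2.55
    sigma12: float = 0.03
    sigma21: float = 0.03
    sigma22: float = 0.015
    mu1: float | None = None
    mu2: float | None = None

    def __post_init__(self):
        if min(self.K12, self.K21, self.K22) < 0:
            raise ValueError("kernel amplitudes must be non-negative")
        if min(self.sigma12, self.sigma21, self.sigma22) <= 0:
            raise ValueError("kernel variances must be positive")


@dataclass(frozen=True)
class KernelSet:
    """Dense synaptic-weight matrices indexed [postsynaptic, presynaptic].

    W11: STN<-STN (identically zero: no STN self-excitation);
    W12: STN<-GPe (<= 0, GABAergic); W21: GPe<-STN (>= 0, glutamatergic);
    W22: GPe<-GPe lateral inhibition (<= 0, zero diagonal, distance-dependent).

    ``measure`` is the spatial quadrature weight absorbed into the matrices:
    the synaptic integral of w(r, r') z(r') dr' is realized as a matrix-vector product,
    so each entry already carries the node measure dr (or 1 under the "plain"
    convention).
    """

    W11: np.ndarray
    W12: np.ndarray
    W21: np.ndarray
    W22: np.ndarray
    measure: float


def build_kernels(
    grid: SpaceGrid,
    kp: KernelParams = KernelParams(),
    quadrature: Literal["measure", "plain"] = "measure",
) -> KernelSet:
    """Build the synaptic weight matrices on the grid.

    Cross-population kernels are Gaussian in the *topographic offset*
    (r - mu_post) - (r' - mu_pre): homologous positions within STN and GPe are
    maximally coupled (short-range excitation/inhibition between the mapped
    populations).  The GPe lateral kernel is -|r - r'| g22(|r - r'|): zero at
    r = r' (neighboring GPe neurons are essentially uncorrelated) and decaying
    at long range.

    With ``quadrature="measure"`` (default) every entry carries the node
    measure dr = 1/m, i.e. the matrices are a midpoint-rule discretization of
    the synaptic integrals.  ``"plain"`` omits the measure.
    """
    r1 = grid.stn_positions
    r2 = grid.gpe_positions
    mu1 = kp.mu1 if kp.mu1 is not None else grid.stn_center
    mu2 = kp.mu2 if kp.mu2 is not None else grid.gpe_center
    measure = grid.dr if quadrature == "measure" else 1.0

    off12 = (r1[:, None] - mu1) - (r2[None, :] - mu2)
    W12 = -kp.K12 * np.exp(-(off12**2) / (2.0 * kp.sigma12)) * measure

    off21 = (r2[:, None] - mu2) - (r1[None, :] - mu1)
    W21 = kp.K21 * np.exp(-(off21**2) / (2.0 * kp.sigma21)) * measure

    d22 = np.abs(r2[:, None] - r2[None, :])
    W22 = -d22 * kp.K22 * np.exp(-(d22**2) / (2.0 * kp.sigma22)) * measure
    np.fill_diagonal(W22, 0.0)

    W11 = np.zeros((grid.n_stn, grid.n_stn))
    return KernelSet(W11=W11, W12=W12, W21=W21, W22=W22, measure=measure)


@dataclass(frozen=True)
class AlphaProfile:
    """Per-node photosensitization gain alpha(r) >= 0, nonzero only on STN.

    ``values`` has one entry per STN node.  ``degeneracy`` is the fraction of
    STN nodes whose gain was forced to zero (failed photosensitization),
    chosen without replacement under ``mask_seed``.
    """

    values: np.ndarray
    degeneracy: float = 0.0
    mask_seed: int | None = None

    @property
    def n_zeroed(self) -> int:
        return int(np.sum(self.values == 0.0))


def build_alpha(
    grid: SpaceGrid,
    center_mm: float = 1.25,
    variance_mm2: float = 1.25,
    degeneracy: float = 0.0,
    seed: int | None = None,
) -> AlphaProfile:
    """Gaussian light-sensitivity profile over the STN.

    Amplitude 1 at the STN center (default 1.25 mm), variance in mm^2
    (default 1.25), zero outside the STN.  ``degeneracy`` in [0, 1] zeroes
    round(degeneracy * n_stn) randomly chosen STN entries, reproducibly under
    ``seed`` — modeling neurons that failed photosensitization or receive no
    light.
    """
    if not 0.0 <= degeneracy <= 1.0:
        raise ValueError(f"degeneracy must lie in [0, 1], got {degeneracy}")
    r = grid.stn_positions
    center = center_mm / grid.scale_mm
    variance = variance_mm2 / grid.scale_mm**2
    values = np.exp(-((r - center) ** 2) / (2.0 * variance))
    n_zero = int(round(degeneracy * grid.n_stn))
    if n_zero > 0:
        rng = np.random.default_rng(seed)
        idx = rng.choice(grid.n_stn, size=n_zero, replace=False)
        values = values.copy()
        values[idx] = 0.0
    return AlphaProfile(values=values, degeneracy=degeneracy, mask_seed=seed)


@dataclass(frozen=True)
class DelayTable:
    """Axonal delays in integer time steps, indexed [postsynaptic, presynaptic].

    ``steps_from_stn`` uses the STN axonal velocity c1, ``steps_from_gpe``
    uses the GPe velocity c2: the delay of a connection is set by the
    *presynaptic* population's conduction velocity.  Entries are
    round(|r - r'| / c_j / dt) with ties rounding half up.
    """

    steps_from_stn: np.ndarray
    steps_from_gpe: np.ndarray
    max_steps: int
    c1: float
    c2: float
    dt: float


def _delay_steps(dist: np.ndarray, c: float, dt: float) -> np.ndarray:
    # round-half-up keeps the convention deterministic across platforms
    return np.floor(dist / c / dt + 0.5).astype(np.int64)


def build_delays(grid: SpaceGrid, c1: float, c2: float, dt: float) -> DelayTable:
    """Delay table over all node pairs for both presynaptic populations.

    ``c1``/``c2`` are normalized-length per ms (use
    :func:`velocity_to_normalized` to convert from m/s); ``dt`` is ms.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError(f"velocities must be positive, got c1={c1}, c2={c2}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    dist = np.abs(grid.positions[:, None] - grid.positions[None, :])
    from_stn = _delay_steps(dist, c1, dt)
    from_gpe = _delay_steps(dist, c2, dt)
    return DelayTable(
        steps_from_stn=from_stn,
        steps_from_gpe=from_gpe,
        max_steps=int(max(from_stn.max(), from_gpe.max())),
        c1=c1,
        c2=c2,
        dt=dt,
    )


@dataclass(frozen=True)
class NeuralFieldModel:
    """Bundle of all static model ingredients used by the integrator."""

    grid: SpaceGrid
    act1: ActivationParams
    act2: ActivationParams
    kernel_params: KernelParams
    kernels: KernelSet
    delays: DelayTable

    def delay_blocks(self):
        """Per-connection delay blocks (post x pre) used by the integrator.

        Returns (D12, D21, D22): STN<-GPe (velocity c2), GPe<-STN (c1),
        GPe<-GPe (c2).
        """
        g = self.grid
        D12 = self.delays.steps_from_gpe[np.ix_(g.stn_indices, g.gpe_indices)]
        D21 = self.delays.steps_from_stn[np.ix_(g.gpe_indices, g.stn_indices)]
        D22 = self.delays.steps_from_gpe[np.ix_(g.gpe_indices, g.gpe_indices)]
        return D12, D21, D22


def build_model(
    m: int = 60,
    scale_mm: float = DEFAULT_SCALE_MM,
    kernel_params: KernelParams | None = None,
    c1: float = 0.166,
    c2: float = 0.09,
    dt: float = 1.0,
    act1: ActivationParams = STN_ACTIVATION,
    act2: ActivationParams = GPE_ACTIVATION,
    quadrature: Literal["measure", "plain"] = "measure",
) -> NeuralFieldModel:
    """Construct the nominal model (all defaults = nominal parameter set)."""
    grid = build_grid(m, scale_mm)
    kp = kernel_params if kernel_params is not None else KernelParams()
    kernels = build_kernels(grid, kp, quadrature=quadrature)
    delays = build_delays(grid, c1, c2, dt)
    return NeuralFieldModel(
        grid=grid, act1=act1, act2=act2, kernel_params=kp, kernels=kernels, delays=delays
    )


def with_scaled_parameters(model: NeuralFieldModel, **factors: float) -> NeuralFieldModel:
    """Return a copy of ``model`` with named parameters scaled multiplicatively.

    Recognized keys: K12, K21, K22, c1, c2.  Used by the sensitivity sweep.
    """
    kp = model.kernel_params
    kp_new = replace(
        kp,
        K12=kp.K12 * factors.get("K12", 1.0),
        K21=kp.K21 * factors.get("K21", 1.0),
        K22=kp.K22 * factors.get("K22", 1.0),
    )
    quadrature = "measure" if model.kernels.measure != 1.0 else "plain"
    kernels = build_kernels(model.grid, kp_new, quadrature=quadrature)
    delays = build_delays(
        model.grid,
        model.delays.c1 * factors.get("c1", 1.0),
        model.delays.c2 * factors.get("c2", 1.0),
        model.delays.dt,
    )
    return replace(model, kernel_params=kp_new, kernels=kernels, delays=delays)
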