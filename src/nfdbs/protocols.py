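"""The five in-silico experimental protocols.

A. sensitivity sweep of (K12, K21, K22, c1, c2) over +/-35% of nominal,
   no stimulation; histogram of main harmonics.
B. proportional closed-loop disruption of the sustained oscillation (kc=2,
   zref=0, stimulation on from 500 ms).
C. photosensitization degeneracy: residual oscillation amplitude vs the
   fraction of non-actuatable STN nodes, for gains kc in {2, 6, 12}.
D. single light source: one scalar stimulation signal for the whole STN
   (spatially integrated proportional law, kc=6.5).
E. acquisition/processing delays: residual amplitude vs controller delay T
   for gains kc in {2, 6, 12}.

Each runner returns plain pandas tables so that every figure analogue can be
regenerated from the emitted CSV alone.  Sweep seeds mix the combination
index into the base seed, making every combination independently
reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import oscillation_amplitude, spectral_summary
from .control import StimulationPolicy
from .model import NeuralFieldModel, build_alpha, build_model, with_scaled_parameters
from .simulate import SimConfig, simulate

__all__ = [
    "SweepSpec",
    "run_protocol_A",
    "run_protocol_grid",
    "run_protocol_B",
    "run_protocol_C",
    "run_protocol_D",
    "run_protocol_E",
    "DISRUPTION_RATIO",
]

logger = logging.getLogger(__name__)

#: post/pre amplitude ratio below which a run counts as "disrupted".
DISRUPTION_RATIO = 0.2

SWEEP_PARAMETERS = ("K12", "K21", "K22", "c1", "c2")

#: analysis windows (ms): unstimulated runs discard 300 ms of transient;
#: stimulated runs are scored on the final 300 ms (onset 500 + settling).
TRANSIENT_MS = 300.0
PRE_WINDOW_MS = (200.0, 500.0)
POST_WINDOW_MS = (700.0, 1000.0)


def _combination_seed(base_seed: int, index: int) -> int:
    """Deterministic per-combination seed, kept below 2**31."""
    return int((base_seed * 1_000_003 + index) % 2_147_483_647)


def _window_slice(cfg: SimConfig, window_ms: tuple[float, float]) -> tuple[int, int]:
    a, b = window_ms
    return int(round(a / cfg.dt)), int(round(b / cfg.dt))


def _stimulated_amplitude(res, cfg) -> float:
    return oscillation_amplitude(res.mean_stn_rate(), _window_slice(cfg, POST_WINDOW_MS))


@dataclass(frozen=True)
class SweepSpec:
    """Parameter grids for the sensitivity sweep (protocol A).

    ``factors`` maps parameter names to multiplicative grids around nominal.
    The default is ``n_values`` linearly spaced factors spanning +/-35%.
    """

    n_values: int = 4
    span: float = 0.35
    parameters: tuple[str, ...] = SWEEP_PARAMETERS
    factors: dict[str, np.ndarray] = field(default_factory=dict)
    base_seed: int = 0

    def grids(self) -> dict[str, np.ndarray]:
        default = np.linspace(1.0 - self.span, 1.0 + self.span, self.n_values)
        out = {}
        for p in self.parameters:
            if p not in SWEEP_PARAMETERS:
                raise ValueError(f"unknown sweep parameter {p!r}")
            g = np.asarray(self.factors.get(p, default), dtype=float)
            if g.size == 0:
                raise ValueError(f"empty grid for parameter {p!r}")
            out[p] = g
        return out

    @property
    def n_combinations(self) -> int:
        return int(np.prod([len(g) for g in self.grids().values()]))


def run_protocol_A(
    spec: SweepSpec = SweepSpec(),
    model: NeuralFieldModel | None = None,
    cfg: SimConfig | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Unstimulated sensitivity sweep; one row per parameter combination.

    Columns: the scale factors, the resulting main harmonic (Hz, 0 when
    non-oscillatory), the amplitude (spk/s), the beta-band flag and the seed.
    The full-scale 10-values-per-parameter sweep (10^5 runs) is obtained with
    ``SweepSpec(n_values=10)``; the default is the desk-scale 4-value grid.
    """
    base = model if model is not None else build_model()
    base_cfg = cfg if cfg is not None else SimConfig()
    grids = spec.grids()
    names = list(grids)
    combos = itertools.product(*(grids[n] for n in names))
    total = spec.n_combinations
    logger.info("protocol A sweep: %d combinations of %s", total, names)
    if progress:
        from tqdm import tqdm

        combos = tqdm(combos, total=total, desc="sweep")
    rows = []
    for idx, values in enumerate(combos):
        factors = dict(zip(names, values))
        seed = _combination_seed(spec.base_seed, idx)
        run_cfg = replace(base_cfg, seed=seed)
        res = simulate(with_scaled_parameters(base, **factors), run_cfg)
        summ = spectral_summary(
            res.mean_stn_rate(), dt_ms=run_cfg.dt, transient_ms=TRANSIENT_MS
        )
        rows.append(
            {
                **{f"{n}_factor": v for n, v in factors.items()},
                "main_harmonic_hz": summ.main_harmonic_hz,
                "amplitude_spk": summ.amplitude_spk,
                "is_beta": summ.is_beta,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def run_protocol_grid(
    pair: tuple[str, str] = ("K12", "K21"),
    factors: np.ndarray | None = None,
    model: NeuralFieldModel | None = None,
    cfg: SimConfig | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Two-parameter frequency map with all other parameters nominal.

    ``factors`` defaults to 8 values spanning 0.2x to 5x nominal (a wider
    range than the sweep, exposing the no-oscillation corners at weak
    coupling / fast conduction).  Returns a long table with one row per cell.
    """
    for p in pair:
        if p not in SWEEP_PARAMETERS:
            raise ValueError(f"unknown parameter {p!r}")
    if factors is None:
        factors = np.geomspace(0.2, 5.0, 8)
    base = model if model is not None else build_model()
    base_cfg = cfg if cfg is not None else SimConfig()
    rows = []
    for idx, (fa, fb) in enumerate(itertools.product(factors, factors)):
        seed = _combination_seed(base_seed, idx)
        run_cfg = replace(base_cfg, seed=seed)
        res = simulate(with_scaled_parameters(base, **{pair[0]: fa, pair[1]: fb}), run_cfg)
        summ = spectral_summary(
            res.mean_stn_rate(), dt_ms=run_cfg.dt, transient_ms=TRANSIENT_MS
        )
        rows.append(
            {
                f"{pair[0]}_factor": fa,
                f"{pair[1]}_factor": fb,
                "main_harmonic_hz": summ.main_harmonic_hz,
                "amplitude_spk": summ.amplitude_spk,
                "is_beta": summ.is_beta,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)


def _disruption_run(
    model: NeuralFieldModel,
    cfg: SimConfig,
    policy: StimulationPolicy,
):
    res = simulate(model, cfg, policy)
    mean_stn = res.mean_stn_rate()
    pre = oscillation_amplitude(mean_stn, _window_slice(cfg, PRE_WINDOW_MS))
    post = oscillation_amplitude(mean_stn, _window_slice(cfg, POST_WINDOW_MS))
    return res, pre, post


def run_protocol_B(
    kc: float = 2.0,
    seed: int | None = 0,
    model: NeuralFieldModel | None = None,
    cfg: SimConfig | None = None,
) -> dict:
    """Proportional closed-loop disruption (zref = 0, onset 500 ms).

    Returns the simulation result plus the pre-onset (200-500 ms) and
    post-onset (700-1000 ms) amplitudes of the mean STN rate and the
    disrupted flag (post/pre < 0.2).
    """
    mdl = model if model is not None else build_model()
    run_cfg = replace(cfg if cfg is not None else SimConfig(), seed=seed)
    policy = StimulationPolicy(
        variant="proportional", kc=kc, zref=0.0, alpha=build_alpha(mdl.grid)
    )
    res, pre, post = _disruption_run(mdl, run_cfg, policy)
    return {
        "result": res,
        "pre_amplitude_spk": pre,
        "post_amplitude_spk": post,
        "ratio": post / pre if pre > 0 else np.nan,
        "disrupted": bool(pre > 0 and post / pre < DISRUPTION_RATIO),
        "peak_abs_u": float(np.abs(res.u).max()),
    }


def run_protocol_C(
    degeneracies=(0.0, 0.25, 0.5, 0.75, 1.0),
    gains=(2.0, 6.0, 12.0),
    n_seeds: int = 10,
    base_seed: int = 0,
    model: NeuralFieldModel | None = None,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Residual amplitude vs photosensitization degeneracy and gain.

    For each (degeneracy, kc) pair, ``n_seeds`` runs with distinct
    degeneracy masks (and matched input noise seeds) are averaged.  Returns
    one row per run; aggregate with groupby for the figure analogue.
    """
    mdl = model if model is not None else build_model()
    base_cfg = cfg if cfg is not None else SimConfig()
    rows = []
    for degeneracy in degeneracies:
        for kc in gains:
            for s in range(n_seeds):
                mask_seed = _combination_seed(base_seed, s)
                run_cfg = replace(base_cfg, seed=_combination_seed(base_seed + 1, s))
                alpha = build_alpha(mdl.grid, degeneracy=degeneracy, seed=mask_seed)
                policy = StimulationPolicy(
                    variant="proportional", kc=kc, zref=0.0, alpha=alpha
                )
                res, pre, post = _disruption_run(mdl, run_cfg, policy)
                rows.append(
                    {
                        "degeneracy": degeneracy,
                        "kc": kc,
                        "mask_seed": mask_seed,
                        "seed": run_cfg.seed,
                        "pre_amplitude_spk": pre,
                        "post_amplitude_spk": post,
                    }
                )
    return pd.DataFrame(rows)


def run_protocol_D(
    kc: float = 6.5,
    seed: int | None = 0,
    model: NeuralFieldModel | None = None,
    cfg: SimConfig | None = None,
) -> dict:
    """Single light source: spatially integrated proportional stimulation.

    The scalar signal u(t) = -kc * integral_STN (z1 - zref) dr is applied to all
    STN nodes through alpha(r).  Returns the same summary as protocol B.
    """
    mdl = model if model is not None else build_model()
    run_cfg = replace(cfg if cfg is not None else SimConfig(), seed=seed)
    policy = StimulationPolicy(
        variant="averaged", kc=kc, zref=0.0, alpha=build_alpha(mdl.grid)
    )
    res, pre, post = _disruption_run(mdl, run_cfg, policy)
    return {
        "result": res,
        "pre_amplitude_spk": pre,
        "post_amplitude_spk": post,
        "ratio": post / pre if pre > 0 else np.nan,
        "disrupted": bool(pre > 0 and post / pre < DISRUPTION_RATIO),
        "peak_abs_u": float(np.abs(res.u).max()),
    }


def run_protocol_E(
    delays_ms=(1.0, 3.0, 5.0, 7.0, 8.0, 9.0, 10.0, 13.0, 15.0, 20.0),
    gains=(2.0, 6.0, 12.0),
    n_seeds: int = 5,
    base_seed: int = 0,
    model: NeuralFieldModel | None = None,
    cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Residual amplitude vs acquisition/processing delay T and gain kc.

    One row per (T, kc, seed) run with pre/post amplitudes of the mean STN
    rate; the disrupted flag uses the post/pre < 0.2 criterion.
    """
    mdl = model if model is not None else build_model()
    base_cfg = cfg if cfg is not None else SimConfig()
    alpha = build_alpha(mdl.grid)
    rows = []
    for T in delays_ms:
        for kc in gains:
            for s in range(n_seeds):
                run_cfg = replace(base_cfg, seed=_combination_seed(base_seed, s))
                policy = StimulationPolicy(
                    variant="delayed_proportional", kc=kc, zref=0.0, alpha=alpha, T=float(T)
                )
                res, pre, post = _disruption_run(mdl, run_cfg, policy)
                rows.append(
                    {
                        "T_ms": float(T),
                        "kc": kc,
                        "seed": run_cfg.seed,
                        "pre_amplitude_spk": pre,
                        "post_amplitude_spk": post,
                        "disrupted": bool(pre > 0 and post / pre < DISRUPTION_RATIO),
                    }
                )
    return pd.DataFrame(rows)
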