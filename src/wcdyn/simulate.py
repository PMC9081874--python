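"""Stochastic network integration and trajectory diagnostics.

The coupled Wilson-Cowan network is integrated with the Euler-Maruyama
scheme at a fixed time step::

    x_{k+1} = x_k + f(x_k) dt + s sqrt(dt) xi_k,    xi_k ~ N(0, 1) i.i.d.

Additive white noise of standard deviation ``s`` (per sqrt-ms) drives both
state variables of every region by default; after each step the state is
clipped back into [0, 1] (with tiny default noise this is essentially never
triggered, and the count is recorded).  Trajectories are produced in chunks
so memory stays bounded for long runs while random-number consumption stays
an exact function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import em_chunk
from .model import NetworkModel, external_input, total_input

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "remove_transient",
    "input_ranges",
    "regime_occupancy",
    "carpet_data",
]

_CHUNK_STEPS = 20_000
_BLOWUP_LIMIT = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    Defaults follow the reference protocol: dt = 0.1 ms, 1.2e5 ms total,
    1 s transient discarded, additive noise with mean 0 and SD 1.3e-5.
    ``initial_state`` is a named preset ('mid', 'low', 'high', 'random') or
    an explicit (2, N) array of (E, I) rows; presets add a seed-controlled
    jitter of 1e-3 so replicates decorrelate even without noise.
    ``store_every`` thins the stored (not the integrated) time base.
    """

    dt: float = 0.1
    T: float = 1.2e5
    transient: float = 1000.0
    noise_mu: float = 0.0
    noise_s: float = 1.3e-5
    seed: int = 0
    initial_state: object = "mid"
    noise_on_i: bool = True
    store_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (self.T > self.transient >= 0):
            raise ValueError("need T > transient >= 0")
        if self.noise_s < 0:
            raise ValueError("noise_s must be non-negative")
        if self.store_every < 1:
            raise ValueError("store_every must be >= 1")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    @property
    def n_steps(self) -> int:
        return int(round(self.T / self.dt))


@dataclass
class SimulationResult:
    """Simulated trajectories: t (ms) and N x n_samples rate arrays E, I."""

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    seed: int
    config: SimulationConfig
    model: NetworkModel
    transient_removed: bool = False
    n_clipped: int = 0

    @property
    def dt_stored(self) -> float:
        return self.config.dt * self.config.store_every


def _initial_state(model: NetworkModel, cfg: SimulationConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = model.n_regions
    init = cfg.initial_state
    if isinstance(init, str):
        base = {"mid": 0.25, "low": 0.05, "high": 0.8}.get(init)
        if base is not None:
            E0 = np.full(n, base) + 1e-3 * rng.standard_normal(n)
            I0 = np.full(n, base) + 1e-3 * rng.standard_normal(n)
        elif init == "random":
            E0 = rng.uniform(0, 1, n)
            I0 = rng.uniform(0, 1, n)
        else:
            raise ValueError(f"unknown initial-state preset {init!r}")
    else:
        arr = np.asarray(init, dtype=float)
        if arr.shape != (2, n):
            raise ValueError(f"initial_state must be (2, {n}), got {arr.shape}")
        E0, I0 = arr[0].copy(), arr[1].copy()
    return np.clip(E0, 0, 1), np.clip(I0, 0, 1)


def simulate(model: NetworkModel, cfg: SimulationConfig) -> SimulationResult:
    """Integrate the network; identical seeds give bit-identical output.

    With ``noise_s = 0`` the scheme reduces to forward Euler.  A pre-clip
    state magnitude above 10 aborts with a diagnostic naming the first
    offending region and step (cannot occur from the clipped dynamics alone,
    only from pathological parameters).
    """
    rng = np.random.default_rng(cfg.seed)
    E, I = _initial_state(model, cfg, rng)
    pa = model.param_arrays()
    A = np.ascontiguousarray(model.connectome.A)

    n_steps = cfg.n_steps
    n_stored = n_steps // cfg.store_every
    out_E = np.empty((n_stored, model.n_regions))
    out_I = np.empty((n_stored, model.n_regions))
    sqrt_dt_s = cfg.noise_s * np.sqrt(cfg.dt)

    n_clipped = 0
    step = 0
    while step < n_steps:
        k = min(_CHUNK_STEPS, n_steps - step)
        if cfg.noise_s > 0:
            noise = rng.standard_normal((k, 2, model.n_regions))
            if cfg.noise_mu != 0.0:
                noise += cfg.noise_mu / max(sqrt_dt_s, np.finfo(float).tiny)
            if not cfg.noise_on_i:
                noise[:, 1, :] = 0.0
        else:
            noise = np.zeros((k, 2, model.n_regions))
        clipped, blow_step, blow_region = em_chunk(
            E, I, A, model.G,
            pa["tau_e"], pa["tau_i"], pa["a_e"], pa["a_i"],
            pa["w_ee"], pa["w_ei"], pa["w_ie"], pa["w_ii"],
            pa["B_e"], pa["B_i"], pa["h"],
            cfg.dt, sqrt_dt_s, noise, out_E, out_I,
            cfg.store_every, step)
        n_clipped += clipped
        if blow_step >= 0:
            label = model.connectome.labels[blow_region]
            raise FloatingPointError(
                f"state blow-up (|x| > {_BLOWUP_LIMIT}) in region "
                f"{label!r} at step {blow_step}")
        step += k

    t = (np.arange(1, n_stored + 1) * cfg.store_every) * cfg.dt
    return SimulationResult(t=t, E=out_E.T.copy(), I=out_I.T.copy(),
                            seed=cfg.seed, config=cfg, model=model,
                            n_clipped=n_clipped)


def remove_transient(r: SimulationResult,
                     transient: float | None = None) -> SimulationResult:
    """Drop the initial transient window (default: the config's value)."""
    if r.transient_removed:
        raise ValueError("transient already removed from this result")
    transient = r.config.transient if transient is None else transient
    n_drop = int(round(transient / r.dt_stored))
    return SimulationResult(
        t=r.t[n_drop:], E=r.E[:, n_drop:], I=r.I[:, n_drop:],
        seed=r.seed, config=r.config, model=r.model,
        transient_removed=True, n_clipped=r.n_clipped)


def input_ranges(r: SimulationResult, model: NetworkModel | None = None):
    """Per-region min/max of the external drive along the trajectory.

    Returns a dict with (N, 2) arrays ``J_e`` and ``J_tot`` (min, max per
    region) and the network-wide unions ``J_e_range`` / ``J_tot_range``.
    """
    if not r.transient_removed:
        raise ValueError("remove the transient before measuring input ranges")
    model = r.model if model is None else model
    J = external_input(r.E.T, model.connectome, model.G)  # (T, N)
    B_e = np.array([p.B_e for p in model.params])
    j_min, j_max = J.min(axis=0), J.max(axis=0)
    je = np.column_stack([j_min, j_max])
    jtot = np.column_stack([total_input(j_min, B_e), total_input(j_max, B_e)])
    return {
        "J_e": je,
        "J_tot": jtot,
        "J_e_range": (float(j_min.min()), float(j_max.max())),
        "J_tot_range": (float(jtot[:, 0].min()), float(jtot[:, 1].max())),
    }


def regime_occupancy(r: SimulationResult, diagrams: list) -> list:
    """Partition each region's experienced J_tot range by its bifurcations.

    ``diagrams`` holds one computed BifurcationDiagram per region (all
    identical for a homogeneous model).  Each region's [J_min, J_max] is
    split at its own fold and Hopf J values; a segment is labelled
    'limit_cycle' when its midpoint lies inside that region's oscillatory
    envelope window, else 'fixed_point'.  Diagrams that do not cover the
    experienced range are recomputed over the union.
    """
    from .bifurcation import OSC_AMP_TOL, compute_diagram

    ranges = input_ranges(r)["J_tot"]
    out = []
    for a in range(r.model.n_regions):
        lo, hi = float(ranges[a, 0]), float(ranges[a, 1])
        d = diagrams[a]
        if lo < d.J_range[0] or hi > d.J_range[1]:
            d = compute_diagram(
                d.params, (min(lo, d.J_range[0]), max(hi, d.J_range[1])))
        cuts = sorted(J for J, _ in list(d.folds) + list(d.hopfs)
                      if lo < J < hi)
        edges = [lo] + cuts + [hi]
        osc_lo = osc_hi = None
        if d.envelope is not None:
            osc = d.envelope[:, 2] - d.envelope[:, 1] > OSC_AMP_TOL
            if osc.any():
                osc_lo = d.envelope[osc, 0].min()
                osc_hi = d.envelope[osc, 0].max()
        segments = []
        for s0, s1 in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (s0 + s1)
            in_osc = osc_lo is not None and osc_lo <= mid <= osc_hi
            # Hopf-bounded windows count even past sampled envelope edges
            if not in_osc and len(d.hopfs) >= 2:
                h = sorted(J for J, _ in d.hopfs)
                in_osc = h[0] <= mid <= h[-1]
            segments.append(((s0, s1),
                             "limit_cycle" if in_osc else "fixed_point"))
        out.append(segments)
    return out


def carpet_data(r: SimulationResult, ordering=None, downsample: int = 1):
    """Node x time matrix of E for heat-map display.

    ``ordering`` is a sequence of region labels (a permutation of the
    model's labels) fixing row order, typically grouped anatomically.
    Returns (matrix, row_labels, row_groups, t).
    """
    labels = list(r.model.connectome.labels)
    groups = list(r.model.connectome.groups)
    if ordering is None:
        idx = np.arange(len(labels))
    else:
        unknown = [x for x in ordering if x not in labels]
        if unknown:
            raise ValueError(f"unknown regions in ordering: {unknown}")
        if len(ordering) != len(labels):
            raise ValueError("ordering must be a permutation of all labels")
        idx = np.array([labels.index(x) for x in ordering])
    if downsample < 1:
        raise ValueError("downsample factor must be >= 1")
    M = r.E[idx, ::downsample]
    return (M, [labels[i] for i in idx], [groups[i] for i in idx],
            r.t[::downsample])
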