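"""Core Wilson-Cowan network model: node parameters, connectome coupling,
and cell-density-driven regional heterogeneity.

Each cortical region is a pair of mean-field populations, excitatory (E) and
inhibitory (I), with rates bounded in [0, 1] (the maximal population rate h
is 1 by default).  Regions are coupled through their excitatory populations
by a binary directed adjacency matrix scaled by a global coupling constant G.

Internal units are mV and ms throughout.  Helpers are provided to convert
parameter values quoted in SI units (V, V*s, s) -- see :func:`params_from_si`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NodeParams",
    "Connectome",
    "DensityMap",
    "PerturbationField",
    "NetworkModel",
    "sigmoid",
    "drift",
    "external_input",
    "total_input",
    "zscore_densities",
    "perturbation_field",
    "apply_perturbations",
    "build_network",
    "params_from_si",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeParams:
    """Full parameter set of one Wilson-Cowan node.

    Parameters
    ----------
    tau_e, tau_i : float
        Time constants of the excitatory / inhibitory populations (ms, > 0).
    a_e, a_i : float
        Sigmoid gain scalings applied to the recurrent excitatory term of
        each population's input (mV^-1, > 0).
    w_ee, w_ei, w_ie, w_ii : float
        Coupling weights w_xy from population y to population x
        (mV*ms, >= 0).
    B_e, B_i : float
        Firing thresholds (mV).
    h : float
        Maximal population rate; the sigmoid saturates at h.  Fixed to 1 in
        the model as analysed, kept explicit so the sigmoid contract is
        testable at other values.
    """

    tau_e: float
    tau_i: float
    a_e: float
    a_i: float
    w_ee: float
    w_ei: float
    w_ie: float
    w_ii: float
    B_e: float
    B_i: float
    h: float = 1.0

    def __post_init__(self) -> None:
        if not (self.tau_e > 0 and self.tau_i > 0):
            raise ValueError("time constants tau_e, tau_i must be positive")
        if not (self.a_e > 0 and self.a_i > 0):
            raise ValueError("sigmoid gains a_e, a_i must be positive")
        for name in ("w_ee", "w_ei", "w_ie", "w_ii"):
            if getattr(self, name) < 0:
                raise ValueError(f"coupling weight {name} must be non-negative")
        if not self.h > 0:
            raise ValueError("maximal rate h must be positive")
        for name in ("tau_e", "tau_i", "a_e", "a_i", "w_ee", "w_ei", "w_ie",
                     "w_ii", "B_e", "B_i", "h"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"parameter {name} must be finite")

    def with_(self, **kwargs) -> "NodeParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in (
            "tau_e", "tau_i", "a_e", "a_i", "w_ee", "w_ei", "w_ie", "w_ii",
            "B_e", "B_i", "h")}

    @classmethod
    def from_dict(cls, d: dict) -> "NodeParams":
        return cls(**{k: float(v) for k, v in d.items()})


def params_from_si(tau_e: float, tau_i: float, a_e: float, a_i: float,
                   w_ee: float, w_ei: float, w_ie: float, w_ii: float,
                   B_e: float, B_i: float, h: float = 1.0) -> NodeParams:
    """Build :class:`NodeParams` from SI-unit inputs (s, V^-1, V*s, V).

    Times are converted s -> ms, voltage-like quantities V -> mV and
    V*s -> mV*s, and gains V^-1 -> mV^-1.
    """
    return NodeParams(
        tau_e=tau_e * 1e3, tau_i=tau_i * 1e3,
        a_e=a_e * 1e-3, a_i=a_i * 1e-3,
        w_ee=w_ee * 1e3, w_ei=w_ei * 1e3, w_ie=w_ie * 1e3, w_ii=w_ii * 1e3,
        B_e=B_e * 1e3, B_i=B_i * 1e3, h=h)


@dataclass(frozen=True)
class Connectome:
    """Binary directed structural connectome over N regions.

    ``A[a, b] = 1`` iff region b projects to region a, so row sums are
    in-degrees.  ``labels`` fixes the canonical region order used by every
    downstream array.
    """

    A: np.ndarray
    labels: tuple
    groups: tuple

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency matrix must be square")
        n = A.shape[0]
        if n < 2:
            raise ValueError("connectome needs at least 2 regions")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be binary (0 or 1)")
        if np.diagonal(A).any():
            raise ValueError("adjacency matrix must have a zero diagonal")
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels/groups length must match adjacency size")
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "groups", tuple(self.groups))

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def in_degree(self) -> np.ndarray:
        return self.A.sum(axis=1)


@dataclass(frozen=True)
class DensityMap:
    """Per-region excitatory and inhibitory cell densities, raw and z-scored."""

    e_raw: np.ndarray
    i_raw: np.ndarray
    e_z: np.ndarray
    i_z: np.ndarray

    def __post_init__(self) -> None:
        for name in ("e_raw", "i_raw", "e_z", "i_z"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        n = self.e_raw.shape[0]
        if any(getattr(self, k).shape != (n,) for k in ("i_raw", "e_z", "i_z")):
            raise ValueError("density vectors must share one length")

    @property
    def n_regions(self) -> int:
        return self.e_raw.shape[0]


@dataclass(frozen=True)
class PerturbationField:
    """Relative weight perturbations R_e, R_i = sigma * (z-scored densities)."""

    sigma: float
    R_e: np.ndarray
    R_i: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        R_e = np.asarray(self.R_e, dtype=float)
        R_i = np.asarray(self.R_i, dtype=float)
        if R_e.shape != R_i.shape or R_e.ndim != 1:
            raise ValueError("R_e, R_i must be 1-d vectors of equal length")
        if self.sigma == 0 and (R_e.any() or R_i.any()):
            raise ValueError("sigma = 0 requires an all-zero field")
        bad = np.nonzero((1.0 + R_e <= 0) | (1.0 + R_i <= 0))[0]
        if bad.size:
            raise ValueError(
                "perturbation would produce non-positive weight factors "
                f"(1+R <= 0) at region indices {bad.tolist()}")
        object.__setattr__(self, "R_e", R_e)
        object.__setattr__(self, "R_i", R_i)


@dataclass(frozen=True)
class NetworkModel:
    """A connectome plus per-region node parameters and global coupling G."""

    connectome: Connectome
    params: tuple          # one NodeParams per region
    G: float               # mV*ms, >= 0

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("global coupling G must be non-negative")
        params = tuple(self.params)
        if len(params) != self.connectome.n_regions:
            raise ValueError("need one parameter set per region")
        object.__setattr__(self, "params", params)

    @property
    def n_regions(self) -> int:
        return self.connectome.n_regions

    @property
    def is_homogeneous(self) -> bool:
        return all(p == self.params[0] for p in self.params)

    def param_arrays(self) -> dict:
        """Stack per-region parameters into arrays keyed by field name."""
        keys = ("tau_e", "tau_i", "a_e", "a_i", "w_ee", "w_ei", "w_ie",
                "w_ii", "B_e", "B_i", "h")
        return {k: np.array([getattr(p, k) for p in self.params]) for k in keys}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def sigmoid(v, h: float = 1.0):
    """Logistic firing-rate function S(v) = h / (1 + exp(-v)).

    Strictly increasing with range (0, h); S(0) = h/2 and
    S(v) + S(-v) = h for all v.
    """
    v = np.asarray(v, dtype=float)
    if not np.isfinite(v).all():
        raise ValueError("sigmoid input must be finite")
    out = h / (1.0 + np.exp(-v))
    return float(out) if out.ndim == 0 else out


def drift(E, I, p: NodeParams, J_e=0.0):
    """Deterministic time derivatives (dE/dt, dI/dt) of one node.

    The excitatory population saturates through a (1 - E) shunting factor::

        tau_e dE/dt = -E + (1 - E) S(a_e w_ee E - w_ei I - B_e + J_e)
        tau_i dI/dt = -I + (1 - I) S(a_i w_ie E - w_ii I - B_i)

    ``J_e`` is the summed external excitatory drive (mV).  Inputs broadcast.
    """
    E = np.asarray(E, dtype=float)
    I = np.asarray(I, dtype=float)
    v_e = p.a_e * p.w_ee * E - p.w_ei * I - p.B_e + np.asarray(J_e, dtype=float)
    v_i = p.a_i * p.w_ie * E - p.w_ii * I - p.B_i
    dE = (-E + (1.0 - E) * sigmoid(v_e, p.h)) / p.tau_e
    dI = (-I + (1.0 - I) * sigmoid(v_i, p.h)) / p.tau_i
    if dE.ndim == 0:
        return float(dE), float(dI)
    return dE, dI


def external_input(E_vec: np.ndarray, c: Connectome, G: float) -> np.ndarray:
    """Per-region external drive J_e^(a) = G * sum_b A_ab E^(b) (mV)."""
    E_vec = np.asarray(E_vec, dtype=float)
    if E_vec.shape[-1] != c.n_regions:
        raise ValueError(
            f"E_vec length {E_vec.shape[-1]} != {c.n_regions} regions")
    return G * (E_vec @ c.A.T)


def total_input(J_e, B_e):
    """Net input J_tot = J_e - B_e (mV); the bifurcation-diagram coordinate."""
    return np.asarray(J_e, dtype=float) - np.asarray(B_e, dtype=float)


def zscore_densities(e_raw: Sequence[float], i_raw: Sequence[float],
                     ddof: int = 1) -> DensityMap:
    """z-score raw cell-density vectors into a :class:`DensityMap`.

    Uses the sample-SD convention (``ddof=1``) by default, so ``(1, 2, 3)``
    maps to ``(-1, 0, 1)``; pass ``ddof=0`` for the population SD.
    """
    e_raw = np.asarray(e_raw, dtype=float)
    i_raw = np.asarray(i_raw, dtype=float)
    if e_raw.shape != i_raw.shape or e_raw.ndim != 1:
        raise ValueError("density vectors must be 1-d and of equal length")
    if e_raw.shape[0] < 2:
        raise ValueError("need at least 2 regions to z-score")
    if (e_raw <= 0).any() or (i_raw <= 0).any():
        raise ValueError("raw cell densities must be positive")
    out = {}
    for name, v in (("e", e_raw), ("i", i_raw)):
        sd = v.std(ddof=ddof)
        if sd == 0:
            raise ValueError(
                f"{name}-density vector is constant; z-score undefined")
        out[name] = (v - v.mean()) / sd
    return DensityMap(e_raw=e_raw, i_raw=i_raw, e_z=out["e"], i_z=out["i"])


def perturbation_field(d: DensityMap, sigma: float) -> PerturbationField:
    """Map z-scored densities to relative weight perturbations.

    R_e = sigma * e_z and R_i = sigma * i_z; sigma = 0 reproduces the
    spatially homogeneous model exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        z = np.zeros(d.n_regions)
        return PerturbationField(sigma=0.0, R_e=z, R_i=z.copy())
    return PerturbationField(sigma=float(sigma),
                             R_e=sigma * d.e_z, R_i=sigma * d.i_z)


def apply_perturbations(nominal: NodeParams,
                        f: PerturbationField) -> tuple:
    """Per-region parameter sets with density-scaled coupling weights.

    Outputs from the excitatory population (w_ee, w_ie) scale with
    (1 + R_e); outputs from the inhibitory population (w_ii, w_ei) scale
    with (1 + R_i).  All other parameters are untouched.
    """
    out = []
    for re_a, ri_a in zip(f.R_e, f.R_i):
        out.append(nominal.with_(
            w_ee=nominal.w_ee * (1.0 + re_a),
            w_ie=nominal.w_ie * (1.0 + re_a),
            w_ii=nominal.w_ii * (1.0 + ri_a),
            w_ei=nominal.w_ei * (1.0 + ri_a)))
    return tuple(out)


def build_network(c: Connectome, nominal: NodeParams, G: float,
                  f: PerturbationField | None = None) -> NetworkModel:
    """Assemble a validated :class:`NetworkModel`.

    With ``f=None`` (or a sigma = 0 field) every region gets the nominal
    parameters; otherwise weights are perturbed per region.
    """
    if f is None:
        params = tuple([nominal] * c.n_regions)
    else:
        if f.R_e.shape[0] != c.n_regions:
            raise ValueError("perturbation field length != number of regions")
        params = apply_perturbations(nominal, f)
    return NetworkModel(connectome=c, params=params, G=float(G))
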