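"""Nominal single-node parameter sets for the three dynamical regimes.

Each set places an isolated Wilson-Cowan node in a qualitatively different
part of its bifurcation structure as a function of net input J_tot:

``fixed_point``
    A single stable equilibrium for every J_tot; the E response to input is
    a smooth sigmoid-like branch (weak recurrent excitation).
``hysteresis``
    A bistable window bounded by two saddle-node bifurcations (strong
    recurrent excitation, weak inhibitory feedback onto E).
``limit_cycle``
    A window of stable oscillations bounded by two Hopf bifurcations
    (strong recurrent excitation destabilised by slower inhibition,
    tau_i = 2 tau_e); the coupling constants descend from the classic
    oscillatory Wilson-Cowan setting.

The sets are validated by topology (fold/Hopf counts and the regime
classifier), not by matching any particular published numeric table; B_e is
the sweepable working-point parameter and carries a per-regime default.
Units: ms, mV.
"""

from __future__ import annotations

from .model import NodeParams

__all__ = ["REGIMES", "nominal_params", "DEFAULT_J_RANGE"]

REGIMES: dict[str, NodeParams] = {
    "fixed_point": NodeParams(
        tau_e=10.0, tau_i=10.0, a_e=1.0, a_i=1.0,
        w_ee=4.0, w_ei=6.0, w_ie=10.0, w_ii=6.0,
        B_e=3.3, B_i=3.5),
    "hysteresis": NodeParams(
        tau_e=10.0, tau_i=10.0, a_e=1.0, a_i=1.0,
        w_ee=16.0, w_ei=4.0, w_ie=12.0, w_ii=11.0,
        B_e=3.7, B_i=3.7),
    "limit_cycle": NodeParams(
        tau_e=10.0, tau_i=20.0, a_e=1.0, a_i=1.0,
        w_ee=16.0, w_ei=12.0, w_ie=15.0, w_ii=3.0,
        B_e=1.5, B_i=3.7),
}

#: J_tot interval (mV) covering every regime's bifurcation structure
DEFAULT_J_RANGE: dict[str, tuple[float, float]] = {
    "fixed_point": (-10.0, 10.0),
    "hysteresis": (-10.0, 4.0),
    "limit_cycle": (-8.0, 8.0),
}


def nominal_params(regime: str) -> NodeParams:
    """Return the nominal :class:`NodeParams` for a named regime."""
    try:
        return REGIMES[regime]
    except KeyError:
        raise ValueError(
            f"unknown regime {regime!r}; pick from {sorted(REGIMES)}"
        ) from None
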