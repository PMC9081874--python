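"""Single-node bifurcation analysis in the net-input coordinate J_tot.

One Wilson-Cowan node driven by a constant net input J_tot = J_e - B_e is a
planar system on [0, 1]^2 with at most three equilibria.  This module traces
equilibrium branches over a J_tot interval, labels their stability from the
2x2 Jacobian, locates saddle-node (fold) and Hopf bifurcations by bisection,
measures the limit-cycle envelope by direct integration, and classifies the
resulting diagram into one of the three canonical regimes: a single stable
fixed point, a bistable (hysteresis) window between two folds, or a stable
limit cycle between two Hopf points.

The continuation strategy is a uniform grid in J_tot with exhaustive
root-finding at each sample and nearest-neighbour branch stitching; folds
are refined by bisection on the root count and Hopf points by bisection on
the real part of the complex eigenvalue pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model import NodeParams, drift, sigmoid

__all__ = [
    "EquilibriumBranch",
    "BifurcationDiagram",
    "RegimeLabel",
    "find_equilibria",
    "jacobian",
    "stability_label",
    "trace_branches",
    "detect_folds",
    "detect_hopf",
    "limit_cycle_envelope",
    "classify_regime",
    "compute_diagram",
    "perturb_node",
    "perturbation_study",
    "plot_diagram",
]

#: default numerical tolerances; overridable per call
ROOT_RESIDUAL_TOL = 1e-9
BISECT_TOL = 1e-6          # fold / Hopf location (mV)
DUPLICATE_TOL = 1e-5       # merge distance for duplicate roots
OSC_AMP_TOL = 1e-4         # peak-to-peak amplitude below this = no oscillation


# ---------------------------------------------------------------------------
# equilibria
# ---------------------------------------------------------------------------

def _inhibitory_nullcline(E, p: NodeParams):
    """I on the dI/dt = 0 nullcline for given E (vectorized bisection).

    g(I) = -I + (1 - I) S(a_i w_ie E - w_ii I - B_i) is strictly decreasing
    in I with g(0) >= 0 > g(1), so the root is unique.
    """
    E = np.asarray(E, dtype=float)
    lo = np.zeros_like(E)
    hi = np.ones_like(E)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        g = -mid + (1.0 - mid) * sigmoid(
            p.a_i * p.w_ie * E - p.w_ii * mid - p.B_i, p.h)
        take_hi = g > 0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    return 0.5 * (lo + hi)


def _excitatory_residual(E, p: NodeParams, J_tot: float):
    """dE/dt (times tau_e) along the inhibitory nullcline."""
    I = _inhibitory_nullcline(E, p)
    v_e = p.a_e * p.w_ee * np.asarray(E, dtype=float) - p.w_ei * I + J_tot
    return -np.asarray(E, dtype=float) + (1.0 - np.asarray(E, dtype=float)) \
        * sigmoid(v_e, p.h)


def find_equilibria(p: NodeParams, J_tot: float, *, n_scan: int = 801,
                    tol: float = DUPLICATE_TOL) -> list[tuple[float, float]]:
    """All equilibria (E*, I*) of one node at constant net input J_tot.

    Reduces the 2-d root problem to a scalar one: I is solved on the
    inhibitory nullcline for each E, and sign changes of the excitatory
    residual along that curve are bracketed on a uniform E grid and refined
    by Brent's method.  Roots closer than ``tol`` are merged.
    """
    E_grid = np.linspace(0.0, 1.0, n_scan)
    f = _excitatory_residual(E_grid, p, J_tot)
    roots: list[float] = []

    def f_scalar(E):
        return float(_excitatory_residual(np.array([E]), p, J_tot)[0])

    # endpoints are never roots: f(0) = S(.) > 0 and f(1) = -1 < 0
    sign = np.sign(f)
    for k in np.nonzero(np.diff(sign) != 0)[0]:
        root = brentq(f_scalar, E_grid[k], E_grid[k + 1], xtol=1e-13)
        if not any(abs(root - r) <= tol for r in roots):
            roots.append(root)
    # exact zeros on grid points (rare)
    for k in np.nonzero(f == 0.0)[0]:
        if not any(abs(E_grid[k] - r) <= tol for r in roots):
            roots.append(float(E_grid[k]))
    roots.sort()
    out = []
    for E in roots:
        I = float(_inhibitory_nullcline(np.array([E]), p)[0])
        dE, dI = drift(E, I, p, J_e=J_tot + p.B_e)
        if max(abs(dE), abs(dI)) * max(p.tau_e, p.tau_i) > ROOT_RESIDUAL_TOL:
            raise RuntimeError(
                f"equilibrium residual too large at J_tot={J_tot}: "
                f"({dE}, {dI})")
        out.append((E, I))
    if not out:
        raise RuntimeError(
            f"no equilibrium found at J_tot={J_tot}; invalid parameters?")
    return out


def jacobian(p: NodeParams, E: float, I: float, J_tot: float) -> np.ndarray:
    """Analytic 2x2 Jacobian of the drift at (E, I), using S' = S(h-S)/h."""
    v_e = p.a_e * p.w_ee * E - p.w_ei * I + J_tot
    v_i = p.a_i * p.w_ie * E - p.w_ii * I - p.B_i
    Se = sigmoid(v_e, p.h)
    Si = sigmoid(v_i, p.h)
    dSe = Se * (p.h - Se) / p.h
    dSi = Si * (p.h - Si) / p.h
    return np.array([
        [(-1.0 - Se + (1.0 - E) * dSe * p.a_e * p.w_ee) / p.tau_e,
         (-(1.0 - E) * dSe * p.w_ei) / p.tau_e],
        [((1.0 - I) * dSi * p.a_i * p.w_ie) / p.tau_i,
         (-1.0 - Si - (1.0 - I) * dSi * p.w_ii) / p.tau_i]])


def stability_label(eigvals: np.ndarray) -> str:
    """'stable', 'unstable-saddle' (real eig > 0) or 'unstable-focus'."""
    if eigvals.real.max() < 0:
        return "stable"
    if abs(eigvals.imag).max() > 1e-12:
        return "unstable-focus"
    return "unstable-saddle"


# ---------------------------------------------------------------------------
# diagram containers
# ---------------------------------------------------------------------------

@dataclass
class EquilibriumBranch:
    """One continuous curve of equilibria, ordered by J_tot."""

    J: np.ndarray                 # (m,) net input samples
    E: np.ndarray                 # (m,) equilibrium E*
    I: np.ndarray                 # (m,) equilibrium I*
    eigvals: np.ndarray           # (m, 2) complex eigenvalue pairs
    stability: list               # (m,) labels

    def __len__(self) -> int:
        return self.J.shape[0]


@dataclass
class BifurcationDiagram:
    """Equilibrium branches plus fold / Hopf points and oscillation envelope."""

    params: NodeParams
    J_range: tuple
    branches: list = field(default_factory=list)
    folds: list = field(default_factory=list)      # (J_tot, E*) pairs
    hopfs: list = field(default_factory=list)      # (J_tot, E*) pairs
    envelope: np.ndarray | None = None             # (m, 3): J, E_min, E_max


@dataclass(frozen=True)
class RegimeLabel:
    """Regime classification with its supporting evidence."""

    label: str                 # fixed_point | hysteresis | limit_cycle | composite
    n_folds: int
    n_hopfs: int
    has_oscillations: bool


# ---------------------------------------------------------------------------
# branch tracing and bifurcation detection
# ---------------------------------------------------------------------------

def trace_branches(p: NodeParams, J_range: tuple[float, float],
                   resolution: int = 201) -> BifurcationDiagram:
    """Trace all equilibrium branches on a uniform J_tot grid.

    Roots at consecutive grid points are stitched into branches by
    nearest-neighbour matching in E; a root with no previous partner starts
    a new branch.
    """
    if resolution < 3:
        raise ValueError("resolution must be at least 3 points")
    J_lo, J_hi = float(J_range[0]), float(J_range[1])
    if not (np.isfinite(J_lo) and np.isfinite(J_hi) and J_hi > J_lo):
        raise ValueError("J_range must be a finite increasing interval")
    Js = np.linspace(J_lo, J_hi, resolution)
    match_tol = 0.2  # max |E| jump considered the same branch across one step

    open_branches: list[dict] = []
    closed: list[dict] = []
    for J in Js:
        roots = find_equilibria(p, J)
        used = [False] * len(roots)
        still_open = []
        for br in open_branches:
            best, best_d = None, match_tol
            for k, (E, _) in enumerate(roots):
                d = abs(E - br["E"][-1])
                if not used[k] and d < best_d:
                    best, best_d = k, d
            if best is None:
                closed.append(br)
            else:
                used[best] = True
                _append_point(br, p, J, *roots[best])
                still_open.append(br)
        for k, (E, I) in enumerate(roots):
            if not used[k]:
                br = {"J": [], "E": [], "I": [], "eig": [], "stab": []}
                _append_point(br, p, J, E, I)
                still_open.append(br)
        open_branches = still_open
    closed.extend(open_branches)

    branches = [EquilibriumBranch(
        J=np.array(b["J"]), E=np.array(b["E"]), I=np.array(b["I"]),
        eigvals=np.array(b["eig"]), stability=b["stab"]) for b in closed]
    branches.sort(key=lambda b: (b.J[0], b.E[0]))
    return BifurcationDiagram(params=p, J_range=(J_lo, J_hi),
                              branches=branches)


def _append_point(br: dict, p: NodeParams, J: float, E: float, I: float):
    lam = np.linalg.eigvals(jacobian(p, E, I, J))
    lam = lam[np.argsort(-lam.real)]
    br["J"].append(J)
    br["E"].append(E)
    br["I"].append(I)
    br["eig"].append(lam)
    br["stab"].append(stability_label(lam))


def detect_folds(d: BifurcationDiagram, *, tol: float = BISECT_TOL) -> list:
    """Locate saddle-node points by bisection on the equilibrium count.

    Scans the traced grid for changes in the number of equilibria between
    adjacent J samples and refines each transition to ``tol``; the fold E is
    taken as the midpoint of the colliding root pair.
    """
    p = d.params
    Js = np.unique(np.concatenate([b.J for b in d.branches]))
    counts = [len(find_equilibria(p, J)) for J in Js]
    folds = []
    for k in range(len(Js) - 1):
        if counts[k] == counts[k + 1]:
            continue
        lo, hi = Js[k], Js[k + 1]
        n_lo = counts[k]
        for _ in range(200):
            if hi - lo <= tol:
                break
            mid = 0.5 * (lo + hi)
            if len(find_equilibria(p, mid)) == n_lo:
                lo = mid
            else:
                hi = mid
        J_fold = 0.5 * (lo + hi)
        # E at fold: the two roots that merge on the many-root side
        side = lo if counts[k] > counts[k + 1] else hi
        roots = sorted(E for E, _ in find_equilibria(p, side))
        gaps = [roots[i + 1] - roots[i] for i in range(len(roots) - 1)]
        if gaps:
            i = int(np.argmin(gaps))
            E_fold = 0.5 * (roots[i] + roots[i + 1])
        else:  # pragma: no cover - count change without visible pair
            E_fold = roots[0]
        folds.append((J_fold, E_fold))
    d.folds = folds
    return folds


def _eig_at(p: NodeParams, J: float, E_guess: float) -> np.ndarray:
    roots = find_equilibria(p, J)
    E, I = min(roots, key=lambda r: abs(r[0] - E_guess))
    lam = np.linalg.eigvals(jacobian(p, E, I, J))
    return lam[np.argsort(-lam.real)], E


def detect_hopf(p: NodeParams, branch: EquilibriumBranch,
                *, tol: float = BISECT_TOL) -> list:
    """Hopf points on one branch: Re of a complex pair crosses zero.

    Each sign change of max Re(lambda) between adjacent samples where the
    pair is complex is refined by bisection on J to ``tol``.
    """
    hopfs = []
    re = branch.eigvals[:, 0].real
    im = np.abs(branch.eigvals[:, 0].imag)
    for k in range(len(branch) - 1):
        if im[k] <= 1e-12 and im[k + 1] <= 1e-12:
            continue
        if np.sign(re[k]) == np.sign(re[k + 1]) or re[k] == 0:
            continue
        lo, hi = branch.J[k], branch.J[k + 1]
        s_lo = np.sign(re[k])
        E_guess = branch.E[k]
        for _ in range(200):
            if hi - lo <= tol:
                break
            mid = 0.5 * (lo + hi)
            lam, E_guess = _eig_at(p, mid, E_guess)
            if np.sign(lam[0].real) == s_lo:
                lo = mid
            else:
                hi = mid
        J_h = 0.5 * (hi + lo)
        lam, E_h = _eig_at(p, J_h, E_guess)
        if abs(lam[0].imag) > 0:
            hopfs.append((J_h, E_h))
    return hopfs


# ---------------------------------------------------------------------------
# limit-cycle envelope by direct integration
# ---------------------------------------------------------------------------

def _integrate_node(p: NodeParams, J_tot: float, x0, t_span, *,
                    rtol=1e-8, atol=1e-10, dense=False):
    def rhs(_t, x):
        return drift(x[0], x[1], p, J_e=J_tot + p.B_e)
    return solve_ivp(rhs, t_span, x0, rtol=rtol, atol=atol,
                     dense_output=dense, max_step=max(p.tau_e, p.tau_i))


def limit_cycle_envelope(p: NodeParams, J_grid,
                         *, transient: float = 500.0,
                         window: float = 500.0) -> np.ndarray:
    """Min/max of E on the attractor for each J in ``J_grid``.

    Integrates the deterministic node from a point displaced 1e-3 from an
    equilibrium, discards ``transient`` ms (extended to 10 estimated
    oscillation periods when the equilibrium is a focus), then records the
    envelope of E over ``window`` ms.  Width below ``OSC_AMP_TOL`` is
    collapsed to the fixed point.

    Returns an (m, 3) array of (J_tot, E_min, E_max).
    """
    rows = []
    for J in np.atleast_1d(np.asarray(J_grid, dtype=float)):
        roots = find_equilibria(p, J)
        # start near the most unstable equilibrium to land on the attractor
        def excess(r):
            lam = np.linalg.eigvals(jacobian(p, r[0], r[1], J))
            return lam.real.max()
        E0, I0 = max(roots, key=excess)
        lam = np.linalg.eigvals(jacobian(p, E0, I0, J))
        t_trans = transient
        if abs(lam.imag).max() > 1e-12:
            period = 2.0 * np.pi / abs(lam.imag).max()
            t_trans = max(transient, 10.0 * period)
        x0 = [min(E0 + 1e-3, 1.0), min(I0 + 1e-3, 1.0)]
        sol = _integrate_node(p, J, x0, (0.0, t_trans + window))
        E_t = sol.y[0][sol.t >= t_trans]
        e_min, e_max = float(E_t.min()), float(E_t.max())
        if e_max - e_min < OSC_AMP_TOL:
            e_min = e_max = float(E_t[-1])
        rows.append((float(J), e_min, e_max))
    return np.array(rows)


# ---------------------------------------------------------------------------
# classification and convenience drivers
# ---------------------------------------------------------------------------

def classify_regime(d: BifurcationDiagram) -> RegimeLabel:
    """Classify a completed diagram as fixed_point / hysteresis / limit_cycle.

    Hysteresis needs >= 2 folds (a bistable window); limit_cycle needs >= 1
    Hopf with a non-degenerate oscillation envelope.  A diagram showing both
    features is labelled 'composite' rather than forced into one class.
    """
    n_folds = len(d.folds)
    n_hopfs = len(d.hopfs)
    has_osc = bool(
        d.envelope is not None
        and (d.envelope[:, 2] - d.envelope[:, 1] > OSC_AMP_TOL).any())
    is_hyst = n_folds >= 2
    is_lc = n_hopfs >= 1 and has_osc
    if is_hyst and is_lc:
        label = "composite"
    elif is_hyst:
        label = "hysteresis"
    elif is_lc:
        label = "limit_cycle"
    else:
        label = "fixed_point"
    return RegimeLabel(label=label, n_folds=n_folds, n_hopfs=n_hopfs,
                       has_oscillations=has_osc)


def compute_diagram(p: NodeParams, J_range: tuple[float, float],
                    resolution: int = 201, *,
                    envelope_points: int = 41) -> BifurcationDiagram:
    """Trace branches, detect folds and Hopf points, and fill the envelope."""
    d = trace_branches(p, J_range, resolution)
    detect_folds(d)
    hopfs = []
    for br in d.branches:
        hopfs.extend(detect_hopf(p, br))
    d.hopfs = sorted(hopfs)
    if d.hopfs:
        # envelope sampled across the (slightly padded) oscillatory window
        J_h = [J for J, _ in d.hopfs]
        pad = 0.05 * (d.J_range[1] - d.J_range[0])
        lo = max(d.J_range[0], min(J_h) - pad)
        hi = min(d.J_range[1], max(J_h) + pad)
        d.envelope = limit_cycle_envelope(
            p, np.linspace(lo, hi, envelope_points))
    return d


def perturb_node(nominal: NodeParams, R_e: float, R_i: float) -> NodeParams:
    """Scale one node's excitatory outputs by (1+R_e), inhibitory by (1+R_i)."""
    if 1.0 + R_e <= 0 or 1.0 + R_i <= 0:
        raise ValueError("perturbation would produce non-positive weights")
    return nominal.with_(
        w_ee=nominal.w_ee * (1.0 + R_e), w_ie=nominal.w_ie * (1.0 + R_e),
        w_ii=nominal.w_ii * (1.0 + R_i), w_ei=nominal.w_ei * (1.0 + R_i))


def perturbation_study(nominal: NodeParams, R_values,
                       mode: str, J_range: tuple[float, float],
                       resolution: int = 121) -> dict:
    """Family of diagrams under coordinated R_e / R_i perturbations.

    ``mode`` selects how the scan value R maps to (R_e, R_i):
    'e_only' -> (R, 0); 'i_only' -> (0, R); 'equal' -> (R, R);
    'opposed' -> (R, -R).  Returns {(R_e, R_i): BifurcationDiagram}.
    """
    mapping = {
        "e_only": lambda r: (r, 0.0),
        "i_only": lambda r: (0.0, r),
        "equal": lambda r: (r, r),
        "opposed": lambda r: (r, -r),
    }
    if mode not in mapping:
        raise ValueError(f"unknown mode {mode!r}; pick from {sorted(mapping)}")
    out = {}
    for r in R_values:
        re_, ri_ = mapping[mode](float(r))
        p = perturb_node(nominal, re_, ri_)
        out[(re_, ri_)] = compute_diagram(p, J_range, resolution)
    return out


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_diagram(d: BifurcationDiagram, ax=None, color="k", label=None):
    """Standard J_tot-E diagram: solid stable, dotted unstable, shaded envelope."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for br in d.branches:
        stab = np.array([s == "stable" for s in br.stability])
        # split into runs of constant stability so line style is correct
        edges = np.nonzero(np.diff(stab.astype(int)))[0] + 1
        for seg in np.split(np.arange(len(br)), edges):
            if seg.size == 0:
                continue
            style = "-" if stab[seg[0]] else ":"
            ax.plot(br.J[seg], br.E[seg], style, color=color,
                    label=label if seg[0] == 0 else None)
            label = None
    if d.envelope is not None:
        osc = d.envelope[:, 2] - d.envelope[:, 1] > OSC_AMP_TOL
        if osc.any():
            ax.fill_between(d.envelope[osc, 0], d.envelope[osc, 1],
                            d.envelope[osc, 2], alpha=0.25, color=color)
    for J, E in d.folds:
        ax.plot(J, E, "s", color=color, ms=5)
    for J, E in d.hopfs:
        ax.plot(J, E, "o", color=color, ms=5)
    ax.set_xlabel(r"$J_\mathrm{tot}$ (mV)")
    ax.set_ylabel(r"$E^*$")
    ax.set_ylim(-0.02, 1.02)
    return ax
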