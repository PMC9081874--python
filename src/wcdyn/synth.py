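"""Synthetic study inputs: connectomes, cell-density maps, and target FC.

The generators emulate the statistical structure of the real study inputs
-- a dense directed binary cortical connectome with heterogeneous
in-degree, positively correlated excitatory/inhibitory cell-density maps
with modest regional variation, and a target FC produced by a ground-truth
simulation plus observation noise -- so the full pipeline is exercisable
and testable without any external downloads.  Target FC is generated by
forward simulation of the same model family, a deliberate self-consistency
choice that makes parameter-recovery properties well-posed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluate import FCMatrix, compute_fc
from .model import (Connectome, DensityMap, NetworkModel, build_network,
                    perturbation_field, zscore_densities)
from .regimes import nominal_params
from .simulate import SimulationConfig, remove_transient, simulate

__all__ = [
    "SynthSpec",
    "GROUP_NAMES",
    "synth_connectome",
    "synth_densities",
    "synth_target_fc",
    "make_fixture_suite",
]

#: six anatomical groupings used to label synthetic regions
GROUP_NAMES = ("Somatomotor", "Medial", "Temporal", "Visual",
               "Anterolateral", "Prefrontal")

#: mean raw densities (cells per mm^3), excitatory ~5x inhibitory
_MEAN_E_DENSITY = 6.0e4
_MEAN_I_DENSITY = 1.2e4


@dataclass(frozen=True)
class SynthSpec:
    """Knobs of the synthetic study-input generators.

    Defaults mirror the real inputs being emulated: 37 cortical regions, a
    dense directed graph (edge density 0.7) with heavy-tailed in-degree,
    positively correlated e/i densities (r = 0.5) with ~25% regional
    coefficient of variation, and six anatomical groupings.
    """

    N: int = 37
    edge_density: float = 0.7
    degree_heterogeneity: str = "heavy_tailed"
    ei_correlation: float = 0.5
    density_cv: float = 0.25
    n_groups: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need at least 2 regions")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if not (-1 <= self.ei_correlation <= 1):
            raise ValueError("ei_correlation must be in [-1, 1]")
        if self.density_cv <= 0:
            raise ValueError("density_cv must be positive")
        if self.degree_heterogeneity not in ("uniform", "heavy_tailed"):
            raise ValueError("degree_heterogeneity must be "
                             "'uniform' or 'heavy_tailed'")


def _labels_groups(spec: SynthSpec) -> tuple[tuple, tuple]:
    labels = tuple(f"R{k:02d}" for k in range(spec.N))
    names = GROUP_NAMES[:spec.n_groups] or tuple(
        f"G{k}" for k in range(spec.n_groups))
    groups = tuple(names[k * len(names) // spec.N] for k in range(spec.N))
    return labels, groups


def synth_connectome(spec: SynthSpec) -> Connectome:
    """Random binary directed connectome with controllable in-degree spread.

    In 'heavy_tailed' mode each region draws a lognormal in-degree
    propensity, so a minority of high in-degree hub regions exists (the
    driver of inter-regional J_e diversity); 'uniform' mode is plain
    Erdos-Renyi.  The expected off-diagonal density equals ``edge_density``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.N
    if spec.degree_heterogeneity == "heavy_tailed":
        prop = rng.lognormal(mean=0.0, sigma=0.8, size=n)
        p_row = spec.edge_density * prop / prop.mean()
        P = np.clip(np.repeat(p_row[:, None], n, axis=1), 0.0, 1.0)
    else:
        P = np.full((n, n), spec.edge_density)
    A = (rng.uniform(size=(n, n)) < P).astype(float)
    np.fill_diagonal(A, 0.0)
    # keep the model connected enough: every region gets >= 1 input
    for a in range(n):
        if A[a].sum() == 0:
            b = rng.integers(n - 1)
            A[a, b + (b >= a)] = 1.0
    labels, groups = _labels_groups(spec)
    return Connectome(A=A, labels=labels, groups=groups)


def synth_densities(spec: SynthSpec) -> DensityMap:
    """Correlated lognormal excitatory/inhibitory cell-density maps.

    Both raw vectors share a latent Gaussian factor with correlation
    ``ei_correlation`` (at +1 the z-scored maps coincide exactly) and are
    exponentiated so raw densities are strictly positive with coefficient
    of variation ~``density_cv``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    r = spec.ei_correlation
    z_e = rng.standard_normal(spec.N)
    w = rng.standard_normal(spec.N)
    z_i = r * z_e + np.sqrt(max(0.0, 1.0 - r * r)) * w
    s = np.sqrt(np.log1p(spec.density_cv ** 2))
    e_raw = _MEAN_E_DENSITY * np.exp(s * z_e - 0.5 * s * s)
    i_raw = _MEAN_I_DENSITY * np.exp(s * z_i - 0.5 * s * s)
    return zscore_densities(e_raw, i_raw)


def synth_target_fc(model: NetworkModel, cfg: SimulationConfig,
                    observation_noise_sd: float = 0.0,
                    seed: int = 0) -> FCMatrix:
    """Target FC from one ground-truth simulation plus observation noise.

    The simulated FC's unique pairs are jittered in Fisher-z space by
    i.i.d. N(0, observation_noise_sd), re-symmetrised, the diagonal reset
    to 1, and entries clipped to [-1, 1].
    """
    if observation_noise_sd < 0:
        raise ValueError("observation_noise_sd must be non-negative")
    fc = compute_fc(remove_transient(simulate(model, cfg.with_(seed=seed))))
    v = fc.values.copy()
    if observation_noise_sd > 0:
        rng = np.random.default_rng(seed + 10_000)
        iu = np.triu_indices(fc.n_regions, k=1)
        z = np.arctanh(np.clip(v[iu], -1 + 1e-12, 1 - 1e-12))
        z += observation_noise_sd * rng.standard_normal(z.size)
        v[iu] = np.tanh(z)
        v.T[iu] = v[iu]
    np.fill_diagonal(v, 1.0)
    return FCMatrix(values=np.clip(v, -1, 1), labels=fc.labels)


#: planted working point of the miniature fixture study
FIXTURE_REGIME = "limit_cycle"
FIXTURE_G = 0.7
FIXTURE_B_E = 1.5
FIXTURE_SIM = SimulationConfig(dt=0.1, T=11_000.0, transient=1000.0)


def make_fixture_suite(out_dir, seed: int = 0, *,
                       N: int = 12, sigma: float = 0.0,
                       observation_noise_sd: float = 0.02) -> dict:
    """Write a complete miniature synthetic study to ``out_dir``.

    Produces adjacency CSV, region table TSV, densities TSV, a target FC
    CSV generated at a known regime/working point, a run-config YAML, and
    a manifest with SHA-256 checksums.  Returns {name: Path}.
    """
    from . import io as io_mod

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = SynthSpec(N=N, seed=seed)
    c = synth_connectome(spec)
    d = synth_densities(spec)
    nominal = nominal_params(FIXTURE_REGIME).with_(B_e=FIXTURE_B_E)
    f = perturbation_field(d, sigma) if sigma > 0 else None
    model = build_network(c, nominal, FIXTURE_G, f)
    target = synth_target_fc(model, FIXTURE_SIM, observation_noise_sd,
                             seed=seed + 500)

    paths = {
        "connectome": out_dir / "connectome.csv",
        "regions": out_dir / "regions.tsv",
        "densities": out_dir / "densities.tsv",
        "target_fc": out_dir / "target_fc.csv",
        "config": out_dir / "config.yaml",
    }
    io_mod.write_adjacency(paths["connectome"], c)
    io_mod.write_region_table(paths["regions"], c)
    io_mod.write_densities(paths["densities"], c, d)
    io_mod.write_fc(paths["target_fc"], target)
    io_mod.write_config(paths["config"], {
        # names are relative to the fixture directory so the suite is
        # byte-identical wherever it is written
        "paths": {k: paths[k].name for k in
                  ("connectome", "regions", "densities", "target_fc")},
        "regime": FIXTURE_REGIME,
        "G": FIXTURE_G,
        "B_e": FIXTURE_B_E,
        "sigma": sigma,
        "simulation": {"dt": FIXTURE_SIM.dt, "T": FIXTURE_SIM.T,
                       "transient": FIXTURE_SIM.transient,
                       "noise_s": FIXTURE_SIM.noise_s},
        "seed": seed,
    })
    manifest = {name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in paths.items()}
    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = man_path
    return paths
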