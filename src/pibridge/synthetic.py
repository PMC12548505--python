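"""Synthetic data emulating the study's inputs: noisy adhesion curves from
known binding constants, grafting-density series, and idealized ring/cation
coordinate fixtures.

The adhesion generator draws curves from the normalized competitive-binding
isotherm with multiplicative Gaussian replicate noise (measurement scatter
in surface-forces experiments grows with the signal).  The geometry
generator places ideal benzene hexagons (C-C 1.39 A, hydrogens omitted) in
canonical stacking motifs — T-shaped, parallel-stacked, cation-bridged —
plus a random-gas control, with optional per-atom Gaussian jitter.  Every
generator is deterministic for a fixed seed; each synthetic curve records
the true constants it was drawn from so parameter-recovery studies can
score themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .adhesion_fit import AdhesionCurve, AdhesionPoint, SaltSpec, bath_for_point
from .equilibria import BindingConstants, extended_no_electrolyte
from .adhesion_fit import predict_normalized
from .ringgeom import CationSite, RingGroup

__all__ = [
    "AdhesionSimSpec",
    "GeometrySimSpec",
    "DEFAULT_TRUE_CONSTANTS",
    "default_sim_spec",
    "simulate_adhesion_curves",
    "simulate_grafting_series",
    "make_ring_fixture",
    "ideal_ring_coords",
]

BENZENE_RADIUS = 1.39  # A; C-C bond length of a regular hexagon

# Reference generating constants: monovalent blocking k1, trivalent blocking
# k2 and bridging-to-pairing ratio k4/k5 chosen so the trivalent curve
# overshoots (k4/k5 > 2 k2) with its peak inside the sampled grid.
DEFAULT_TRUE_CONSTANTS = BindingConstants(k1=0.5, k2=0.2, k4=1.0, k5=1.0)

DEFAULT_IONIC_STRENGTH_GRID = (0.0, 1.0, 3.0, 6.0, 10.0, 30.0, 60.0, 100.0)  # mM

KNO3 = SaltSpec("KNO3", 1)
MGNO32 = SaltSpec("Mg(NO3)2", 2)
YNO33 = SaltSpec("Y(NO3)3", 3)


@dataclass
class AdhesionSimSpec:
    """Design of a synthetic adhesion experiment.

    Defaults mirror the study conditions: an 8-point ionic-strength grid
    including 0, monovalent and trivalent single-salt series, mixed series
    with the trivalent cation held at 1 and 5 mM, 3 replicates, and 5%
    multiplicative Gaussian noise on a 10 mJ/m^2 salt-free baseline.
    """

    true_constants: BindingConstants = DEFAULT_TRUE_CONSTANTS
    ionic_strength_grid: tuple = DEFAULT_IONIC_STRENGTH_GRID
    salts: tuple = (KNO3, YNO33)
    mixed_series: tuple = (1.0, 5.0)  # held [T] in mM; uses the monovalent salt
    n_replicates: int = 3
    noise_sd: float = 0.05  # fraction of the noiseless value
    baseline_adhesion: float = 10.0  # mJ/m^2 at zero ionic strength
    seed: int = 0
    surface_label: str = "BB-Pep6.5"

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if 0.0 not in self.ionic_strength_grid:
            raise ValueError("ionic_strength_grid must include 0 (the baseline)")


def default_sim_spec(seed: int = 0, **overrides) -> AdhesionSimSpec:
    """The study-condition simulation spec with a chosen seed."""
    return AdhesionSimSpec(seed=seed, **overrides)


@dataclass
class GeometrySimSpec:
    """Design of an idealized two-layer ring/cation fixture."""

    motif: str = "parallel_stacked"  # t_shaped | parallel_stacked | cation_bridge | random_gas
    n_rings: int = 2  # per layer
    layer_separation: float = 3.5  # A, centroid distance between paired rings
    jitter_sd: float = 0.0  # A, per-coordinate Gaussian jitter
    cation_species: str = "Y3+"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.motif not in ("t_shaped", "parallel_stacked", "cation_bridge", "random_gas"):
            raise ValueError(f"unknown motif {self.motif!r}")
        if self.layer_separation <= 0:
            raise ValueError("layer_separation must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")


def simulate_adhesion_curves(spec: AdhesionSimSpec) -> list[AdhesionCurve]:
    """Generate noisy adhesion curves from known constants.

    For every salt series (and every mixed series with held [T]), adhesion
    at each grid point is baseline * predicted_normalized * (1 + eps) with
    eps ~ N(0, noise_sd), independently per replicate.  Deterministic for a
    fixed seed; each curve's ``meta`` records the true constants and seed.
    """
    rng = np.random.default_rng(spec.seed)
    k = spec.true_constants
    meta = {
        "true_constants": {
            "k1": k.k1,
            "k2": k.k2,
            "k4_over_k5": k.k4 / k.k5 if k.k5 > 0 else None,
        },
        "baseline_adhesion": spec.baseline_adhesion,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }

    series: list[tuple[SaltSpec, float, tuple]] = []
    for salt in spec.salts:
        series.append((salt, 0.0, tuple(spec.ionic_strength_grid)))
    mono = next((s for s in spec.salts if s.cation_valence == 1), KNO3)
    for t_conc in spec.mixed_series:
        # the monovalent salt is added on top of the held trivalent salt,
        # so the total ionic strength starts at the trivalent floor 6*t
        grid = (0.0,) + tuple(
            6.0 * t_conc + i for i in spec.ionic_strength_grid if i > 0
        )
        series.append((mono, t_conc, grid))

    curves = []
    for salt, t_conc, grid in series:
        points = []
        for i in grid:
            bath = bath_for_point(
                i, salt, t_conc, divalent_as_trivalent=(salt.cation_valence == 2)
            )
            clean = spec.baseline_adhesion * predict_normalized(bath, k)
            for rep in range(spec.n_replicates):
                eps = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
                points.append(
                    AdhesionPoint(
                        ionic_strength=i,
                        adhesion_energy=clean * (1.0 + eps),
                        replicate_id=f"r{rep + 1}",
                    )
                )
        curves.append(
            AdhesionCurve(
                points=points,
                salt=salt,
                surface_label=spec.surface_label,
                fixed_t_conc=t_conc,
                normalized=False,
                meta=dict(meta),
            )
        )
    return curves


def simulate_grafting_series(
    k5: float,
    k6: float,
    densities,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Salt-free adhesion vs grafting density from the crowded-surface form.

    adhesion = K5 rho^2 / (1 + 2 K6 rho)^2 * (1 + eps), eps ~ N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    rho = np.asarray(densities, dtype=float)
    clean = np.array([extended_no_electrolyte(r, k5, k6) for r in rho])
    if noise_sd > 0:
        clean = clean * (1.0 + rng.normal(0.0, noise_sd, size=clean.shape))
    return rho, clean


def ideal_ring_coords(
    centroid: np.ndarray, normal: np.ndarray, radius: float = BENZENE_RADIUS
) -> np.ndarray:
    """Regular hexagon of the given radius in the plane normal to ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    # deterministic in-plane axes
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    angles = np.deg2rad(np.arange(0, 360, 60))
    return np.asarray(centroid, float) + radius * (
        np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v)
    )


def make_ring_fixture(spec: GeometrySimSpec) -> tuple[list[RingGroup], list[CationSite]]:
    """Place ideal rings (and cations) in the requested motif.

    Pairs are laid out 10 A apart laterally so neighbouring pairs never
    touch at the default cutoffs.  Per-atom Gaussian jitter is applied
    after placement; jitter large enough to break ring planarity surfaces
    as the usual planarity warning on the affected rings.
    """
    rng = np.random.default_rng(spec.seed)
    sep = spec.layer_separation
    rings: list[RingGroup] = []
    cations: list[CationSite] = []
    spacing = 10.0

    def add_ring(coords, idx, layer):
        jittered = coords + rng.normal(0.0, spec.jitter_sd, coords.shape)
        prefix = "U" if layer == "upper" else "L"
        rings.append(
            RingGroup(
                atom_coords=jittered,
                ring_id=f"{prefix}{idx}",
                residue_id=f"PHE{idx}",
                layer=layer,
            )
        )

    if spec.motif == "random_gas":
        box = max(spacing * spec.n_rings, 20.0)
        for layer, z_lo in (("lower", 0.0), ("upper", sep)):
            for j in range(spec.n_rings):
                centroid = np.array(
                    [rng.uniform(0, box), rng.uniform(0, box), z_lo + rng.uniform(0, 5.0)]
                )
                normal = rng.normal(size=3)
                normal /= np.linalg.norm(normal)
                add_ring(ideal_ring_coords(centroid, normal), j, layer)
        for j in range(spec.n_rings):
            coord = np.array(
                [rng.uniform(0, box), rng.uniform(0, box), rng.uniform(0, sep + 5.0)]
            )
            cations.append(
                CationSite(
                    coord=coord + rng.normal(0.0, spec.jitter_sd, 3),
                    species=spec.cation_species,
                    site_id=f"C{j}",
                    layer="bath",
                )
            )
        return rings, cations

    for j in range(spec.n_rings):
        x = j * spacing
        lower_centroid = np.array([x, 0.0, 0.0])
        upper_centroid = np.array([x, 0.0, sep])
        if spec.motif == "t_shaped":
            add_ring(ideal_ring_coords(lower_centroid, [0.0, 0.0, 1.0]), j, "lower")
            add_ring(ideal_ring_coords(upper_centroid, [1.0, 0.0, 0.0]), j, "upper")
        elif spec.motif == "parallel_stacked":
            add_ring(ideal_ring_coords(lower_centroid, [0.0, 0.0, 1.0]), j, "lower")
            add_ring(ideal_ring_coords(upper_centroid, [0.0, 0.0, 1.0]), j, "upper")
        elif spec.motif == "cation_bridge":
            add_ring(ideal_ring_coords(lower_centroid, [0.0, 0.0, 1.0]), j, "lower")
            add_ring(ideal_ring_coords(upper_centroid, [0.0, 0.0, 1.0]), j, "upper")
            cations.append(
                CationSite(
                    coord=np.array([x, 0.0, sep / 2.0])
                    + rng.normal(0.0, spec.jitter_sd, 3),
                    species=spec.cation_species,
                    site_id=f"C{j}",
                    layer="bath",
                )
            )
    return rings, cations
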