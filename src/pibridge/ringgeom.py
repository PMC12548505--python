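"""Geometric analysis of pi-pi and cation-pi contacts in coordinate snapshots.

Phenyl rings are declared (six atoms each, with an upper/lower layer tag),
not perceived from connectivity.  Contact criteria follow the trajectory-
analysis conventions used for peptide-brush simulations:

* a pi-pi contact exists when ANY atom pair of two rings is closer than
  4.5 A (strict inequality);
* a cation-pi contact exists when a cation lies within 10 A of a ring
  centroid (strict inequality);
* the angle between two ring normals is folded to [0, 90] deg by taking
  the supplement when it exceeds 90 deg.

The 2D distribution of stacking geometry over (centroid distance, folded
normal angle) is estimated with a product-Gaussian kernel density with
Scott's-rule bandwidths per axis and boundary reflection, so the density
integrates to 1 on the folded domain.  Coordinates are treated as unwrapped
(no periodic images).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "RingGroup",
    "CationSite",
    "ContactRecord",
    "RingFrame",
    "BridgeMotif",
    "DensitySurface",
    "Nh3PiResult",
    "ring_frame",
    "plane_angle",
    "detect_pi_pi",
    "detect_cation_pi",
    "bridging_motifs",
    "stacking_distribution",
    "nh3_pi_distances",
    "contact_summary",
]

PI_PI_CUTOFF = 4.5  # A, min any-atom pair distance
CATION_PI_CUTOFF = 10.0  # A, cation to ring centroid

CATION_SPECIES = ("NH3+", "K+", "Y3+")
LAYERS = ("upper", "lower")

PLANARITY_WARN = 0.5  # A, max out-of-plane deviation before warning
PLANARITY_ERROR = 1.5  # A, hard limit

# bandwidth floors for degenerate (point-mass) KDE axes
_BW_FLOOR_DISTANCE = 0.25  # A
_BW_FLOOR_ANGLE = 2.5  # deg


@dataclass(frozen=True)
class RingFrame:
    centroid: np.ndarray
    normal: np.ndarray


@dataclass
class RingGroup:
    """A six-atom aromatic ring with a layer tag.

    Planarity is validated on construction: rings deviating more than 0.5 A
    from their best-fit plane are flagged with a warning, more than 1.5 A
    is an error.
    """

    atom_coords: np.ndarray  # (6, 3) in A
    ring_id: str
    residue_id: str = ""
    layer: str = "upper"
    snapshot_index: int = 0
    planarity_warning: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.atom_coords, dtype=float)
        if coords.shape != (6, 3):
            raise ValueError(f"ring {self.ring_id!r}: expected 6 atoms, got shape {coords.shape}")
        if self.layer not in LAYERS:
            raise ValueError(f"ring {self.ring_id!r}: layer must be one of {LAYERS}")
        self.atom_coords = coords
        frame = ring_frame(self)
        deviation = float(np.max(np.abs((coords - frame.centroid) @ frame.normal)))
        if deviation > PLANARITY_ERROR:
            raise ValueError(
                f"ring {self.ring_id!r} is not planar "
                f"(max out-of-plane deviation {deviation:.2f} A)"
            )
        if deviation > PLANARITY_WARN:
            self.planarity_warning = True
            warnings.warn(
                f"ring {self.ring_id!r}: out-of-plane deviation {deviation:.2f} A "
                f"exceeds {PLANARITY_WARN} A",
                stacklevel=2,
            )


@dataclass
class CationSite:
    """A cation position: a metal ion or the nitrogen of a lysine NH3+ group."""

    coord: np.ndarray  # (3,) in A
    species: str
    site_id: str
    layer: str = "bath"  # upper | lower | bath
    snapshot_index: int = 0

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,):
            raise ValueError(f"site {self.site_id!r}: coord must have shape (3,)")
        self.coord = coord
        if self.species not in CATION_SPECIES:
            raise ValueError(
                f"site {self.site_id!r}: species {self.species!r} not in {CATION_SPECIES}"
            )
        if self.layer not in LAYERS + ("bath",):
            raise ValueError(f"site {self.site_id!r}: bad layer {self.layer!r}")


@dataclass(frozen=True)
class ContactRecord:
    """One detected pi-pi or cation-pi contact.

    ``metric_distance`` is the minimum atom-pair distance for pi-pi and the
    cation-to-centroid distance for cation-pi.  ``span`` classifies the
    contact as within one layer or bridging the two; a bath cation inherits
    the ring's layer (its contacts are labelled intra-plane).
    """

    kind: str  # pi_pi | cation_pi
    partner_a: str  # ring_id
    partner_b: str  # ring_id or site_id
    metric_distance: float
    plane_angle: float | None  # deg in [0, 90]; pi_pi only
    span: str  # intra_plane | inter_plane
    snapshot_index: int = 0
    ring_layer: str | None = None  # layer of partner_a's ring
    species: str | None = None  # cation species; cation_pi only


@dataclass(frozen=True)
class BridgeMotif:
    """A cation coordinating one or more rings; order >= 2 spanning both
    layers is an inter-plane pi-cation-pi bridge."""

    site_id: str
    ring_ids: tuple
    order: int
    layers: tuple
    is_bridge: bool
    snapshot_index: int = 0


@dataclass
class DensitySurface:
    """2D KDE over (centroid distance, folded normal angle)."""

    distance_grid: np.ndarray
    angle_grid: np.ndarray
    density: np.ndarray  # shape (len(distance_grid), len(angle_grid))
    meta: dict

    def integral(self) -> float:
        inner = np.trapezoid(self.density, self.angle_grid, axis=1)
        return float(np.trapezoid(inner, self.distance_grid))

    def mode(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.density), self.density.shape)
        return float(self.distance_grid[i]), float(self.angle_grid[j])


@dataclass
class Nh3PiResult:
    """NH3+-to-ring-centroid distance collection with histogram and summary."""

    distances: np.ndarray
    hist_counts: np.ndarray
    bin_edges: np.ndarray
    summary: dict


def ring_frame(ring: RingGroup | np.ndarray) -> RingFrame:
    """Centroid and unit normal of a ring from its atom coordinates.

    The normal is the direction of least variance of the centered atoms
    (smallest principal component); its sign is fixed to positive z,
    breaking ties by positive x then positive y.
    """
    coords = ring.atom_coords if isinstance(ring, RingGroup) else np.asarray(ring, float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate ring: atoms are collinear or coincident")
    normal = vt[-1]
    tol = 1e-10
    for axis in (2, 0, 1):
        if normal[axis] > tol:
            break
        if normal[axis] < -tol:
            normal = -normal
            break
    return RingFrame(centroid=centroid, normal=normal)


def plane_angle(normal_a: np.ndarray, normal_b: np.ndarray) -> float:
    """Angle between ring normals in degrees, folded to [0, 90].

    The supplement is taken when the raw angle exceeds 90 deg, so the
    result is insensitive to the sign of either normal.
    """
    a = np.asarray(normal_a, dtype=float)
    b = np.asarray(normal_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("zero-length normal vector")
    cos = abs(float(a @ b) / (na * nb))
    return math.degrees(math.acos(min(cos, 1.0)))


def _ring_span(layer_a: str, layer_b: str) -> str:
    return "intra_plane" if layer_a == layer_b else "inter_plane"


def detect_pi_pi(
    rings_a: list[RingGroup],
    rings_b: list[RingGroup],
    cutoff: float = PI_PI_CUTOFF,
) -> list[ContactRecord]:
    """Detect pi-pi contacts: any atom pair closer than ``cutoff`` (strict).

    When both arguments are the same list, each unordered pair is examined
    once and self-pairs are skipped; rings are only paired within the same
    snapshot.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    same = rings_a is rings_b
    contacts: list[ContactRecord] = []
    frames_a = [ring_frame(r) for r in rings_a]
    frames_b = frames_a if same else [ring_frame(r) for r in rings_b]
    for i, ra in enumerate(rings_a):
        j_start = i + 1 if same else 0
        for j in range(j_start, len(rings_b)):
            rb = rings_b[j]
            if ra.snapshot_index != rb.snapshot_index:
                continue
            if not same and ra.ring_id == rb.ring_id:
                continue
            min_dist = float(cdist(ra.atom_coords, rb.atom_coords).min())
            if min_dist < cutoff:
                contacts.append(
                    ContactRecord(
                        kind="pi_pi",
                        partner_a=ra.ring_id,
                        partner_b=rb.ring_id,
                        metric_distance=min_dist,
                        plane_angle=plane_angle(frames_a[i].normal, frames_b[j].normal),
                        span=_ring_span(ra.layer, rb.layer),
                        snapshot_index=ra.snapshot_index,
                        ring_layer=ra.layer,
                    )
                )
    return contacts


def detect_cation_pi(
    rings: list[RingGroup],
    cations: list[CationSite],
    cutoff: float = CATION_PI_CUTOFF,
) -> list[ContactRecord]:
    """Detect cation-pi contacts: cation within ``cutoff`` of a ring
    centroid (strict).  A bath cation labels its contacts by the ring's
    layer (intra_plane)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    contacts: list[ContactRecord] = []
    frames = [ring_frame(r) for r in rings]
    for ring, frame in zip(rings, frames):
        for cat in cations:
            if ring.snapshot_index != cat.snapshot_index:
                continue
            dist = float(np.linalg.norm(cat.coord - frame.centroid))
            if dist < cutoff:
                span = (
                    "intra_plane"
                    if cat.layer == "bath"
                    else _ring_span(ring.layer, cat.layer)
                )
                contacts.append(
                    ContactRecord(
                        kind="cation_pi",
                        partner_a=ring.ring_id,
                        partner_b=cat.site_id,
                        metric_distance=dist,
                        plane_angle=None,
                        span=span,
                        snapshot_index=ring.snapshot_index,
                        ring_layer=ring.layer,
                        species=cat.species,
                    )
                )
    return contacts


def bridging_motifs(contacts: list[ContactRecord]) -> list[BridgeMotif]:
    """Group cation-pi contacts by cation into coordination motifs.

    ``order`` counts coordinated rings; a motif of order >= 2 whose rings
    come from both layers is an inter-plane pi-cation-pi bridge.
    """
    grouped: dict[tuple[str, int], list[ContactRecord]] = {}
    for c in contacts:
        if c.kind != "cation_pi":
            continue
        grouped.setdefault((c.partner_b, c.snapshot_index), []).append(c)
    motifs = []
    for (site_id, snap), recs in grouped.items():
        ring_ids = tuple(r.partner_a for r in recs)
        layers = tuple(r.ring_layer for r in recs)
        motifs.append(
            BridgeMotif(
                site_id=site_id,
                ring_ids=ring_ids,
                order=len(ring_ids),
                layers=layers,
                is_bridge=len(ring_ids) >= 2 and len(set(layers)) == 2,
                snapshot_index=snap,
            )
        )
    return motifs


def _pairs_to_points(pairs) -> np.ndarray:
    points = []
    for item in pairs:
        if isinstance(item, ContactRecord):
            if item.plane_angle is None:
                raise ValueError("cation_pi contacts carry no plane angle")
            points.append((item.metric_distance, item.plane_angle))
        elif isinstance(item, tuple) and len(item) == 2 and isinstance(item[0], RingGroup):
            fa, fb = ring_frame(item[0]), ring_frame(item[1])
            points.append(
                (
                    float(np.linalg.norm(fa.centroid - fb.centroid)),
                    plane_angle(fa.normal, fb.normal),
                )
            )
        else:
            points.append((float(item[0]), float(item[1])))
    return np.asarray(points, dtype=float)


def _axis_kernel(grid: np.ndarray, centers: np.ndarray, h: float, reflect) -> np.ndarray:
    """Sum of a Gaussian kernel and its reflections, shape (len(grid), n)."""
    def gauss(x):
        return np.exp(-0.5 * (x / h) ** 2) / (h * math.sqrt(2.0 * math.pi))

    diff = grid[:, None] - centers[None, :]
    out = gauss(diff)
    for bound in reflect:
        out += gauss(grid[:, None] - (2.0 * bound - centers)[None, :])
    return out


def stacking_distribution(
    pairs,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
    angle_max: float = 90.0,
) -> DensitySurface:
    """2D KDE of stacking geometry over (centroid distance, folded angle).

    ``pairs`` may be pi-pi ContactRecords, ``(RingGroup, RingGroup)``
    tuples, or raw ``(distance, angle)`` pairs; at least two are required.
    Bandwidths follow Scott's rule per axis (sigma * n^(-1/6)) with
    absolute floors of 0.25 A / 2.5 deg for degenerate axes.  Kernel mass
    is reflected at the angle boundaries (0 and ``angle_max``) and at
    distance 0, so the density integrates to 1 over the folded domain;
    the bandwidth rule is recorded in the output metadata.
    """
    points = _pairs_to_points(pairs)
    n = points.shape[0]
    if n < 2:
        raise ValueError("stacking_distribution requires at least 2 pairs")
    d, a = points[:, 0], points[:, 1]
    factor = n ** (-1.0 / 6.0)  # Scott's rule in 2D
    h_d = max(float(np.std(d, ddof=1)) * factor, _BW_FLOOR_DISTANCE)
    h_a = max(float(np.std(a, ddof=1)) * factor, _BW_FLOOR_ANGLE)

    if grid is None:
        d_lo = max(0.0, float(d.min()) - 3.0 * h_d)
        d_hi = float(d.max()) + 3.0 * h_d
        d_grid = np.linspace(d_lo, d_hi, 121)
        a_grid = np.linspace(0.0, angle_max, 91)
    else:
        d_grid = np.asarray(grid[0], dtype=float)
        a_grid = np.asarray(grid[1], dtype=float)

    kd = _axis_kernel(d_grid, d, h_d, reflect=(0.0,))
    ka = _axis_kernel(a_grid, a, h_a, reflect=(0.0, angle_max))
    density = (kd @ ka.T) / n

    meta = {
        "n_pairs": int(n),
        "bandwidth_rule": "scott per axis, floors 0.25 A / 2.5 deg",
        "bandwidth_distance": h_d,
        "bandwidth_angle": h_a,
        "reflected_boundaries": {"distance": [0.0], "angle": [0.0, angle_max]},
    }
    return DensitySurface(distance_grid=d_grid, angle_grid=a_grid, density=density, meta=meta)


def nh3_pi_distances(
    lys_sites: list[CationSite],
    rings: list[RingGroup],
    max_distance: float = 10.0,
    bin_width: float = 0.5,
) -> Nh3PiResult:
    """Distances from lysine NH3+ nitrogens to phenyl-ring centroids.

    Collects all site-ring centroid distances <= ``max_distance`` within
    matching snapshots; returns the distances, a fixed-bin histogram, and
    min/max/mean summary statistics.  Empty inputs give an empty result.
    """
    frames = [ring_frame(r) for r in rings]
    dists = []
    for site in lys_sites:
        if site.species != "NH3+":
            continue
        for ring, frame in zip(rings, frames):
            if ring.snapshot_index != site.snapshot_index:
                continue
            dist = float(np.linalg.norm(site.coord - frame.centroid))
            if dist <= max_distance:
                dists.append(dist)
    distances = np.array(sorted(dists))
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    if distances.size:
        summary = {
            "n": int(distances.size),
            "min": float(distances.min()),
            "max": float(distances.max()),
            "mean": float(distances.mean()),
        }
    else:
        summary = {"n": 0, "min": None, "max": None, "mean": None}
    return Nh3PiResult(distances=distances, hist_counts=counts, bin_edges=edges, summary=summary)


def contact_summary(contacts: list[ContactRecord]) -> pd.DataFrame:
    """Contact counts per (kind, span, cation species, snapshot).

    The ``count`` column sums to the number of input contacts; pi-pi rows
    carry species ``"-"``.
    """
    columns = ["kind", "span", "species", "snapshot_index", "count"]
    if not contacts:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(
        {
            "kind": [c.kind for c in contacts],
            "span": [c.span for c in contacts],
            "species": [c.species if c.species is not None else "-" for c in contacts],
            "snapshot_index": [c.snapshot_index for c in contacts],
        }
    )
    out = (
        df.groupby(["kind", "span", "species", "snapshot_index"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out[columns]
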