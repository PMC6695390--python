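"""Morphometry of serial-EM neuron annotations.

Neurons traced in a serial-EM volume are represented as linked circular
"disc" annotations (center, radius, section) plus closed-curve polygons
outlining cone pedicles.  All coordinates are stored in nm with z as a
section index; metrics are reported in um / um^2.

Metric conventions:

* soma diameter — twice the radius of the single largest disc (assumed to
  be the soma); ties go to the lowest annotation id.
* primary dendrite diameter — median disc diameter in a shell 0.5-1.5 um
  from the soma *boundary* (center distance minus soma radius).  Soma
  radii (~4.5 um) exceed 1.5 um, so a shell measured from the soma center
  would always be empty; the boundary convention is the one that yields a
  usable measurement.
* pedicle area — area enclosed by a closed centripetal Catmull-Rom spline
  through the control points, via the shoelace formula on a dense sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.validation import explain_validity

__all__ = [
    "AnnotationDisc",
    "ClosedCurveAnnotation",
    "SynapseLink",
    "NeuronAnnotation",
    "soma_disc",
    "soma_diameter",
    "primary_dendrite_diameter",
    "catmull_rom_closed",
    "pedicle_area",
    "count_ribbon_synapses",
]

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class AnnotationDisc:
    """A circular annotation on one EM section."""

    id: int
    x_nm: float
    y_nm: float
    z_section: int
    radius_nm: float
    links: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.radius_nm <= 0:
            raise ValueError("disc radius must be positive")


@dataclass(frozen=True)
class ClosedCurveAnnotation:
    """A closed polygon annotation (>= 3 control points) on one section."""

    curve_id: int
    z_section: int
    control_points_nm: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points_nm, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("closed curve needs >= 3 (x, y) control points")
        object.__setattr__(self, "control_points_nm", pts)


@dataclass(frozen=True)
class SynapseLink:
    pre_neuron: int
    post_neuron: int
    kind: str  # "ribbon" | "basal"
    z_section: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("ribbon", "basal"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")


@dataclass(frozen=True)
class NeuronAnnotation:
    """All annotations belonging to one traced neuron."""

    neuron_id: int
    discs: tuple[AnnotationDisc, ...]
    curves: tuple[ClosedCurveAnnotation, ...] = ()
    synapse_links: tuple[SynapseLink, ...] = ()
    section_thickness_nm: float = 90.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "discs", tuple(self.discs))
        object.__setattr__(self, "curves", tuple(self.curves))
        object.__setattr__(self, "synapse_links", tuple(self.synapse_links))
        ids = [d.id for d in self.discs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate disc ids within a neuron")

    def disc_by_id(self, disc_id: int) -> AnnotationDisc:
        for d in self.discs:
            if d.id == disc_id:
                return d
        raise KeyError(disc_id)


def soma_disc(neuron: NeuronAnnotation) -> AnnotationDisc:
    """The single largest disc, assumed to be the soma (ties: lowest id)."""
    if not neuron.discs:
        raise ValueError("neuron has no disc annotations")
    return max(neuron.discs, key=lambda d: (d.radius_nm, -d.id))


def soma_diameter(neuron: NeuronAnnotation) -> float:
    """Soma diameter in um: twice the largest annotation radius."""
    return 2.0 * soma_disc(neuron).radius_nm / NM_PER_UM


def _distance_nm(a: AnnotationDisc, b: AnnotationDisc, section_thickness_nm: float) -> float:
    dz = (a.z_section - b.z_section) * section_thickness_nm
    return float(np.hypot(np.hypot(a.x_nm - b.x_nm, a.y_nm - b.y_nm), dz))


def primary_dendrite_diameter(
    neuron: NeuronAnnotation,
    shell_um: tuple[float, float] = (0.5, 1.5),
) -> float:
    """Median disc diameter (um) within a shell around the soma boundary.

    Distances are 3D Euclidean with z = section index x section thickness,
    measured from the soma surface (center distance minus soma radius);
    the shell bounds are inclusive.
    """
    soma = soma_disc(neuron)
    lo, hi = shell_um
    diameters = []
    boundary_dists = []
    for d in neuron.discs:
        if d.id == soma.id:
            continue
        dist_um = (_distance_nm(d, soma, neuron.section_thickness_nm) - soma.radius_nm) / NM_PER_UM
        boundary_dists.append(dist_um)
        if lo - 1e-12 <= dist_um <= hi + 1e-12:
            diameters.append(2.0 * d.radius_nm / NM_PER_UM)
    if not diameters:
        nearest = sorted(boundary_dists)[:5]
        raise ValueError(
            f"no annotations {lo}-{hi} um from the soma boundary; "
            f"nearest boundary distances (um): {np.round(nearest, 3).tolist()}"
        )
    return float(np.median(diameters))


def catmull_rom_closed(
    points: np.ndarray,
    samples_per_segment: int = 20,
    alpha: float = 0.5,
) -> np.ndarray:
    """Sample a closed Catmull-Rom spline through ``points``.

    Centripetal parameterization (alpha = 0.5) avoids cusps and self
    intersections for convex-ish control polygons.  Returns the sampled
    polygon, one point per sample, segment endpoints not duplicated.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("closed spline needs >= 3 control points")
    if samples_per_segment < 1:
        raise ValueError("samples_per_segment must be >= 1")
    out = []
    for i in range(n):
        p0 = pts[(i - 1) % n]
        p1 = pts[i]
        p2 = pts[(i + 1) % n]
        p3 = pts[(i + 2) % n]
        out.append(_catmull_rom_segment(p0, p1, p2, p3, samples_per_segment, alpha))
    return np.vstack(out)


def _knot(t0: float, pa: np.ndarray, pb: np.ndarray, alpha: float) -> float:
    d = np.linalg.norm(pb - pa)
    return t0 + max(d, 1e-9) ** alpha


def _catmull_rom_segment(p0, p1, p2, p3, n_samples: int, alpha: float) -> np.ndarray:
    # Barry-Goldman recursive evaluation between p1 and p2
    t0 = 0.0
    t1 = _knot(t0, p0, p1, alpha)
    t2 = _knot(t1, p1, p2, alpha)
    t3 = _knot(t2, p2, p3, alpha)
    t = np.linspace(t1, t2, n_samples, endpoint=False)[:, None]
    a1 = (t1 - t) / (t1 - t0) * p0 + (t - t0) / (t1 - t0) * p1
    a2 = (t2 - t) / (t2 - t1) * p1 + (t - t1) / (t2 - t1) * p2
    a3 = (t3 - t) / (t3 - t2) * p2 + (t - t2) / (t3 - t2) * p3
    b1 = (t2 - t) / (t2 - t0) * a1 + (t - t0) / (t2 - t0) * a2
    b2 = (t3 - t) / (t3 - t1) * a2 + (t - t1) / (t3 - t1) * a3
    return (t2 - t) / (t2 - t1) * b1 + (t - t1) / (t2 - t1) * b2


def shoelace_area(polygon: np.ndarray) -> float:
    """Absolute enclosed area of a closed polygon given as (n, 2) vertices."""
    x, y = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def pedicle_area(curve: ClosedCurveAnnotation, samples_per_segment: int = 20) -> float:
    """Enclosed area of a pedicle outline, in um^2.

    The control points are joined by a closed centripetal Catmull-Rom
    spline, densely sampled, checked for self-intersection, and the
    enclosed area computed with the shoelace formula.
    """
    poly = catmull_rom_closed(curve.control_points_nm, samples_per_segment)
    shp = Polygon(poly)
    if not shp.is_valid:
        raise ValueError(f"sampled pedicle outline self-intersects: {explain_validity(shp)}")
    return shoelace_area(poly) / NM_PER_UM**2


def count_ribbon_synapses(neuron: NeuronAnnotation, partner_id: int) -> int:
    """Number of ribbon synapses between this neuron and a partner neuron."""
    known = {s.pre_neuron for s in neuron.synapse_links} | {
        s.post_neuron for s in neuron.synapse_links
    }
    if partner_id not in known:
        raise KeyError(f"no synapse links involve partner neuron {partner_id}")
    return sum(
        1
        for s in neuron.synapse_links
        if s.kind == "ribbon" and partner_id in (s.pre_neuron, s.post_neuron)
    )
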