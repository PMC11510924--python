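"""2D shoulder-analog tissue phantom.

A phantom is an ordered stack of analytic tissue regions (disk, annulus,
ellipse, polygon) immersed in a lossy matching medium that fills a circular
sensing chamber.  Each region carries a complex relative permittivity
``eps = eps_real - 1j * eps_imag`` (time convention ``e^{+i omega t}``, so the
loss term is stored positive).  The whole body can be perturbed by a rigid
in-plane transform (dx, dz, rotation about a pivot) and by signed
"dehydration" fractions that scale tissue permittivities componentwise.

Coordinates are Cartesian ``(x, z)`` in centimetres with the chamber centre
at the origin; angles are counterclockwise-positive degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComplexPermittivity",
    "TissueRegion",
    "RigidTransform",
    "Phantom",
    "GeometryConfig",
    "BASE_TISSUES",
    "SF_BASELINES",
    "MATCHING_MEDIUM",
    "MAX_HDERR",
    "tissue_permittivity",
    "build_phantom",
    "permittivity_at",
    "rasterize",
]

MAX_HDERR = 0.2  # |hderr| beyond the studied +/-9% range (with headroom)


@dataclass(frozen=True)
class ComplexPermittivity:
    """Relative permittivity ``eps_real - 1j * eps_imag`` with ``eps_imag >= 0``."""

    eps_real: float
    eps_imag: float

    def __post_init__(self) -> None:
        if self.eps_real <= 0:
            raise ValueError(f"eps_real must be > 0, got {self.eps_real}")
        if self.eps_imag < 0:
            raise ValueError(f"eps_imag must be >= 0, got {self.eps_imag}")

    @property
    def value(self) -> complex:
        return complex(self.eps_real, -self.eps_imag)

    def scaled(self, factor: float) -> "ComplexPermittivity":
        return ComplexPermittivity(self.eps_real * factor, self.eps_imag * factor)


# Complex dielectric properties at 1 GHz (relative permittivity, loss term).
BASE_TISSUES: dict[str, ComplexPermittivity] = {
    "bone": ComplexPermittivity(12.4, 2.79),
    "tendon": ComplexPermittivity(45.6, 13.66),
    "muscle": ComplexPermittivity(54.8, 17.43),
    "skin": ComplexPermittivity(40.9, 16.17),
    "synovial_fluid": ComplexPermittivity(68.42, 29.12),
}

# Two synovial-fluid baselines circulate in the source material: the nominal
# table value and a rounded one used in the dehydration sweep.  Scenario
# configs must state which one they perturb.
SF_BASELINES: dict[str, ComplexPermittivity] = {
    "nominal": ComplexPermittivity(68.42, 29.12),
    "rounded": ComplexPermittivity(68.0, 29.0),
}

# The matching medium is pinned to the unperturbed muscle value for every
# simulation; dehydration never touches it.
MATCHING_MEDIUM = BASE_TISSUES["muscle"]


def tissue_permittivity(
    tissue: str, hderr: float = 0.0, *, sf_baseline: str = "nominal"
) -> ComplexPermittivity:
    """Permittivity of ``tissue`` with a signed dehydration fraction applied.

    Both the real part and the loss term are multiplied by ``(1 + hderr)``.

    Parameters
    ----------
    tissue:
        One of ``bone, tendon, muscle, skin, synovial_fluid, matching_medium``.
    hderr:
        Signed fraction, ``|hderr| <= 0.2``.
    sf_baseline:
        Which synovial-fluid baseline to perturb (``"nominal"`` 68.42-29.12i
        or ``"rounded"`` 68.0-29.0i).
    """
    if abs(hderr) > MAX_HDERR:
        raise ValueError(
            f"|hderr| = {abs(hderr)} exceeds the studied range {MAX_HDERR}"
        )
    if tissue == "matching_medium":
        base = MATCHING_MEDIUM
    elif tissue == "synovial_fluid":
        try:
            base = SF_BASELINES[sf_baseline]
        except KeyError:
            raise ValueError(
                f"unknown sf_baseline {sf_baseline!r}; choose from "
                f"{sorted(SF_BASELINES)}"
            ) from None
    else:
        try:
            base = BASE_TISSUES[tissue]
        except KeyError:
            raise ValueError(
                f"unknown tissue {tissue!r}; choose from "
                f"{sorted(BASE_TISSUES) + ['matching_medium']}"
            ) from None
    return base.scaled(1.0 + hderr)


# ---------------------------------------------------------------------------
# shapes


@dataclass(frozen=True)
class Disk:
    center: tuple[float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return (d * d).sum(axis=-1) <= self.radius**2


@dataclass(frozen=True)
class Annulus:
    center: tuple[float, float]
    r_inner: float
    r_outer: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        r2 = (d * d).sum(axis=-1)
        return (r2 >= self.r_inner**2) & (r2 <= self.r_outer**2)


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_x: float
    semi_z: float
    angle_deg: float = 0.0

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        t = math.radians(self.angle_deg)
        c, s = math.cos(t), math.sin(t)
        u = d[..., 0] * c + d[..., 1] * s
        v = -d[..., 0] * s + d[..., 1] * c
        return (u / self.semi_x) ** 2 + (v / self.semi_z) ** 2 <= 1.0


@dataclass(frozen=True)
class Polygon:
    vertices: tuple[tuple[float, float], ...]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        # even-odd ray casting, vectorized over pts
        p = np.atleast_2d(pts)
        v = np.asarray(self.vertices)
        inside = np.zeros(len(p), dtype=bool)
        x, z = p[:, 0], p[:, 1]
        n = len(v)
        for i in range(n):
            x1, z1 = v[i]
            x2, z2 = v[(i + 1) % n]
            crosses = (z1 > z) != (z2 > z)
            with np.errstate(divide="ignore", invalid="ignore"):
                xin = x1 + (z - z1) * (x2 - x1) / (z2 - z1)
            inside ^= crosses & (x < xin)
        return inside.reshape(np.shape(pts)[:-1])


Shape = Disk | Annulus | Ellipse | Polygon


@dataclass(frozen=True)
class TissueRegion:
    name: str
    shape: Shape
    permittivity: ComplexPermittivity
    precedence: int

    @property
    def center(self) -> tuple[float, float]:
        if isinstance(self.shape, Polygon):
            v = np.asarray(self.shape.vertices)
            return tuple(v.mean(axis=0))
        return self.shape.center


# ---------------------------------------------------------------------------
# rigid transform


@dataclass(frozen=True)
class RigidTransform:
    """In-plane rigid motion: rotate by ``theta`` (deg, CCW) about ``pivot``,
    then translate by ``(dx, dz)`` cm."""

    dx: float = 0.0
    dz: float = 0.0
    theta: float = 0.0
    pivot: tuple[float, float] = (0.0, 0.0)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, dtype=float)
        t = math.radians(self.theta)
        c, s = math.cos(t), math.sin(t)
        piv = np.asarray(self.pivot)
        d = p - piv
        out = np.empty_like(d)
        out[..., 0] = c * d[..., 0] - s * d[..., 1]
        out[..., 1] = s * d[..., 0] + c * d[..., 1]
        return out + piv + np.asarray([self.dx, self.dz])

    def inverse_apply(self, pts: np.ndarray) -> np.ndarray:
        p = np.asarray(pts, dtype=float) - np.asarray([self.dx, self.dz])
        t = math.radians(self.theta)
        c, s = math.cos(t), math.sin(t)
        piv = np.asarray(self.pivot)
        d = p - piv
        out = np.empty_like(d)
        out[..., 0] = c * d[..., 0] + s * d[..., 1]
        out[..., 1] = -s * d[..., 0] + c * d[..., 1]
        return out + piv

    def inverse(self) -> "RigidTransform":
        # pivot-form inverse: rotate by -theta about (pivot + shift)
        px, pz = self.pivot
        return RigidTransform(
            dx=-self.dx, dz=-self.dz, theta=-self.theta,
            pivot=(px + self.dx, pz + self.dz),
        )

    @property
    def is_identity(self) -> bool:
        return self.dx == 0.0 and self.dz == 0.0 and self.theta == 0.0


IDENTITY = RigidTransform()


# ---------------------------------------------------------------------------
# geometry configuration and phantom assembly


@dataclass(frozen=True)
class GeometryConfig:
    """Default 2D analog geometry (all lengths in cm).

    The body outline is an ellipse kept small enough that the largest studied
    offsets (|shift| up to 4.5 cm plus rotation) stay inside the 24 cm
    chamber.  The joint complex (bone + tendon band + injury) sits off-centre,
    mirroring the near-surface location of the real joint.
    """

    chamber_radius: float = 12.0
    body_center: tuple[float, float] = (0.0, 0.0)
    body_semi_x: float = 7.0
    body_semi_z: float = 5.5
    skin_thickness: float = 0.2
    bone_center: tuple[float, float] = (3.5, 0.0)
    bone_radius: float = 1.6
    tendon_width: float = 1.0
    injury_center: tuple[float, float] = (5.5, 0.0)
    injury_semi_x: float = 1.0
    injury_semi_z: float = 0.5
    injury_angle_deg: float = 0.0


DEFAULT_GEOMETRY = GeometryConfig()


@dataclass(frozen=True)
class Phantom:
    regions: tuple[TissueRegion, ...]
    transform: RigidTransform
    injured: bool
    hderr_muscle: float
    hderr_sf: float
    chamber_radius: float
    sf_baseline: str = "nominal"

    def key(self) -> tuple:
        """Hashable content key (used for forward-solve caching)."""
        return (
            self.injured,
            round(self.hderr_muscle, 12),
            round(self.hderr_sf, 12),
            self.sf_baseline,
            round(self.transform.dx, 12),
            round(self.transform.dz, 12),
            round(self.transform.theta, 12),
            tuple(round(v, 12) for v in self.transform.pivot),
            self.chamber_radius,
            tuple(
                (r.name, repr(r.shape), r.permittivity.eps_real, r.permittivity.eps_imag)
                for r in self.regions
            ),
        )


def build_phantom(
    geometry: GeometryConfig = DEFAULT_GEOMETRY,
    *,
    injured: bool,
    hderr_muscle: float = 0.0,
    hderr_sf: float = 0.0,
    transform: RigidTransform = IDENTITY,
    sf_baseline: str = "nominal",
    injury_override: ComplexPermittivity | None = None,
) -> Phantom:
    """Assemble the layered phantom.

    In the healthy phantom the injury ellipse is filled with muscle at the
    same ``hderr_muscle`` as the surrounding muscle, so there is no hidden
    contrast.  The matching medium always keeps the unperturbed muscle value.
    """
    g = geometry
    hm = hderr_muscle
    skin = tissue_permittivity("skin", hm)
    muscle = tissue_permittivity("muscle", hm)
    tendon = tissue_permittivity("tendon", hm)
    bone = tissue_permittivity("bone", hm)
    if injury_override is not None:
        # explicit fill (e.g. the zero-contrast limit where the "injury" is
        # assigned the muscle value on purpose)
        injury = injury_override
        injury_name = "synovial_fluid" if injured else "muscle"
    elif injured:
        injury = tissue_permittivity("synovial_fluid", hderr_sf, sf_baseline=sf_baseline)
        injury_name = "synovial_fluid"
    else:
        injury = muscle
        injury_name = "muscle"

    body = Ellipse(g.body_center, g.body_semi_x, g.body_semi_z)
    inner = Ellipse(
        g.body_center,
        g.body_semi_x - g.skin_thickness,
        g.body_semi_z - g.skin_thickness,
    )
    regions = (
        TissueRegion("skin", body, skin, 1),
        TissueRegion("muscle", inner, muscle, 2),
        TissueRegion(
            "tendon",
            Annulus(g.bone_center, g.bone_radius, g.bone_radius + g.tendon_width),
            tendon,
            3,
        ),
        TissueRegion("bone", Disk(g.bone_center, g.bone_radius), bone, 4),
        TissueRegion(
            injury_name,
            Ellipse(g.injury_center, g.injury_semi_x, g.injury_semi_z, g.injury_angle_deg),
            injury,
            5,
        ),
    )
    prec = [r.precedence for r in regions]
    if len(set(prec)) != len(prec):
        raise ValueError("region precedence values must be unique")

    # reject transforms that push any body-contour point out of the chamber
    ang = np.linspace(0.0, 2.0 * math.pi, 720, endpoint=False)
    contour = np.stack(
        [
            g.body_center[0] + g.body_semi_x * np.cos(ang),
            g.body_center[1] + g.body_semi_z * np.sin(ang),
        ],
        axis=1,
    )
    moved = transform.apply(contour)
    rmax = float(np.max(np.hypot(moved[:, 0], moved[:, 1])))
    if rmax >= g.chamber_radius:
        raise ValueError(
            f"transform moves the body contour to radius {rmax:.2f} cm, "
            f"outside the chamber interior (radius {g.chamber_radius} cm)"
        )

    return Phantom(
        regions=regions,
        transform=transform,
        injured=injured,
        hderr_muscle=hderr_muscle,
        hderr_sf=hderr_sf,
        chamber_radius=g.chamber_radius,
        sf_baseline=sf_baseline,
    )


def permittivity_values_at(phantom: Phantom, pts: np.ndarray) -> np.ndarray:
    """Vectorized complex permittivity lookup at an (n, 2) array of points.

    Points are pulled back through the body transform, then matched against
    the untransformed region stack in decreasing precedence order.
    """
    p = np.atleast_2d(np.asarray(pts, dtype=float))
    r = np.hypot(p[:, 0], p[:, 1])
    if np.any(r > phantom.chamber_radius * (1 + 1e-9)):
        raise ValueError("point outside the chamber")
    local = phantom.transform.inverse_apply(p)
    out = np.full(len(p), MATCHING_MEDIUM.value, dtype=complex)
    undecided = np.ones(len(p), dtype=bool)
    for region in sorted(phantom.regions, key=lambda r: -r.precedence):
        if not undecided.any():
            break
        hit = undecided & region.shape.contains(local)
        out[hit] = region.permittivity.value
        undecided &= ~hit
    return out


def permittivity_at(phantom: Phantom, point) -> ComplexPermittivity:
    """Permittivity of the highest-precedence region containing ``point``."""
    val = permittivity_values_at(phantom, np.asarray(point, dtype=float))[0]
    return ComplexPermittivity(val.real, -val.imag)


def rasterize(phantom: Phantom, n: int = 256) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raster permittivity map on an n x n grid covering the chamber.

    Returns ``(x, z, eps)`` where ``eps`` is complex with NaN outside the
    chamber disk.
    """
    R = phantom.chamber_radius
    x = np.linspace(-R, R, n)
    z = np.linspace(-R, R, n)
    X, Z = np.meshgrid(x, z)
    pts = np.stack([X.ravel(), Z.ravel()], axis=1)
    inside = np.hypot(pts[:, 0], pts[:, 1]) <= R
    eps = np.full(len(pts), np.nan + 0j, dtype=complex)
    if inside.any():
        eps[inside] = permittivity_values_at(phantom, pts[inside])
    return x, z, eps.reshape(n, n)
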