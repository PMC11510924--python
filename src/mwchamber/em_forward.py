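"""Time-harmonic 2D forward solver for the multi-port sensing chamber.

Scalar TMz reduction of the chamber boundary-value problem: the out-of-plane
electric field ``u`` satisfies ``-div(grad u) - k0^2 eps_r(x) u = 0`` inside
the chamber disk, with

* homogeneous Dirichlet on metallic wall segments (PEC),
* a port condition ``du/dn + i beta u = g`` on waveguide apertures, where the
  excitation of the transmitting aperture is ``g = 2 i beta m(s)`` and
  ``m`` is the half-sine aperture mode (the 2D stand-in for TE10),
* optionally a first-order absorbing condition on open arcs.

Time convention is ``e^{+i omega t}`` with ``eps_r = eps' - i eps''``
(``eps'' >= 0``), so waves decay in lossy media.

Scattering entries are mode overlaps of each solution's trace on every
aperture; the transmitting diagonal subtracts the unit incident amplitude.
The discrete system is symmetric (not Hermitian), which makes the
non-conjugated S-matrix reciprocal to solver tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu
from scipy.spatial import Delaunay

from .phantom import Phantom, MATCHING_MEDIUM, permittivity_values_at

__all__ = [
    "C0_M",
    "C0_CM",
    "PortSpec",
    "Mesh",
    "FieldSolution",
    "SMatrix",
    "wavelength",
    "waveguide_mode",
    "ring_ports",
    "generate_mesh",
    "assemble_and_solve",
    "compute_smatrix",
    "solve_scattered_planewave",
    "ChamberModel",
    "WALL",
    "OPEN",
]

C0_M = 299_792_458.0          # m/s
C0_CM = C0_M * 100.0          # cm/s

WALL = -1   # boundary-edge tag: metallic wall (Dirichlet)
OPEN = -2   # boundary-edge tag: absorbing arc


def wavelength(eps_real: float, frequency: float) -> float:
    """Wavelength in cm of a medium with real permittivity ``eps_real``."""
    if eps_real <= 0 or frequency <= 0:
        raise ValueError("eps_real and frequency must be positive")
    return C0_CM / (frequency * math.sqrt(eps_real))


def waveguide_mode(width_cm: float, eps_load: float, frequency: float) -> tuple[float, float]:
    """Dominant-mode propagation constant of a loaded rectangular guide.

    Returns ``(beta, cutoff)`` with ``beta`` in rad/m and ``cutoff`` in Hz.
    Raises if the mode is evanescent at ``frequency``.
    """
    if width_cm <= 0:
        raise ValueError("width must be positive")
    if eps_load < 1:
        raise ValueError("eps_load must be >= 1")
    a = width_cm / 100.0
    cutoff = C0_M / (2.0 * a * math.sqrt(eps_load))
    if frequency <= cutoff:
        raise ValueError(
            f"mode evanescent: f = {frequency:.4g} Hz is at or below the "
            f"cutoff {cutoff:.4g} Hz"
        )
    k0 = 2.0 * math.pi * frequency / C0_M
    beta = math.sqrt(eps_load * k0**2 - (math.pi / a) ** 2)
    return beta, cutoff


@dataclass(frozen=True)
class PortSpec:
    """Aperture arc on the chamber wall with a half-sine mode profile."""

    index: int
    start_angle: float   # radians, CCW from +x
    end_angle: float     # radians; end > start
    radius: float        # chamber radius, cm
    beta: float          # propagation constant, rad/m

    @property
    def width(self) -> float:
        """Aperture arc length in cm."""
        return (self.end_angle - self.start_angle) * self.radius

    @property
    def beta_cm(self) -> float:
        return self.beta / 100.0

    def mode(self, angles: np.ndarray) -> np.ndarray:
        """Half-sine profile evaluated at boundary angles (0 at the ends)."""
        t = (np.asarray(angles) - self.start_angle) / (self.end_angle - self.start_angle)
        out = np.sin(math.pi * np.clip(t, 0.0, 1.0))
        out[(t < 0) | (t > 1)] = 0.0
        return out


def ring_ports(
    n_ports: int,
    radius: float,
    *,
    width: float = 2.1,
    eps_load: float = 59.0,
    frequency: float = 1e9,
    start_angle: float = 0.0,
) -> list[PortSpec]:
    """``n_ports`` equal apertures evenly spaced on the chamber wall."""
    if n_ports < 1:
        raise ValueError("need at least one port")
    if n_ports * width >= 2.0 * math.pi * radius:
        raise ValueError(
            f"{n_ports} apertures of width {width} cm do not fit on a "
            f"chamber of radius {radius} cm"
        )
    beta, _ = waveguide_mode(width, eps_load, frequency)
    half = width / (2.0 * radius)
    ports = []
    for i in range(n_ports):
        c = start_angle + 2.0 * math.pi * i / n_ports
        ports.append(PortSpec(i, c - half, c + half, radius, beta))
    return ports


# ---------------------------------------------------------------------------
# mesh


@dataclass
class Mesh:
    nodes: np.ndarray            # (n, 2) cm
    triangles: np.ndarray        # (m, 3) int
    boundary_edges: np.ndarray   # (e, 2) int, consecutive along the circle
    edge_tags: np.ndarray        # (e,) int: WALL, OPEN or port index
    h: float                     # target max cell diameter, cm
    chamber_radius: float
    _tri_finder: Delaunay | None = field(default=None, repr=False)
    _p1_cache: dict | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def max_cell_diameter(self) -> float:
        t = self.nodes[self.triangles]
        e = np.concatenate([
            t[:, 1] - t[:, 0], t[:, 2] - t[:, 1], t[:, 0] - t[:, 2],
        ])
        return float(np.max(np.hypot(e[:, 0], e[:, 1])))

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def interpolate(self, dof: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """P1 interpolation of a nodal field at arbitrary interior points."""
        if self._tri_finder is None:
            raise RuntimeError("mesh has no point locator")
        p = np.atleast_2d(pts)
        simp = self._tri_finder.find_simplex(p)
        if np.any(simp < 0):
            raise ValueError("point outside the mesh")
        trans = self._tri_finder.transform[simp]
        bary2 = np.einsum("ijk,ik->ij", trans[:, :2], p - trans[:, 2])
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        verts = self._tri_finder.simplices[simp]
        return np.einsum("ij,ij->i", dof[verts], bary)

    def save_text(self, path) -> None:
        """Plain-text node/triangle/edge dump."""
        with open(path, "w") as f:
            f.write(f"# mwchamber mesh h={self.h} R={self.chamber_radius}\n")
            f.write(f"{len(self.nodes)} {len(self.triangles)} {len(self.boundary_edges)}\n")
            for x, z in self.nodes:
                f.write(f"{x:.12g} {z:.12g}\n")
            for a, b, c in self.triangles:
                f.write(f"{a} {b} {c}\n")
            for (a, b), t in zip(self.boundary_edges, self.edge_tags):
                f.write(f"{a} {b} {t}\n")


def _boundary_layout(
    radius: float,
    ports: list[PortSpec],
    spacing: float,
    open_arcs: list[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Angles of boundary nodes and the tag of each consecutive edge.

    Aperture endpoints land exactly on nodes so aperture widths are exact.
    """
    two_pi = 2.0 * math.pi
    segs: list[tuple[float, float, int]] = []
    for p in ports:
        segs.append((p.start_angle % two_pi, p.end_angle - p.start_angle, p.index))
    for a0, a1 in open_arcs:
        segs.append((a0 % two_pi, a1 - a0, OPEN))
    segs.sort()
    # measure angles from the first arc start so that no aperture straddles
    # the coordinate seam; every port then gets an identical node layout and
    # the discrete mode norms match exactly (reciprocity at solver tolerance)
    shift = segs[0][0] if segs else 0.0
    segs = [(a0 - shift, w, tag) for a0, w, tag in segs]
    # fill gaps with wall segments
    full: list[tuple[float, float, int]] = []
    cursor = 0.0
    for a0, width, tag in segs:
        if a0 < cursor - 1e-12:
            raise ValueError("overlapping boundary arcs (apertures must be disjoint)")
        if a0 > cursor + 1e-12:
            full.append((cursor, a0 - cursor, WALL))
        full.append((a0, width, tag))
        cursor = a0 + width
    if cursor > two_pi + 1e-12:
        raise ValueError("overlapping boundary arcs (apertures must be disjoint)")
    if cursor < two_pi - 1e-12:
        full.append((cursor, two_pi - cursor, WALL))
    full = [(a0 + shift, w, tag) for a0, w, tag in full]

    angles: list[float] = []
    tags: list[int] = []
    d_ang = spacing / radius
    port_cells: dict[int, int] = {}
    for a0, width, tag in full:
        n = max(1, int(round(width / d_ang)))
        for k in range(n):
            angles.append(a0 + width * k / n)
            tags.append(tag)
        if tag >= 0:
            port_cells[tag] = port_cells.get(tag, 0) + n
    for p in ports:
        if port_cells.get(p.index, 0) < 3:
            raise ValueError(
                "mesh too coarse: fewer than 3 boundary cells per aperture"
            )
    return np.asarray(angles), np.asarray(tags, dtype=int)


def generate_mesh(
    phantom_or_radius,
    ports: list[PortSpec] | None = None,
    h: float = 0.45,
    *,
    open_arcs: list[tuple[float, float]] | None = None,
    open_all: bool = False,
) -> Mesh:
    """Unstructured triangular mesh of the chamber disk.

    Boundary nodes follow the aperture layout; interior nodes sit on
    concentric rings with a small deterministic jitter (degeneracy guard).
    The resulting maximum cell diameter is verified against ``1.1 h``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    if isinstance(phantom_or_radius, Phantom):
        radius = phantom_or_radius.chamber_radius
    else:
        radius = float(phantom_or_radius)
    ports = list(ports or [])
    if open_all:
        if ports:
            raise ValueError("open_all is only for port-free validation meshes")
        open_arcs = [(0.0, 2.0 * math.pi)]
    open_arcs = list(open_arcs or [])

    spacing = 0.66 * h
    b_ang, edge_tags = _boundary_layout(radius, ports, spacing, open_arcs)
    b_nodes = radius * np.stack([np.cos(b_ang), np.sin(b_ang)], axis=1)

    pts = [b_nodes]
    k = 1
    idx = 0
    while True:
        r = radius - spacing * k
        if r < 0.55 * spacing:
            break
        m = max(6, int(round(2.0 * math.pi * r / spacing)))
        off = 0.5 * (k % 2) * 2.0 * math.pi / m
        ang = off + 2.0 * math.pi * np.arange(m) / m
        # deterministic jitter kills collinear ring runs that would give
        # zero-area Delaunay triangles
        jit = 0.03 * spacing * np.sin(12.9898 * (idx + np.arange(m)) + 78.233 * k)
        rr = r + jit
        pts.append(np.stack([rr * np.cos(ang), rr * np.sin(ang)], axis=1))
        idx += m
        k += 1
    pts.append(np.zeros((1, 2)))
    nodes = np.concatenate(pts, axis=0)

    tri = Delaunay(nodes)
    # drop degenerate triangles (none expected with the jitter)
    p = nodes[tri.simplices]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    if np.any(area < 1e-12 * spacing**2):
        raise RuntimeError("degenerate triangles in generated mesh")

    nb = len(b_nodes)
    edges = np.stack([np.arange(nb), (np.arange(nb) + 1) % nb], axis=1)

    mesh = Mesh(
        nodes=nodes,
        triangles=tri.simplices.copy(),
        boundary_edges=edges,
        edge_tags=edge_tags,
        h=h,
        chamber_radius=radius,
        _tri_finder=tri,
    )
    dmax = mesh.max_cell_diameter()
    if dmax > 1.1 * h:
        raise RuntimeError(
            f"mesh quality failure: max cell diameter {dmax:.3g} > 1.1 h"
        )
    return mesh


# ---------------------------------------------------------------------------
# P1 assembly


def _p1_structures(mesh: Mesh) -> dict:
    """Per-triangle stiffness/mass values and global COO index arrays."""
    if mesh._p1_cache is not None:
        return mesh._p1_cache
    t = mesh.triangles
    p = mesh.nodes[t]
    x, z = p[..., 0], p[..., 1]
    b = np.stack([z[:, 1] - z[:, 2], z[:, 2] - z[:, 0], z[:, 0] - z[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
    area = np.abs(0.5 * (x[:, 0] * (z[:, 1] - z[:, 2]) + x[:, 1] * (z[:, 2] - z[:, 0])
                         + x[:, 2] * (z[:, 0] - z[:, 1])))
    K = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (4.0 * area)[:, None, None]
    Mref = (np.ones((3, 3)) + np.eye(3)) / 12.0
    M = area[:, None, None] * Mref[None, :, :]
    rows = np.repeat(t, 3, axis=1).reshape(-1)
    cols = np.tile(t, (1, 3)).reshape(-1)
    cache = {
        "area": area,
        "K_flat": K.reshape(len(t), 9),
        "M_flat": M.reshape(len(t), 9),
        "rows": rows,
        "cols": cols,
    }
    mesh._p1_cache = cache
    return cache


def _edge_mass(mesh: Mesh, edge_sel: np.ndarray) -> sp.csr_matrix:
    """Boundary mass matrix over the selected boundary edges."""
    n = mesh.n_nodes
    e = mesh.boundary_edges[edge_sel]
    p0, p1 = mesh.nodes[e[:, 0]], mesh.nodes[e[:, 1]]
    L = np.hypot(*(p1 - p0).T)
    vals = np.stack([L / 3, L / 6, L / 6, L / 3], axis=1).reshape(-1)
    rows = np.stack([e[:, 0], e[:, 0], e[:, 1], e[:, 1]], axis=1).reshape(-1)
    cols = np.stack([e[:, 0], e[:, 1], e[:, 0], e[:, 1]], axis=1).reshape(-1)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _port_vectors(mesh: Mesh, ports: list[PortSpec]) -> list[dict]:
    """Per-port mode data: nodal mode, edge-mass-weighted mode, mode norm."""
    node_angle = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0]) % (2 * math.pi)
    out = []
    for p in ports:
        sel = mesh.edge_tags == p.index
        if not sel.any():
            raise ValueError(f"port {p.index} has no boundary edges in the mesh")
        B = _edge_mass(mesh, sel)
        nodes = np.unique(mesh.boundary_edges[sel])
        m = np.zeros(mesh.n_nodes)
        ang = node_angle[nodes]
        # unwrap across the 0/2pi seam relative to the port start
        rel = (ang - p.start_angle % (2 * math.pi)) % (2 * math.pi)
        m[nodes] = np.sin(math.pi * np.clip(rel / (p.end_angle - p.start_angle), 0, 1))
        w = B @ m
        out.append({"B": B, "m": m, "w": w, "norm": float(m @ w)})
    return out


# degree-balanced interior points used to volume-average the coefficient on
# each triangle; plain centroid sampling staircases the tissue interfaces
_BARY6 = np.array(
    [
        [2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3],
        [0.6, 0.2, 0.2], [0.2, 0.6, 0.2], [0.2, 0.2, 0.6],
    ]
)


def permittivity_on_mesh(mesh: Mesh, phantom: Phantom | None) -> np.ndarray:
    """Per-triangle complex permittivity, volume-averaged over 6 points."""
    if phantom is None:
        return np.full(len(mesh.triangles), MATCHING_MEDIUM.value, dtype=complex)
    t = mesh.nodes[mesh.triangles]
    acc = np.zeros(len(t), dtype=complex)
    for b in _BARY6:
        pts = np.einsum("k,mkd->md", b, t)
        acc += permittivity_values_at(phantom, pts)
    return acc / len(_BARY6)


@dataclass
class FieldSolution:
    transmitting_port: int
    dof_values: np.ndarray
    residual: float


def _chamber_system(
    mesh: Mesh,
    eps_tri: np.ndarray,
    ports: list[PortSpec],
    frequency: float,
    *,
    port_bc: str = "modal",
    open_eps: complex | None = None,
    _reciprocity_bug: float = 0.0,
):
    """Assemble the chamber system matrix; returns (A_csc, port data, dirichlet mask)."""
    s = _p1_structures(mesh)
    k0 = 2.0 * math.pi * frequency / C0_CM  # rad/cm
    coef = (k0**2) * eps_tri
    vals = s["K_flat"].astype(complex) - coef[:, None] * s["M_flat"]
    A = sp.coo_matrix(
        (vals.reshape(-1), (s["rows"], s["cols"])),
        shape=(mesh.n_nodes, mesh.n_nodes),
    ).tocsr()

    pdata = _port_vectors(mesh, ports)
    for p, d in zip(ports, pdata):
        jb = 1j * p.beta_cm
        if port_bc == "modal":
            w = d["w"]
            nz = np.nonzero(w)[0]
            W = sp.coo_matrix(
                (np.outer(w[nz], w[nz]).reshape(-1) / d["norm"],
                 (np.repeat(nz, len(nz)), np.tile(nz, len(nz)))),
                shape=A.shape,
            ).tocsr()
            A = A + jb * W
        elif port_bc == "robin":
            A = A + jb * d["B"]
        else:
            raise ValueError(f"unknown port_bc {port_bc!r}")

    open_sel = mesh.edge_tags == OPEN
    if open_sel.any():
        if open_eps is None:
            open_eps = MATCHING_MEDIUM.value
        k_open = k0 * np.sqrt(complex(open_eps))
        if k_open.imag > 0:
            k_open = -k_open  # decaying branch under e^{+i omega t}
        Bo = _edge_mass(mesh, open_sel)
        A = A + (1j * k_open + 0.5 / mesh.chamber_radius) * Bo

    if _reciprocity_bug:
        # deliberate asymmetric perturbation used by the mutation-test
        # harness; targets interior nodes so Dirichlet elimination cannot
        # silently remove it (the centre node is always interior)
        n = mesh.n_nodes
        A = A + sp.coo_matrix(
            ([_reciprocity_bug, -_reciprocity_bug],
             ([n - 1, n - 2], [n - 2, n - 1])),
            shape=(n, n),
        ).tocsr()

    # Dirichlet on every node touching a metallic wall edge
    wall_nodes = np.unique(mesh.boundary_edges[mesh.edge_tags == WALL])
    dir_mask = np.zeros(mesh.n_nodes, dtype=bool)
    dir_mask[wall_nodes] = True
    if dir_mask.any():
        keep = sp.diags((~dir_mask).astype(float))
        A = keep @ A @ keep + sp.diags(dir_mask.astype(float))
    return A.tocsc(), pdata, dir_mask


def assemble_and_solve(
    mesh: Mesh,
    phantom: Phantom | None,
    ports: list[PortSpec],
    frequency: float,
    *,
    port_bc: str = "modal",
    _reciprocity_bug: float = 0.0,
) -> list[FieldSolution]:
    """Solve the chamber problem once per transmitting port.

    ``phantom=None`` means the chamber holds only matching medium (the
    "empty" reference).  A single sparse LU factorization is reused for all
    right-hand sides.
    """
    if not ports:
        raise ValueError("at least one port is required")
    eps_tri = permittivity_on_mesh(mesh, phantom)
    A, pdata, dir_mask = _chamber_system(
        mesh, eps_tri, ports, frequency,
        port_bc=port_bc, _reciprocity_bug=_reciprocity_bug,
    )
    try:
        lu = splu(A)
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"singular chamber system: {exc}") from exc

    sols = []
    for p, d in zip(ports, pdata):
        b = 2j * p.beta_cm * d["w"].astype(complex)
        b[dir_mask] = 0.0
        u = lu.solve(b)
        res = float(np.linalg.norm(A @ u - b) / np.linalg.norm(b))
        if not np.isfinite(u).all() or res > 1e-8:
            raise RuntimeError(
                f"ill-conditioned solve for port {p.index}: residual {res:.3g}"
            )
        sols.append(FieldSolution(p.index, u, res))
    return sols


@dataclass
class SMatrix:
    """N x N complex scattering matrix with port metadata."""

    entries: np.ndarray
    frequency: float
    kind: str = "full"   # full | empty | differential

    @property
    def n_ports(self) -> int:
        return self.entries.shape[0]

    def __sub__(self, other: "SMatrix") -> "SMatrix":
        if self.entries.shape != other.entries.shape:
            raise ValueError("port-count mismatch")
        if self.frequency != other.frequency:
            raise ValueError("frequency mismatch")
        return SMatrix(self.entries - other.entries, self.frequency, "differential")


def compute_smatrix(
    solutions: list[FieldSolution],
    ports: list[PortSpec],
    mesh: Mesh,
    *,
    conjugate: bool = False,
    frequency: float = 1e9,
) -> SMatrix:
    """Mode-overlap scattering matrix.

    ``S_ij`` is the overlap of solution ``j``'s aperture trace with port
    ``i``'s mode, normalized by the mode's own norm; the diagonal subtracts
    the unit incident amplitude (the energy-consistent form of the printed
    ``+1`` correction under this sign convention).  ``conjugate=True``
    conjugates the field in the overlap; this variant breaks reciprocity and
    exists for convention comparisons only.
    """
    if len(solutions) != len(ports):
        raise ValueError(
            f"{len(solutions)} solutions for {len(ports)} ports"
        )
    pdata = _port_vectors(mesh, ports)
    n = len(ports)
    S = np.empty((n, n), dtype=complex)
    for j, sol in enumerate(solutions):
        u = np.conj(sol.dof_values) if conjugate else sol.dof_values
        for i, d in enumerate(pdata):
            S[i, j] = (d["w"] @ u) / d["norm"]
    S -= np.eye(n)
    if not np.isfinite(S).all():
        raise RuntimeError("non-finite S-matrix entries")
    return SMatrix(S, frequency, "full")


def solve_scattered_planewave(
    mesh: Mesh,
    eps_tri: np.ndarray,
    eps_bg: complex,
    frequency: float,
    inc_angle: float = 0.0,
) -> np.ndarray:
    """Scattered-field FEM solve for plane-wave incidence (validation path).

    The mesh must have a fully absorbing boundary (``open_all=True``).  The
    incident field ``exp(-i k_bg d.r)`` is exact; the contrast source is
    ``k0^2 (eps - eps_bg) u_inc``.  Returns nodal scattered-field values.
    """
    if np.any(mesh.edge_tags != OPEN):
        raise ValueError("scattered-field solve needs a fully open boundary")
    s = _p1_structures(mesh)
    k0 = 2.0 * math.pi * frequency / C0_CM
    kbg = k0 * np.sqrt(complex(eps_bg))
    if kbg.imag > 0:
        kbg = -kbg
    vals = s["K_flat"].astype(complex) - (k0**2 * eps_tri)[:, None] * s["M_flat"]
    A = sp.coo_matrix(
        (vals.reshape(-1), (s["rows"], s["cols"])),
        shape=(mesh.n_nodes, mesh.n_nodes),
    ).tocsr()
    Bo = _edge_mass(mesh, np.ones(len(mesh.boundary_edges), dtype=bool))
    A = A + (1j * kbg + 0.5 / mesh.chamber_radius) * Bo

    d = np.array([math.cos(inc_angle), math.sin(inc_angle)])
    u_inc = np.exp(-1j * kbg * (mesh.nodes @ d))
    contrast = (k0**2) * (eps_tri - eps_bg)
    vals_rhs = contrast[:, None] * s["M_flat"]
    Mc = sp.coo_matrix(
        (vals_rhs.reshape(-1), (s["rows"], s["cols"])),
        shape=(mesh.n_nodes, mesh.n_nodes),
    ).tocsr()
    b = Mc @ u_inc
    u = splu(A.tocsc()).solve(b)
    if not np.isfinite(u).all():
        raise RuntimeError("non-finite scattered field")
    return u


class ChamberModel:
    """Mesh + port layout held fixed while phantoms vary.

    Re-using one mesh for the empty and loaded runs makes the differential
    S-matrix cancel discretization error exactly at zero contrast.
    """

    def __init__(
        self,
        chamber_radius: float = 12.0,
        n_ports: int = 16,
        frequency: float = 1e9,
        h: float | None = None,
        port_width: float = 2.1,
        eps_load: float = 59.0,
        port_bc: str = "modal",
    ):
        self.frequency = frequency
        self.port_bc = port_bc
        if h is None:
            h = wavelength(MATCHING_MEDIUM.eps_real, frequency) / 9.0
        self.h = h
        self.ports = ring_ports(
            n_ports, chamber_radius,
            width=port_width, eps_load=eps_load, frequency=frequency,
        )
        self.mesh = generate_mesh(chamber_radius, self.ports, h)

    @property
    def n_ports(self) -> int:
        return len(self.ports)

    def smatrix(self, phantom: Phantom | None) -> SMatrix:
        sols = assemble_and_solve(
            self.mesh, phantom, self.ports, self.frequency, port_bc=self.port_bc
        )
        S = compute_smatrix(sols, self.ports, self.mesh, frequency=self.frequency)
        S.kind = "full" if phantom is not None else "empty"
        return S
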