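"""Closed-form scattering references used to validate the FEM solver.

Partial-wave (Bessel/Hankel) series for a homogeneous dielectric cylinder in
a homogeneous (possibly lossy) background under TMz plane-wave incidence,
plus S-matrix power-balance checks.  Time convention ``e^{+i omega t}``:
outgoing waves are Hankel functions of the second kind and the incident
plane wave along direction ``d`` is ``exp(-i k d.r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import h2vp, hankel2, jv, jvp

from .em_forward import C0_CM, SMatrix

__all__ = [
    "CylinderProblem",
    "cylinder_coefficients",
    "cylinder_scattered_field",
    "cylinder_interior_field",
    "energy_balance",
]


@dataclass(frozen=True)
class CylinderProblem:
    """Plane wave hitting a homogeneous dielectric cylinder.

    ``series_order`` must exceed ``|k a|`` by a comfortable margin for the
    partial-wave series to converge.
    """

    radius: float                       # cm
    eps_inside: complex
    eps_outside: complex
    frequency: float                    # Hz
    inc_angle: float = 0.0              # propagation direction, radians
    series_order: int | None = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.series_order is not None:
            kmax = max(abs(self.k_out), abs(self.k_in))
            if self.series_order < math.ceil(kmax * self.radius) + 10:
                raise ValueError(
                    "series_order below ceil(|k| a) + 10; series may not converge"
                )

    @property
    def k_out(self) -> complex:
        k = 2 * math.pi * self.frequency / C0_CM * np.sqrt(complex(self.eps_outside))
        return -k if k.imag > 0 else k

    @property
    def k_in(self) -> complex:
        k = 2 * math.pi * self.frequency / C0_CM * np.sqrt(complex(self.eps_inside))
        return -k if k.imag > 0 else k

    @property
    def order(self) -> int:
        if self.series_order is not None:
            return self.series_order
        kmax = max(abs(self.k_out), abs(self.k_in))
        return math.ceil(kmax * self.radius) + 15


def cylinder_coefficients(problem: CylinderProblem) -> tuple[np.ndarray, np.ndarray]:
    """Scattered (a_n) and interior (b_n) partial-wave coefficients, n = 0..N.

    Obtained by enforcing continuity of the field and its radial derivative
    at the cylinder surface for each azimuthal order.
    """
    a = problem.radius
    k0, k1 = problem.k_out, problem.k_in
    N = problem.order
    n = np.arange(N + 1)
    J0, J0p = jv(n, k0 * a), jvp(n, k0 * a)
    J1, J1p = jv(n, k1 * a), jvp(n, k1 * a)
    H0, H0p = hankel2(n, k0 * a), h2vp(n, k0 * a)
    # [H0 -J1; k0 H0p -k1 J1p] [a_n b_n]^T = [-J0, -k0 J0p]^T
    det = H0 * (-k1 * J1p) - (-J1) * k0 * H0p
    if np.any(np.abs(det) < 1e-300):
        raise RuntimeError("degenerate partial-wave system")
    a_n = (-J0 * (-k1 * J1p) - (-J1) * (-k0 * J0p)) / det
    b_n = (H0 * (-k0 * J0p) - (-J0) * k0 * H0p) / det

    tail = np.max(np.abs(a_n[-3:])) if N >= 3 else np.inf
    if not np.isfinite(a_n).all() or tail > 1e-10 * max(1.0, np.abs(a_n).max()):
        raise RuntimeError(
            f"partial-wave series not converged at order {N}; tail {tail:.3g}"
        )
    return a_n, b_n


def _polar(problem: CylinderProblem, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.atleast_2d(np.asarray(points, dtype=float))
    rho = np.hypot(p[:, 0], p[:, 1])
    phi = np.arctan2(p[:, 1], p[:, 0]) - problem.inc_angle
    return rho, phi


def cylinder_scattered_field(problem: CylinderProblem, points: np.ndarray) -> np.ndarray:
    """Scattered field outside the cylinder at the given (n, 2) points."""
    rho, phi = _polar(problem, points)
    if np.any(rho < problem.radius * (1 - 1e-9)):
        raise ValueError("exterior evaluation requires points outside the cylinder")
    a_n, _ = cylinder_coefficients(problem)
    N = problem.order
    out = np.zeros(len(rho), dtype=complex)
    k0 = problem.k_out
    for n in range(N + 1):
        term = (-1j) ** n * a_n[n] * hankel2(n, k0 * rho)
        if n == 0:
            out += term
        else:
            out += term * 2.0 * np.cos(n * phi)
    return out


def cylinder_interior_field(problem: CylinderProblem, points: np.ndarray) -> np.ndarray:
    """Total field inside the cylinder at the given (n, 2) points."""
    rho, phi = _polar(problem, points)
    if np.any(rho > problem.radius * (1 + 1e-9)):
        raise ValueError("interior evaluation requires points inside the cylinder")
    _, b_n = cylinder_coefficients(problem)
    N = problem.order
    out = np.zeros(len(rho), dtype=complex)
    k1 = problem.k_in
    for n in range(N + 1):
        term = (-1j) ** n * b_n[n] * jv(n, k1 * rho)
        if n == 0:
            out += term
        else:
            out += term * 2.0 * np.cos(n * phi)
    return out


def cylinder_incident_field(problem: CylinderProblem, points: np.ndarray) -> np.ndarray:
    """Incident plane wave ``exp(-i k0 d.r)`` at the given points."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.array([math.cos(problem.inc_angle), math.sin(problem.inc_angle)])
    return np.exp(-1j * problem.k_out * (p @ d))


def cylinder_eps_on_mesh(mesh, problem: CylinderProblem) -> np.ndarray:
    """Per-triangle permittivity of the cylinder problem, volume-averaged
    with the same rule the chamber assembly uses (6 interior points)."""
    from .em_forward import _BARY6

    t = mesh.nodes[mesh.triangles]
    acc = np.zeros(len(t), dtype=complex)
    for b in _BARY6:
        pts = np.einsum("k,mkd->md", b, t)
        inside = np.hypot(pts[:, 0], pts[:, 1]) <= problem.radius
        acc += np.where(inside, complex(problem.eps_inside), complex(problem.eps_outside))
    return acc / len(_BARY6)


def energy_balance(smatrix: SMatrix) -> np.ndarray:
    """Per-column power sums ``sum_i |S_ij|^2`` of a full S-matrix."""
    if smatrix.kind != "full":
        raise ValueError("energy balance is defined for kind='full' matrices")
    return np.sum(np.abs(smatrix.entries) ** 2, axis=0)
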