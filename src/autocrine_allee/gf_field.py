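"""Reaction-diffusion solver for the secreted growth-factor field.

The concentration g on an N x N lattice obeys

    dg/dt = D * lap(g) + rho * c - delta * g

where c is the binary cell occupancy, with no-flux (reflecting) boundaries.
Discretization is explicit forward-time / central-space with mirror ghost
cells; ``advance_field`` sub-steps internally so any horizon can be
requested, while ``step_field`` exposes the raw single-step contract.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["GFField", "max_stable_dt", "step_field", "advance_field", "steady_state_field"]


@dataclass(frozen=True)
class GFField:
    """Growth-factor concentration grid with its physical parameters."""

    values: np.ndarray  # N x N, non-negative
    spacing: float      # site size d = L/N (cm)
    D: float            # diffusion coefficient (cm^2/s)
    rho: float          # production rate (1/s)
    delta: float        # decay rate (1/s)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square 2-D grid")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("field values must be finite and >= 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.D < 0 or self.rho < 0 or self.delta < 0:
            raise ValueError("D, rho, delta must be >= 0")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def max_stable_dt(D: float, spacing: float) -> float:
    """Largest explicit-scheme step: spacing^2 / (4*D)."""
    if D <= 0 or spacing <= 0:
        raise ValueError("max_stable_dt requires D > 0 and spacing > 0")
    return spacing * spacing / (4.0 * D)


def _check_occupancy(field: GFField, occupancy: np.ndarray) -> np.ndarray:
    occ = np.asarray(occupancy)
    if occ.shape != field.values.shape:
        raise ValueError(
            f"occupancy shape {occ.shape} does not match field shape {field.values.shape}"
        )
    if not np.isin(occ, (0, 1)).all():
        raise ValueError("occupancy entries must be 0 or 1")
    return occ.astype(float)


def _euler_step(g: np.ndarray, occ: np.ndarray, field: GFField, dt: float) -> np.ndarray:
    # mirror ghost cells implement the zero-gradient boundary
    padded = np.pad(g, 1, mode="edge")
    lap = (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * g
    ) / field.spacing**2
    return g + dt * (field.D * lap + field.rho * occ - field.delta * g)


def step_field(field: GFField, occupancy: np.ndarray, dt: float) -> GFField:
    """One forward-Euler update of the field driven by ``occupancy``.

    Rejects steps beyond the diffusive stability bound; use
    :func:`advance_field` for arbitrary horizons.
    """
    occ = _check_occupancy(field, occupancy)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if field.D > 0:
        bound = max_stable_dt(field.D, field.spacing)
        if dt > bound * (1 + 1e-12):
            raise ValueError(
                f"dt={dt} exceeds the explicit stability bound "
                f"spacing^2/(4*D) = {bound}"
            )
    if field.delta > 0 and dt * field.delta > 1.0:
        raise ValueError(f"dt={dt} exceeds the decay stability bound 1/delta = {1.0 / field.delta}")
    g = _euler_step(field.values, occ, field, dt)
    return replace(field, values=np.maximum(g, 0.0))


def advance_field(field: GFField, occupancy: np.ndarray, dt: float) -> GFField:
    """Advance the field by ``dt``, splitting into stable sub-steps as needed."""
    occ = _check_occupancy(field, occupancy)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    # joint diffusion+decay bound: keeps the stiffest (checkerboard) mode's
    # amplification within (-1, 1] and the update positivity-preserving
    rate = 4.0 * field.D / field.spacing**2 + field.delta
    bound = 1.0 / rate if rate > 0 else np.inf
    n_sub = max(1, int(np.ceil(dt / bound))) if np.isfinite(bound) else 1
    sub = dt / n_sub
    g = field.values
    for _ in range(n_sub):
        g = _euler_step(g, occ, field, sub)
    return replace(field, values=np.maximum(g, 0.0))


def _neumann_laplacian_1d(n: int) -> sp.csr_matrix:
    lap = sp.diags([1.0, -2.0, 1.0], offsets=[-1, 0, 1], shape=(n, n), format="lil")
    lap[0, 0] = -1.0
    lap[n - 1, n - 1] = -1.0
    return lap.tocsr()


def steady_state_field(
    occupancy: np.ndarray,
    D: float,
    rho: float,
    delta: float,
    spacing: float,
) -> GFField:
    """Direct sparse solve of D*lap(g) + rho*c - delta*g = 0 with no-flux walls.

    Requires delta > 0 (the pure-Neumann diffusion operator is singular).
    """
    if delta <= 0:
        raise ValueError("steady_state_field requires delta > 0 (singular system otherwise)")
    occ = np.asarray(occupancy)
    if occ.ndim != 2 or occ.shape[0] != occ.shape[1]:
        raise ValueError("occupancy must be a square 2-D grid")
    if not np.isin(occ, (0, 1)).all():
        raise ValueError("occupancy entries must be 0 or 1")
    n = occ.shape[0]
    lap1 = _neumann_laplacian_1d(n)
    eye = sp.identity(n, format="csr")
    lap2 = sp.kron(eye, lap1) + sp.kron(lap1, eye)
    A = (delta * sp.identity(n * n) - (D / spacing**2) * lap2).tocsc()
    g = spla.spsolve(A, rho * occ.astype(float).ravel())
    g = np.maximum(g.reshape(n, n), 0.0)
    return GFField(values=g, spacing=spacing, D=D, rho=rho, delta=delta)
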