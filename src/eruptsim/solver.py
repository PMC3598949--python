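"""Small-strain linear isotropic elasticity on 4-node tetrahedra.

Constant-strain tet4 elements; global sparse assembly; Dirichlet
conditions imposed by row/column elimination (prescribed DOFs are removed
from the system exactly, supporting non-zero prescribed values); direct
sparse LU factorization.  Units: mm, N, MPa.

The element is the classical constant-strain tetrahedron: displacement is
affine within each element, so it reproduces any affine field exactly
(patch test) and carries exactly six rigid-body zero-energy modes.  No
locking mitigation is applied; the softest nearly-incompressible tissues
modelled (Poisson's ratio 0.45-0.49) are below the severe-locking regime
and the downstream analysis is pattern-level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from eruptsim.geometry import TetMesh
from eruptsim.loading import LoadCase
from eruptsim.materials import CODE_TO_REGION, Material, MaterialTable

__all__ = [
    "ElementTensorField",
    "element_stiffness",
    "solve",
    "recover_strain_stress",
    "reaction_forces",
]

#: Relative equilibrium-residual bound enforced after each solve.
EQUILIBRIUM_RTOL = 1e-6


@dataclass
class ElementTensorField:
    """Per-element symmetric strain and stress tensors.

    ``strain``: (m, 3, 3) unitless (engineering small-strain definition);
    ``stress``: (m, 3, 3) MPa, related to strain by each element's
    isotropic Hooke's law.
    """

    strain: np.ndarray
    stress: np.ndarray


def _isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix in Voigt order
    (xx, yy, zz, xy, yz, xz) with engineering shear strains."""
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[:3, :3] += 2.0 * mu * np.eye(3)
    D[3:, 3:] = mu * np.eye(3)
    return D


def _grads_and_volumes(coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Shape-function gradients (m, 4, 3) and volumes (m,) for tet batches."""
    edges = coords[:, 1:] - coords[:, :1]  # rows are edge vectors
    det = np.linalg.det(edges)
    vols = np.abs(det) / 6.0
    # gradient of barycentric coordinate i (i=1..3) is row i-1 of inv(A)
    # where A has edge vectors as columns, i.e. A = edges^T.
    G = np.linalg.inv(edges.transpose(0, 2, 1))
    grads = np.empty((coords.shape[0], 4, 3))
    grads[:, 1:, :] = G
    grads[:, 0, :] = -G.sum(axis=1)
    return grads, vols


def _B_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (m, 6, 12), Voigt order with
    engineering shear, DOF order (ux0, uy0, uz0, ux1, ...)."""
    m = grads.shape[0]
    B = np.zeros((m, 6, 12))
    for a in range(4):
        bx, by, bz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = bx
        B[:, 1, c + 1] = by
        B[:, 2, c + 2] = bz
        B[:, 3, c + 0] = by
        B[:, 3, c + 1] = bx
        B[:, 4, c + 1] = bz
        B[:, 4, c + 2] = by
        B[:, 5, c + 0] = bz
        B[:, 5, c + 2] = bx
    return B


def element_stiffness(coords: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 constant-strain tetrahedron stiffness matrix.

    Symmetric positive semi-definite with exactly six zero eigenvalues
    (the rigid-body modes).  Raises ``ValueError`` for a degenerate
    (coplanar) tetrahedron.
    """
    coords = np.asarray(coords, dtype=float)[None]
    edges = coords[0, 1:] - coords[0, 0]
    vol = abs(np.linalg.det(edges)) / 6.0
    scale = max(np.abs(edges).max(), 1.0)
    if vol <= 1e-12 * scale**3:
        raise ValueError("degenerate tetrahedron: zero volume")
    Material(E, nu)  # validate
    grads, vols = _grads_and_volumes(coords)
    B = _B_matrices(grads)[0]
    D = _isotropic_D(E, nu)
    Ke = vols[0] * B.T @ D @ B
    return 0.5 * (Ke + Ke.T)


def _materials_per_element(mesh: TetMesh, materials: MaterialTable) -> Tuple[np.ndarray, np.ndarray]:
    E = np.empty(mesh.n_elements)
    nu = np.empty(mesh.n_elements)
    cache: Dict[int, Tuple[float, float]] = {}
    for code in np.unique(mesh.region):
        mat = materials[CODE_TO_REGION[int(code)]]
        cache[int(code)] = (mat.E, mat.nu)
    for code, (e_val, nu_val) in cache.items():
        mask = mesh.region == code
        E[mask] = e_val
        nu[mask] = nu_val
    return E, nu


def _assemble(mesh: TetMesh, materials: MaterialTable) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3n x 3n, CSR)."""
    coords = mesh.element_coords()
    grads, vols = _grads_and_volumes(coords)
    if (vols <= 1e-12).any():
        bad = int(np.argmin(vols))
        raise ValueError(f"degenerate element {bad}: volume {vols[bad]:.3e} mm^3")
    B = _B_matrices(grads)
    E, nu = _materials_per_element(mesh, materials)
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    # D @ B without forming per-element D: split normal and shear blocks.
    DB = np.empty_like(B)
    trace_rows = B[:, 0, :] + B[:, 1, :] + B[:, 2, :]
    for i in range(3):
        DB[:, i, :] = lam[:, None] * trace_rows + 2.0 * mu[:, None] * B[:, i, :]
    for i in range(3, 6):
        DB[:, i, :] = mu[:, None] * B[:, i, :]
    Ke = np.einsum("eik,eij->ekj", B, DB) * vols[:, None, None]

    dof = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    return K


def solve(mesh: TetMesh, materials: MaterialTable, load: LoadCase) -> np.ndarray:
    """Solve for nodal displacements (n, 3), mm.

    Prescribed DOFs take their prescribed values exactly; the reduced
    system is solved by sparse LU.  Raises ``ValueError`` if the
    constraints leave the system singular (rigid-body modes remain) or the
    equilibrium residual exceeds ``EQUILIBRIUM_RTOL``.
    """
    if load.n_nodes != mesh.n_nodes:
        raise ValueError("load case node count does not match mesh")
    K = _assemble(mesh, materials)
    n_dof = 3 * mesh.n_nodes
    fixed = load.fixed_mask.ravel()
    free = ~fixed
    if fixed.sum() < 6:
        raise ValueError(
            "insufficient constraints: fewer than 6 fixed DOFs cannot remove "
            "rigid-body modes"
        )
    f = load.forces.ravel().copy()
    u = np.zeros(n_dof)
    u[fixed] = load.fixed_values.ravel()[fixed]
    rhs = f[free] - K[free][:, fixed] @ u[fixed]
    K_ff = K[free][:, free].tocsc()
    try:
        lu = spla.splu(K_ff)
    except RuntimeError as exc:
        raise ValueError(
            "singular stiffness system: constraints do not remove all "
            f"rigid-body modes ({exc})"
        ) from exc
    u[free] = lu.solve(rhs)
    if not np.isfinite(u).all():
        raise ValueError("singular stiffness system: non-finite solution")
    residual = np.linalg.norm(K_ff @ u[free] - rhs)
    scale = max(np.linalg.norm(rhs), np.linalg.norm(K_ff @ u[free]), 1e-30)
    if residual > EQUILIBRIUM_RTOL * scale:
        raise ValueError(
            f"solver residual {residual:.3e} exceeds {EQUILIBRIUM_RTOL:.0e} "
            "relative; system may be ill-conditioned or under-constrained"
        )
    return u.reshape(-1, 3)


def recover_strain_stress(
    mesh: TetMesh, materials: MaterialTable, u: np.ndarray
) -> ElementTensorField:
    """Per-element constant strain from shape-function gradients and
    stress from each element's isotropic Hooke's law."""
    u = np.asarray(u, dtype=float)
    if u.shape != (mesh.n_nodes, 3):
        raise ValueError("displacement field must have shape (n_nodes, 3)")
    coords = mesh.element_coords()
    grads, _ = _grads_and_volumes(coords)
    u_e = u[mesh.elements]  # (m, 4, 3)
    H = np.einsum("mai,maj->mij", u_e, grads)
    strain = 0.5 * (H + H.transpose(0, 2, 1))
    E, nu = _materials_per_element(mesh, materials)
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = E / (2.0 * (1.0 + nu))
    tr = np.trace(strain, axis1=1, axis2=2)
    stress = 2.0 * mu[:, None, None] * strain
    stress[:, np.arange(3), np.arange(3)] += (lam * tr)[:, None]
    return ElementTensorField(strain=strain, stress=stress)


def reaction_forces(
    mesh: TetMesh, materials: MaterialTable, u: np.ndarray, load: LoadCase
) -> Dict[Tuple[int, int], float]:
    """Reaction forces (N) at the prescribed DOFs: r = K u - f.

    Their vector sum balances the applied loads componentwise (global
    equilibrium).
    """
    K = _assemble(mesh, materials)
    r = (K @ np.asarray(u, dtype=float).ravel() - load.forces.ravel()).reshape(-1, 3)
    nodes, axes = np.nonzero(load.fixed_mask)
    return {(int(n), int(a)): float(r[n, a]) for n, a in zip(nodes, axes)}
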