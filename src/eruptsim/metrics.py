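"""Per-element scalar measures: volume, principal strains, equivalent
strain, hydrostatic stress, and the Biological Response Unit (BRU).

Sign convention: negative hydrostatic stress means net compression,
positive means net tension.  BRU is the product of hydrostatic stress
(MPa) and element volume (mm^3) and therefore carries units of N.mm;
increasingly negative BRU marks an increasingly strong expected biological
response to compression, increasingly positive BRU to tension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PrincipalStrains",
    "element_volume",
    "principal_strains",
    "equivalent_strain",
    "hydrostatic_stress",
    "bru",
    "element_records",
]


@dataclass(frozen=True)
class PrincipalStrains:
    """Principal strains sorted descending (S1 >= S2 >= S3), unitless."""

    S1: float
    S2: float
    S3: float

    def __post_init__(self) -> None:
        if not (self.S1 >= self.S2 >= self.S3):
            raise ValueError("principal strains must be sorted descending")

    def as_array(self) -> np.ndarray:
        return np.array([self.S1, self.S2, self.S3])


def element_volume(coords: np.ndarray) -> float:
    """Volume of a tetrahedron from its 4 corner coordinates (mm -> mm^3).

    Raises ``ValueError`` for (numerically) coplanar corners.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (4, 3):
        raise ValueError("expected 4 corner points in 3D")
    edges = coords[1:] - coords[0]
    vol = abs(np.linalg.det(edges)) / 6.0
    scale = max(np.abs(edges).max(), 1.0)
    if vol <= 1e-12 * scale**3:
        raise ValueError("degenerate tetrahedron: corner points are coplanar")
    return float(vol)


def _check_symmetric(tensor: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3):
        raise ValueError("expected a 3x3 tensor")
    scale = max(np.abs(tensor).max(), 1.0)
    if np.abs(tensor - tensor.T).max() > tol * scale:
        raise ValueError("tensor is not symmetric within tolerance")
    return tensor


def principal_strains(strain: np.ndarray) -> PrincipalStrains:
    """Eigenvalues of a symmetric strain tensor, sorted descending."""
    strain = _check_symmetric(strain)
    vals = np.linalg.eigvalsh(0.5 * (strain + strain.T))
    return PrincipalStrains(float(vals[2]), float(vals[1]), float(vals[0]))


def equivalent_strain(p: PrincipalStrains, nu_eff: float) -> float:
    """Scalar deformation measure from principal strains.

    S_e = 1/(1+nu_eff) * sqrt(((S1-S2)^2 + (S2-S3)^2 + (S3-S1)^2) / 2)

    It is homogeneous of degree 1 in the strains and vanishes exactly for
    purely volumetric (isotropic) strain states.  ``nu_eff`` is the
    effective Poisson's ratio, normally that of the element's material.
    """
    if not (-1.0 < nu_eff <= 0.5):
        raise ValueError(f"nu_eff must lie in (-1, 0.5], got {nu_eff}")
    s1, s2, s3 = p.S1, p.S2, p.S3
    dev = ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2) / 2.0
    return float(np.sqrt(dev) / (1.0 + nu_eff))


def hydrostatic_stress(stress: np.ndarray) -> float:
    """Mean of the three normal stress components, MPa.

    sigma_h = (sigma_xx + sigma_yy + sigma_zz) / 3; rotation invariant.
    Negative values mark net compression, positive net tension.
    """
    stress = _check_symmetric(stress)
    return float(np.trace(stress) / 3.0)


def bru(sigma_h: float, volume: float) -> float:
    """Biological Response Unit: hydrostatic stress x element volume, N.mm."""
    if not volume > 0:
        raise ValueError(f"element volume must be positive, got {volume}")
    return float(sigma_h * volume)


def _equivalent_strain_batch(principals: np.ndarray, nu_eff: np.ndarray) -> np.ndarray:
    s1, s2, s3 = principals[:, 2], principals[:, 1], principals[:, 0]
    dev = ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2) / 2.0
    return np.sqrt(dev) / (1.0 + nu_eff)


def element_records(mesh, tensors, materials=None, element_mask=None) -> pd.DataFrame:
    """Tabulate per-element scalars from a solved tensor field.

    Parameters
    ----------
    mesh : TetMesh
    tensors : ElementTensorField
        Per-element strain and stress from the solver.
    materials : MaterialTable, optional
        Supplies the per-element effective Poisson's ratio for the
        equivalent strain; defaults to the package material table.
    element_mask : bool array, optional
        Restrict the table to a subset of elements.

    Returns
    -------
    pandas.DataFrame
        Columns ``element, region, volume, sigma_h, S_e, bru`` (mm^3, MPa,
        unitless, N.mm).  ``bru`` is exactly ``sigma_h * volume``.
    """
    from eruptsim.materials import CODE_TO_REGION, MaterialTable

    if materials is None:
        materials = MaterialTable()
    idx = np.arange(mesh.n_elements)
    if element_mask is not None:
        idx = idx[np.asarray(element_mask)]
    vols = mesh.volumes()[idx]
    stress = np.asarray(tensors.stress)[idx]
    strain = np.asarray(tensors.strain)[idx]
    sigma_h = np.trace(stress, axis1=1, axis2=2) / 3.0
    principals = np.linalg.eigvalsh(strain)
    nu_eff = np.array(
        [materials[CODE_TO_REGION[int(c)]].nu for c in mesh.region[idx]]
    )
    s_e = _equivalent_strain_batch(principals, nu_eff)
    return pd.DataFrame(
        {
            "element": idx,
            "region": [CODE_TO_REGION[int(c)].value for c in mesh.region[idx]],
            "volume": vols,
            "sigma_h": sigma_h,
            "S_e": s_e,
            "bru": sigma_h * vols,
        }
    )
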