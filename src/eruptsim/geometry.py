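"""Synthetic tooth-in-crypt geometry: labelled voxel grid and tet mesh.

The generated scene is an idealized stand-in for a CT-derived jaw segment:
a rectangular bone block (cortical shell around a cancellous core)
containing a capsule-shaped tooth (enamel crown cap over a dentine body
with an optional pulp core) separated from bone everywhere by a soft
follicle / periodontal-ligament shell.  Voxels are converted to a
conforming tetrahedral mesh by the Freudenthal/Kuhn 6-tet cube split with a
globally consistent diagonal, so no external mesher is needed.

Units are mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage

from eruptsim.materials import (
    BONE_LABELS,
    CODE_TO_REGION,
    REGION_CODES,
    TOOTH_LABELS,
    RegionLabel,
)

_TOOTH_CODES = np.array([REGION_CODES[r] for r in TOOTH_LABELS])
_BONE_CODES = np.array([REGION_CODES[r] for r in BONE_LABELS])


@dataclass
class GeometryConfig:
    """Parameters of the synthetic tooth-in-crypt scene (mm).

    The tooth is a capsule (cylinder with hemispherical ends) whose axis
    runs from the crown centre towards the root apex.  The follicle shell
    surrounds the capsule; a cortical shell lines the outer surface of the
    domain box; everything else is cancellous bone.
    """

    box: Tuple[float, float, float] = (32.0, 12.0, 14.0)
    pitch: float = 1.0
    crown_centre: Tuple[float, float, float] = (16.0, 6.0, 10.5)
    axis: Tuple[float, float, float] = (0.0, 0.0, -1.0)  # crown -> apex
    crown_radius: float = 1.8
    root_length: float = 5.5
    pulp_radius: float = 0.0  # 0 disables the pulp core
    follicle_thickness: float = 1.0
    cortical_thickness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.box = tuple(float(b) for b in self.box)  # type: ignore[assignment]
        self.crown_centre = tuple(float(c) for c in self.crown_centre)  # type: ignore[assignment]
        axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("tooth axis direction must be non-zero")
        self.axis = tuple(axis / norm)  # type: ignore[assignment]
        if self.crown_radius <= 0:
            raise ValueError("degenerate tooth: crown_radius must be positive")
        if self.root_length < 0:
            raise ValueError("root_length must be non-negative")
        if self.follicle_thickness <= 0:
            raise ValueError("follicle_thickness must be positive")
        if self.pitch <= 0:
            raise ValueError("voxel pitch must be positive")
        if self.follicle_thickness < self.pitch:
            raise ValueError(
                "follicle shell thinner than one voxel: follicle_thickness="
                f"{self.follicle_thickness} < pitch={self.pitch}"
            )
        for extent in self.box:
            n = extent / self.pitch
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"voxel pitch {self.pitch} does not divide box extent {extent}"
                )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(b / self.pitch)) for b in self.box)  # type: ignore[return-value]


def _capsule_distance(points: np.ndarray, config: GeometryConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Distance from points to the tooth capsule axis segment.

    Returns ``(d, t)`` where ``d`` is the Euclidean distance to the segment
    and ``t`` the axial coordinate of the projection (0 at the crown
    centre, clipped to [0, root_length])."""
    c = np.asarray(config.crown_centre, dtype=float)
    a = np.asarray(config.axis, dtype=float)
    rel = points - c
    t = np.clip(rel @ a, 0.0, config.root_length)
    closest = c + t[:, None] * a
    d = np.linalg.norm(points - closest, axis=1)
    return d, t


def build_labelled_grid(config: GeometryConfig) -> np.ndarray:
    """Label every voxel of the domain with a tissue region code.

    Returns a ``(nx, ny, nz)`` int array of :data:`~eruptsim.materials.REGION_CODES`
    values.  The tooth capsule is fully enclosed by a follicle shell of at
    least the requested thickness (guaranteed by a 26-connected dilation
    pass), itself enclosed by bone; a cortical shell lines the box surface.

    Raises
    ------
    ValueError
        If the configuration violates a geometric constraint (degenerate
        tooth, follicle thinner than one voxel, or tooth/follicle touching
        the domain boundary so that no bone remains beyond the follicle).
    """
    nx, ny, nz = config.shape
    p = config.pitch
    centres = (
        np.stack(
            np.meshgrid(
                (np.arange(nx) + 0.5) * p,
                (np.arange(ny) + 0.5) * p,
                (np.arange(nz) + 0.5) * p,
                indexing="ij",
            ),
            axis=-1,
        )
        .reshape(-1, 3)
    )
    d, t = _capsule_distance(centres, config)
    d = d.reshape(nx, ny, nz)
    t = t.reshape(nx, ny, nz)

    labels = np.full((nx, ny, nz), REGION_CODES[RegionLabel.CANCELLOUS_BONE], dtype=np.int32)

    # Cortical shell lining the domain box.
    n_shell = max(1, int(round(config.cortical_thickness / p)))
    cortical = np.zeros((nx, ny, nz), dtype=bool)
    for ax_i in range(3):
        idx_lo = [slice(None)] * 3
        idx_lo[ax_i] = slice(0, n_shell)
        cortical[tuple(idx_lo)] = True
        idx_hi = [slice(None)] * 3
        idx_hi[ax_i] = slice(-n_shell, None)
        cortical[tuple(idx_hi)] = True
    labels[cortical] = REGION_CODES[RegionLabel.CORTICAL_BONE]

    tooth = d <= config.crown_radius
    if not tooth.any():
        raise ValueError(
            "degenerate tooth: capsule encloses no voxel centre at this pitch"
        )
    follicle = (~tooth) & (d <= config.crown_radius + config.follicle_thickness)

    # Guarantee a full 26-connected voxel shell of follicle around the tooth
    # even where the nominal thickness band misses a diagonal neighbour.
    dilated = ndimage.binary_dilation(tooth, structure=np.ones((3, 3, 3), dtype=bool))
    follicle |= dilated & ~tooth

    # Inside the tooth: enamel cap near the crown end, dentine below,
    # optional pulp core inside the dentine.
    enamel = tooth & (t <= config.crown_radius)
    dentine = tooth & ~enamel
    labels[dentine] = REGION_CODES[RegionLabel.DENTINE]
    labels[enamel] = REGION_CODES[RegionLabel.ENAMEL]
    if config.pulp_radius > 0:
        pulp = dentine & (d <= config.pulp_radius)
        labels[pulp] = REGION_CODES[RegionLabel.PULP]
    labels[follicle] = REGION_CODES[RegionLabel.FOLLICLE_PDL]

    # The follicle must be enclosed by bone: no tooth or follicle voxel may
    # reach the outermost voxel layer of the domain.
    boundary = np.zeros((nx, ny, nz), dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    if (tooth | follicle)[boundary].any():
        raise ValueError(
            "tooth capsule plus follicle shell reaches the domain boundary; "
            "need at least one voxel of bone beyond the follicle"
        )
    return labels


@dataclass
class TetMesh:
    """Labelled tetrahedral mesh.

    Attributes
    ----------
    nodes : (n, 3) float array
        Node coordinates, mm.
    elements : (m, 4) int array
        Node indices per tetrahedron, positively oriented.
    region : (m,) int array
        Region code per element (see :data:`~eruptsim.materials.REGION_CODES`).
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    pitch: float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.region = np.asarray(self.region)
        if self.region.dtype.kind in "OU":
            self.region = np.array(
                [REGION_CODES[RegionLabel(r)] for r in self.region], dtype=np.int32
            )
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be an (m, 4) index array")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= len(self.nodes):
            raise ValueError("element node indices out of range")
        if len(self.region) != len(self.elements):
            raise ValueError("region array must have one label per element")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def region_labels(self) -> np.ndarray:
        """Region of each element as a string array."""
        return np.array([CODE_TO_REGION[int(c)].value for c in self.region])

    def element_coords(self) -> np.ndarray:
        """(m, 4, 3) coordinates of each element's nodes."""
        return self.nodes[self.elements]

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def volumes(self) -> np.ndarray:
        coords = self.element_coords()
        e = coords[:, 1:] - coords[:, :1]
        return np.abs(np.linalg.det(e)) / 6.0

    def mask(self, labels) -> np.ndarray:
        """Boolean element mask for one label or an iterable of labels."""
        if isinstance(labels, (RegionLabel, str, int)):
            labels = [labels]
        codes = [
            lab if isinstance(lab, (int, np.integer)) else REGION_CODES[RegionLabel(lab)]
            for lab in labels
        ]
        return np.isin(self.region, codes)


# The 6 tetrahedra of the Freudenthal split of the unit cube, as corner
# indices where corner (i, j, k) has index i*4 + j*2 + k.  Every tet shares
# the main diagonal 0 -> 7, which makes adjacent cubes conform.
_CUBE_TETS = np.array(
    [
        [0, 4, 6, 7],
        [0, 6, 2, 7],
        [0, 2, 3, 7],
        [0, 3, 1, 7],
        [0, 1, 5, 7],
        [0, 5, 4, 7],
    ],
    dtype=np.int64,
)


def voxels_to_tets(grid: np.ndarray, pitch: float = 1.0) -> TetMesh:
    """Convert a labelled voxel grid to a conforming tetrahedral mesh.

    Every voxel cube is split into 6 tetrahedra around its main diagonal;
    all cubes share the same diagonal orientation, so shared faces conform.
    Element region = voxel label.  All elements are reoriented to positive
    signed volume.
    """
    grid = np.asarray(grid)
    nx, ny, nz = grid.shape
    # Lattice node index (i, j, k) -> flat id.
    node_id = lambda i, j, k: (i * (ny + 1) + j) * (nz + 1) + k  # noqa: E731

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    # Corner flat ids per voxel, ordered by corner bit index.
    corners = np.empty((ii.size, 8), dtype=np.int64)
    for c in range(8):
        di, dj, dk = (c >> 2) & 1, (c >> 1) & 1, c & 1
        corners[:, c] = node_id(ii + di, jj + dj, kk + dk)

    elements = corners[:, _CUBE_TETS].reshape(-1, 4)
    region = np.repeat(grid.ravel(), 6)

    gi, gj, gk = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    nodes = np.stack([gi.ravel(), gj.ravel(), gk.ravel()], axis=1).astype(float) * pitch

    # Orientation fix: swap two nodes of any negatively oriented tet.
    coords = nodes[elements]
    sign = np.linalg.det(coords[:, 1:] - coords[:, :1])
    flip = sign < 0
    elements[flip, 2], elements[flip, 3] = (
        elements[flip, 3].copy(),
        elements[flip, 2].copy(),
    )
    return TetMesh(nodes=nodes, elements=elements, region=region, pitch=pitch)
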