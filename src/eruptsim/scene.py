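"""Default synthetic loading scene for the tooth-in-crypt block.

The bone block is treated as a simply supported jaw segment: its bottom
edges at both ends are fixed (the condylar support stand-in), adductor
muscle tractions pull upward near the two ends of the top surface, and
the bite point resists vertically at a patch *away* from the unerupted
tooth at mid-span — anatomically the occlusal contact lands on erupted
teeth, not over the crypt.  The block therefore flexes around the
unerupted tooth: with the crown near the top surface the coronal follicle
sits in the compressive bending fibre and the apical follicle towards the
tensile fibre, echoing the eruption pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from eruptsim.geometry import GeometryConfig, TetMesh
from eruptsim.loading import LoadCase, MuscleSpec, make_load_case

__all__ = ["SceneSpec", "build_scene_load_case", "default_muscles"]

#: Default relative muscle activation per bite mode.
DEFAULT_ACTIVATION = {"incisive": 0.4, "unilateral_molar": 0.8}

#: Skeletal-muscle force constant, N/cm^2.
DEFAULT_K = 40.0

#: Adductor physiological cross-section, cm^2 (per side).
DEFAULT_CROSS_SECTION = 6.0


@dataclass
class SceneSpec:
    """Node-set geometry of the default scene (mm)."""

    geometry: GeometryConfig
    muscle_cross_section: float = DEFAULT_CROSS_SECTION
    muscle_constant: float = DEFAULT_K
    activation: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACTIVATION)
    )
    #: half-width of the bite patches in x and y, mm
    bite_halfwidth: float = 1.8
    #: x-centres of the bite patches as fractions of the box length; both
    #: sit away from the unerupted tooth at mid-span, mirroring erupted
    #: incisors and a first molar carrying the occlusal contact
    incisal_position: float = 0.25
    molar_position: float = 0.75
    #: x-extent of each muscle attachment strip measured from the ends, mm
    attachment_inset: Tuple[float, float] = (1.0, 4.0)


def _top_nodes(mesh: TetMesh, tol: float = 1e-9) -> np.ndarray:
    z = mesh.nodes[:, 2]
    return np.nonzero(z >= z.max() - tol)[0]


def _bottom_end_nodes(mesh: TetMesh, tol: float = 1e-9) -> np.ndarray:
    """Bottom edge node lines at the two x-ends (knife-edge supports)."""
    x, z = mesh.nodes[:, 0], mesh.nodes[:, 2]
    on_bottom = z <= z.min() + tol
    on_end = (x <= x.min() + tol) | (x >= x.max() - tol)
    return np.nonzero(on_bottom & on_end)[0]


def _patch(mesh: TetMesh, nodes: np.ndarray, centre_xy, halfwidth: float) -> np.ndarray:
    xy = mesh.nodes[nodes, :2]
    keep = (np.abs(xy[:, 0] - centre_xy[0]) <= halfwidth) & (
        np.abs(xy[:, 1] - centre_xy[1]) <= halfwidth
    )
    return nodes[keep]


def default_muscles(mesh: TetMesh, scene: SceneSpec, mode: str) -> List[MuscleSpec]:
    """Two mirrored adductor muscles pulling up near the block ends.

    Their lateral (y) direction components are equal and opposite, so the
    net applied lateral force vanishes.
    """
    top = _top_nodes(mesh)
    x = mesh.nodes[:, 0]
    lo, hi = scene.attachment_inset
    x_max = x.max()
    left = top[(x[top] >= lo) & (x[top] <= hi)]
    right = top[(x[top] >= x_max - hi) & (x[top] <= x_max - lo)]
    if left.size == 0 or right.size == 0:
        raise ValueError("muscle attachment strips contain no surface nodes")
    act = scene.activation[mode]
    d = np.array([0.0, 0.1, 1.0])
    d /= np.linalg.norm(d)
    muscles = [
        MuscleSpec(
            name="adductor_anterior",
            cross_section_cm2=scene.muscle_cross_section,
            force_constant=scene.muscle_constant,
            activation=act,
            direction=tuple(d),
            attachment=left,
        ),
        MuscleSpec(
            name="adductor_posterior",
            cross_section_cm2=scene.muscle_cross_section,
            force_constant=scene.muscle_constant,
            activation=act,
            direction=tuple(d * np.array([1.0, -1.0, 1.0])),
            attachment=right,
        ),
    ]
    return muscles


def build_scene_load_case(mesh: TetMesh, scene: SceneSpec, mode: str) -> LoadCase:
    """Assemble the default scene's load case for one bite mode."""
    geom = scene.geometry
    top = _top_nodes(mesh)
    incisal = _patch(
        mesh,
        top,
        (scene.incisal_position * geom.box[0], geom.crown_centre[1]),
        scene.bite_halfwidth,
    )
    occlusal = _patch(
        mesh,
        top,
        (scene.molar_position * geom.box[0], geom.crown_centre[1]),
        scene.bite_halfwidth,
    )
    support = _bottom_end_nodes(mesh)
    muscles = default_muscles(mesh, scene, mode)
    return make_load_case(
        mesh,
        muscles,
        mode,
        incisal_nodes=incisal,
        occlusal_nodes=occlusal,
        support_nodes=support,
    )
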