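"""Muscle-derived loading and boundary conditions.

Masticatory muscle force magnitudes follow the standard product rule
M = X * K * EMG: physiological cross-sectional area X (cm^2), the skeletal
muscle force constant K (N/cm^2), and the task-specific relative
activation EMG in [0, 1].  Each muscle's total force is distributed
equally over its attachment node set along its direction cosines.

Two bite modes are supported, mirroring incisive and unilateral molar
biting: both fix the support-block corner nodes in all three axes; the
incisive mode additionally fixes the vertical degree of freedom at the
incisal node set, the molar mode at the designated occlusal node set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Set, Tuple

import numpy as np

__all__ = ["MuscleSpec", "LoadCase", "muscle_force", "make_load_case"]

#: Vertical axis index (z) in the scene coordinate frame.
VERTICAL_AXIS = 2


@dataclass
class MuscleSpec:
    """One masticatory muscle acting on the mesh surface.

    Parameters
    ----------
    name : str
    cross_section_cm2 : float
        Physiological cross-sectional area X, cm^2.
    force_constant : float
        Skeletal-muscle force constant K, N/cm^2 (conventionally 40).
    activation : float
        Relative EMG activation in [0, 1] for the bite task.
    direction : 3-vector
        Unit direction cosines of the muscle pull.
    attachment : int array
        Surface node indices the force is spread over.
    """

    name: str
    cross_section_cm2: float
    force_constant: float
    activation: float
    direction: Tuple[float, float, float]
    attachment: Sequence[int]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-6:
            raise ValueError(
                f"muscle '{self.name}': direction cosines must form a unit "
                f"vector, |d| = {np.linalg.norm(d):.6f}"
            )
        self.direction = tuple(d)
        self.attachment = np.asarray(self.attachment, dtype=np.int64)
        if self.attachment.size == 0:
            raise ValueError(f"muscle '{self.name}': empty attachment node set")
        # magnitude validation
        muscle_force(self.cross_section_cm2, self.force_constant, self.activation)

    @property
    def force(self) -> float:
        """Total muscle force magnitude, N."""
        return muscle_force(
            self.cross_section_cm2, self.force_constant, self.activation
        )


def muscle_force(X_MI: float, K: float, EMG_MI: float) -> float:
    """Muscle force magnitude M = X_MI * K * EMG_MI, in N."""
    if not X_MI > 0:
        raise ValueError(f"cross-sectional area must be positive, got {X_MI}")
    if not K > 0:
        raise ValueError(f"muscle force constant must be positive, got {K}")
    if not 0.0 <= EMG_MI <= 1.0:
        raise ValueError(f"EMG activation must lie in [0, 1], got {EMG_MI}")
    return float(X_MI * K * EMG_MI)


@dataclass
class LoadCase:
    """Boundary conditions: prescribed (fixed) DOFs and nodal forces.

    ``fixed_mask[node, axis]`` marks a prescribed DOF whose value is
    ``fixed_values[node, axis]`` (mm, zero unless set); ``forces`` holds
    applied nodal forces in N.
    """

    n_nodes: int
    fixed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fixed_values: np.ndarray = field(default=None)  # type: ignore[assignment]
    forces: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros((self.n_nodes, 3), dtype=bool)
        if self.fixed_values is None:
            self.fixed_values = np.zeros((self.n_nodes, 3))
        if self.forces is None:
            self.forces = np.zeros((self.n_nodes, 3))
        for arr, name in [
            (self.fixed_mask, "fixed_mask"),
            (self.fixed_values, "fixed_values"),
            (self.forces, "forces"),
        ]:
            if np.asarray(arr).shape != (self.n_nodes, 3):
                raise ValueError(f"{name} must have shape (n_nodes, 3)")

    def fix(self, nodes: Iterable[int] | int, axes=(0, 1, 2), value: float = 0.0) -> None:
        nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        for ax in np.atleast_1d(axes):
            self.fixed_mask[nodes, ax] = True
            self.fixed_values[nodes, ax] = value

    def add_force(self, nodes: Iterable[int] | int, vector: np.ndarray) -> None:
        nodes = np.atleast_1d(np.asarray(nodes, dtype=np.int64))
        self.forces[nodes] += np.asarray(vector, dtype=float)

    @property
    def fixed_dofs(self) -> Set[Tuple[int, int]]:
        nodes, axes = np.nonzero(self.fixed_mask)
        return {(int(n), int(a)) for n, a in zip(nodes, axes)}

    @property
    def n_fixed(self) -> int:
        return int(self.fixed_mask.sum())


def make_load_case(
    mesh,
    muscles: Sequence[MuscleSpec],
    mode: str,
    incisal_nodes: Sequence[int] = (),
    occlusal_nodes: Sequence[int] = (),
    support_nodes: Sequence[int] = (),
) -> LoadCase:
    """Assemble a :class:`LoadCase` for one bite mode.

    Each muscle's total force is split equally across its attachment nodes
    along its direction cosines.  Support nodes are fixed in all three
    axes.  ``mode='incisive'`` fixes the vertical DOF at ``incisal_nodes``;
    ``mode='unilateral_molar'`` fixes the vertical DOF at
    ``occlusal_nodes``.
    """
    if mode not in ("incisive", "unilateral_molar"):
        raise ValueError(f"unknown bite mode '{mode}'")
    support_nodes = np.asarray(support_nodes, dtype=np.int64)
    if support_nodes.size == 0:
        raise ValueError("empty support fixity node set")
    bite_nodes = np.asarray(
        incisal_nodes if mode == "incisive" else occlusal_nodes, dtype=np.int64
    )
    if bite_nodes.size == 0:
        raise ValueError(f"empty bite fixity node set for mode '{mode}'")

    load = LoadCase(n_nodes=mesh.n_nodes)
    load.fix(support_nodes, axes=(0, 1, 2))
    load.fix(bite_nodes, axes=(VERTICAL_AXIS,))

    for muscle in muscles:
        if muscle.attachment.max() >= mesh.n_nodes:
            raise ValueError(
                f"muscle '{muscle.name}': attachment node index out of range"
            )
        per_node = muscle.force / muscle.attachment.size
        load.add_force(muscle.attachment, per_node * np.asarray(muscle.direction))
    return load
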