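"""Tissue region labels and isotropic linear-elastic material properties.

The default material table carries the literature values used for child
mandible modelling: stiff mineralized tissues (enamel, dentine, cortical and
cancellous bone) and compliant soft tissues (dental follicle / periodontal
ligament, pulp), plus the elastic condylar support materials that stand in
for the temporomandibular joint.  Units are MPa for Young's modulus;
Poisson's ratio is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Mapping, Tuple


class RegionLabel(str, Enum):
    """Tissue regions a mesh element can belong to.

    Integer codes (see :data:`REGION_CODES`) are stable and used when
    writing region ids as VTK cell data.
    """

    CORTICAL_BONE = "cortical_bone"
    CANCELLOUS_BONE = "cancellous_bone"
    ENAMEL = "enamel"
    DENTINE = "dentine"
    PULP = "pulp"
    FOLLICLE_PDL = "follicle_pdl"
    CONDYLAR_SUPPORT_ANTERIOR = "condylar_support_anterior"
    CONDYLAR_SUPPORT_POSTERIOR = "condylar_support_posterior"


#: Stable label -> integer code mapping for file I/O.
REGION_CODES: Dict[RegionLabel, int] = {
    RegionLabel.CORTICAL_BONE: 1,
    RegionLabel.CANCELLOUS_BONE: 2,
    RegionLabel.ENAMEL: 3,
    RegionLabel.DENTINE: 4,
    RegionLabel.PULP: 5,
    RegionLabel.FOLLICLE_PDL: 6,
    RegionLabel.CONDYLAR_SUPPORT_ANTERIOR: 7,
    RegionLabel.CONDYLAR_SUPPORT_POSTERIOR: 8,
}

CODE_TO_REGION: Dict[int, RegionLabel] = {v: k for k, v in REGION_CODES.items()}

#: Labels belonging to the tooth proper (enclosed by the follicle shell).
TOOTH_LABELS = frozenset(
    {RegionLabel.ENAMEL, RegionLabel.DENTINE, RegionLabel.PULP}
)

#: Labels belonging to bone (enclosing the follicle shell).
BONE_LABELS = frozenset(
    {RegionLabel.CORTICAL_BONE, RegionLabel.CANCELLOUS_BONE}
)


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material.

    Parameters
    ----------
    E : float
        Young's modulus in MPa.  Must be positive.
    nu : float
        Poisson's ratio, dimensionless, in the open interval (-1, 0.5).
    """

    E: float
    nu: float

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError(f"Young's modulus must be positive, got E={self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(
                f"Poisson's ratio must lie in (-1, 0.5), got nu={self.nu}"
            )


# Literature defaults (MPa, dimensionless).
_DEFAULTS: Dict[RegionLabel, Material] = {
    RegionLabel.CANCELLOUS_BONE: Material(1_500.0, 0.30),
    RegionLabel.CONDYLAR_SUPPORT_ANTERIOR: Material(44.1, 0.40),
    RegionLabel.CONDYLAR_SUPPORT_POSTERIOR: Material(0.49, 0.49),
    RegionLabel.CORTICAL_BONE: Material(15_000.0, 0.30),
    RegionLabel.FOLLICLE_PDL: Material(12.0, 0.45),
    RegionLabel.PULP: Material(2.0, 0.45),
    RegionLabel.DENTINE: Material(18_600.0, 0.31),
    RegionLabel.ENAMEL: Material(84_100.0, 0.20),
}


@dataclass
class MaterialTable:
    """Region label -> material map with validated entries.

    Constructed empty it carries the package defaults; individual regions
    can be overridden via ``overrides`` or :meth:`override`.
    """

    materials: Dict[RegionLabel, Material] = field(
        default_factory=lambda: dict(_DEFAULTS)
    )

    @classmethod
    def with_overrides(
        cls, overrides: Mapping[RegionLabel | str, Tuple[float, float] | Material]
    ) -> "MaterialTable":
        table = cls()
        for label, value in overrides.items():
            table.override(label, value)
        return table

    def override(
        self, label: RegionLabel | str, value: Tuple[float, float] | Material
    ) -> None:
        label = RegionLabel(label)
        if not isinstance(value, Material):
            value = Material(*value)
        self.materials[label] = value

    def __getitem__(self, label: RegionLabel | str) -> Material:
        return self.materials[RegionLabel(label)]

    def __contains__(self, label: object) -> bool:
        try:
            return RegionLabel(label) in self.materials  # type: ignore[arg-type]
        except ValueError:
            return False
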