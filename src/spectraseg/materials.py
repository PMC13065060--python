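"""Material definitions for the synthetic multi-energy phantom.

Each material carries a per-energy-bin mean attenuation signature ``mu``
(arbitrary attenuation units) over the F = 5 photon-counting bins
(7-12, 12-15, 15-18, 18-21, 21-120 keV by default).  Hydroxyapatite (HA)
and iodine signatures follow a water-anchored linear mixing model,

    mu = mu_water + c * shape,

with the HA shape falling steeply with energy (photoelectric-dominated
calcium mineral) and the iodine shape flat at low energies with a rise in
the widest top bin (which contains the iodine K-edge at 33.2 keV).  The two
unit shapes are normalized to the same band-integrated sum, so that the
pairs (I5, HA100) and (I10, HA200) have *identical* total attenuation while
differing per bin: a voxel classifier that collapses the energy axis cannot
separate them, one that preserves spectral shape can.  This is the hard
case the phantom is engineered to probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialSpec",
    "default_materials",
    "material_by_name",
    "CLASS_NAMES",
    "CONFUSABLE_PAIRS",
    "HA_GROUP",
    "IODINE_GROUP",
]

#: Reference water signature across the five default bins (arbitrary units).
MU_WATER = np.array([1.00, 0.85, 0.75, 0.68, 0.45])

#: Unit HA shape: monotone decrease with energy.
SHAPE_HA = np.array([1.00, 0.72, 0.50, 0.35, 0.18])

#: Unit iodine shape: flat low-energy bins, K-edge rise in the wide top bin.
#: Normalized so sum(SHAPE_I) == sum(SHAPE_HA) exactly (2.75), which makes
#: the band-integral ties below exact by construction.
SHAPE_I = np.array([0.55, 0.50, 0.55, 0.65, 0.50])

# class_id order: HA50..HA800 = 1..5, I5/I10/I15 = 6..8, tissues 9..11, water 12
CLASS_NAMES = {
    0: "background",
    1: "HA50",
    2: "HA100",
    3: "HA200",
    4: "HA400",
    5: "HA800",
    6: "I5",
    7: "I10",
    8: "I15",
    9: "adipose",
    10: "liver",
    11: "lung",
    12: "water",
}

#: (iodine, HA) pairs with identical band-integrated attenuation.
CONFUSABLE_PAIRS = (("I5", "HA100"), ("I10", "HA200"))

HA_GROUP = ("HA800", "HA400", "HA200", "HA100")
IODINE_GROUP = ("I15", "I10", "I5")


@dataclass(frozen=True)
class MaterialSpec:
    """One phantom material: label, concentration and spectral signature.

    Parameters
    ----------
    name : str
        Short identifier, e.g. ``"HA200"`` or ``"I10"``.
    class_id : int
        Voxel label in 1..12 (0 is background and never a material).
    concentration : float
        Numeric concentration; 0.0 for tissues and water.
    unit : str
        ``"mg/cm^3"`` for HA, ``"mg/mL"`` for iodine, ``""`` otherwise.
    mu : ndarray
        Per-bin mean attenuation values, length F.
    """

    name: str
    class_id: int
    concentration: float
    unit: str
    mu: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if not (1 <= self.class_id <= 12):
            raise ValueError(f"class_id must be in 1..12, got {self.class_id}")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError(f"non-finite attenuation for material {self.name}")


def _ha(conc: float, class_id: int) -> MaterialSpec:
    # HA coefficient: c = concentration / 1000 (mg/cm^3 -> dimensionless mix)
    return MaterialSpec(f"HA{conc:g}", class_id, conc, "mg/cm^3",
                        MU_WATER + (conc / 1000.0) * SHAPE_HA)


def _iodine(conc: float, class_id: int) -> MaterialSpec:
    # Iodine coefficient c = concentration / 50, so that I5 matches HA100 and
    # I10 matches HA200 in band-integrated attenuation (shapes share the sum).
    return MaterialSpec(f"I{conc:g}", class_id, conc, "mg/mL",
                        MU_WATER + (conc / 50.0) * SHAPE_I)


def default_materials() -> list[MaterialSpec]:
    """The 12-material table of the default phantom (deterministic).

    Returns the five HA concentrations (50-800 mg/cm^3), three iodine
    concentrations (5-15 mg/mL), three soft-tissue surrogates and water,
    with class ids 1..12 each used exactly once.
    """
    return [
        _ha(50, 1), _ha(100, 2), _ha(200, 3), _ha(400, 4), _ha(800, 5),
        _iodine(5, 6), _iodine(10, 7), _iodine(15, 8),
        MaterialSpec("adipose", 9, 0.0, "",
                     np.array([0.82, 0.72, 0.64, 0.58, 0.40])),
        MaterialSpec("liver", 10, 0.0, "",
                     np.array([1.12, 0.97, 0.86, 0.78, 0.52])),
        MaterialSpec("lung", 11, 0.0, "",
                     np.array([0.30, 0.26, 0.23, 0.21, 0.14])),
        MaterialSpec("water", 12, 0.0, "", MU_WATER.copy()),
    ]


def material_by_name(materials: list[MaterialSpec], name: str) -> MaterialSpec:
    for m in materials:
        if m.name == name:
            return m
    raise KeyError(f"no material named {name!r}")
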