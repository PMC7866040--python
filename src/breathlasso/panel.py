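"""Catalogue of the measured volatile-compound panel.

Ion-molecule-reaction mass spectrometry (IMR-MS) quantifies 95 trace gases
per breath sample, with masses between 16 and 123 Da.  Twenty-seven of them
have a known chemical identity (sixteen directly calibrated against liquid
standards, the rest semi-quantitatively calibrated on the sensitivity of
benzene); the remainder are known only by the molecular weight of the
detected ion and are labelled ``M<mass>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Compounds calibrated directly against gas-phase dilutions of standards.
DIRECTLY_CALIBRATED: tuple[str, ...] = (
    "formaldehyde",
    "acetonitrile",
    "formic_acid",
    "acetic_acid",
    "acetaldehyde",
    "methyl_ethyl_ketone",
    "isoprene",
    "acetone",
    "methanol",
    "n_propanol",
    "n_butanol",
    "pentane",
    "hexane",
    "benzene",
    "toluene",
    "heptane",
)

#: Named compounds calibrated semi-quantitatively on the benzene response.
BENZENE_EQUIVALENT_NAMED: tuple[str, ...] = (
    "methane",
    "acetylene",
    "ethane",
    "ethylene",
    "ammonia",
    "propene",
    "1,3-butadiene",
    "nitrous_acid",
    "nitric_oxide",
    "dinitrogen_oxide",
    "hydrogen_sulfide",
)

#: Mass-only species that appear in at least one discriminant model or in
#: the environmental-contamination exclusion set.
_REQUIRED_MASSES: tuple[int, ...] = (
    19, 27, 31, 32, 33, 43, 46, 47, 48, 49, 62, 67, 74, 75,
    91, 93, 98, 99, 103, 105, 106, 109, 120, 121, 123,
)

_PANEL_SIZE = 95
_N_MASS_ONLY = _PANEL_SIZE - len(DIRECTLY_CALIBRATED) - len(BENZENE_EQUIVALENT_NAMED)


def _mass_only_labels() -> tuple[str, ...]:
    labels = [f"M{m}" for m in _REQUIRED_MASSES]
    mass = 16
    while len(labels) < _N_MASS_ONLY:
        if mass not in _REQUIRED_MASSES:
            labels.append(f"M{mass}")
        mass += 1
    return tuple(sorted(labels, key=lambda s: int(s[1:])))


#: Compounds excluded from modelling because their environmental (room air)
#: concentration significantly exceeds the paired alveolar concentration:
#: they carry information about background pollution, not physiology.
ENVIRONMENTAL_EXCLUSION_SET: tuple[str, ...] = (
    "M27",
    "ethane",
    "formaldehyde",
    "methanol",
    "ethylene",
    "nitric_oxide",
    "M31",
    "M32",
    "hydrogen_sulfide",
    "M46",
    "M49",
)


@dataclass(frozen=True)
class CompoundPanel:
    """The measured-compound catalogue: labels plus calibration class."""

    compounds: tuple[str, ...]
    calibration: dict[str, str] = field(repr=False)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.compounds)

    def __contains__(self, name: str) -> bool:
        return name in self.compounds

    def __iter__(self):
        return iter(self.compounds)


def default_panel() -> CompoundPanel:
    """The 95-compound IMR-MS panel used throughout the package."""
    mass_only = _mass_only_labels()
    compounds = DIRECTLY_CALIBRATED + BENZENE_EQUIVALENT_NAMED + mass_only
    calibration = {c: "direct" for c in DIRECTLY_CALIBRATED}
    calibration.update({c: "benzene_equivalent" for c in BENZENE_EQUIVALENT_NAMED})
    calibration.update({c: "benzene_equivalent" for c in mass_only})
    return CompoundPanel(compounds=tuple(compounds), calibration=calibration)
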