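"""Conceptual-DFT global reactivity indices from frontier-orbital energies.

Within the frozen-core (Koopmans) picture, I = −E_HOMO and A = −E_LUMO give

    chi      = (I + A)/2                  absolute electronegativity, eV
    hardness = (I − A)/2                  absolute hardness, eV
    omega    = chi^2 / (2 hardness)       global electrophilicity, eV
    softness = 1 / hardness               1/eV
    omega_donating  = (3I + A)^2 / (16 (I − A))   electro-donating power
    omega_accepting = (I + 3A)^2 / (16 (I − A))   electro-accepting power
    net_electrophilicity = omega_donating + omega_accepting
    dn_max   = chi / hardness             max electrons transferred

Relative descriptors normalize the donating/accepting powers against a
reference ligand: R+ = donating(lig)/donating(ref), R− = accepting ratio.
Beware the literature's sign-superscript conventions for ω±: published
tables sometimes head the donating power "ω⁺" and the accepting power "ω⁻"
— this module names fields by what they compute, and the fixture loader
maps printed columns onto them explicitly (ω⁺ column → ``omega_donating``,
ω⁻ column → ``omega_accepting``).
"""

from __future__ import annotations

from typing import Sequence

from pydantic import BaseModel, model_validator

from .errors import DomainError

__all__ = [
    "FrontierEnergies",
    "ReactivityIndices",
    "RelativeReactivity",
    "global_indices",
    "relative_reactivity",
    "rank_by",
]

_RANKABLE = (
    "gap",
    "chi",
    "hardness",
    "omega",
    "softness",
    "omega_donating",
    "omega_accepting",
    "net_electrophilicity",
    "dn_max",
)


class FrontierEnergies(BaseModel):
    """HOMO/LUMO energies of one ligand, eV."""

    ligand_id: str
    e_homo: float
    e_lumo: float

    @model_validator(mode="after")
    def _check(self) -> "FrontierEnergies":
        if self.e_homo >= self.e_lumo:
            raise ValueError(
                f"{self.ligand_id}: e_homo ({self.e_homo}) must lie below "
                f"e_lumo ({self.e_lumo})"
            )
        return self


class ReactivityIndices(BaseModel):
    ligand_id: str = ""
    gap: float
    chi: float
    hardness: float
    omega: float
    softness: float
    omega_donating: float
    omega_accepting: float
    net_electrophilicity: float
    dn_max: float

    @model_validator(mode="after")
    def _check(self) -> "ReactivityIndices":
        if self.gap <= 0 or self.hardness <= 0:
            raise ValueError("gap and hardness must be positive")
        return self


class RelativeReactivity(BaseModel):
    """Reference-normalized donating/accepting powers (R+, R−)."""

    ligand_id: str = ""
    reference_id: str = ""
    r_plus: float
    r_minus: float

    @model_validator(mode="after")
    def _check(self) -> "RelativeReactivity":
        if self.r_plus <= 0 or self.r_minus <= 0:
            raise ValueError("relative powers must be positive")
        return self


def global_indices(f: FrontierEnergies) -> ReactivityIndices:
    """All global descriptors from one HOMO/LUMO pair."""
    i, a = -f.e_homo, -f.e_lumo
    if i <= a:
        raise DomainError(f"{f.ligand_id}: requires I > A (e_homo < e_lumo)")
    chi = (i + a) / 2.0
    hardness = (i - a) / 2.0
    return ReactivityIndices(
        ligand_id=f.ligand_id,
        gap=f.e_lumo - f.e_homo,
        chi=chi,
        hardness=hardness,
        omega=chi**2 / (2.0 * hardness),
        softness=1.0 / hardness,
        omega_donating=(3.0 * i + a) ** 2 / (16.0 * (i - a)),
        omega_accepting=(i + 3.0 * a) ** 2 / (16.0 * (i - a)),
        net_electrophilicity=(3.0 * i + a) ** 2 / (16.0 * (i - a))
        + (i + 3.0 * a) ** 2 / (16.0 * (i - a)),
        dn_max=chi / hardness,
    )


def relative_reactivity(
    lig: FrontierEnergies, ref: FrontierEnergies
) -> RelativeReactivity:
    """R± of a ligand against a reference ligand."""
    gl, gr = global_indices(lig), global_indices(ref)
    if gr.omega_donating == 0 or gr.omega_accepting == 0:
        raise DomainError(f"reference {ref.ligand_id!r} has zero donating/accepting power")
    return RelativeReactivity(
        ligand_id=lig.ligand_id,
        reference_id=ref.ligand_id,
        r_plus=gl.omega_donating / gr.omega_donating,
        r_minus=gl.omega_accepting / gr.omega_accepting,
    )


def rank_by(descriptor: str, panel: Sequence[FrontierEnergies]) -> list[str]:
    """Ligand ids in descending order of a global descriptor; deterministic
    tie-break by ligand_id."""
    if descriptor not in _RANKABLE:
        raise KeyError(f"unknown descriptor {descriptor!r}; one of {_RANKABLE}")
    scored = [(getattr(global_indices(f), descriptor), f.ligand_id) for f in panel]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [lig for _, lig in scored]
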