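"""Modification registry.

Modifications are named ``"UniModName@Site"`` (``"Oxidation@M"``,
``"Acetyl@Protein N-term"``) and carry an elemental composition plus an
optional neutral-loss composition.  Masses are derived from the built-in
monoisotopic element table, never stored independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import chem


@dataclass(frozen=True)
class Modification:
    name: str
    composition: dict[str, int] = field(default_factory=dict)
    modloss_composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name.count("@") != 1:
            raise ValueError(
                f"modification name must contain exactly one '@': {self.name!r}"
            )
        if self.modloss_mass < 0:
            raise ValueError(f"negative neutral-loss mass for {self.name!r}")

    @property
    def site(self) -> str:
        return self.name.split("@", 1)[1]

    @property
    def mono_mass(self) -> float:
        return chem.composition_mass(self.composition)

    @property
    def modloss_mass(self) -> float:
        if not self.modloss_composition:
            return 0.0
        return chem.composition_mass(self.modloss_composition)


# ~20 common UniMod entries.  The phospho neutral loss is H3PO4 (-97.9769 Da)
# on Ser/Thr; phospho-Tyr does not lose the phosphate under CID/HCD.
_BUILTIN = [
    ("Oxidation@M", "O", ""),
    ("Oxidation@P", "O", ""),  # hydroxyproline
    ("Carbamidomethyl@C", "C(2)H(3)N(1)O(1)", ""),
    ("Phospho@S", "H(1)O(3)P(1)", "H(3)O(4)P(1)"),
    ("Phospho@T", "H(1)O(3)P(1)", "H(3)O(4)P(1)"),
    ("Phospho@Y", "H(1)O(3)P(1)", ""),
    ("Acetyl@K", "C(2)H(2)O(1)", ""),
    ("Acetyl@Protein N-term", "C(2)H(2)O(1)", ""),
    ("Methyl@K", "C(1)H(2)", ""),
    ("Methyl@R", "C(1)H(2)", ""),
    ("Dimethyl@K", "C(2)H(4)", ""),
    ("Dimethyl@R", "C(2)H(4)", ""),
    ("Trimethyl@K", "C(3)H(6)", ""),
    ("GlyGly@K", "C(4)H(6)N(2)O(2)", ""),
    ("Succinyl@K", "C(4)H(4)O(3)", ""),
    ("Malonyl@K", "C(3)H(2)O(3)", ""),
    ("Deamidated@N", "H(-1)N(-1)O(1)", ""),
    ("Deamidated@Q", "H(-1)N(-1)O(1)", ""),
    ("Gln->pyro-Glu@Q", "H(-3)N(-1)", ""),
    ("Cysteinyl@C", "C(3)H(5)N(1)O(2)S(1)", ""),
    ("Biotin@K", "C(10)H(14)N(2)O(2)S(1)", ""),
]


class ModificationRegistry:
    """Name -> :class:`Modification` mapping with TSV (de)serialization."""

    def __init__(self, load_builtin: bool = True) -> None:
        self._mods: dict[str, Modification] = {}
        if load_builtin:
            for name, comp, loss in _BUILTIN:
                self.register(name, comp, loss)

    def register(
        self,
        name: str,
        composition: str | dict[str, int] = "",
        modloss: str | dict[str, int] = "",
        replace: bool = False,
    ) -> Modification:
        if name in self._mods and not replace:
            raise ValueError(
                f"modification {name!r} already registered; pass replace=True "
                "to overwrite"
            )
        if isinstance(composition, str):
            composition = chem.parse_composition(composition)
        if isinstance(modloss, str):
            modloss = chem.parse_composition(modloss)
        mod = Modification(name, dict(composition), dict(modloss))
        self._mods[name] = mod
        return mod

    def __getitem__(self, name: str) -> Modification:
        try:
            return self._mods[name]
        except KeyError:
            raise KeyError(f"unregistered modification: {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._mods

    def __iter__(self):
        return iter(self._mods.values())

    def __len__(self) -> int:
        return len(self._mods)

    def names(self) -> list[str]:
        return list(self._mods)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tcomposition\tmodloss_composition\n")
            for mod in self:
                fh.write(
                    f"{mod.name}\t{chem.format_composition(mod.composition)}"
                    f"\t{chem.format_composition(mod.modloss_composition)}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ModificationRegistry":
        reg = cls(load_builtin=False)
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["name", "composition", "modloss_composition"]:
                raise ValueError(f"unrecognized registry TSV header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                name, comp, loss = (line.rstrip("\n").split("\t") + ["", ""])[:3]
                reg.register(name, comp, loss)
        return reg
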