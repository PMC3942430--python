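"""Species panels: a reference species plus an ordered target panel.

A conservation profile is always expressed with respect to a fixed,
ordered panel of target species; bit ``j`` of every profile refers to
``panel.targets[j]``.  The reference species (the proteome being
profiled) is never part of the target panel — a protein trivially
"exists" in its own species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: The 18-taxon metazoan set used throughout: 7 mammals, 4 non-mammalian
#: vertebrates, and 7 invertebrates (3 of them insects).  Order follows
#: the leaf order of the reference species tree (outgroup first).
METAZOAN_SPECIES: tuple[str, ...] = (
    "sea_anemone",
    "worm",
    "fly",
    "fly_yakuba",
    "bee",
    "sea_urchin",
    "ciona",
    "zebrafish",
    "lizard",
    "chicken",
    "zebra_finch",
    "platypus",
    "opossum",
    "cow",
    "human",
    "chimpanzee",
    "mouse",
    "rat",
)

#: The 11 vertebrates among the metazoan set (a monophyletic clade).
VERTEBRATES: frozenset[str] = frozenset(
    {
        "zebrafish",
        "lizard",
        "chicken",
        "zebra_finch",
        "platypus",
        "opossum",
        "cow",
        "human",
        "chimpanzee",
        "mouse",
        "rat",
    }
)


@dataclass(frozen=True)
class SpeciesPanel:
    """A reference species and the ordered panel of target species.

    Parameters
    ----------
    reference
        Name of the reference species whose proteome is profiled.
    targets
        Ordered names of the target species; the order is fixed and
        defines the bit positions of every conservation profile.
    """

    reference: str
    targets: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        targets = tuple(self.targets)
        object.__setattr__(self, "targets", targets)
        names = (self.reference,) + targets
        if len(set(names)) != len(names):
            raise ValueError("panel species names must be unique")
        if self.reference in targets:
            raise ValueError("reference species cannot be a target")
        if not targets:
            raise ValueError("panel needs at least one target species")

    @property
    def k(self) -> int:
        """Number of target species (profile length)."""
        return len(self.targets)

    @property
    def all_species(self) -> frozenset[str]:
        """Reference plus targets."""
        return frozenset((self.reference,) + self.targets)

    def index(self, species: str) -> int:
        """Bit position of a target species."""
        return self.targets.index(species)


def default_panel(reference: str = "human") -> SpeciesPanel:
    """The 17-target metazoan panel for a given reference species."""
    if reference not in METAZOAN_SPECIES:
        raise ValueError(
            f"unknown reference {reference!r}; expected one of {METAZOAN_SPECIES}"
        )
    targets = tuple(s for s in METAZOAN_SPECIES if s != reference)
    return SpeciesPanel(reference=reference, targets=targets)
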