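"""Reciprocal-cross designs for hybrid allele-specific analysis.

A hybrid pair such as ``BC/CB`` denotes the two reciprocal F1 crosses between
two inbred parents (here B73 x CAU5 and CAU5 x B73).  The first letter of a
cross id names the maternal parent.  The tissue fixes the expected
maternal:paternal read ratio under unbiased expression: 1:1 in the diploid
embryo and 2:1 in the triploid endosperm (two maternal genome copies).
"""

from __future__ import annotations

from dataclasses import dataclass

TISSUES = ("embryo", "endosperm")

#: Default inbred-line letter codes used by the simulator and fixtures.
PARENT_CODES = {"B": "B73", "M": "Mo17", "C": "CAU5"}

#: The three reciprocal hybrid pairs of the default study design.
DEFAULT_HYBRIDS = ("BC/CB", "MC/CM", "BM/MB")


class DesignError(ValueError):
    """Raised for inconsistent cross/tissue configuration."""


@dataclass(frozen=True)
class CrossDesign:
    """One cross x tissue unit with its expected maternal:paternal ratio."""

    cross: str
    maternal: str
    paternal: str
    tissue: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DesignError(f"unknown tissue {self.tissue!r}")
        if self.maternal == self.paternal:
            raise DesignError("maternal and paternal parents must differ")

    @property
    def expected_ratio(self) -> float:
        """Maternal:paternal ratio r (maternal expectation is r/(r+1))."""
        return 2.0 if self.tissue == "endosperm" else 1.0

    @property
    def parents(self) -> frozenset[str]:
        return frozenset((self.maternal, self.paternal))

    def genotype_of(self, role: str) -> str:
        """Resolve 'maternal'/'paternal' to the parent genotype id."""
        if role == "maternal":
            return self.maternal
        if role == "paternal":
            return self.paternal
        raise DesignError(f"unknown allele role {role!r}")

    def role_of(self, genotype: str) -> str:
        """Inverse of :meth:`genotype_of`."""
        if genotype == self.maternal:
            return "maternal"
        if genotype == self.paternal:
            return "paternal"
        raise DesignError(f"{genotype!r} is not a parent of cross {self.cross}")


def parse_hybrid(hybrid: str) -> tuple[str, str]:
    """Split a hybrid pair id like ``'BC/CB'`` into its two cross ids."""
    try:
        fwd, rev = hybrid.split("/")
    except ValueError as exc:
        raise DesignError(f"hybrid id {hybrid!r} is not 'XY/YX'") from exc
    if fwd[::-1] != rev:
        raise DesignError(f"{hybrid!r}: crosses are not reciprocal")
    return fwd, rev


def cross_design(cross: str, tissue: str,
                 parent_codes: dict[str, str] | None = None) -> CrossDesign:
    """Build a :class:`CrossDesign` from a two-letter cross id.

    The first letter is the maternal parent, the second the paternal parent.
    """
    codes = PARENT_CODES if parent_codes is None else parent_codes
    if len(cross) != 2 or cross[0] not in codes or cross[1] not in codes:
        raise DesignError(f"cannot resolve parents of cross id {cross!r}")
    return CrossDesign(cross=cross, maternal=codes[cross[0]],
                       paternal=codes[cross[1]], tissue=tissue)


def hybrid_designs(hybrid: str, tissue: str) -> tuple[CrossDesign, CrossDesign]:
    """The forward and reverse :class:`CrossDesign` of a hybrid pair."""
    fwd, rev = parse_hybrid(hybrid)
    return cross_design(fwd, tissue), cross_design(rev, tissue)
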