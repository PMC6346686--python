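"""Recognition-site model for restriction-modification (R-M) specificities.

Staphylococcus aureus lineage-specific Type I R-M systems (collectively
"Sau1") recognise bipartite, asymmetric sites: two short specific
half-sites separated by a fixed-length run of unspecified nucleotides,
written here in ``X-n-Y`` notation, e.g. ``CCAY-5-TTAA`` (4 specified
bases, 5-nt spacer, 4 specified bases). Type II enzymes such as Sau3A
(``GATC``) and Sau96I (``GGNCC``) recognise contiguous sites. Both kinds
use the full IUPAC degenerate nucleotide alphabet.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "RMType",
    "RecognitionSite",
    "BaseComposition",
    "SiteNotationError",
    "expand_iupac",
    "iupac_complement",
    "reverse_complement_iupac",
    "parse_site_notation",
    "format_site_notation",
    "reverse_complement_site",
    "is_palindromic",
    "concrete_words",
]

#: IUPAC nucleotide ambiguity codes -> concrete base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC complement (R<->Y, K<->M, B<->V, D<->H; W, S, N self-complementary).
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "W": "W", "S": "S",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)


class SiteNotationError(ValueError):
    """Raised for malformed recognition-site notation."""


class RMType(str, enum.Enum):
    """Restriction-modification system type."""

    TYPE_I = "TypeI"
    TYPE_II = "TypeII"


def expand_iupac(code: str) -> frozenset[str]:
    """Return the set of concrete bases an IUPAC code stands for.

    >>> sorted(expand_iupac("R"))
    ['A', 'G']
    """
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise SiteNotationError(f"not an IUPAC nucleotide code: {code!r}") from None


def iupac_complement(code: str) -> str:
    try:
        return IUPAC_COMPLEMENT[code.upper()]
    except KeyError:
        raise SiteNotationError(f"not an IUPAC nucleotide code: {code!r}") from None


def reverse_complement_iupac(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) IUPAC string."""
    return "".join(iupac_complement(c) for c in reversed(seq))


@dataclass(frozen=True)
class RecognitionSite:
    """One R-M recognition specificity.

    ``part5`` and ``part3`` are the 5' and 3' specific components; for a
    contiguous (Type II style) site ``part3`` is empty and ``spacer`` is 0.
    ``width`` is the total footprint on the duplex:
    ``len(part5) + spacer + len(part3)``.
    """

    name: str
    enzyme: str
    rm_type: RMType
    part5: str
    spacer: int = 0
    part3: str = ""

    def __post_init__(self) -> None:
        if not self.part5:
            raise SiteNotationError(f"{self.name}: empty 5' component")
        for half in (self.part5, self.part3):
            for c in half:
                if c not in IUPAC_ALPHABET:
                    raise SiteNotationError(
                        f"{self.name}: invalid IUPAC letter {c!r} in {half!r}"
                    )
        if self.spacer < 0:
            raise SiteNotationError(f"{self.name}: negative spacer")
        # contiguous  <=>  spacer == 0 and no 3' part
        if (self.spacer == 0) != (self.part3 == ""):
            raise SiteNotationError(
                f"{self.name}: bipartite sites need both a spacer and a 3' "
                f"component (got spacer={self.spacer}, part3={self.part3!r})"
            )

    @property
    def width(self) -> int:
        return len(self.part5) + self.spacer + len(self.part3)

    @property
    def is_bipartite(self) -> bool:
        return self.spacer > 0

    @property
    def notation(self) -> str:
        return format_site_notation(self)

    def position_sets(self) -> list[frozenset[str] | None]:
        """Per-position allowed base sets over the full width.

        Spacer positions are ``None`` (any nucleotide, including ambiguity
        codes in the subject); specified positions are concrete base sets —
        an ambiguous subject base never satisfies a specified position.
        """
        out: list[frozenset[str] | None] = [IUPAC_SETS[c] for c in self.part5]
        out.extend([None] * self.spacer)
        out.extend(IUPAC_SETS[c] for c in self.part3)
        return out


def parse_site_notation(
    notation: str,
    name: str = "",
    enzyme: str = "",
    rm_type: RMType | str = RMType.TYPE_II,
) -> RecognitionSite:
    """Parse ``X-n-Y`` (bipartite) or plain IUPAC (contiguous) notation.

    Input is case-insensitive; the canonical form is uppercase.  The parse
    round-trips: ``format_site_notation(parse_site_notation(s)) == s.upper()``.
    """
    if isinstance(rm_type, str):
        rm_type = RMType(rm_type)
    text = notation.strip().upper()
    if not text:
        raise SiteNotationError("empty notation")
    parts = text.split("-")
    if len(parts) == 1:
        return RecognitionSite(name, enzyme, rm_type, part5=parts[0])
    if len(parts) != 3:
        raise SiteNotationError(
            f"malformed notation {notation!r}: expected IUPAC or IUPAC-n-IUPAC"
        )
    part5, spacer_text, part3 = parts
    if not spacer_text.isdigit():
        raise SiteNotationError(
            f"malformed notation {notation!r}: spacer {spacer_text!r} is not a number"
        )
    if not part3:
        raise SiteNotationError(f"malformed notation {notation!r}: missing 3' half")
    spacer = int(spacer_text)
    if spacer == 0:
        # "X-0-Y" is just a contiguous site written oddly; normalise.
        return RecognitionSite(name, enzyme, rm_type, part5=part5 + part3)
    return RecognitionSite(name, enzyme, rm_type, part5=part5, spacer=spacer, part3=part3)


def format_site_notation(site: RecognitionSite) -> str:
    if site.is_bipartite:
        return f"{site.part5}-{site.spacer}-{site.part3}"
    return site.part5


def reverse_complement_site(site: RecognitionSite) -> RecognitionSite:
    """The same specificity read on the complementary strand.

    For a bipartite site the halves swap and are individually
    reverse-complemented; the spacer length is preserved.  The operation is
    an involution.
    """
    if site.is_bipartite:
        return RecognitionSite(
            name=site.name,
            enzyme=site.enzyme,
            rm_type=site.rm_type,
            part5=reverse_complement_iupac(site.part3),
            spacer=site.spacer,
            part3=reverse_complement_iupac(site.part5),
        )
    return RecognitionSite(
        name=site.name,
        enzyme=site.enzyme,
        rm_type=site.rm_type,
        part5=reverse_complement_iupac(site.part5),
    )


def is_palindromic(site: RecognitionSite) -> bool:
    """True iff the site equals its own reverse complement component-wise."""
    rc = reverse_complement_site(site)
    return (rc.part5, rc.spacer, rc.part3) == (site.part5, site.spacer, site.part3)


def concrete_words(site: RecognitionSite) -> set[str]:
    """Enumerate every concrete width-mer the site matches.

    Exponential in degeneracy; intended for small widths (oracle checks).
    """
    words = [""]
    for s in site.position_sets():
        bases = "ACGT" if s is None else sorted(s)
        words = [w + b for w in words for b in bases]
    return set(words)


@dataclass(frozen=True)
class BaseComposition:
    """IID base probabilities (A, C, G, T), the null for site statistics."""

    a: float
    c: float
    g: float
    t: float

    def __post_init__(self) -> None:
        probs = (self.a, self.c, self.g, self.t)
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"probabilities outside [0,1]: {probs}")
        if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)!r}")

    @classmethod
    def uniform(cls) -> "BaseComposition":
        return cls(0.25, 0.25, 0.25, 0.25)

    def __getitem__(self, base: str) -> float:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}[base]

    def as_dict(self) -> dict[str, float]:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t}
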