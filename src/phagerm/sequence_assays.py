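"""Accessory sequence computations: in-silico PCR and codon-level
annotation of single-nucleotide substitutions in a CDS.

The PCR model is a presence/absence probe: exact matching (optionally with
a mismatch allowance at specified positions), IUPAC degeneracy in the
primer treated as degeneracy rather than mismatch, no melting-temperature
or 3'-anchoring heuristics, no product-size window.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

from Bio.Seq import Seq

from .genome import GenomeRecord, reverse_complement
from .motif_model import IUPAC_ALPHABET, expand_iupac

__all__ = [
    "Primer",
    "Amplicon",
    "Consequence",
    "VariantAnnotation",
    "find_amplicons",
    "annotate_cds_substitution",
]

logger = logging.getLogger(__name__)

#: NCBI translation table for bacteria/archaea (the S. aureus chromosome).
BACTERIAL_TABLE = 11

START_CODONS = {"ATG", "GTG", "TTG"}


@dataclass(frozen=True)
class Primer:
    """An oligonucleotide, written 5'->3', IUPAC degeneracy allowed."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.name}: empty primer")
        bad = set(seq) - IUPAC_ALPHABET
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


class TemplateOrientation(str, enum.Enum):
    AS_GIVEN = "as_given"
    REVERSE_COMPLEMENTED = "reverse_complemented"


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product; coordinates are 1-based inclusive on the
    template's forward strand and span both primer footprints."""

    start: int
    end: int
    template_orientation: TemplateOrientation

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _mismatches(primer: Primer, subject: str, pos0: int) -> int:
    """Mismatch count of the primer laid on subject[pos0:], degeneracy-aware."""
    n = 0
    for offset, code in enumerate(primer.sequence):
        if subject[pos0 + offset] not in expand_iupac(code):
            n += 1
    return n


def _primer_hits(primer: Primer, subject: str, max_mismatch: int) -> list[int]:
    k = len(primer)
    return [
        i for i in range(len(subject) - k + 1)
        if _mismatches(primer, subject, i) <= max_mismatch
    ]


def find_amplicons(
    template: GenomeRecord,
    fwd: Primer,
    rev: Primer,
    max_mismatch: int = 0,
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on a template.

    A product requires the forward primer annealed on one strand and the
    reverse primer on the opposite strand downstream, 3' ends facing
    inward and footprints non-overlapping.  Both template orientations are
    searched; results are sorted by length then start.
    """
    seq = template.sequence
    products: set[Amplicon] = set()

    # fwd on plus strand, rev on minus strand (its footprint on plus
    # coordinates is revcomp(rev) read forward)
    rev_rc = Primer(rev.name, reverse_complement(rev.sequence))
    fwd_rc = Primer(fwd.name, reverse_complement(fwd.sequence))
    for s in _primer_hits(fwd, seq, max_mismatch):
        for t in _primer_hits(rev_rc, seq, max_mismatch):
            if t >= s + len(fwd):
                products.add(
                    Amplicon(s + 1, t + len(rev), TemplateOrientation.AS_GIVEN)
                )
    # fwd on minus strand, rev on plus strand (the same physical product
    # read off the complementary strand of the template)
    for s in _primer_hits(rev, seq, max_mismatch):
        for t in _primer_hits(fwd_rc, seq, max_mismatch):
            if t >= s + len(rev):
                products.add(
                    Amplicon(s + 1, t + len(fwd), TemplateOrientation.REVERSE_COMPLEMENTED)
                )
    return sorted(products, key=lambda a: (a.length, a.start, a.template_orientation.value))


class Consequence(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"


@dataclass(frozen=True)
class VariantAnnotation:
    cds_position: int
    codon_index: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: Consequence
    residues_lost: int | None = None


def annotate_cds_substitution(
    cds: str,
    cds_position: int,
    alt_base: str,
    genetic_code: int = BACTERIAL_TABLE,
) -> VariantAnnotation:
    """Codon-level consequence of a single-nucleotide substitution.

    ``cds`` must be a complete CDS (length divisible by 3, including the
    terminal stop codon); ``cds_position`` is 1-based within the CDS.  For
    a nonsense change the number of C-terminal residues lost is computed
    against the full protein length ``len(cds)/3 - 1`` (stop excluded).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if cds[:3] not in START_CODONS:
        warnings.warn(f"CDS does not begin with a start codon ({cds[:3]})", stacklevel=2)
    if not 1 <= cds_position <= len(cds):
        raise ValueError(f"position {cds_position} outside CDS of length {len(cds)}")
    alt_base = alt_base.upper()
    if alt_base not in "ACGT":
        raise ValueError(f"alternative base must be concrete, got {alt_base!r}")
    ref_base = cds[cds_position - 1]
    if alt_base == ref_base:
        raise ValueError(f"position {cds_position}: alternative equals reference {ref_base}")

    codon_index = (cds_position - 1) // 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    within = (cds_position - 1) % 3
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    ref_aa = str(Seq(ref_codon).translate(table=genetic_code))
    alt_aa = str(Seq(alt_codon).translate(table=genetic_code))

    if alt_aa == ref_aa:
        consequence = Consequence.SYNONYMOUS
    elif alt_aa == "*" and ref_aa != "*":
        consequence = Consequence.NONSENSE
    else:
        consequence = Consequence.MISSENSE

    residues_lost = None
    if consequence is Consequence.NONSENSE:
        protein_length = len(cds) // 3 - 1
        residues_lost = protein_length - codon_index + 1

    return VariantAnnotation(
        cds_position=cds_position,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        residues_lost=residues_lost,
    )
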