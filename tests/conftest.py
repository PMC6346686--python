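"""Shared fixtures and an independent brute-force scanning oracle.

The oracle re-derives duplex-locus counting from first principles: its own
IUPAC table, its own reverse complement, a check of every start position in
both orientations, and interval-level deduplication.  It shares no code
with the package's scanner.
"""

from __future__ import annotations

import pytest

import phagerm as pm

ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_COMPLEMENT = str.maketrans("ACGTRYWSKMBDHVN", "TGCAYRWSMKVHDBN")


def oracle_pattern(site: pm.RecognitionSite) -> list[str | None]:
    """Per-position allowed bases; None marks a spacer position."""
    out: list[str | None] = [ORACLE_IUPAC[c] for c in site.part5]
    out += [None] * site.spacer
    out += [ORACLE_IUPAC[c] for c in site.part3]
    return out


def oracle_revcomp_pattern(site: pm.RecognitionSite) -> list[str | None]:
    full = site.part5 + "n" * site.spacer + site.part3
    rc = full.translate(ORACLE_COMPLEMENT)[::-1]
    return [None if c == "n" else ORACLE_IUPAC[c] for c in rc]


def _fits(seq: str, pattern: list[str | None], start: int, L: int, circular: bool) -> bool:
    for offset, allowed in enumerate(pattern):
        idx = start + offset
        if idx >= L:
            if not circular:
                return False
            idx -= L
        if allowed is not None and seq[idx] not in allowed:
            return False
    return True


def oracle_duplex_starts(genome: pm.GenomeRecord, site: pm.RecognitionSite) -> set[int]:
    """0-based duplex-locus starts: union of both orientations, deduplicated."""
    seq, L, w = genome.sequence, len(genome), site.width
    circular = genome.topology is pm.Topology.CIRCULAR
    fwd = oracle_pattern(site)
    rev = oracle_revcomp_pattern(site)
    last = L if circular else L - w + 1
    return {
        s for s in range(max(last, 0))
        if _fits(seq, fwd, s, L, circular) or _fits(seq, rev, s, L, circular)
    }


@pytest.fixture(scope="session")
def registry() -> pm.Registry:
    return pm.load_registry()


def make_site(notation: str, name: str = "site", rm_type: str = "TypeI") -> pm.RecognitionSite:
    return pm.parse_site_notation(notation, name=name, rm_type=rm_type)


@pytest.fixture(scope="session")
def gatc() -> pm.RecognitionSite:
    return make_site("GATC", "Sau3A", "TypeII")


@pytest.fixture(scope="session")
def cc22_site() -> pm.RecognitionSite:
    return make_site("AGG-6-TGAR", "CC22-1")
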