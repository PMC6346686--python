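"""Duplex-locus scanning for R-M recognition sites.

A recognition site sits on double-stranded DNA: a locus where the pattern
matches in either orientation is one cleavable target.  The scanner
therefore reports *duplex loci*: forward-strand intervals ``[start, end]``
(1-based inclusive) where the site matches in the forward orientation, the
reverse orientation, or both.  A palindromic site (``GATC``) matches both
orientations at the same interval and is counted once there, with
``orientation = forward`` by convention.  Overlapping loci are all
reported — each is a potential cleavage target.

Matching semantics: IUPAC degeneracy in the *site* is degeneracy; ambiguity
in the *subject* (e.g. ``N`` in a draft assembly) satisfies only spacer
positions, never specified positions (conservative counting).
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass

from .genome import GenomeRecord, Topology
from .motif_model import (
    IUPAC_ALPHABET,
    RecognitionSite,
    is_palindromic,
    reverse_complement_site,
)

__all__ = ["Orientation", "SiteMatch", "matches_at", "scan_duplex", "count_duplex_loci"]

logger = logging.getLogger(__name__)

_SPACER_CLASS = "[" + "".join(sorted(IUPAC_ALPHABET)) + "]"


class Orientation(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass(frozen=True)
class SiteMatch:
    """One duplex locus. Coordinates are 1-based inclusive on the forward
    strand; for circular genomes a wrap-around match has ``end < start``."""

    site_name: str
    start: int
    end: int
    orientation: Orientation
    matched_text: str


def _site_regex(site: RecognitionSite) -> re.Pattern[str]:
    parts = []
    for s in site.position_sets():
        parts.append(_SPACER_CLASS if s is None else "[" + "".join(sorted(s)) + "]")
    # lookahead so overlapping loci are all found
    return re.compile("(?=(" + "".join(parts) + "))")


def matches_at(
    genome: GenomeRecord,
    site: RecognitionSite,
    start: int,
    orientation: Orientation = Orientation.FORWARD,
) -> bool:
    """Does the site match the forward strand at 1-based ``start``?

    ``orientation=reverse`` tests the reverse-complemented pattern at the
    same forward-strand interval (i.e. a site on the other strand).
    """
    L = len(genome)
    w = site.width
    if genome.topology is Topology.LINEAR:
        if start < 1 or start > L - w + 1:
            raise ValueError(
                f"start {start} out of range [1, {L - w + 1}] for linear genome"
            )
    else:
        if start < 1 or start > L:
            raise ValueError(f"start {start} out of range [1, {L}]")
    pattern = site if orientation is Orientation.FORWARD else reverse_complement_site(site)
    seq = genome.sequence
    for offset, allowed in enumerate(pattern.position_sets()):
        base = seq[(start - 1 + offset) % L]
        if allowed is not None and base not in allowed:
            return False
    return True


def scan_duplex(genome: GenomeRecord, site: RecognitionSite) -> list[SiteMatch]:
    """All duplex loci for ``site`` in ``genome``, ordered by start.

    Forward- and reverse-orientation matches at the same interval are
    deduplicated into one match (orientation forward).  For circular
    genomes the scan wraps across the origin.
    """
    L = len(genome)
    w = site.width
    if genome.topology is Topology.LINEAR and L < w:
        logger.warning(
            "genome %s (%d nt) shorter than site %s (%d nt); no loci",
            genome.identifier, L, site.name, w,
        )
        return []

    if genome.topology is Topology.CIRCULAR:
        subject = genome.sequence + genome.sequence[: w - 1]
    else:
        subject = genome.sequence

    starts: dict[int, Orientation] = {}
    for m in _site_regex(site).finditer(subject):
        if m.start() < L:
            starts[m.start()] = Orientation.FORWARD
    if not is_palindromic(site):
        rc = reverse_complement_site(site)
        for m in _site_regex(rc).finditer(subject):
            if m.start() < L:
                starts.setdefault(m.start(), Orientation.REVERSE)

    matches = []
    for start0 in sorted(starts):
        end0 = start0 + w - 1
        text = subject[start0 : start0 + w]
        matches.append(
            SiteMatch(
                site_name=site.name,
                start=start0 + 1,
                end=end0 % L + 1 if genome.topology is Topology.CIRCULAR else end0 + 1,
                orientation=starts[start0],
                matched_text=text,
            )
        )
    return matches


def count_duplex_loci(genome: GenomeRecord, site: RecognitionSite) -> int:
    return len(scan_duplex(genome, site))
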