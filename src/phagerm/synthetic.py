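"""Seeded synthetic-sequence generators.

Every input class the pipeline consumes can be generated deterministically:
random genomes of controlled composition, genomes with an exact planted
number of recognition-site loci and no spurious matches, PCR templates
with a known amplicon, and CDSs with a chosen codon at a chosen position.
All generators are pure functions of their arguments including the seed.

Planting works by rejection: lay down a random background, insert concrete
instantiations of the requested sites at non-overlapping positions, then
repeatedly destroy accidental matches (of the planted site and of any
other site that must stay absent) by resampling one position per offending
locus — choosing a base that breaks the spurious match while staying
compatible with any planted site covering that position — and re-scanning
globally after each round.  The result is re-verified with a naive position-by-
position scan before it is returned; failure to converge raises, never
returns silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeRecord, Topology
from .motif_model import BaseComposition, RecognitionSite, reverse_complement_site
from .sequence_assays import Primer
from .site_scanner import Orientation, SiteMatch

__all__ = [
    "PlantSpec",
    "PlantingError",
    "random_genome",
    "plant_sites",
    "plant_profile",
    "make_pcr_template",
    "make_cds_with_codon",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
)

_DESTRUCTION_ROUNDS = 100
_PLANT_ATTEMPTS = 25


class PlantingError(RuntimeError):
    """Site planting could not satisfy the spec (overcrowded or non-convergent)."""


@dataclass(frozen=True)
class PlantSpec:
    """Request for a genome with exactly ``k`` duplex loci of ``site``."""

    genome_length: int
    site: RecognitionSite
    k: int
    seed: int
    composition: BaseComposition = field(default_factory=BaseComposition.uniform)
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.k * self.site.width > self.genome_length:
            raise PlantingError(
                f"cannot place {self.k} non-overlapping {self.site.width}-nt "
                f"sites in {self.genome_length} nt"
            )


def random_genome(
    length: int,
    comp: BaseComposition | None = None,
    seed: int = 0,
    identifier: str = "synthetic",
    topology: Topology = Topology.LINEAR,
) -> GenomeRecord:
    """IID random genome; identical output for identical arguments."""
    if length < 1:
        raise ValueError("length must be >= 1")
    comp = comp or BaseComposition.uniform()
    rng = np.random.default_rng(seed)
    probs = [comp[b] for b in _BASES]
    seq = "".join(rng.choice(list(_BASES), size=length, p=probs))
    return GenomeRecord(identifier, seq, topology)


# -- naive duplex scanning (internal verification; independent of the regex
#    scanner in site_scanner) -------------------------------------------------

def _pattern_matches(seq: str, sets, start0: int, L: int, wrap: bool) -> bool:
    for offset, allowed in enumerate(sets):
        idx = start0 + offset
        if idx >= L:
            if not wrap:
                return False
            idx %= L
        if allowed is not None and seq[idx] not in allowed:
            return False
    return True


def naive_duplex_starts(seq: str, site: RecognitionSite, topology: Topology) -> dict[int, list[str]]:
    """0-based start -> orientations matching there ('fwd'/'rev')."""
    L = len(seq)
    w = site.width
    wrap = topology is Topology.CIRCULAR
    fwd_sets = site.position_sets()
    rev_sets = reverse_complement_site(site).position_sets()
    last = L if wrap else L - w + 1
    hits: dict[int, list[str]] = {}
    for s in range(max(last, 0)):
        orientations = []
        if _pattern_matches(seq, fwd_sets, s, L, wrap):
            orientations.append("fwd")
        if rev_sets != fwd_sets and _pattern_matches(seq, rev_sets, s, L, wrap):
            orientations.append("rev")
        if orientations:
            hits[s] = orientations
    return hits


def _instantiate(sets, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(sorted(allowed) if allowed is not None else list(_BASES))
        for allowed in sets
    )


def _choose_starts(
    rng: np.random.Generator, length: int, widths: list[int]
) -> list[int] | None:
    """Non-overlapping 0-based starts for intervals of the given widths."""
    chosen: list[tuple[int, int]] = []
    starts: list[int] = []
    for w in widths:
        placed = False
        for _ in range(2000):
            s = int(rng.integers(0, length - w + 1))
            if all(s + w <= a or s >= a + b for a, b in chosen):
                chosen.append((s, w))
                starts.append(s)
                placed = True
                break
        if not placed:
            return None
    return starts


def _destroy_locus(
    seq: list[str],
    site: RecognitionSite,
    start0: int,
    orientations: list[str],
    constraint: dict[int, frozenset[str]],
    L: int,
    rng: np.random.Generator,
) -> bool:
    """Resample one position to break a spurious match.

    A position qualifies if some base both breaks the spurious pattern
    there and stays compatible with every planted site covering it
    (``constraint``; planted spacer and degenerate positions remain
    mutable within their allowed sets).
    """
    sets = (site if orientations[0] == "fwd" else reverse_complement_site(site)).position_sets()
    candidates = []
    for offset, allowed in enumerate(sets):
        if allowed is None:
            continue
        pos = (start0 + offset) % L
        choices = constraint.get(pos, frozenset(_BASES)) - allowed
        if choices:
            candidates.append((pos, choices))
    if not candidates:
        return False
    pos, choices = candidates[int(rng.integers(0, len(candidates)))]
    seq[pos] = str(rng.choice(sorted(choices)))
    return True


def _plant(
    length: int,
    counts: dict[str, int],
    sites: dict[str, RecognitionSite],
    comp: BaseComposition,
    seed: int,
    topology: Topology,
    identifier: str,
) -> tuple[GenomeRecord, list[SiteMatch]]:
    """Genome with exactly counts[name] duplex loci per site, 0 spurious.

    Sites present in ``sites`` but absent from ``counts`` are held at zero.
    """
    rng = np.random.default_rng(seed)
    planted_names = [n for n, k in counts.items() if k > 0]
    widths = [sites[n].width for n in planted_names for _ in range(counts[n])]
    if sum(widths) > length:
        raise PlantingError(f"{sum(widths)} planted nt exceed genome length {length}")

    last_error = "placement failed"
    for _ in range(_PLANT_ATTEMPTS):
        seq = list(random_genome(length, comp, int(rng.integers(0, 2**31))).sequence)
        starts = _choose_starts(rng, length, widths)
        if starts is None:
            last_error = "could not place non-overlapping sites"
            continue

        order = [n for n in planted_names for _ in range(counts[n])]
        truth: dict[str, list[int]] = {n: [] for n in sites}
        constraint: dict[int, frozenset[str]] = {}
        for name, s in zip(order, starts):
            position_sets = sites[name].position_sets()
            word = _instantiate(position_sets, rng)
            seq[s : s + len(word)] = word
            truth[name].append(s)
            for offset, allowed in enumerate(position_sets):
                if allowed is not None:
                    constraint[s + offset] = allowed

        converged = False
        for _ in range(_DESTRUCTION_ROUNDS):
            spurious = []
            for name, site in sites.items():
                hits = naive_duplex_starts("".join(seq), site, topology)
                for s, orientations in hits.items():
                    if s not in truth[name]:
                        spurious.append((site, s, orientations))
            if not spurious:
                converged = True
                break
            stuck = False
            for site, s, orientations in spurious:
                if not _destroy_locus(seq, site, s, orientations, constraint, length, rng):
                    stuck = True
            if stuck:
                last_error = "spurious locus pinned by planted-site constraints"
                break
        if not converged:
            last_error = last_error if last_error else "destruction did not converge"
            continue

        genome = GenomeRecord(identifier, "".join(seq), topology)
        matches = []
        for name in sites:
            observed = naive_duplex_starts(genome.sequence, sites[name], topology)
            if sorted(observed) != sorted(truth[name]):
                raise PlantingError(f"verification failed for {name}")  # pragma: no cover
            for s in sorted(truth[name]):
                w = sites[name].width
                matches.append(
                    SiteMatch(
                        site_name=name,
                        start=s + 1,
                        end=s + w,
                        orientation=Orientation.FORWARD,
                        matched_text=genome.sequence[s : s + w],
                    )
                )
        return genome, matches

    raise PlantingError(f"planting failed after {_PLANT_ATTEMPTS} attempts: {last_error}")


def plant_sites(spec: PlantSpec) -> tuple[GenomeRecord, list[SiteMatch]]:
    """Genome with exactly ``spec.k`` duplex loci of ``spec.site``."""
    return _plant(
        length=spec.genome_length,
        counts={spec.site.name: spec.k},
        sites={spec.site.name: spec.site},
        comp=spec.composition,
        seed=spec.seed,
        topology=spec.topology,
        identifier=f"planted_{spec.site.name}_k{spec.k}",
    )


def plant_profile(
    length: int,
    counts: dict[str, int],
    sites: list[RecognitionSite],
    seed: int,
    comp: BaseComposition | None = None,
    topology: Topology = Topology.LINEAR,
    identifier: str = "planted_profile",
) -> tuple[GenomeRecord, list[SiteMatch]]:
    """Genome realising an exact per-site count profile.

    Every site in ``sites`` is controlled: those named in ``counts`` get
    exactly that many duplex loci, all others get zero.  This is how a
    published count table is turned into a concrete test genome.
    """
    site_map = {s.name: s for s in sites}
    unknown = set(counts) - set(site_map)
    if unknown:
        raise KeyError(f"counts refer to unknown sites {sorted(unknown)}")
    return _plant(
        length=length,
        counts=counts,
        sites=site_map,
        comp=comp or BaseComposition.uniform(),
        seed=seed,
        topology=topology,
        identifier=identifier,
    )


def make_pcr_template(
    fwd: Primer,
    rev: Primer,
    insert_len: int,
    seed: int = 0,
    flank_len: int = 50,
    identifier: str = "pcr_template",
) -> GenomeRecord:
    """Template with one guaranteed product: flank + fwd + insert + rc(rev) + flank.

    Degenerate primer positions are instantiated per seed; flanks and
    insert are re-drawn (up to 100 times) until neither primer matches
    anywhere except its intended footprint, on either strand.
    """
    if insert_len < 0 or flank_len < 0:
        raise ValueError("insert_len and flank_len must be >= 0")
    from .genome import reverse_complement  # local to avoid cycle at import time
    from .sequence_assays import _primer_hits

    rng = np.random.default_rng(seed)
    fwd_concrete = _instantiate_primer(fwd, rng)
    rev_concrete = _instantiate_primer(rev, rng)

    for _ in range(100):
        flank5 = "".join(rng.choice(list(_BASES), size=flank_len)) if flank_len else ""
        flank3 = "".join(rng.choice(list(_BASES), size=flank_len)) if flank_len else ""
        insert = "".join(rng.choice(list(_BASES), size=insert_len)) if insert_len else ""
        seq = flank5 + fwd_concrete + insert + reverse_complement(rev_concrete) + flank3

        fwd_plus = _primer_hits(fwd, seq, 0)
        rev_minus = _primer_hits(Primer(rev.name, reverse_complement(rev.sequence)), seq, 0)
        fwd_minus = _primer_hits(Primer(fwd.name, reverse_complement(fwd.sequence)), seq, 0)
        rev_plus = _primer_hits(rev, seq, 0)
        expected_fwd = flank_len
        expected_rev = flank_len + len(fwd) + insert_len
        if (fwd_plus == [expected_fwd] and rev_minus == [expected_rev]
                and not fwd_minus and not rev_plus):
            return GenomeRecord(identifier, seq, Topology.LINEAR)
    raise PlantingError("could not build a template free of extra primer matches")


def _instantiate_primer(primer: Primer, rng: np.random.Generator) -> str:
    from .motif_model import expand_iupac

    return "".join(str(rng.choice(sorted(expand_iupac(c)))) for c in primer.sequence)


def make_cds_with_codon(
    protein_length: int,
    codon_index: int,
    codon: str,
    seed: int = 0,
) -> str:
    """CDS of ``(protein_length + 1) * 3`` nt with ``codon`` at ``codon_index``.

    Codon 1 is ATG (unless the requested codon sits there), internal codons
    are random sense codons, and a random stop codon terminates the frame.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(c not in _BASES for c in codon):
        raise ValueError(f"not a concrete codon: {codon!r}")
    if codon in _STOPS:
        raise ValueError(f"requested codon {codon} is a stop codon")
    if not 1 <= codon_index <= protein_length:
        raise ValueError(
            f"codon_index {codon_index} outside protein of {protein_length} residues"
        )
    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        str(rng.choice(_SENSE_CODONS)) for _ in range(protein_length - 1)
    ]
    codons[codon_index - 1] = codon
    codons.append(str(rng.choice(sorted(_STOPS))))
    return "".join(codons)
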