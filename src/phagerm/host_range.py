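"""Host-range prediction from R-M site counts.

Cleavage by a classical Type I restriction endonuclease requires the
collision of two enzyme complexes translocating toward each other, so a
linear phage chromosome carrying at most one recognition site for a system
escapes it.  A clonal complex (CC) is therefore predicted susceptible
("escape") when every one of its Type I systems finds <= 1 site in the
phage genome, and restriction-limited otherwise.

Type II enzymes cleave at single sites, but the phage studied here retains
two Sau3A (GATC) sites alongside a wide host range, so Type II counts are
reported separately and excluded from the default verdict; pass
``include_type_ii=True`` to fold them in (any Type II site then blocks the
escape prediction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .genome import GenomeRecord
from .motif_model import RecognitionSite, RMType, parse_site_notation
from .site_scanner import count_duplex_loci

__all__ = [
    "CCProfile",
    "Verdict",
    "SusceptibilityVerdict",
    "Registry",
    "RegistryError",
    "load_registry",
    "default_registry_path",
    "predict_cc_susceptibility",
    "predict_all",
    "ConcordanceReport",
    "concordance_report",
]

#: empirical infected/tested fraction at or above which a CC counts as
#: susceptible when scoring concordance (the published comparison is
#: qualitative; 0.5 splits "most strains infected" from "most refractory").
SUSCEPTIBLE_FRACTION = 0.5


class RegistryError(ValueError):
    pass


class Verdict(str, enum.Enum):
    ESCAPE = "predicted_escape"
    RESTRICTION_LIMITED = "predicted_restriction_limited"


@dataclass(frozen=True)
class CCProfile:
    """A clonal complex's active R-M systems plus empirical infection data."""

    clonal_complex: str
    systems: tuple[str, ...]
    infected: int | None = None
    tested: int | None = None

    def __post_init__(self) -> None:
        if not self.systems:
            raise RegistryError(f"{self.clonal_complex}: empty systems list")
        if (self.infected is None) != (self.tested is None):
            raise RegistryError(f"{self.clonal_complex}: partial I/T data")
        if self.infected is not None:
            if not (0 <= self.infected <= self.tested):
                raise RegistryError(
                    f"{self.clonal_complex}: impossible I/T "
                    f"{self.infected}/{self.tested}"
                )

    @property
    def empirical_fraction(self) -> float | None:
        if self.infected is None or not self.tested:
            return None
        return self.infected / self.tested


@dataclass(frozen=True)
class SusceptibilityVerdict:
    clonal_complex: str
    per_system_counts: dict[str, int]
    type_ii_counts: dict[str, int]
    verdict: Verdict
    empirical_fraction: float | None = None
    concordant: bool | None = None


@dataclass(frozen=True)
class Registry:
    sites: tuple[RecognitionSite, ...]
    profiles: tuple[CCProfile, ...]
    printed_counts: dict[str, int] = field(default_factory=dict)

    def site(self, name: str) -> RecognitionSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise RegistryError(f"unknown system name {name!r}")

    @property
    def type_ii_sites(self) -> tuple[RecognitionSite, ...]:
        return tuple(s for s in self.sites if s.rm_type is RMType.TYPE_II)


def default_registry_path() -> Path:
    return Path(resources.files("phagerm") / "data" / "registry.yaml")


def _parse_it(text: str | None) -> tuple[int | None, int | None]:
    if text is None or str(text).strip().upper() in {"", "NT", "NA"}:
        return None, None
    try:
        infected_s, tested_s = str(text).split("/")
        return int(infected_s), int(tested_s)
    except ValueError:
        raise RegistryError(f"malformed I/T value {text!r}") from None


def load_registry(path: str | Path | None = None) -> Registry:
    """Load the recognition-site/CC-profile registry from YAML.

    Validates uniqueness of site names, resolvability of every profile
    system, and I <= T for empirical data.
    """
    path = default_registry_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw or not raw.get("sites"):
        raise RegistryError(f"{path}: registry has no sites")

    sites: list[RecognitionSite] = []
    printed: dict[str, int] = {}
    seen: set[str] = set()
    for row in raw["sites"]:
        name = row["name"]
        if name in seen:
            raise RegistryError(f"duplicate site name {name!r}")
        seen.add(name)
        sites.append(
            parse_site_notation(
                row["notation"], name=name, enzyme=row.get("enzyme", ""),
                rm_type=row.get("rm_type", "TypeII"),
            )
        )
        if row.get("printed_count") is not None:
            printed[name] = int(row["printed_count"])

    profiles: list[CCProfile] = []
    for row in raw.get("profiles", []):
        infected, tested = _parse_it(row.get("i_t"))
        profile = CCProfile(
            clonal_complex=row["clonal_complex"],
            systems=tuple(row["systems"]),
            infected=infected,
            tested=tested,
        )
        for system in profile.systems:
            if system not in seen:
                raise RegistryError(
                    f"{profile.clonal_complex}: unknown system {system!r}"
                )
        profiles.append(profile)

    return Registry(tuple(sites), tuple(profiles), printed)


def _verdict_from_counts(
    type_i_counts: dict[str, int],
    type_ii_counts: dict[str, int],
    include_type_ii: bool,
) -> Verdict:
    escape = all(c <= 1 for c in type_i_counts.values())
    if include_type_ii:
        escape = escape and all(c == 0 for c in type_ii_counts.values())
    return Verdict.ESCAPE if escape else Verdict.RESTRICTION_LIMITED


def predict_cc_susceptibility(
    genome: GenomeRecord,
    profile: CCProfile,
    registry: Registry,
    include_type_ii: bool = False,
    counts: dict[str, int] | None = None,
) -> SusceptibilityVerdict:
    """Scan the genome for the profile's systems and apply the two-site rule.

    ``counts`` may supply precomputed per-site duplex-locus counts (e.g. a
    published table) to avoid rescanning; missing entries are scanned.
    """

    def count_for(site: RecognitionSite) -> int:
        if counts is not None and site.name in counts:
            return counts[site.name]
        return count_duplex_loci(genome, site)

    per_system = {name: count_for(registry.site(name)) for name in profile.systems}
    type_ii = {s.name: count_for(s) for s in registry.type_ii_sites}
    verdict = _verdict_from_counts(per_system, type_ii, include_type_ii)

    fraction = profile.empirical_fraction
    concordant: bool | None = None
    if fraction is not None:
        susceptible = fraction >= SUSCEPTIBLE_FRACTION
        concordant = (verdict is Verdict.ESCAPE) == susceptible
    return SusceptibilityVerdict(
        clonal_complex=profile.clonal_complex,
        per_system_counts=per_system,
        type_ii_counts=type_ii,
        verdict=verdict,
        empirical_fraction=fraction,
        concordant=concordant,
    )


def predict_all(
    genome: GenomeRecord,
    registry: Registry,
    include_type_ii: bool = False,
    counts: dict[str, int] | None = None,
) -> list[SusceptibilityVerdict]:
    return [
        predict_cc_susceptibility(genome, p, registry, include_type_ii, counts)
        for p in registry.profiles
    ]


@dataclass(frozen=True)
class ConcordanceReport:
    """2x2 tally of predicted vs empirical susceptibility across CCs."""

    escape_susceptible: int
    escape_refractory: int
    limited_susceptible: int
    limited_refractory: int
    discordant: tuple[str, ...]
    untested: tuple[str, ...]

    @property
    def n_with_data(self) -> int:
        return (self.escape_susceptible + self.escape_refractory
                + self.limited_susceptible + self.limited_refractory)

    @property
    def agreement_fraction(self) -> float:
        return (self.escape_susceptible + self.limited_refractory) / self.n_with_data


def concordance_report(verdicts: list[SusceptibilityVerdict]) -> ConcordanceReport:
    tally = {(v, s): 0 for v in Verdict for s in (True, False)}
    discordant: list[str] = []
    untested: list[str] = []
    for v in verdicts:
        if v.empirical_fraction is None:
            untested.append(v.clonal_complex)
            continue
        susceptible = v.empirical_fraction >= SUSCEPTIBLE_FRACTION
        tally[(v.verdict, susceptible)] += 1
        if not v.concordant:
            discordant.append(v.clonal_complex)
    if sum(tally.values()) == 0:
        raise ValueError("no verdict carries empirical I/T data")
    return ConcordanceReport(
        escape_susceptible=tally[(Verdict.ESCAPE, True)],
        escape_refractory=tally[(Verdict.ESCAPE, False)],
        limited_susceptible=tally[(Verdict.RESTRICTION_LIMITED, True)],
        limited_refractory=tally[(Verdict.RESTRICTION_LIMITED, False)],
        discordant=tuple(discordant),
        untested=tuple(untested),
    )
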