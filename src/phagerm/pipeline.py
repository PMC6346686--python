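"""End-to-end run: genome in -> site-count table, avoidance report,
host-range verdicts, BED of matches, and a run manifest.

Outputs (a)-(d) are deterministic given identical inputs and config; the
manifest additionally records input hashes, package version, seed and a
timestamp (and is therefore the only output allowed to differ between
otherwise identical runs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .avoidance import avoidance_report
from .genome import GenomeRecord, Topology, read_genome
from .host_range import Registry, concordance_report, load_registry, predict_all
from .site_scanner import SiteMatch, scan_duplex

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "write_bed", "matches_to_bed_rows"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-named pipeline failure."""


@dataclass
class RunConfig:
    genome: str
    out_dir: str
    registry: str | None = None  # None -> shipped registry
    null_model: str = "iid"
    topology: str | None = None  # override; None -> from file/linear
    include_type_ii: bool = False
    seed: int = 0

    def validate(self, require_genome_file: bool = True) -> None:
        if require_genome_file and not Path(self.genome).exists():
            raise PipelineError(f"config: genome file not found: {self.genome}")
        if self.registry is not None and not Path(self.registry).exists():
            raise PipelineError(f"config: registry file not found: {self.registry}")
        if self.null_model not in {"iid", "markov1"}:
            raise PipelineError(f"config: unknown null model {self.null_model!r}")
        if self.topology not in {None, "linear", "circular"}:
            raise PipelineError(f"config: unknown topology {self.topology!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def matches_to_bed_rows(matches: list[SiteMatch], chrom: str) -> list[tuple]:
    """BED6 rows (0-based half-open) from 1-based inclusive matches."""
    rows = []
    for m in matches:
        strand = "+" if m.orientation.value == "forward" else "-"
        rows.append((chrom, m.start - 1, m.start - 1 + len(m.matched_text),
                     m.site_name, 0, strand))
    return rows


def write_bed(matches: list[SiteMatch], chrom: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in matches_to_bed_rows(matches, chrom):
            fh.write("\t".join(map(str, row)) + "\n")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raise stage-named
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(
    config: RunConfig,
    genome: GenomeRecord | None = None,
    registry: Registry | None = None,
) -> dict[str, Path]:
    """Run scan -> avoidance -> host-range on one genome; write reports.

    ``genome``/``registry`` may be passed in-memory (e.g. synthetic
    fixtures); otherwise they are loaded from the config paths.
    """
    config.validate(require_genome_file=genome is None)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if registry is None:
        registry = _stage("load_registry")(load_registry)(config.registry)
    if not registry.sites:
        raise PipelineError("stage 'load_registry' failed: registry has no sites")
    if genome is None:
        genome = _stage("read_genome")(read_genome)(config.genome, config.topology)
    elif config.topology is not None:
        genome = GenomeRecord(genome.identifier, genome.sequence, Topology(config.topology))
    logger.info("scan: genome %s (%d nt, %s), %d registry sites",
                genome.identifier, len(genome), genome.topology.value, len(registry.sites))

    # (a) per-site count table + (d) BED of matches
    scan = _stage("scan")(lambda: {s.name: scan_duplex(genome, s) for s in registry.sites})()
    count_rows = [
        {"site": s.name, "enzyme": s.enzyme, "rm_type": s.rm_type.value,
         "notation": s.notation, "count": len(scan[s.name])}
        for s in registry.sites
    ]
    counts_df = pd.DataFrame(count_rows)
    all_matches = [m for s in registry.sites for m in scan[s.name]]
    logger.info("scan: %d duplex loci across all sites", len(all_matches))

    # (b) avoidance
    avoidance = _stage("avoidance")(avoidance_report)(
        genome, list(registry.sites), config.null_model
    )
    avoid_df = pd.DataFrame(
        [{"site": r.site_name, "notation": r.notation, "observed": r.observed,
          "expected": round(r.expected, 6), "p_under": round(r.p_under, 6),
          "null_model": r.null_model} for r in avoidance]
    )

    # (c) host range + concordance
    counts_by_site = {s.name: len(scan[s.name]) for s in registry.sites}
    verdicts = _stage("host_range")(predict_all)(
        genome, registry, config.include_type_ii, counts=counts_by_site
    )
    hr_rows = []
    for v in verdicts:
        hr_rows.append({
            "clonal_complex": v.clonal_complex,
            "systems": ";".join(f"{k}={c}" for k, c in v.per_system_counts.items()),
            "type_ii": ";".join(f"{k}={c}" for k, c in v.type_ii_counts.items()),
            "verdict": v.verdict.value,
            "empirical_fraction": "" if v.empirical_fraction is None
                                  else round(v.empirical_fraction, 4),
            "concordant": "" if v.concordant is None else v.concordant,
        })
    hr_df = pd.DataFrame(hr_rows)
    concordance = None
    if any(v.empirical_fraction is not None for v in verdicts):
        concordance = _stage("host_range")(concordance_report)(verdicts)

    paths: dict[str, Path] = {}

    def emit(df: pd.DataFrame, stem: str) -> None:
        tsv, js = out / f"{stem}.tsv", out / f"{stem}.json"
        df.to_csv(tsv, sep="\t", index=False)
        js.write_text(json.dumps(df.to_dict(orient="records"), indent=1) + "\n")
        paths[f"{stem}.tsv"], paths[f"{stem}.json"] = tsv, js

    emit(counts_df, "site_counts")
    emit(avoid_df, "avoidance")
    emit(hr_df, "host_range")
    if concordance is not None:
        summary = {
            "escape_susceptible": concordance.escape_susceptible,
            "escape_refractory": concordance.escape_refractory,
            "limited_susceptible": concordance.limited_susceptible,
            "limited_refractory": concordance.limited_refractory,
            "agreement_fraction": concordance.agreement_fraction,
            "discordant": list(concordance.discordant),
            "untested": list(concordance.untested),
        }
        p = out / "concordance.json"
        p.write_text(json.dumps(summary, indent=1) + "\n")
        paths["concordance.json"] = p

    bed = out / "matches.bed"
    write_bed(sorted(all_matches, key=lambda m: (m.start, m.site_name)),
              genome.identifier, bed)
    paths["matches.bed"] = bed

    manifest = {
        "package": "phagerm",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.seed,
        "genome": {"identifier": genome.identifier, "length": len(genome),
                   "topology": genome.topology.value,
                   "path": config.genome,
                   "sha256": _sha256(config.genome) if Path(config.genome).is_file() else None},
        "registry": {"path": config.registry or "shipped",
                     "n_sites": len(registry.sites),
                     "sha256": _sha256(config.registry) if config.registry else None},
        "null_model": config.null_model,
        "include_type_ii": config.include_type_ii,
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1) + "\n")
    paths["manifest.json"] = mpath
    return paths
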