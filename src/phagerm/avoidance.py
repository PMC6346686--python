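"""Site-avoidance statistics.

A phage that has purged recognition sites from its genome escapes the
corresponding R-M systems.  "Lack or sparsity" of a site is quantified
against a composition null: the expected number of duplex loci in a random
sequence with the genome's base composition (iid, or first-order Markov
estimated from the genome), with a lower-tail Poisson test for
under-representation.

The Poisson approximation to the overlapping-window count is standard
motif-statistics practice and is accurate when the per-window probability
is small (lambda << number of windows), which holds for every site in the
shipped registry; it ignores overlap dependence between windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome import GenomeRecord, Topology
from .motif_model import BaseComposition, RecognitionSite, is_palindromic, reverse_complement_site
from .site_scanner import count_duplex_loci

__all__ = [
    "AvoidanceResult",
    "composition_of",
    "transition_matrix_of",
    "site_probability",
    "site_probability_markov1",
    "expected_duplex_count",
    "underrepresentation_pvalue",
    "avoidance_report",
]

_BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class AvoidanceResult:
    site_name: str
    notation: str
    observed: int
    expected: float
    p_under: float
    null_model: str  # "iid" or "markov1"


def composition_of(genome: GenomeRecord) -> BaseComposition:
    """Base frequencies over unambiguous positions (ambiguity codes excluded)."""
    seq = genome.sequence
    counts = np.array([seq.count(b) for b in _BASES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"{genome.identifier}: no unambiguous bases to tally")
    freqs = counts / total
    return BaseComposition(*freqs)


def transition_matrix_of(genome: GenomeRecord) -> np.ndarray:
    """First-order transition frequencies P[i, j] = P(next=j | current=i).

    Estimated from unambiguous adjacent pairs; for circular genomes the
    wrap-around pair is included.  Rows with no observations fall back to
    the marginal composition.
    """
    seq = genome.sequence
    if genome.topology is Topology.CIRCULAR:
        seq = seq + seq[0]
    counts = np.zeros((4, 4))
    for a, b in zip(seq, seq[1:]):
        ia, ib = _INDEX.get(a), _INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    comp = composition_of(genome)
    marginal = np.array([comp[b] for b in _BASES])
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(rows > 0, counts / rows, marginal)
    return P


def site_probability(site: RecognitionSite, comp: BaseComposition) -> float:
    """P(a window drawn iid from ``comp`` matches the site in one orientation).

    Product over specified positions of the summed probabilities of each
    position's base set; spacer positions contribute a factor of 1.
    """
    p = 1.0
    for allowed in site.position_sets():
        if allowed is not None:
            p *= sum(comp[b] for b in allowed)
    return p


def site_probability_markov1(
    site: RecognitionSite, comp: BaseComposition, P: np.ndarray
) -> float:
    """Window match probability under a first-order Markov chain.

    The first position uses the marginal composition; subsequent positions
    use the transition matrix, summing over all concrete words matching the
    site via a forward pass (spacer positions allow all four bases).
    """
    marginal = np.array([comp[b] for b in _BASES])
    sets = site.position_sets()
    mask0 = _set_mask(sets[0])
    v = marginal * mask0
    for allowed in sets[1:]:
        v = (v @ P) * _set_mask(allowed)
    return float(v.sum())


def _set_mask(allowed: frozenset[str] | None) -> np.ndarray:
    if allowed is None:
        return np.ones(4)
    return np.array([1.0 if b in allowed else 0.0 for b in _BASES])


def expected_duplex_count(
    site: RecognitionSite,
    genome_length: int,
    comp: BaseComposition,
    topology: Topology = Topology.LINEAR,
    transition: np.ndarray | None = None,
) -> float:
    """Expected number of duplex loci under the composition null.

    Windows: ``L - width + 1`` (linear) or ``L`` (circular).  A palindromic
    site is counted in one orientation only (mirroring the scanner's
    dedup); a non-palindromic site accrues both orientations, i.e.
    ``W * (p(site) + p(revcomp(site)))`` — equal to ``2*W*p`` when the
    composition is strand-symmetric.
    """
    W = genome_length if topology is Topology.CIRCULAR else genome_length - site.width + 1
    if W <= 0:
        return 0.0
    if transition is None:
        p_fwd = site_probability(site, comp)
        p_rev = site_probability(reverse_complement_site(site), comp)
    else:
        p_fwd = site_probability_markov1(site, comp, transition)
        p_rev = site_probability_markov1(reverse_complement_site(site), comp, transition)
    if is_palindromic(site):
        return W * p_fwd
    return W * (p_fwd + p_rev)


def underrepresentation_pvalue(observed: int, expected: float) -> float:
    """Lower-tail Poisson probability P(X <= observed | lambda = expected).

    Small values mean the observed count is unexpectedly low, i.e. the site
    is avoided.  Degenerate null (expected = 0) returns 1.
    """
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if expected < 0:
        raise ValueError("expected count must be >= 0")
    if expected == 0:
        return 1.0
    return float(stats.poisson.cdf(observed, expected))


def avoidance_report(
    genome: GenomeRecord,
    sites: list[RecognitionSite],
    null_model: str = "iid",
) -> list[AvoidanceResult]:
    """Observed vs expected duplex-locus counts for each site."""
    if null_model not in {"iid", "markov1"}:
        raise ValueError(f"unknown null model {null_model!r}")
    comp = composition_of(genome)
    P = transition_matrix_of(genome) if null_model == "markov1" else None
    results = []
    for site in sites:
        observed = count_duplex_loci(genome, site)
        expected = expected_duplex_count(
            site, len(genome), comp, genome.topology, transition=P
        )
        results.append(
            AvoidanceResult(
                site_name=site.name,
                notation=site.notation,
                observed=observed,
                expected=expected,
                p_under=underrepresentation_pvalue(observed, expected),
                null_model=null_model,
            )
        )
    return results
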