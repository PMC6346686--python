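# Methods

## Recognition-site model

An R-M recognition specificity is a pair of IUPAC strings (5′ and 3′
specific components) separated by a fixed-length spacer of unspecified
nucleotides, written `X-n-Y`; contiguous (Type II style) sites are the
special case `n = 0` with an empty 3′ component, and the two cases are
mutually exclusive by construction. Degeneracy is carried by the standard
15-letter IUPAC alphabet. The reverse complement of a bipartite site swaps
the halves and reverse-complements each (`CCAY-5-TTAA` ↔ `TTAA-5-RTGG`);
the operation is an involution, and a site is palindromic iff it equals
its own reverse complement component-wise (equivalently: its concrete
match set is closed under reverse complement, which the tests verify by
exhaustive enumeration at small widths).

One row of the shipped registry carries a specificity that the source
table annotates as "or complement". No flag is stored for it: the scanner
always considers both orientations of every site, so the annotation is
redundant under duplex-locus semantics.

## Duplex-locus counting

A recognition site sits on double-stranded DNA, so the scanner counts
*duplex loci*: forward-strand intervals where the site matches in either
orientation. Forward- and reverse-orientation matches at the same interval
are deduplicated into one locus (palindromes therefore count once per
locus); overlapping loci are all reported, each being a potential cleavage
target. This convention makes counts invariant under reverse-complementing
the deposited sequence — a property the source data cannot depend on —
and is the semantics assumed throughout (scanner, null model, verdicts).

Matching is asymmetric about ambiguity: IUPAC codes in the *site* denote
degeneracy; ambiguity codes in the *subject* (e.g. `N` in a draft
assembly) satisfy only spacer positions, never specified positions.
This under-counts rather than over-counts sites on imperfect assemblies.

Phage genomes are treated as linear by default ("infecting linear phage
DNA" is the biologically relevant state, and the two-site rule depends on
it); circular scanning wraps the origin and is invariant under rotation.
Coordinates are 1-based inclusive in reports; BED output is 0-based
half-open. The scanner compiles each orientation to a regular expression
with a look-ahead group so overlapping matches are found; the tests hold
it against an independent position-by-position oracle.

## Avoidance statistics

For a site with per-position allowed sets `S_i`, the one-orientation match
probability under an iid null with composition `q` is
`p = Π_i Σ_{b∈S_i} q(b)` (spacer positions contribute 1). With
`W = L − w + 1` windows (linear; `W = L` circular), the expected
duplex-locus count is `λ = W·p` for palindromic sites and
`λ = W·(p(s) + p(s̄))` otherwise — the two orientations at a window are
disjoint events for every specificity in the registry. The closed form
`2·W·p` quoted for the uniform case is recovered whenever the composition
is strand-symmetric (`q(A)=q(T)`, `q(C)=q(G)`); using `p(s) + p(s̄)`
keeps the null correct for skewed compositions.

Under-representation is scored as the Poisson lower tail
`P(X ≤ observed | λ)`, returning 1 for the degenerate null `λ = 0`. The
Poisson approximation ignores the (weak, positive) dependence between
overlapping windows; at the registry's site widths and realistic genome
sizes λ ≪ W and the Monte-Carlo calibration test keeps the closed form
within 3 standard errors of the empirical mean over 2,000 simulated 5-kb
genomes. A first-order Markov null is also provided: transition
frequencies are estimated from the genome's unambiguous dinucleotides
(wrap-around pair included for circular genomes), the first position uses
the marginal composition, and the match probability is computed by a
forward pass over the per-position allowed sets. Higher-order and
codon-preserving nulls, and multiple-testing correction across sites, are
out of scope — the claim being formalised is about counts, not
discoveries.

## Host-range rule

Type I cleavage needs two enzyme complexes translocating toward each
other, so the verdict for a clonal complex is *predicted escape* iff every
one of its Type I systems finds ≤ 1 duplex locus, else *predicted
restriction-limited*. Type II counts are reported alongside but excluded
from the default verdict: the studied phage retains two `GATC` loci while
infecting Sau3A-carrying lineages, so a strict "any Type II site blocks
escape" rule (available as `include_type_ii=True`) would contradict the
observation the rule exists to explain. Concordance against empirical
infected/tested data uses a 0.5 fraction threshold for "susceptible CC";
the published comparison is qualitative and this single number is an
implementation choice, recorded in every report. Discordant CCs are
flagged, not explained: anti-restriction, inactive systems, CRISPR-Cas,
Abi and adsorption effects are outside the model.

## Sequence assays

In-silico PCR is an exact-match presence/absence probe: a product is any
pair of primer footprints on opposite strands with 3′ ends facing inward
and no overlap, searched in both template orientations; primer IUPAC
codes are degeneracy, an optional `max_mismatch` allows mismatches at
specified positions, and no melting-temperature, 3′-anchor or product-size
heuristics are applied (the primer pair the package ships,
OMLO707/OMLO708, was designed as a diagnostic probe, not for
quantification). Product length is the outermost span of both footprints.

CDS substitution annotation is codon arithmetic under the bacterial
genetic code (NCBI table 11): codon index `⌈pos/3⌉`, consequence
synonymous/missense/nonsense, and for nonsense changes the C-terminal
truncation `residues_lost = L/3 − 1 − codon_index + 1` against the
stop-inclusive CDS length. The annotated arlS case (G→T at CDS position
1252, Gly `GGA` codon 418 → `TGA`, 34 residues lost upstream of the
kinase's dimerisation/phospho-acceptor domain) is reproduced on a
synthetic 451-codon CDS built by the generator; the real chromosomal CDS
is not redistributed with the package.

## Synthetic data

All generators are pure functions of their arguments including the seed
(numpy `default_rng`; no global state). The planted-site generator draws
an iid background, writes concrete instantiations of the requested sites
at non-overlapping random positions, then iteratively destroys accidental
matches — of the planted site and of every other site that must stay
absent — by resampling, per offending locus, one position at which some
base both breaks the spurious pattern and remains compatible with any
planted site covering it (planted spacer and degenerate positions stay
mutable within their allowed sets). Each round rescans globally, because a
fix can create a new match elsewhere; rounds are bounded (100) and the
whole construction is retried with derived seeds (25 attempts) before
failing loudly. The result is re-verified against a naive
position-by-position scan before being returned, so a returned genome
always realises the requested count profile exactly.

What the generator emulates: genome length, base composition, exact site
counts, amplifiable templates, codon placement. What it does not: real
genomic correlation structure (repeats, coding bias, terminal repeats),
methylation, or sequencing artefacts. Passing tests therefore demonstrate
the correctness of the counting, statistics and rule machinery on
sequences whose ground truth is known by construction — not the biological
accuracy of the published counts themselves, which require the deposited
genomes.

### Default study conditions

The published-profile genome is built at 17.6 kb (the phage's genome
size) with the registry's published per-site counts; null-model
calibration uses 2,000 genomes of 5 kb (large enough that λ ≈ 20 for the
4-mer sites, small enough to keep the whole suite fast); oracle
equivalence uses genomes up to 2 kb across all registry specificities plus
contrived degenerate sites; planted-site recovery spans k = 0..20 in 4-kb
genomes. The registry's CC93 printed counts follow the accompanying text
where the table itself is ambiguous (no CC93-3 sites, one CC93-2 site),
and the CC8 profile references the sites it shares with CC1/CC5.

## Known limitations

- The expectation model treats orientations as disjoint; a contrived site
  whose forward and reverse-complement match sets intersect on concrete
  words (while not being component-wise palindromic) would be slightly
  over-expected. No registry site has this property.
- Poisson, not compound-Poisson: clumping of self-overlapping sites is
  ignored (negligible at the λ/W ratios involved).
- The in-silico PCR reports all inward-facing pairs with no size cap; on
  repeat-rich templates this can be quadratic in primer-site count.
- Host-range verdicts depend only on counts, never on site positions or
  methylation state.
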