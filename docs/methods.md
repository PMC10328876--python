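# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `vegfsurvey` package — what each stage computes, why the
defaults are what they are, and what the synthetic-data tests do and do not
demonstrate about real data.

## Hit classification

A homology-search hit carries a free-text annotation (its Hit_def), the
clade it came from, and optionally its sequence.  Classification proceeds
in a cascade:

1. **Primary categorization.** The annotation is matched against a synonym
   map: ten ortholog groups (VEGF-A, PlGF, VEGF-B, VEGF-C, VEGF-D, VEGF-F,
   PDGF-A/-B/-C/-D), each with a list of case-insensitive aliases (gene
   symbols such as FIGF for VEGF-D or PGF for PlGF, and spelled-out protein
   names).  Matching is whole-token/whole-phrase: an alias must not be
   embedded in a longer alphanumeric run, so "PGF" never fires inside
   "somePGFlike".  A hit naming the query's own group is *synonymous*, one
   naming a different group is *related*, anything else (e.g. "hypothetical
   protein") is *undefined*.  A related hit whose annotation names exactly
   one foreign group is assigned to that group directly; annotations
   matching several groups at once are demoted to the vote stage rather
   than guessed at.  The shipped alias lists are a documented default and
   are editable via a YAML config; they are deliberately conservative
   (bare "VEGF" or "PDGF" tokens map to no group).
2. **Secondary-search majority vote.** Undefined hits with a sequence of at
   least `min_length` residues (default 60, about half a VEGF homology
   domain) are re-searched through a pluggable provider; a group is
   accepted only if it wins strictly more than 50% of the secondary hits
   whose annotations map unambiguously to a single group.  Uninformative
   secondary annotations do not dilute the denominator — they are exactly
   the records the next stage exists for.  The strict inequality is the
   safeguard: an evenly split vote abstains, so the rule can abstain but
   not mis-assign when no true majority exists.
3. **Profile-search fallback.** Hits still undecided go to a second,
   profile-flavored provider under the same vote rule; after that they are
   reported unresolved.

False positives are flagged on two signals and never receive a group: an
annotation naming a known non-family protein (a configurable blocklist —
Balbiani ring proteins, collagens and other cysteine-rich repeat proteins
dominate it), or a domain architecture consisting of BR3P repeats without
the family signature (see below).  Search providers are plain callables
from a sequence to a hit list; the test suite and the `survey` pipeline use
deterministic fixture providers backed by TSV tables, so no live database
is ever contacted.

**Isoform bucketing.** VEGF-A protein lengths are bucketed against the four
major splice isoforms (mature lengths 121, 165, 189, 206), each represented
by its mature and precursor form (mature + 26-residue signal peptide), with
a ±5-residue tolerance and ties broken toward the shorter isoform.  Bucket
counts can be rendered as a GCD-reduced ratio.  VEGF-B's frame-shifted dual
isoforms are not bucketed programmatically.

**Nearest-reference assignment.** Given a tree containing reference-labeled
leaves, each unlabeled leaf is assigned the group of the reference leaf at
minimal patristic distance; exact ties across groups are reported as
ambiguous rather than broken arbitrarily.

## Motif scanning

The family signature is the relaxed cysteine pattern `P.?C.{2,8}C.?G.?C`;
the BR3P repeat is `C-X10-C-X-C-X(1,3)-C`, with the truncation `C-X10-C-X-C`
(not extendable to a complete repeat) counted as incomplete.  Two
documented readings are baked in: `X` means any residue *including*
cysteine, and repeats are counted by a greedy, non-overlapping,
left-to-right scan in which each residue belongs to at most one repeat.
Greediness has a visible consequence: the optional `X(1,3)` tail will
bridge into a directly adjacent repeat's opening cysteine; repeats
separated by any linker of two or more residues count exactly.  Labels:
signature plus ≥ 2 complete repeats → `VEGF_C_like` (VEGF-C/D-like proteins
carry three to five; the longer VEGF-A isoforms at most one complete
repeat, making 2 the separating value — configurable); signature with fewer
→ `PDGF_VEGF_short`; repeats without signature → `BR3P_only`; neither →
`none`.

## Clade census

The sampling-reliability heuristic is
`log10(n_genomes^2.5 / (n_species · n_proteins + 1))`: more sequenced
genomes raise confidence in absence calls, more known species and more
deposited proteins raise the bar a clade should have cleared.  A clade with
zero sequenced genomes returns −∞, which reports render as a distinguished
`no_data` category rather than a numeric minimum — such clades cannot rank,
they simply lack evidence.  The presence matrix counts assigned unique hits
per (clade, group); false-positive counts are kept per clade (flagged hits
carry no group) and only for clades with at most 500 species, the size
beyond which manual review is not attempted.

WGD projection is arithmetic made explicit: after n whole-genome
duplications a base count b can reach at most b·2^n genes; the expected
range applies retention fractions (default 20–50%, the range within which
ohnologs tend to survive by neo- or subfunctionalization), rounded half
away from zero.  Transcript normalization rescales each species' per-gene
counts by total(reference)/total(species), preserving within-species
ratios.

## Diversity and windowing

Per-column diversity is the inverse Simpson index normalized by alphabet
size, `d = 1/(N·Σ p_i²)`, ranging from 1/N (monomorphic) to 1 (uniform).
Protein mode uses N = 20 and excludes gaps and nonstandard residues from
the frequencies (an all-gap column is undefined, reported NaN); nucleotide
mode uses N = 5 with the gap as a full-fledged fifth state, so alignment
holes themselves register as variation.  Window averaging (default width
11, centered) keeps the window at full width near the edges by clamping it
inside the sequence, shrinking only when the whole input is shorter than
the window; output length always equals input length.

## Per-site selection test

The test is a counting approximation in the SLAC family, applied to a codon
alignment on a rooted tree (≥ 3 sequences; unrooted input errors unless
midpoint rooting is requested):

* **Site fractions.** Each codon's synonymous site fraction S is the sum
  over its three positions of the fraction of single-nucleotide changes at
  that position that are synonymous, with changes to stop codons excluded
  from numerator and denominator; N = 3 − S.  The expected synonymous
  proportion at a site is the mean S/3 over the ungapped codons present.
* **Ancestors.** Ancestral codon states are reconstructed by parsimony over
  the codon states observed at the site (unit cost per state change),
  implemented as a Sankoff-style dynamic program with an inside–outside
  pass that also counts minimum-change labelings exactly.  The reported
  ancestor sets are the states attainable in at least one minimal labeling,
  and per-branch substitution counts weight every (parent, child) state
  pair by the number of minimal labelings realizing it — an exact uniform
  average over all minimal resolutions of the ambiguity, verified against
  brute-force enumeration on small instances.
* **Path averaging.** A branch whose codons differ at k positions
  contributes the average synonymous/nonsynonymous step counts over all k!
  single-nucleotide orderings; orderings passing through a stop codon are
  excluded unless every ordering does.
* **Test.** Observed synonymous and total change counts (fractional after
  averaging; rounded to the nearest integers for the test) enter an exact
  two-sided binomial test against the expected synonymous proportion.  A
  site is called purifying (nonsynonymous deficit) or diversifying (excess)
  when p < α; the default α = 0.001 is used with no multiple-testing
  correction.  Gap-containing codons are skipped per site, with the tree
  pruned accordingly.

**Numerical notes.** dN − dS is reported as n_obs/N̄ − s_obs/S̄ with
zero-denominator terms dropped; invariant or data-free sites report p = 1
and no call; minimal-labeling counts use exact integer arithmetic, so deep
ambiguity cannot overflow or lose precision.

## Synthetic data

Generators emulate every pipeline input with planted truth, byte-
reproducible under an integer seed (numpy PCG64):

* **Hit tables.** A chosen fraction of hits gets uninformative annotations
  and a fixture secondary-hit list agreeing with the planted group at an
  exactly realized rate (the agreement × list-size product must be an
  integer; disagreeing votes are spread so no rival group can reach a
  strict majority); the rest are annotated with an alias of their planted
  group.
* **Domain sequences.** Background residues are drawn from an alphabet
  without cysteine or proline, so neither motif can arise or extend by
  chance and planted counts are exact.  Spacers enforce the two greedy-scan
  adjacency rules above (≥ 10 residues after the signature, whose regex
  spans at most 16; ≥ 2 between repeats).  This is a deliberate
  simplification: real sequences can contain chance cysteines, so exact
  recovery on synthetic data bounds scanner correctness, not annotation
  accuracy on real proteomes.
* **Codon alignments.** Root codons are uniform over the 61 sense codons;
  along each branch a Poisson number of single-nucleotide events per codon
  is proposed (branch length = expected proposals per codon site,
  transitions weighted by κ), stop-creating proposals are rejected,
  synonymous ones accepted, nonsynonymous ones accepted with probability
  ω_site.  This rejection sampler is simple enough to oracle-check and
  adequate for calibration studies; it is not a matrix-exponential
  substitution model and simulates no indels.  The default κ = 1 matches
  the transition-agnostic neutral expectation the counting test assumes;
  raising κ makes synonymous changes relatively more frequent than the
  Nei–Gojobori expectation anticipates (the classic transition bias of
  counting methods) and is exposed for sensitivity analysis, not used in
  the calibration suite.
* **Clade censuses.** Counts log-uniform over several orders of magnitude,
  always including a zero-genome clade (the −∞ path) and a monotone pair
  (same species/protein counts, doubled genomes) whose reliabilities must
  order correctly downstream.

## Calibration and power of the selection test

The calibration suite simulates a balanced 16-taxon tree with total length
50 (in proposed events per codon site) and 300 sites.  The length was fixed
by a design-time power analysis over lengths 20–100 and two topologies
(balanced, radiation-like): it sits on the plateau of the power curve —
long enough to accumulate countable synonymous changes, short enough that
parsimony is not fully saturated.  Under neutrality (ω = 1) the observed
false-call rate at α = 0.001 is 0/300.

Power to call ω = 0.05 sites purifying at α = 0.001 measures ≈ 21–25%
across seeds, and this ceiling is structural rather than a tuning artifact:
a site under strong purifying selection is confined to one synonymous codon
family (2–6 states), which caps the number of changes parsimony can infer
on 16 taxa at roughly 5–9 per site, while the exact binomial at α = 0.001
demands nearly all inferred changes be synonymous against a conditional
expectation of 1/9–1/3.  Even ω = 0 yields only ≈ 65% power, and doubling
the taxa to 32 reaches ≈ 69% — the taxon count, not the implementation, is
the binding constraint.  Counting-style tests are known to be conservative
at strict significance levels; detecting moderate purifying selection per
site reliably needs either more taxa or a likelihood-based rate test, both
outside this package's scope.

## Problem sizes

Defaults throughout the test suite and the acceptance script are sized for
a single CPU: 1000-hit tables over five seeds for the classifier, a
2800-sequence planted-motif grid, 16 taxa × 300 codon sites for the
selection studies, and 500 random ≤ 4-taxon instances for the counting
oracle.  The whole suite runs in well under a minute.

## Known limitations

* Annotation matching is lexical; real-world annotation noise beyond the
  undefined-marker vocabulary (typos, species-specific gene names) is not
  modeled.
* Alignment computation, tree inference and live database searches are
  out of scope by design; trees and alignments are consumed, not built.
* Only the standard genetic code is implemented (a config hook reserves
  the extension point).
* Manual curation steps of a real survey — resolution of truncated
  transcript predictions, VEGF-B isoform assignment — are intentionally
  not reproduced.
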