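# vegfsurvey

Survey machinery for mapping the occurrence of PDGF/VEGF-family growth
factors across the animal kingdom.

The platelet-derived and vascular endothelial growth factors (PDGFs/VEGFs)
form a cystine-knot family with ten named vertebrate ortholog groups
(VEGF-A, PlGF, VEGF-B, VEGF-C, VEGF-D, VEGF-F, PDGF-A/-B/-C/-D).  Surveying
their presence and absence across dozens of animal clades means processing
tens of thousands of homology-search hits whose free-text annotations range
from explicit ("vascular endothelial growth factor D") to useless
("hypothetical protein"), separating genuine family members from look-alike
false positives such as Balbiani ring-3 protein (BR3P) homologs, and being
honest about clades the sequence databases barely sample.  This package
implements that survey's computational core for phylogenetics /
molecular-evolution practitioners, exercisable entirely on synthetic inputs
with planted ground truth:

* **classifier** — annotation-based hit categorization (synonymous /
  related / undefined against a configurable synonym map), a strict
  majority vote over secondary-search annotations (a group is accepted only
  when it wins **more than 50%** of the annotated secondary hits — a
  deliberately conservative rule), a profile-search fallback, false-positive
  flagging, VEGF-A splice-isoform length bucketing (121/165/189/206), and
  nearest-reference assignment on a phylogenetic tree by patristic distance.
* **motifscan** — the relaxed PDGF/VEGF cysteine signature
  `P.?C.{2,8}C.?G.?C` and the BR3P repeat `C-X10-C-X-C-X(1,3)-C`
  (complete/incomplete), combined into domain-architecture labels
  (`VEGF_C_like`, `PDGF_VEGF_short`, `BR3P_only`, `none`).
* **census** — the clade sampling-reliability heuristic

  ```
  reliability = log10( n_genomes^2.5 / (n_species · n_proteins + 1) )
  ```

  presence/absence matrices with per-clade false-positive bookkeeping,
  whole-genome-duplication ohnolog projection (base · 2^n with 20–50%
  retention bounds), and cross-species transcript-count normalization.
* **divsel** — positional diversity as the normalized inverse Simpson
  index `d = 1/(N·Σ p_i²)` (N = 20 amino acids, or 5 nucleotide states
  counting the gap), sliding-window conservation profiles (default width
  11), Nei–Gojobori synonymous/nonsynonymous site fractions, and a
  counting-based per-codon-site selection test (SLAC-style): parsimony
  ancestors, branch substitution counts averaged over all minimal
  resolutions and minimal mutational paths, and an exact two-sided binomial
  test at α = 0.001.
* **seqio** — FASTA/Newick I/O, standard-code translation, and PAL2NAL-style
  back-translation of a protein alignment onto its source CDS set,
  including explicit stop-codon read-through preprocessing (TGA→TCA).
* **synth** — generators for every input above (hit tables with planted
  vote outcomes, sequences with planted motif architectures, codon
  alignments evolved under per-site ω, clade censuses spanning orders of
  magnitude), byte-reproducible under a seed.
* **cli** — a `vegfsurvey` command with `simulate`, `scan`, `classify`,
  `census`, `diversity`, `selection` and `survey` subcommands.

## Worked example

Simulate a survey bundle and run the full pipeline:

```sh
vegfsurvey simulate --out bundle --seed 3 --n-hits 40
vegfsurvey survey --bundle bundle --out report
```

The survey prints its run log, ending with (seed 3, 40 hits):

```json
{
  "stages": {
    "scan": {"n_sequences": 50},
    "classify": {
      "n_input": 40,
      "n_unique": 40,
      "n_primary": 28,
      "n_secondary_vote": 12,
      "n_profile_fallback": 0,
      "n_unresolved": 0,
      "n_false_positive": 0,
      "n_too_short": 0,
      "n_assigned": 40,
      "fraction_programmatic": 1.0
    },
    "census": {"n_assigned_cells": 40},
    "selection": {"n_sites": 60, "n_called": 0}
  }
}
```

Twenty-eight hits carried informative annotations and were categorized
directly (`n_primary`); the twelve "hypothetical protein" hits were resolved by the
secondary-search majority vote (`n_secondary_vote`); every unique hit ended
up assigned (`fraction_programmatic = 1.0`), and the presence matrix in
`report/presence_matrix.tsv` tabulates them per clade and ortholog group
with each clade's reliability score.  On this short neutral test alignment
no site reaches the α = 0.001 selection threshold (`n_called = 0`).

A library-level taste of the same machinery:

```pycon
>>> import vegfsurvey as vs
>>> vs.clade_reliability(10, 100, 1000)      # well-sequenced small clade
-2.5000043429231043
>>> vs.project_wgd_counts(9, 2)              # 9 genes through 2 WGDs
(36, 7, 18)
>>> vs.classify_architecture("M"*20 + "PACAAACAGAC" + "A"*12 +
...     ("C" + "A"*10 + "CAC" + "AA" + "C" + "DD")*3).label
'VEGF_C_like'
```

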