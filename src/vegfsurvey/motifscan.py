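"""Cysteine-motif scanning and domain-architecture typing.

Two motifs drive the typing of PDGF/VEGF-family candidates:

* the relaxed PDGF/VEGF signature ``P.?C.{2,8}C.?G.?C`` — a loose rendering
  of the cysteine spacing of the central cystine-knot (VEGF homology)
  domain;
* the BR3P repeat ``C-X10-C-X-C-X(1,3)-C`` of the Balbiani ring-3 protein,
  tandem copies of which form the C-terminal silk homology domain of
  VEGF-C/VEGF-D.  An *incomplete* repeat is the prefix ``C-X10-C-X-C`` that
  cannot be extended to a complete repeat.

``X`` means any amino acid, including cysteine (a naive regex reading of the
pattern).  Repeats are counted by a greedy, non-overlapping, left-to-right
scan: each residue belongs to at most one repeat.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PDGF_SIGNATURE_PATTERN",
    "MotifMatch",
    "DomainArchitecture",
    "scan_pdgf_signature",
    "count_br3p_repeats",
    "classify_architecture",
]

#: Relaxed PDGF/VEGF cysteine-signature regular expression.
PDGF_SIGNATURE_PATTERN = r"P.?C.{2,8}C.?G.?C"

# A BR3P repeat: anchor C, 10 spacers, C, spacer, C, then (greedily) the
# 1-3 spacer tail closed by a final C.  When the optional tail is absent the
# core is an incomplete repeat by construction ("not extendable").
_BR3P_RE = re.compile(r"C.{10}C.C(.{1,3}C)?")

_NT_ALPHABET = set("ACGTUN")


def _check_protein(sequence: str, context: str) -> str:
    """Reject sequences that are clearly nucleotide.

    Heuristic: a sequence of length >= 30 drawn entirely from {A,C,G,T,U,N}
    and using at least three of the four DNA/RNA bases is treated as
    nucleotide.  Short all-ACGT strings (legitimate peptide fragments such
    as ``"AAAA"``) and low-complexity Ala/Cys runs pass.
    """
    sequence = sequence.upper()
    if "U" in sequence or (
        len(sequence) >= 30
        and set(sequence) <= _NT_ALPHABET
        and len(set(sequence) & set("ACGTU")) >= 3
    ):
        raise ValueError(
            f"{context} expects a protein sequence; input looks like nucleotide"
        )
    return sequence


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence: 0-based half-open span plus matched text."""

    start: int
    end: int
    kind: str  # pdgf_signature | br3p_complete | br3p_incomplete
    matched_text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid motif span [{self.start}, {self.end})")
        if len(self.matched_text) != self.end - self.start:
            raise ValueError("matched_text length disagrees with span")


def scan_pdgf_signature(
    sequence: str, pattern: str = PDGF_SIGNATURE_PATTERN
) -> list[MotifMatch]:
    """All non-overlapping, leftmost-first matches of the signature pattern."""
    sequence = _check_protein(sequence, "scan_pdgf_signature")
    return [
        MotifMatch(m.start(), m.end(), "pdgf_signature", m.group(0))
        for m in re.finditer(pattern, sequence)
    ]


def count_br3p_repeats(
    sequence: str, search_start: int = 0
) -> tuple[int, int, list[MotifMatch]]:
    """Greedy left-to-right count of complete/incomplete BR3P repeats.

    Scanning begins at ``search_start`` (typically the end of the signature
    match); consumed residues are never reused.  Returns
    ``(n_complete, n_incomplete, matches)``.
    """
    sequence = _check_protein(sequence, "count_br3p_repeats")
    if not (0 <= search_start <= len(sequence)):
        raise ValueError(
            f"search_start {search_start} out of range for sequence of length "
            f"{len(sequence)}"
        )
    matches: list[MotifMatch] = []
    n_complete = n_incomplete = 0
    pos = search_start
    while True:
        nxt = sequence.find("C", pos)
        if nxt < 0:
            break
        m = _BR3P_RE.match(sequence, nxt)
        if m is None:
            pos = nxt + 1
            continue
        if m.group(1) is not None:
            kind = "br3p_complete"
            n_complete += 1
        else:
            kind = "br3p_incomplete"
            n_incomplete += 1
        matches.append(MotifMatch(m.start(), m.end(), kind, m.group(0)))
        pos = m.end()
    return n_complete, n_incomplete, matches


@dataclass
class DomainArchitecture:
    """Per-sequence motif layout and the derived architecture label.

    Labels (deterministic given the matches):

    * ``VEGF_C_like``     — signature present and >= 2 complete BR3P repeats
      C-terminal to it (VEGF-C/D-like proteins carry three to five);
    * ``PDGF_VEGF_short`` — signature present, fewer than 2 complete repeats
      (PDGFs, PlGF and the short VEGF-A/B isoforms carry at most one);
    * ``BR3P_only``       — no signature but at least one complete repeat
      (Balbiani ring-3 protein homologs, the survey's main false positives);
    * ``none``            — neither.
    """

    sequence_id: str
    signature_matches: list[MotifMatch] = field(default_factory=list)
    n_br3p_complete: int = 0
    n_br3p_incomplete: int = 0
    label: str = "none"
    br3p_matches: list[MotifMatch] = field(default_factory=list)


def classify_architecture(
    sequence: str,
    sequence_id: str = "",
    pattern: str = PDGF_SIGNATURE_PATTERN,
    min_complete_for_vegf_c_like: int = 2,
) -> DomainArchitecture:
    """Scan a protein sequence and assign its domain-architecture label.

    BR3P repeats are counted C-terminally to the signature when one is
    present, from the start of the sequence otherwise.
    """
    sequence = _check_protein(sequence, "classify_architecture")
    sig = scan_pdgf_signature(sequence, pattern)
    search_start = sig[0].end if sig else 0
    n_complete, n_incomplete, matches = count_br3p_repeats(sequence, search_start)
    if sig:
        label = (
            "VEGF_C_like"
            if n_complete >= min_complete_for_vegf_c_like
            else "PDGF_VEGF_short"
        )
    elif n_complete >= 1:
        label = "BR3P_only"
    else:
        label = "none"
    return DomainArchitecture(
        sequence_id=sequence_id,
        signature_matches=sig,
        n_br3p_complete=n_complete,
        n_br3p_incomplete=n_incomplete,
        label=label,
        br3p_matches=matches,
    )
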