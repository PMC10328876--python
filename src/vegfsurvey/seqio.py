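"""Sequence and tree I/O plus codon-aware utilities.

Readers and writers for the formats the survey pipeline touches (FASTA,
Newick) and the codon-level plumbing needed for selection analysis:
translation under the standard genetic code and back-translation of a
protein alignment onto its source CDS set (PAL2NAL-style codon threading).

Coordinates are 0-based half-open throughout; identifiers are the first
whitespace-delimited token of a FASTA header, with the full header kept as
the record description (free-text annotations are primary evidence for the
classifier, so both must survive I/O).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import dendropy
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "SequenceRecord",
    "Alignment",
    "CodonAlignment",
    "Tree",
    "read_fasta",
    "write_fasta",
    "parse_newick",
    "translate_cds",
    "back_translate_alignment",
]

PathLike = Union[str, Path]


@dataclass
class SequenceRecord:
    """A single sequence: accession, free-text description, residues."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record requires a non-empty id")
        self.residues = self.residues.upper()

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(source: Union[PathLike, io.TextIOBase]) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords.

    The record id is the first whitespace-delimited header token; the full
    header line is retained as the description.  An empty file yields an
    empty list; duplicate ids raise a ValueError naming the offender.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_fasta(handle)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(source, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in FASTA input: {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    target: Union[PathLike, io.TextIOBase],
    width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    if isinstance(target, (str, Path)):
        with open(target, "w") as handle:
            write_fasta(records, handle, width=width)
            return
    for rec in records:
        header = rec.description if rec.description else rec.id
        if not header.split() or header.split()[0] != rec.id:
            header = f"{rec.id} {header}".strip()
        target.write(f">{header}\n")
        for i in range(0, len(rec.residues), width):
            target.write(rec.residues[i : i + width] + "\n")


@dataclass
class Alignment:
    """An aligned, equal-length collection of sequences.

    This is a container only; alignment computation is out of scope.
    """

    records: list[SequenceRecord]
    alphabet: str  # "protein" | "nucleotide"

    def __post_init__(self) -> None:
        if self.alphabet not in ("protein", "nucleotide"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        if not self.records:
            raise ValueError("alignment requires at least one record")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned records differ in length: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in alignment: {dup}")

    @property
    def columns(self) -> int:
        return len(self.records[0].residues)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, record_id: str) -> str:
        for r in self.records:
            if r.id == record_id:
                return r.residues
        raise KeyError(record_id)


# --- genetic code -----------------------------------------------------------

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))
_CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
_CODON_TO_AA.update({c: "*" for c in STOP_CODONS})


def translate_codon(codon: str, genetic_code: int = 1) -> str:
    """Translate one codon; '---' maps to '-', ambiguity maps to 'X'."""
    if genetic_code != 1:
        raise NotImplementedError("only the standard genetic code is supported")
    codon = codon.upper().replace("U", "T")
    if codon == "---":
        return "-"
    if len(codon) != 3:
        raise ValueError(f"codon of length {len(codon)}: {codon!r}")
    if "-" in codon:
        raise ValueError(f"partially gapped codon: {codon!r}")
    return _CODON_TO_AA.get(codon, "X")


def translate_cds(nt_sequence: str, genetic_code: int = 1) -> str:
    """Translate an in-frame CDS (length divisible by 3) to protein.

    Gap codons '---' become '-', codons containing ambiguous bases become
    'X', and stop codons are rendered as '*'.
    """
    nt_sequence = nt_sequence.upper().replace("U", "T")
    if len(nt_sequence) % 3 != 0:
        raise ValueError(
            f"CDS length {len(nt_sequence)} is not divisible by 3 (frame error)"
        )
    return "".join(
        translate_codon(nt_sequence[i : i + 3], genetic_code)
        for i in range(0, len(nt_sequence), 3)
    )


@dataclass
class CodonAlignment:
    """An in-frame nucleotide alignment whose columns come in codon triplets.

    Invariants: the underlying alignment is nucleotide with a column count
    divisible by 3, every ungapped codon is a sense codon (stop codons must
    have been removed or replaced by read-through preprocessing upstream).
    """

    alignment: Alignment
    genetic_code: int = 1
    source_cds_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.alignment.alphabet != "nucleotide":
            raise ValueError("codon alignment requires a nucleotide alignment")
        if self.alignment.columns % 3 != 0:
            raise ValueError(
                f"codon alignment column count {self.alignment.columns} "
                "is not divisible by 3"
            )
        for rec in self.alignment.records:
            for i in range(0, len(rec.residues), 3):
                codon = rec.residues[i : i + 3]
                if "-" in codon:
                    continue
                if translate_codon(codon, self.genetic_code) == "*":
                    raise ValueError(
                        f"stop codon {codon} at column {i} in record {rec.id!r}; "
                        "apply read-through preprocessing if intended"
                    )

    @property
    def n_sites(self) -> int:
        return self.alignment.columns // 3

    def codon(self, record_id: str, site: int) -> str:
        return self.alignment.row(record_id)[3 * site : 3 * site + 3]


def back_translate_alignment(
    protein_alignment: Alignment,
    cds_by_id: Mapping[str, str],
    replace_terminal_stop_with: Optional[str] = None,
) -> CodonAlignment:
    """Thread each aligned protein row onto its source CDS (codon alignment).

    Every aligned residue is replaced by its source codon and every gap by
    '---', so that translating and degapping the result reproduces each
    degapped protein row.

    Stop-codon handling is explicit, never automatic: without
    ``replace_terminal_stop_with``, a CDS containing any stop codon is an
    error.  With it, a trailing stop codon (beyond the protein's last
    residue) is trimmed, and a stop codon aligned to a protein residue is
    replaced by the given codon (mimicking translational read-through), whose
    translation must then match the protein residue.
    """
    if protein_alignment.alphabet != "protein":
        raise ValueError("back-translation expects a protein alignment")
    if replace_terminal_stop_with is not None:
        repl = replace_terminal_stop_with.upper().replace("U", "T")
        if len(repl) != 3 or translate_codon(repl) == "*":
            raise ValueError(
                f"replacement codon must be a sense codon, got {replace_terminal_stop_with!r}"
            )
    rows = []
    for rec in protein_alignment.records:
        if rec.id not in cds_by_id:
            raise KeyError(f"no CDS provided for record {rec.id!r}")
        cds = cds_by_id[rec.id].upper().replace("U", "T")
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS for {rec.id!r} has length not divisible by 3")
        if (
            replace_terminal_stop_with is not None
            and len(cds) >= 3
            and translate_codon(cds[-3:]) == "*"
        ):
            cds = cds[:-3]  # trailing stop trimmed under read-through preprocessing
        ungapped = rec.ungapped
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"CDS length mismatch for {rec.id!r}: {len(cds)} nt for "
                f"{len(ungapped)} residues"
            )
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        for idx, (aa, codon) in enumerate(zip(ungapped, codons)):
            t = translate_codon(codon)
            if t == "*":
                if replace_terminal_stop_with is None:
                    raise ValueError(
                        f"internal stop codon {codon} at residue index {idx} of "
                        f"{rec.id!r}; pass replace_terminal_stop_with to model "
                        "read-through"
                    )
                codon = repl
                codons[idx] = codon
                t = translate_codon(codon)
            if t != aa and aa != "X" and t != "X":
                raise ValueError(
                    f"translation mismatch for {rec.id!r} at residue index {idx}: "
                    f"protein has {aa!r}, CDS codon {codon} translates to {t!r}"
                )
        it = iter(codons)
        threaded = "".join("---" if aa == "-" else next(it) for aa in rec.residues)
        rows.append(SequenceRecord(id=rec.id, residues=threaded, description=rec.description))
    return CodonAlignment(
        alignment=Alignment(records=rows, alphabet="nucleotide"),
        source_cds_ids={r.id: r.id for r in rows},
    )


# --- trees ------------------------------------------------------------------


class Tree:
    """A phylogenetic tree (dendropy-backed) with patristic-distance helpers.

    Trees are consumed, never inferred.  Leaf labels must be unique and
    branch lengths non-negative.  Plain Newick input is treated as rooted at
    its first node unless tagged ``[&U]``.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate leaf labels in tree: {dup}")
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError(f"negative branch length {edge.length} in tree")
        self._pdm = None

    @property
    def is_rooted(self) -> bool:
        return bool(self._tree.is_rooted)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def n_leaves(self) -> int:
        return len(self.leaf_labels())

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self._tree.preorder_edge_iter() if e.head_node.parent_node
        )

    def patristic_distance(self, label_a: str, label_b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        if self._pdm is None:
            self._pdm = self._tree.phylogenetic_distance_matrix()
        ns = self._tree.taxon_namespace
        ta = ns.get_taxon(label_a)
        tb = ns.get_taxon(label_b)
        if ta is None or tb is None:
            missing = label_a if ta is None else label_b
            raise KeyError(f"leaf label not in tree: {missing!r}")
        return self._pdm.patristic_distance(ta, tb)

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()

    def midpoint_rooted(self) -> "Tree":
        clone = self._tree.clone(depth=1)
        clone.reroot_at_midpoint(update_bipartitions=False)
        clone.is_rooted = True
        return Tree(clone)


def parse_newick(text: str, rooting: str = "default-rooted") -> Tree:
    """Parse a Newick string (optionally with branch lengths) into a Tree.

    Malformed input (e.g. unbalanced parentheses) raises ValueError carrying
    the parser's position diagnostics.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting=rooting,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    return Tree(dtree)
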