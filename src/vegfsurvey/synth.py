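"""Synthetic-data generators with known ground truth for every pipeline stage.

Real inputs to a family survey — homology-search hit tables, protein
sequences with cysteine-motif architectures, codon alignments shaped by
per-site selection, clade sampling censuses — come from live databases.
These generators emulate each of them with planted, fully known truth so
the classification, motif-scanning, census and selection stages can be
scored end-to-end without any download.

Conventions: every generator takes an integer seed and is byte-reproducible
under it (numpy's integer-state PCG64 generator); every generator returns a
truth artifact sufficient to score the downstream stage without re-deriving
anything.  Background protein sequence is drawn from an alphabet without
cysteine or proline, so planted signature/repeat counts are exact (neither
motif can arise or extend by chance); this is a deliberate simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .census import DEFAULT_CLADES, CladeCensus
from .classifier import (
    DEFAULT_UNDEFINED_MARKERS,
    FixtureSearchProvider,
    HitRecord,
    ORTHOLOG_GROUPS,
    SynonymMap,
)
from .seqio import (
    Alignment,
    CodonAlignment,
    SENSE_CODONS,
    SequenceRecord,
    Tree,
    parse_newick,
    translate_codon,
)

__all__ = [
    "BACKGROUND_ALPHABET",
    "gen_hit_table",
    "gen_domain_sequences",
    "gen_codon_alignment",
    "gen_clade_census",
    "balanced_tree",
    "HitTableBundle",
    "write_bundle",
]

#: Amino acids used for background sequence: no C (motif anchor) and no P
#: (signature anchor), so planted motif counts are exact.
BACKGROUND_ALPHABET = "ADEFGHIKLMNQRSTVWY"


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND_ALPHABET), size=n))


# --- domain sequences ---------------------------------------------------------


def _planted_signature(rng: np.random.Generator) -> str:
    """A random instantiation of the relaxed signature P.?C.{2,8}C.?G.?C."""
    return (
        "P"
        + _bg(rng, int(rng.integers(0, 2)))
        + "C"
        + _bg(rng, int(rng.integers(2, 9)))
        + "C"
        + _bg(rng, int(rng.integers(0, 2)))
        + "G"
        + _bg(rng, int(rng.integers(0, 2)))
        + "C"
    )


def _planted_repeat(rng: np.random.Generator, complete: bool = True) -> str:
    core = "C" + _bg(rng, 10) + "C" + _bg(rng, 1) + "C"
    if not complete:
        return core
    return core + _bg(rng, int(rng.integers(1, 4))) + "C"


def _expected_label(has_signature: bool, k_complete: int, threshold: int = 2) -> str:
    if has_signature:
        return "VEGF_C_like" if k_complete >= threshold else "PDGF_VEGF_short"
    return "BR3P_only" if k_complete >= 1 else "none"


def gen_domain_sequences(
    n_sequences: int = 100,
    k_complete: int = 4,
    incomplete_tail: bool = False,
    include_signature: bool = True,
    seed: int = 0,
    n_flank: tuple[int, int] = (15, 40),
    id_prefix: str = "SYN",
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Protein sequences with a planted signature and BR3P repeat block.

    Each record is background + (optional) signature + spacer + exactly
    ``k_complete`` complete BR3P repeats (+ optionally one incomplete
    trailing repeat) + background.  Returns the records and a truth table
    with columns id, signature_start, signature_end, k_complete,
    k_incomplete, label.
    """
    if not 0 <= k_complete <= 6:
        raise ValueError("k_complete must lie in [0, 6]")
    rng = np.random.default_rng(seed)
    records = []
    truth_rows = []
    for i in range(n_sequences):
        n_lead = int(rng.integers(*n_flank))
        parts = [_bg(rng, n_lead)]
        sig_start = sig_end = -1
        if include_signature:
            sig = _planted_signature(rng)
            sig_start = n_lead
            sig_end = n_lead + len(sig)
            parts.append(sig)
        # spacer >= 10 keeps any later cysteine beyond the signature regex's
        # maximal 16-residue greedy span, so the match ends exactly where
        # planted; inter-repeat spacers >= 2 keep the greedy {1,3} repeat
        # tail from swallowing the next repeat's opening cysteine.
        parts.append(_bg(rng, int(rng.integers(10, 20))))
        for r in range(k_complete):
            if r:
                parts.append(_bg(rng, int(rng.integers(2, 6))))
            parts.append(_planted_repeat(rng, complete=True))
        if incomplete_tail:
            if k_complete:
                parts.append(_bg(rng, int(rng.integers(2, 6))))
            parts.append(_planted_repeat(rng, complete=False))
        parts.append(_bg(rng, int(rng.integers(*n_flank))))
        seq = "".join(parts)
        rec_id = f"{id_prefix}{i:05d}"
        records.append(SequenceRecord(id=rec_id, residues=seq, description=f"{rec_id} synthetic domain sequence"))
        truth_rows.append(
            {
                "id": rec_id,
                "signature_start": sig_start,
                "signature_end": sig_end,
                "k_complete": k_complete,
                "k_incomplete": int(incomplete_tail),
                "label": _expected_label(include_signature, k_complete),
            }
        )
    return records, pd.DataFrame(truth_rows)


# --- hit tables ---------------------------------------------------------------


@dataclass
class HitTableBundle:
    """A synthetic hit table with its truth labels and fixture providers."""

    hits: list[HitRecord]
    truth: dict[str, str]  # hit_id -> planted group
    secondary_provider: FixtureSearchProvider
    profile_provider: FixtureSearchProvider
    secondary_map: dict[str, list[HitRecord]] = field(default_factory=dict)
    profile_map: dict[str, list[HitRecord]] = field(default_factory=dict)


def gen_hit_table(
    n_hits: int = 1000,
    fraction_undefined: float = 0.3,
    secondary_agreement: float = 0.6,
    secondary_size: int = 5,
    profile_fraction: float = 0.0,
    clades: Sequence[str] = DEFAULT_CLADES,
    groups: Sequence[str] = ORTHOLOG_GROUPS,
    synonym_map: Optional[SynonymMap] = None,
    seed: int = 0,
    sequence_length_kwargs: Optional[dict] = None,
) -> HitTableBundle:
    """A hit table with planted group truth and deterministic providers.

    A ``fraction_undefined`` share of hits carries an uninformative
    annotation (e.g. "hypothetical protein") and must be resolved by vote;
    the rest are annotated with an alias of their planted group.  The
    fixture secondary provider returns, for each undefined hit's sequence, a
    list of ``secondary_size`` annotated hits of which exactly
    ``secondary_agreement * secondary_size`` name the planted group (the
    product must be an integer, otherwise the requested agreement is
    unreachable and an error is raised); the remainder are split across
    other groups so no other group can reach a strict majority.  A
    ``profile_fraction`` share of the undefined hits receives uninformative
    secondary annotations and is resolvable only through the profile
    provider (same agreement rule).
    """
    if not 0 <= fraction_undefined <= 1 or not 0 <= secondary_agreement <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    if not 0 <= profile_fraction <= 1:
        raise ValueError("profile_fraction must lie in [0, 1]")
    k_agree = secondary_agreement * secondary_size
    if abs(k_agree - round(k_agree)) > 1e-9:
        raise ValueError(
            f"agreement {secondary_agreement} is unreachable with "
            f"{secondary_size} secondary hits"
        )
    k_agree = int(round(k_agree))
    synonym_map = synonym_map or SynonymMap()
    rng = np.random.default_rng(seed)
    groups = list(groups)
    hits: list[HitRecord] = []
    truth: dict[str, str] = {}
    secondary_map: dict[str, list[HitRecord]] = {}
    profile_map: dict[str, list[HitRecord]] = {}
    n_undefined = int(round(n_hits * fraction_undefined))
    undefined_flags = np.array([True] * n_undefined + [False] * (n_hits - n_undefined))
    rng.shuffle(undefined_flags)
    for i in range(n_hits):
        hit_id = f"HIT{i:06d}"
        group = groups[int(rng.integers(len(groups)))]
        clade = clades[int(rng.integers(len(clades)))]
        truth[hit_id] = group
        # flanks sized so every sequence clears the classifier's default
        # 60-residue minimum classifiable length
        seq_records, _ = gen_domain_sequences(
            n_sequences=1,
            k_complete=0,
            include_signature=True,
            seed=int(rng.integers(2**31)),
            id_prefix=f"S{i:06d}_",
            **({"n_flank": (30, 60)} | (sequence_length_kwargs or {})),
        )
        sequence = seq_records[0].residues
        if undefined_flags[i]:
            marker = DEFAULT_UNDEFINED_MARKERS[int(rng.integers(len(DEFAULT_UNDEFINED_MARKERS)))]
            hit_def = f"{marker} LOC{100000 + i}"
            votes = _vote_list(hit_id, group, groups, k_agree, secondary_size, synonym_map, rng)
            if rng.random() < profile_fraction:
                # secondary search is uninformative; profile search decides
                secondary_map[sequence] = _uninformative_list(hit_id, secondary_size, rng)
                profile_map[sequence] = votes
            else:
                secondary_map[sequence] = votes
        else:
            alias = synonym_map.alias_for(group)
            hit_def = f"{alias} [synthetic species {i % 97}]"
        hits.append(
            HitRecord(
                query_group=group,
                hit_id=hit_id,
                hit_def=hit_def,
                clade=clade,
                evalue=float(10 ** -rng.uniform(5, 100)),
                sequence=sequence,
            )
        )
    return HitTableBundle(
        hits=hits,
        truth=truth,
        secondary_provider=FixtureSearchProvider(secondary_map),
        profile_provider=FixtureSearchProvider(profile_map),
        secondary_map=secondary_map,
        profile_map=profile_map,
    )


def _vote_list(
    hit_id: str,
    group: str,
    groups: Sequence[str],
    k_agree: int,
    size: int,
    synonym_map: SynonymMap,
    rng: np.random.Generator,
) -> list[HitRecord]:
    others = [g for g in groups if g != group]
    records = []
    for j in range(size):
        if j < k_agree:
            g = group
        else:
            g = others[(j - k_agree) % len(others)]  # spread: no rival majority
        records.append(
            HitRecord(
                query_group="",
                hit_id=f"{hit_id}_sec{j}",
                hit_def=f"{synonym_map.alias_for(g)} [secondary]",
                evalue=1e-30,
            )
        )
    return records


def _uninformative_list(hit_id: str, size: int, rng: np.random.Generator) -> list[HitRecord]:
    return [
        HitRecord(
            query_group="",
            hit_id=f"{hit_id}_sec{j}",
            hit_def=f"hypothetical protein LOC{int(rng.integers(10**6))}",
            evalue=1e-5,
        )
        for j in range(size)
    ]


# --- codon alignments ---------------------------------------------------------


def balanced_tree(n_taxa: int = 16, total_length: float = 50.0) -> Tree:
    """A rooted, balanced binary tree with equal branch lengths.

    ``n_taxa`` must be a power of two; branch lengths are chosen so the tree
    length (sum over the 2*n_taxa - 2 branches) equals ``total_length``.
    Branch-length units are expected proposed single-nucleotide mutation
    events per codon site (see :func:`gen_codon_alignment`).
    """
    if n_taxa < 2 or n_taxa & (n_taxa - 1):
        raise ValueError("n_taxa must be a power of two >= 2")
    n_branches = 2 * n_taxa - 2
    bl = total_length / n_branches

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"T{lo + 1}:{bl:.10g}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{bl:.10g}"

    mid = n_taxa // 2
    newick = f"({build(0, mid)},{build(mid, n_taxa)});"
    return parse_newick(newick, rooting="default-rooted")


def _mutate_codon(
    codon: str,
    rng: np.random.Generator,
    kappa: float,
) -> str:
    """Propose one single-nucleotide change; transitions weighted by kappa."""
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    pos = int(rng.integers(3))
    base = codon[pos]
    alts = [b for b in "ACGT" if b != base]
    weights = np.array([kappa if transitions[base] == b else 1.0 for b in alts])
    new_base = alts[int(rng.choice(3, p=weights / weights.sum()))]
    return codon[:pos] + new_base + codon[pos + 1 :]


def gen_codon_alignment(
    tree: Tree,
    n_codons: int = 300,
    omega: Union[float, Sequence[float]] = 1.0,
    kappa: float = 1.0,
    seed: int = 0,
) -> tuple[CodonAlignment, Tree, dict]:
    """Evolve a codon alignment along a tree under per-site selection omega.

    Root codons are drawn uniformly from the 61 sense codons.  Along each
    branch of length t, a Poisson(t) number of single-nucleotide mutation
    events is proposed per codon (transitions weighted by kappa); a proposal
    creating a stop codon is rejected, a synonymous proposal is always
    accepted, and a nonsynonymous proposal is accepted with probability
    ``omega[site]``.  Branch length is therefore the expected number of
    proposed events per codon site, and the realized substitution process is
    a rejection sampler rather than a matrix-exponential model.

    Returns the alignment, the (same) tree, and a truth dict with the omega
    vector, the root codon sequence, and realized per-site accepted
    synonymous/nonsynonymous and transition/transversion event counts.
    """
    omega_vec = np.asarray(
        [omega] * n_codons if np.isscalar(omega) else list(omega), dtype=float
    )
    if len(omega_vec) != n_codons:
        raise ValueError("omega vector length must equal n_codons")
    if (omega_vec < 0).any():
        raise ValueError("omega must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if tree.total_length() == 0 and n_codons > 0:
        raise ValueError("tree has zero total length; no changes can be simulated")
    rng = np.random.default_rng(seed)
    sense = list(SENSE_CODONS)
    root_seq = [sense[int(i)] for i in rng.integers(len(sense), size=n_codons)]
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    realized = {
        "syn": np.zeros(n_codons, dtype=int),
        "nonsyn": np.zeros(n_codons, dtype=int),
        "transition": np.zeros(n_codons, dtype=int),
        "transversion": np.zeros(n_codons, dtype=int),
    }
    leaf_seqs: dict[str, list[str]] = {}

    def evolve(node, seq):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = list(seq)
            for j in range(n_codons):
                for _ in range(rng.poisson(t)):
                    proposal = _mutate_codon(child_seq[j], rng, kappa)
                    aa_new = translate_codon(proposal)
                    if aa_new == "*":
                        continue
                    if aa_new != translate_codon(child_seq[j]):
                        if rng.random() >= omega_vec[j]:
                            continue
                        realized["nonsyn"][j] += 1
                    else:
                        realized["syn"][j] += 1
                    diff_pos = next(
                        p for p in range(3) if proposal[p] != child_seq[j][p]
                    )
                    if transitions[child_seq[j][diff_pos]] == proposal[diff_pos]:
                        realized["transition"][j] += 1
                    else:
                        realized["transversion"][j] += 1
                    child_seq[j] = proposal
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = child_seq
            else:
                evolve(child, child_seq)

    evolve(tree.dendropy_tree.seed_node, root_seq)
    records = [
        SequenceRecord(id=label, residues="".join(leaf_seqs[label]))
        for label in tree.leaf_labels()
    ]
    caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
    truth = {
        "omega": omega_vec,
        "root": "".join(root_seq),
        "realized": realized,
    }
    return caln, tree, truth


# --- clade censuses -----------------------------------------------------------


def gen_clade_census(
    n_clades: int = 52,
    seed: int = 0,
    species_range: tuple[float, float] = (1.0, 1e6),
    genome_range: tuple[float, float] = (1.0, 1.1e3),
    protein_range: tuple[float, float] = (10.0, 1e8),
) -> list[CladeCensus]:
    """Clade censuses with counts log-uniform over several orders of magnitude.

    Always includes at least one clade with zero sequenced genomes (to
    exercise the -inf reliability path) and a planted monotone pair (same
    species and protein counts, doubled genome count) whose reliabilities
    must be ordered downstream.
    """
    if n_clades < 4:
        raise ValueError("need at least 4 clades for the planted structure")
    rng = np.random.default_rng(seed)
    names = list(DEFAULT_CLADES[:n_clades])
    names += [f"SynClade{i:02d}" for i in range(len(names), n_clades)]

    def log_uniform(lo: float, hi: float) -> int:
        return int(round(10 ** rng.uniform(np.log10(lo), np.log10(hi))))

    census = []
    for i, name in enumerate(names):
        n_species = log_uniform(*species_range)
        n_genomes = log_uniform(*genome_range)
        n_proteins = log_uniform(*protein_range)
        census.append(
            CladeCensus(
                clade=name,
                n_species=n_species,
                n_genomes=n_genomes,
                n_proteins=n_proteins,
            )
        )
    # zero-genome clade and a monotone (genomes doubled) pair
    census[0] = CladeCensus(
        clade=census[0].clade,
        n_species=census[0].n_species,
        n_genomes=0,
        n_proteins=census[0].n_proteins,
    )
    base = census[-2]
    census[-1] = CladeCensus(
        clade=census[-1].clade,
        n_species=base.n_species,
        n_genomes=max(2 * base.n_genomes, 2),
        n_proteins=base.n_proteins,
    )
    return census


# --- bundle writing -----------------------------------------------------------


def write_bundle(
    out_dir: Union[str, Path],
    seed: int = 0,
    n_hits: int = 500,
    fraction_undefined: float = 0.3,
    secondary_agreement: float = 0.6,
    secondary_size: int = 5,
    n_taxa: int = 8,
    n_codons: int = 60,
    omega: float = 1.0,
    kappa: float = 1.0,
    tree_length: float = 8.0,
) -> Path:
    """Write a complete synthetic input bundle for the survey pipeline.

    Emits hits.tsv, seqs.fasta, codon_aln.fasta, tree.nwk, census.tsv,
    synonyms.yaml, the fixture provider tables (secondary_hits.tsv,
    profile_hits.tsv) and plain-TSV truth sidecars.
    """
    from .census import write_census_table
    from .classifier import write_hit_table
    from .seqio import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    synonym_map = SynonymMap()
    bundle = gen_hit_table(
        n_hits=n_hits,
        fraction_undefined=fraction_undefined,
        secondary_agreement=secondary_agreement,
        secondary_size=secondary_size,
        synonym_map=synonym_map,
        seed=seed,
    )
    write_hit_table(bundle.hits, out / "hits.tsv")
    bundle.secondary_provider.to_tsv(out / "secondary_hits.tsv")
    bundle.profile_provider.to_tsv(out / "profile_hits.tsv")
    pd.DataFrame(
        [{"hit_id": h, "group": g} for h, g in bundle.truth.items()]
    ).to_csv(out / "truth_hits.tsv", sep="\t", index=False)
    records, domain_truth = gen_domain_sequences(
        n_sequences=50, k_complete=4, seed=seed + 1
    )
    write_fasta(records, out / "seqs.fasta")
    domain_truth.to_csv(out / "truth_domains.tsv", sep="\t", index=False)
    tree = balanced_tree(n_taxa=n_taxa, total_length=tree_length)
    caln, _, truth = gen_codon_alignment(
        tree, n_codons=n_codons, omega=omega, kappa=kappa, seed=seed + 2
    )
    write_fasta(caln.alignment.records, out / "codon_aln.fasta")
    (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    pd.DataFrame(
        {
            "site": np.arange(n_codons) + 1,
            "omega": truth["omega"],
            "realized_syn": truth["realized"]["syn"],
            "realized_nonsyn": truth["realized"]["nonsyn"],
        }
    ).to_csv(out / "truth_omega.tsv", sep="\t", index=False)
    census = gen_clade_census(seed=seed + 3)
    write_census_table(census, out / "census.tsv")
    synonym_map.to_yaml(out / "synonyms.yaml")
    return out
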