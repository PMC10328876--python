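"""Clade-level accounting: sampling reliability, presence/absence, WGD arithmetic.

Absence of evidence is not evidence of absence when a clade is barely
sequenced.  The survey therefore scores every clade with a heuristic
sampling-reliability value

    reliability = log10( n_genomes**2.5 / (n_species * n_proteins + 1) )

which grows with the number of fully sequenced genomes and shrinks with the
number of known species and deposited protein records.  A clade with no
sequenced genome has no data to argue from; its reliability is the -inf
sentinel and is reported as a distinguished "no data" category, never as a
numeric minimum.

The module also builds the per-clade x per-group presence matrix with
false-positive bookkeeping (manually reviewable only for small clades),
projects ohnolog counts through whole-genome duplications, and normalizes
cross-species transcript counts to a reference species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .classifier import ClassificationResult, ORTHOLOG_GROUPS

__all__ = [
    "DEFAULT_CLADES",
    "CladeCensus",
    "PresenceMatrix",
    "clade_reliability",
    "build_presence_matrix",
    "project_wgd_counts",
    "normalize_transcript_counts",
    "read_census_table",
    "write_census_table",
]

#: 52 animal clades at the granularity the survey samples (vertebrate
#: classes plus invertebrate phyla/subphyla).
DEFAULT_CLADES = (
    "Mammalia",
    "Aves",
    "Crocodylia",
    "Testudines",
    "Lepidosauria",
    "Amphibia",
    "Dipnoi",
    "Actinistia",
    "Actinopterygii",
    "Chondrichthyes",
    "Cyclostomata",
    "Cephalochordata",
    "Tunicata",
    "Echinodermata",
    "Hemichordata",
    "Xenacoelomorpha",
    "Cnidaria",
    "Porifera",
    "Placozoa",
    "Ctenophora",
    "Priapulida",
    "Kinorhyncha",
    "Loricifera",
    "Nematoda",
    "Nematomorpha",
    "Tardigrada",
    "Onychophora",
    "Arachnida",
    "Xiphosura",
    "Pycnogonida",
    "Myriapoda",
    "Crustacea",
    "Hexapoda",
    "Chaetognatha",
    "Rotifera",
    "Gnathostomulida",
    "Micrognathozoa",
    "Gastrotricha",
    "Platyhelminthes",
    "Annelida",
    "Mollusca",
    "Nemertea",
    "Brachiopoda",
    "Phoronida",
    "Bryozoa",
    "Entoprocta",
    "Cycliophora",
    "Dicyemida",
    "Orthonectida",
    "Sipuncula",
    "Echiura",
    "Myzostomida",
)


def clade_reliability(n_genomes: float, n_species: float, n_proteins: float) -> float:
    """Heuristic sampling-reliability score for one clade.

    ``log10(n_genomes**2.5 / (n_species * n_proteins + 1))``; a clade with
    zero sequenced genomes returns ``-inf``.
    """
    if n_genomes < 0 or n_species < 0 or n_proteins < 0:
        raise ValueError("census counts must be non-negative")
    if n_genomes == 0:
        return float("-inf")
    return math.log10(n_genomes**2.5 / (n_species * n_proteins + 1))


@dataclass
class CladeCensus:
    """Per-clade sampling counts with the derived reliability score."""

    clade: str
    n_species: int
    n_genomes: int
    n_proteins: int

    def __post_init__(self) -> None:
        if min(self.n_species, self.n_genomes, self.n_proteins) < 0:
            raise ValueError(f"clade {self.clade!r}: counts must be non-negative")

    @property
    def reliability(self) -> float:
        return clade_reliability(self.n_genomes, self.n_species, self.n_proteins)


@dataclass
class PresenceMatrix:
    """Clades x ortholog groups hit counts with false-positive bookkeeping.

    ``counts``            assigned unique hits per (clade, group);
    ``false_positives``   flagged hits per clade, <NA> for clades too large
                          to review manually (n_species > review cutoff);
    ``reviewed``          whether the clade's false positives were reviewable;
    ``reliability``       the sampling-reliability score per clade.
    """

    counts: pd.DataFrame
    false_positives: pd.Series
    reviewed: pd.Series
    reliability: pd.Series

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["false_positives"] = self.false_positives
        out["reviewed"] = self.reviewed
        out["reliability"] = [
            "no_data" if math.isinf(r) and r < 0 else f"{r:.4f}" for r in self.reliability
        ]
        return out

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="clade")


def build_presence_matrix(
    classification_results: Sequence[ClassificationResult],
    clade_census_list: Sequence[CladeCensus],
    review_cutoff: int = 500,
    groups: Sequence[str] = ORTHOLOG_GROUPS,
) -> PresenceMatrix:
    """Tabulate assigned hits per (clade, group) with per-clade bookkeeping.

    False-positive counts are populated only for clades small enough to
    review (n_species <= ``review_cutoff``); larger clades carry <NA> there.
    Results referencing a clade missing from the census list raise an error
    naming the offenders.
    """
    census_by_clade = {c.clade: c for c in clade_census_list}
    unknown = sorted(
        {r.clade for r in classification_results if r.clade not in census_by_clade}
    )
    if unknown:
        raise ValueError(f"classification results reference unknown clades: {unknown}")
    clades = [c.clade for c in clade_census_list]
    counts = pd.DataFrame(0, index=clades, columns=list(groups), dtype=int)
    fp_raw = {clade: 0 for clade in clades}
    for r in classification_results:
        if r.assigned_group is not None and r.assigned_group in counts.columns:
            counts.loc[r.clade, r.assigned_group] += 1
        if r.flags & {"false_positive_named_other", "br3p_only"}:
            fp_raw[r.clade] += 1
    reviewed = pd.Series(
        {c.clade: c.n_species <= review_cutoff for c in clade_census_list}
    )
    false_positives = pd.Series(
        {clade: (fp_raw[clade] if reviewed[clade] else pd.NA) for clade in clades},
        dtype="Int64",
    )
    reliability = pd.Series({c.clade: c.reliability for c in clade_census_list})
    return PresenceMatrix(
        counts=counts,
        false_positives=false_positives,
        reviewed=reviewed,
        reliability=reliability,
    )


def project_wgd_counts(
    base_gene_count: int,
    n_duplications: int,
    retention_low: float = 0.2,
    retention_high: float = 0.5,
) -> tuple[int, int, int]:
    """Project a gene count through whole-genome duplications.

    The theoretical maximum after ``n`` duplications is ``base * 2**n``; the
    expected range applies the retention fractions (about 20-50% of ohnologs
    stay functional through neo- or subfunctionalization), rounded to the
    nearest integer (half away from zero).
    """
    if base_gene_count < 0 or n_duplications < 0:
        raise ValueError("base gene count and duplication count must be non-negative")
    if not (0 < retention_low <= 1 and 0 < retention_high <= 1):
        raise ValueError("retention fractions must lie in (0, 1]")
    if retention_low > retention_high:
        raise ValueError("retention_low must not exceed retention_high")
    max_count = base_gene_count * 2**n_duplications
    expected_low = int(math.floor(max_count * retention_low + 0.5))
    expected_high = int(math.floor(max_count * retention_high + 0.5))
    return max_count, expected_low, expected_high


def normalize_transcript_counts(
    counts_by_species: pd.DataFrame,
    totals_by_species: Mapping[str, float],
    reference_species: str,
) -> pd.DataFrame:
    """Scale per-gene transcript counts to a reference species' total.

    Each species' row is multiplied by ``total(reference) / total(species)``
    so that differences in sequencing depth do not masquerade as expression
    differences.  Within-species ratios are preserved by construction.
    """
    totals = pd.Series(dict(totals_by_species), dtype=float)
    if reference_species not in totals.index:
        raise ValueError(f"reference species {reference_species!r} missing from totals")
    missing = [s for s in counts_by_species.index if s not in totals.index]
    if missing:
        raise ValueError(f"species missing from totals: {missing}")
    if (totals.loc[counts_by_species.index] <= 0).any():
        bad = totals.loc[counts_by_species.index]
        raise ValueError(
            f"species totals must be positive; offenders: "
            f"{sorted(bad[bad <= 0].index)}"
        )
    factors = totals[reference_species] / totals.loc[counts_by_species.index]
    return counts_by_species.mul(factors, axis=0)


# --- TSV plumbing -------------------------------------------------------------


def read_census_table(path: Union[str, Path]) -> list[CladeCensus]:
    frame = pd.read_csv(path, sep="\t")
    required = ["clade", "n_species", "n_genomes", "n_proteins"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"census table {path} lacks columns: {missing}")
    return [
        CladeCensus(
            clade=str(row.clade),
            n_species=int(row.n_species),
            n_genomes=int(row.n_genomes),
            n_proteins=int(row.n_proteins),
        )
        for row in frame.itertuples()
    ]


def write_census_table(census: Sequence[CladeCensus], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "clade": c.clade,
                "n_species": c.n_species,
                "n_genomes": c.n_genomes,
                "n_proteins": c.n_proteins,
            }
            for c in census
        ]
    ).to_csv(path, sep="\t", index=False)
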