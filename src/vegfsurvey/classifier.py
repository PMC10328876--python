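"""Annotation-driven classification of homology-search hits.

The survey assigns each homology-search hit to one of the ten named
vertebrate PDGF/VEGF ortholog groups using, in order:

1. *primary categorization* of the hit's free-text annotation (Hit_def)
   against a synonym map — a hit is *synonymous* when the annotation names
   the query's own group, *related* when it names a different group, and
   *undefined* otherwise (e.g. "hypothetical protein");
2. a *secondary-search majority vote*: undefined hits are re-searched and
   assigned to a group only when strictly more than 50% of the annotated
   secondary hits agree (a deliberately conservative threshold);
3. a *profile-search fallback* applying the same vote rule to
   profile-search (RPS-style) results.

Hits that remain undecided are reported as unresolved.  False positives —
annotations naming a known non-PDGF/VEGF protein, or sequences whose domain
architecture is BR3P-repeats-only — are flagged and excluded from group
assignment.  Searches themselves are pluggable: any callable mapping a
sequence to a list of hits satisfies the provider contract, and the test
suite uses deterministic fixture providers.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .motifscan import classify_architecture

__all__ = [
    "ORTHOLOG_GROUPS",
    "REFERENCE_QUERIES",
    "DEFAULT_BLOCKLIST",
    "SynonymMap",
    "HitRecord",
    "ClassificationResult",
    "FixtureSearchProvider",
    "categorize_primary",
    "majority_vote",
    "classify_hit_table",
    "assign_isoform_bucket",
    "isoform_ratio",
    "nearest_reference_assign",
    "enumerate_search_jobs",
    "read_hit_table",
    "write_hit_table",
    "results_to_frame",
]

#: The ten named vertebrate ortholog groups of the PDGF/VEGF family.
ORTHOLOG_GROUPS = (
    "VEGF-A",
    "PlGF",
    "VEGF-B",
    "VEGF-C",
    "VEGF-D",
    "VEGF-F",
    "PDGF-A",
    "PDGF-B",
    "PDGF-C",
    "PDGF-D",
)

#: The 13 reference query proteins used to seed the survey (human paralogs
#: and splice isoforms plus the snake-venom VEGF vammin-1).
REFERENCE_QUERIES = (
    "PDGF-A",
    "PDGF-B",
    "PDGF-C",
    "PDGF-D",
    "PlGF-3",
    "VEGF-A121",
    "VEGF-A165",
    "VEGF-A206",
    "VEGF-B167",
    "VEGF-B186",
    "VEGF-C",
    "VEGF-D",
    "vammin-1",
)

_DEFAULT_GROUP_ALIASES: dict[str, list[str]] = {
    "VEGF-A": ["VEGF-A", "VEGFA", "vascular endothelial growth factor A"],
    "PlGF": ["PlGF", "PGF", "placenta growth factor", "placental growth factor"],
    "VEGF-B": ["VEGF-B", "VEGFB", "vascular endothelial growth factor B"],
    "VEGF-C": ["VEGF-C", "VEGFC", "vascular endothelial growth factor C"],
    "VEGF-D": [
        "VEGF-D",
        "VEGFD",
        "FIGF",
        "fos-induced growth factor",
        "c-fos-induced growth factor",
        "vascular endothelial growth factor D",
    ],
    "VEGF-F": ["VEGF-F", "vammin", "svVEGF", "snake venom vascular endothelial growth factor"],
    "PDGF-A": ["PDGF-A", "PDGFA", "platelet-derived growth factor A", "platelet-derived growth factor alpha"],
    "PDGF-B": ["PDGF-B", "PDGFB", "platelet-derived growth factor B", "platelet-derived growth factor beta", "c-sis"],
    "PDGF-C": ["PDGF-C", "PDGFC", "platelet-derived growth factor C"],
    "PDGF-D": ["PDGF-D", "PDGFD", "platelet-derived growth factor D"],
}

#: Annotation phrases signalling an uninformative (undefined) record.
DEFAULT_UNDEFINED_MARKERS = (
    "hypothetical protein",
    "uncharacterized protein",
    "unnamed protein product",
    "predicted protein",
    "uncharacterized",
)

#: Named non-PDGF/VEGF proteins whose curated annotations mark a hit as a
#: false positive (cysteine-rich repeat proteins dominate this set).
DEFAULT_BLOCKLIST = (
    "balbiani ring",
    "BR3P",
    "balbiani ring protein 3",
    "collagen",
    "fibrillin",
    "mucin",
    "von Willebrand factor",
)


def _alias_regex(alias: str) -> re.Pattern:
    # Whole-token / whole-phrase, case-insensitive: the alias must not be
    # embedded in a longer alphanumeric run ("PGF" must not match "xPGFy").
    return re.compile(
        r"(?<![A-Za-z0-9])" + re.escape(alias) + r"(?![A-Za-z0-9])",
        re.IGNORECASE,
    )


class SynonymMap:
    """Ortholog group -> annotation aliases, plus undefined-marker phrases.

    Alias matching is case-insensitive whole-token/whole-phrase matching;
    alias lists must be pairwise disjoint across groups.
    """

    def __init__(
        self,
        groups: Optional[Mapping[str, Sequence[str]]] = None,
        undefined_markers: Sequence[str] = DEFAULT_UNDEFINED_MARKERS,
    ):
        src = groups if groups is not None else _DEFAULT_GROUP_ALIASES
        self.groups: dict[str, list[str]] = {g: list(a) for g, a in src.items()}
        self.undefined_markers = list(undefined_markers)
        seen: dict[str, str] = {}
        for group, aliases in self.groups.items():
            if not aliases:
                raise ValueError(f"group {group!r} has an empty alias list")
            for alias in aliases:
                key = alias.lower()
                if key in seen and seen[key] != group:
                    raise ValueError(
                        f"alias {alias!r} is shared by groups {seen[key]!r} and {group!r}"
                    )
                seen[key] = group
        self._compiled = [
            (group, _alias_regex(alias))
            for group, aliases in self.groups.items()
            for alias in sorted(aliases, key=len, reverse=True)
        ]

    def matched_groups(self, text: str) -> set[str]:
        """Set of groups with at least one alias occurring in ``text``."""
        return {group for group, rx in self._compiled if rx.search(text)}

    def alias_for(self, group: str) -> str:
        return self.groups[group][0]

    # -- config round-trip ---------------------------------------------------

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"groups": self.groups, "undefined_markers": self.undefined_markers},
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SynonymMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            groups=data["groups"],
            undefined_markers=data.get("undefined_markers", DEFAULT_UNDEFINED_MARKERS),
        )


@dataclass
class HitRecord:
    """One homology-search hit."""

    query_group: str
    hit_id: str
    hit_def: str
    clade: str = ""
    evalue: float = 1e-10
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"hit {self.hit_id!r}: evalue must be positive")


@dataclass
class ClassificationResult:
    """Outcome of the classification cascade for one unique hit."""

    hit_id: str
    category: str  # synonymous | related | undefined
    assigned_group: Optional[str]
    assignment_route: str  # primary | secondary_vote | profile_fallback | unresolved
    flags: set[str] = field(default_factory=set)
    clade: str = ""
    query_group: str = ""

    def __post_init__(self) -> None:
        fp = bool(self.flags & {"false_positive_named_other", "br3p_only"})
        ok = self.assignment_route != "unresolved" and not fp
        if (self.assigned_group is not None) != ok:
            raise ValueError(
                f"hit {self.hit_id!r}: assigned_group must be set exactly when the "
                "route resolved and no false-positive flag is present"
            )
        if "too_short" in self.flags and self.assigned_group is not None:
            raise ValueError(f"hit {self.hit_id!r}: too_short cannot co-occur with an assignment")


SearchProvider = Callable[[str], list[HitRecord]]


class FixtureSearchProvider:
    """Deterministic search provider backed by a sequence -> hits mapping."""

    def __init__(self, hits_by_sequence: Mapping[str, list[HitRecord]]):
        self._hits = dict(hits_by_sequence)

    def __call__(self, sequence: str) -> list[HitRecord]:
        return list(self._hits.get(sequence, []))

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "FixtureSearchProvider":
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        mapping: dict[str, list[HitRecord]] = {}
        for _, row in frame.iterrows():
            mapping.setdefault(row["sequence"], []).append(
                HitRecord(
                    query_group=row.get("query_group", ""),
                    hit_id=row["hit_id"],
                    hit_def=row["hit_def"],
                    clade=row.get("clade", ""),
                    evalue=float(row.get("evalue", "1e-10") or "1e-10"),
                )
            )
        return cls(mapping)

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = [
            {
                "sequence": seq,
                "query_group": h.query_group,
                "hit_id": h.hit_id,
                "hit_def": h.hit_def,
                "clade": h.clade,
                "evalue": h.evalue,
            }
            for seq, hits in self._hits.items()
            for h in hits
        ]
        pd.DataFrame(rows, columns=["sequence", "query_group", "hit_id", "hit_def", "clade", "evalue"]).to_csv(
            path, sep="\t", index=False
        )


# --- primary categorization and voting -------------------------------------


def categorize_primary(hit: HitRecord, synonym_map: SynonymMap) -> str:
    """Categorize a hit from its annotation: synonymous/related/undefined."""
    if not hit.hit_def:
        raise ValueError(f"hit {hit.hit_id!r} has an empty hit_def")
    groups = synonym_map.matched_groups(hit.hit_def)
    if hit.query_group in groups:
        return "synonymous"
    if groups:
        return "related"
    return "undefined"


def majority_vote(
    secondary_hits: Iterable[HitRecord],
    synonym_map: SynonymMap,
    threshold: float = 0.5,
) -> Optional[str]:
    """Strict majority vote over annotated secondary hits.

    The denominator is the number of secondary hits whose annotation maps
    unambiguously to a single group; a group wins only with strictly more
    than ``threshold`` of those votes.  Returns None when undecided (empty
    or tied vote).
    """
    counts: dict[str, int] = {}
    total = 0
    for hit in secondary_hits:
        groups = synonym_map.matched_groups(hit.hit_def)
        if len(groups) != 1:
            continue  # undefined or ambiguous annotations do not vote
        (group,) = groups
        counts[group] = counts.get(group, 0) + 1
        total += 1
    if total == 0:
        return None
    best_group, best = max(counts.items(), key=lambda kv: kv[1])
    if best / total > threshold:
        return best_group
    return None


def _dedup(hits: Sequence[HitRecord]) -> list[HitRecord]:
    seen: set[str] = set()
    unique = []
    for hit in hits:
        if hit.hit_id in seen:
            continue
        seen.add(hit.hit_id)
        unique.append(hit)
    return unique


def classify_hit_table(
    hits: Sequence[HitRecord],
    synonym_map: Optional[SynonymMap] = None,
    secondary_provider: Optional[SearchProvider] = None,
    profile_provider: Optional[SearchProvider] = None,
    min_length: int = 60,
    vote_threshold: float = 0.5,
    blocklist: Sequence[str] = DEFAULT_BLOCKLIST,
) -> tuple[list[ClassificationResult], dict]:
    """Run the full classification cascade over a hit table.

    Steps: deduplicate by hit id (first occurrence wins); primary
    categorization; undefined hits without a sequence of at least
    ``min_length`` residues are excluded as too short; remaining undefined
    hits go to the secondary-search majority vote and, still undecided, to
    the profile-search fallback; anything left is unresolved.  Hits whose
    annotation names a blocklisted non-family protein, or whose domain
    architecture is BR3P-only, are flagged as false positives and carry no
    assignment.

    Returns the per-hit results plus a summary with stage counts and the
    fraction of unique hits classified programmatically.
    """
    synonym_map = synonym_map or SynonymMap()
    unique = _dedup(hits)
    block_rx = [_alias_regex(term) for term in blocklist]
    results: list[ClassificationResult] = []
    n_routes = {"primary": 0, "secondary_vote": 0, "profile_fallback": 0, "unresolved": 0}
    n_fp = 0
    for hit in unique:
        flags: set[str] = set()
        if any(rx.search(hit.hit_def) for rx in block_rx):
            flags.add("false_positive_named_other")
        if hit.sequence:
            try:
                arch = classify_architecture(hit.sequence, sequence_id=hit.hit_id)
            except ValueError:
                arch = None
            if arch is not None and arch.label == "BR3P_only":
                flags.add("br3p_only")
        category = categorize_primary(hit, synonym_map)
        group: Optional[str] = None
        route = "unresolved"
        if category == "synonymous":
            group, route = hit.query_group, "primary"
        elif category == "related":
            matched = synonym_map.matched_groups(hit.hit_def)
            if len(matched) == 1:
                group, route = next(iter(matched)), "primary"
            else:
                category = "undefined"  # ambiguous annotation: treat as undefined
        if category == "undefined" and route == "unresolved":
            if hit.sequence is None or len(hit.sequence) < min_length:
                flags.add("too_short")
            else:
                for provider, provider_route, stage in (
                    (secondary_provider, "secondary_vote", "secondary search"),
                    (profile_provider, "profile_fallback", "profile search"),
                ):
                    if provider is None:
                        continue
                    try:
                        voted = majority_vote(
                            provider(hit.sequence), synonym_map, vote_threshold
                        )
                    except Exception as exc:
                        raise RuntimeError(
                            f"search provider failed at stage {stage!r} for hit "
                            f"{hit.hit_id!r}: {exc}"
                        ) from exc
                    if voted is not None:
                        group, route = voted, provider_route
                        break
        if flags & {"false_positive_named_other", "br3p_only"}:
            n_fp += 1
            group = None
        if group is None:
            route = "unresolved"
        n_routes[route] += 1
        results.append(
            ClassificationResult(
                hit_id=hit.hit_id,
                category=category,
                assigned_group=group,
                assignment_route=route,
                flags=flags,
                clade=hit.clade,
                query_group=hit.query_group,
            )
        )
    n_unique = len(unique)
    n_assigned = sum(1 for r in results if r.assigned_group is not None)
    summary = {
        "n_input": len(hits),
        "n_unique": n_unique,
        "n_primary": n_routes["primary"],
        "n_secondary_vote": n_routes["secondary_vote"],
        "n_profile_fallback": n_routes["profile_fallback"],
        "n_unresolved": n_routes["unresolved"],
        "n_false_positive": n_fp,
        "n_too_short": sum(1 for r in results if "too_short" in r.flags),
        "n_assigned": n_assigned,
        "fraction_programmatic": n_assigned / n_unique if n_unique else float("nan"),
    }
    return results, summary


# --- VEGF-A isoform bucketing -----------------------------------------------

#: Mature lengths of the four major VEGF-A splice isoforms.
VEGFA_ISOFORM_LENGTHS = (121, 165, 189, 206)
#: Signal-peptide length separating mature from precursor forms.
SIGNAL_PEPTIDE_LENGTH = 26


def assign_isoform_bucket(
    protein_length: int,
    reference_lengths: Sequence[int] = VEGFA_ISOFORM_LENGTHS,
    tolerance: int = 5,
    signal_peptide_length: int = SIGNAL_PEPTIDE_LENGTH,
) -> Optional[str]:
    """Bucket a VEGF-A protein by length against reference isoform lengths.

    Each reference isoform is represented by its mature length and its
    precursor length (mature + signal peptide).  The nearest reference form
    within ``tolerance`` residues wins; exact distance ties break toward the
    shorter isoform.  Returns the bucket label (e.g. ``"165"``) or None when
    unbinned.
    """
    if protein_length <= 0:
        raise ValueError(f"protein length must be positive, got {protein_length}")
    best: Optional[tuple[int, int]] = None  # (distance, isoform)
    for iso in sorted(reference_lengths):
        for form in (iso, iso + signal_peptide_length):
            dist = abs(protein_length - form)
            if dist > tolerance:
                continue
            if best is None or dist < best[0]:
                best = (dist, iso)
            # ties keep the earlier (shorter) isoform
    return str(best[1]) if best else None


def isoform_ratio(
    bucket_counts: Mapping[Union[str, int], int],
    order: Optional[Sequence[Union[str, int]]] = None,
) -> str:
    """Render bucket counts as a reduced integer ratio, e.g. ``"9:4:3:1"``.

    Counts are divided by their collective GCD; zero counts are preserved.
    ``order`` fixes the rendering order (default: descending count).
    """
    if not bucket_counts or all(c == 0 for c in bucket_counts.values()):
        raise ValueError("isoform ratio requires at least one non-zero count")
    if any(c < 0 for c in bucket_counts.values()):
        raise ValueError("bucket counts must be non-negative")
    keys = list(order) if order is not None else sorted(
        bucket_counts, key=lambda k: -bucket_counts[k]
    )
    counts = [bucket_counts[k] for k in keys]
    g = math.gcd(*counts) if len(counts) > 1 else counts[0]
    return ":".join(str(c // g) for c in counts)


# --- tree-based nearest-reference assignment --------------------------------


def nearest_reference_assign(
    tree,
    reference_labels: Mapping[str, str],
    rel_tol: float = 1e-9,
) -> dict[str, Optional[str]]:
    """Assign each unlabeled leaf the group of its nearest reference leaf.

    Distance is patristic (sum of branch lengths).  A leaf exactly
    equidistant from reference leaves of two different groups is flagged
    ambiguous and maps to None.  Raises ValueError when the tree contains no
    reference leaves.
    """
    leaves = tree.leaf_labels()
    refs = {l: g for l, g in reference_labels.items() if l in set(leaves)}
    if not refs:
        raise ValueError("tree contains no reference leaves")
    assignments: dict[str, Optional[str]] = {}
    for leaf in leaves:
        if leaf in refs:
            continue
        dists = [(tree.patristic_distance(leaf, ref), group) for ref, group in refs.items()]
        dmin = min(d for d, _ in dists)
        close = {
            group
            for d, group in dists
            if math.isclose(d, dmin, rel_tol=rel_tol, abs_tol=rel_tol)
        }
        assignments[leaf] = next(iter(close)) if len(close) == 1 else None
    return assignments


# --- search-job bookkeeping --------------------------------------------------


def enumerate_search_jobs(
    queries: Sequence[str],
    clades: Sequence[str],
) -> list[tuple[str, str]]:
    """Cross reference queries with clades into the survey's search jobs."""
    if not queries or not clades:
        raise ValueError("both queries and clades must be non-empty")
    return [(q, c) for q in queries for c in clades]


# --- TSV plumbing -------------------------------------------------------------

_HIT_COLUMNS = ["query_group", "hit_id", "hit_def", "clade", "evalue", "sequence"]


def read_hit_table(path: Union[str, Path]) -> list[HitRecord]:
    """Read a hit table TSV (columns: query_group, hit_id, hit_def, clade,
    evalue, sequence — the last optional)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _HIT_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise ValueError(f"hit table {path} lacks required columns: {missing}")
    hits = []
    for _, row in frame.iterrows():
        seq = row.get("sequence", "")
        hits.append(
            HitRecord(
                query_group=row["query_group"],
                hit_id=row["hit_id"],
                hit_def=row["hit_def"],
                clade=row["clade"],
                evalue=float(row["evalue"]),
                sequence=seq if seq else None,
            )
        )
    return hits


def write_hit_table(hits: Sequence[HitRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "query_group": h.query_group,
            "hit_id": h.hit_id,
            "hit_def": h.hit_def,
            "clade": h.clade,
            "evalue": h.evalue,
            "sequence": h.sequence or "",
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False)


def results_to_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Tabulate classification results (one row per unique hit)."""
    return pd.DataFrame(
        [
            {
                "hit_id": r.hit_id,
                "query_group": r.query_group,
                "clade": r.clade,
                "category": r.category,
                "assigned_group": r.assigned_group or "",
                "assignment_route": r.assignment_route,
                "flags": ",".join(sorted(r.flags)),
            }
            for r in results
        ],
        columns=[
            "hit_id",
            "query_group",
            "clade",
            "category",
            "assigned_group",
            "assignment_route",
            "flags",
        ],
    )
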