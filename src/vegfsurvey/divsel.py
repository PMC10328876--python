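"""Positional diversity and counting-based per-site selection tests.

Diversity
---------
Per-column diversity is the inverse Simpson index normalized by alphabet
size, ``d = 1 / (N * sum_i p_i**2)``, where the p_i are the column's state
frequencies and N the alphabet size (20 amino acids, or 5 nucleotide states
counting the gap as a state).  d ranges from 1/N (monomorphic column) to 1
(uniform over the alphabet).  Sliding-window averaging (default width 11,
centered, truncated at the edges) turns per-site scalars into conservation
profiles.

Selection
---------
The per-codon-site test is a counting approximation in the SLAC family:
ancestral codon states are reconstructed by parsimony (unit cost per
codon-state change; ambiguity kept as sets and averaged over uniformly
across all minimum-change resolutions), substitutions on each branch are
decomposed into single-nucleotide steps averaged over all minimal
mutational paths (paths through stop codons are excluded when avoidable),
and the observed synonymous fraction is compared with its neutral
expectation — derived from Nei–Gojobori-style synonymous/nonsynonymous site
fractions of the codons present at the site — by an exact two-sided
binomial test.  A site is called purifying (nonsynonymous deficit) or
diversifying (excess) when p falls below alpha (default 0.001); no
multiple-testing correction is applied by default.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Alignment, CodonAlignment, STOP_CODONS, Tree, translate_codon

__all__ = [
    "PROTEIN_STATES",
    "NUCLEOTIDE_STATES",
    "DiversityProfile",
    "SiteSelectionResult",
    "positional_diversity",
    "window_average",
    "ng_site_fractions",
    "parsimony_ancestors",
    "slac_site_test",
    "selection_to_frame",
]

PROTEIN_STATES = tuple("ACDEFGHIKLMNPQRSTVWY")
NUCLEOTIDE_STATES = ("A", "T", "G", "C", "-")


@dataclass
class DiversityProfile:
    """Per-column inverse-Simpson diversity with its state frequencies."""

    diversity: np.ndarray  # length = columns; NaN marks undefined columns
    frequencies: np.ndarray  # columns x alphabet size
    states: tuple[str, ...]
    alphabet: str

    def __len__(self) -> int:
        return len(self.diversity)


def positional_diversity(
    alignment: Alignment, alphabet_mode: Optional[str] = None
) -> DiversityProfile:
    """Column-wise normalized inverse-Simpson diversity of an alignment.

    Protein mode excludes gaps (and nonstandard residues) from the
    frequency counts; an all-gap column is marked undefined (NaN).
    Nucleotide mode counts the gap as a fifth state, so only columns with no
    countable state at all (e.g. all ambiguity codes) are undefined.
    """
    mode = alphabet_mode or alignment.alphabet
    if mode not in ("protein", "nucleotide"):
        raise ValueError(f"unknown alphabet mode {mode!r}")
    if mode != alignment.alphabet:
        raise ValueError(
            f"alphabet mode {mode!r} conflicts with alignment alphabet "
            f"{alignment.alphabet!r}"
        )
    states = PROTEIN_STATES if mode == "protein" else NUCLEOTIDE_STATES
    index = {s: i for i, s in enumerate(states)}
    n_states = len(states)
    cols = alignment.columns
    freqs = np.zeros((cols, n_states))
    diversity = np.full(cols, np.nan)
    rows = [r.residues for r in alignment.records]
    for j in range(cols):
        counts = np.zeros(n_states)
        for row in rows:
            ch = row[j]
            if mode == "nucleotide" and ch == "U":
                ch = "T"
            i = index.get(ch)
            if i is not None:
                counts[i] += 1
        total = counts.sum()
        if total == 0:
            continue
        p = counts / total
        freqs[j] = p
        diversity[j] = 1.0 / (n_states * float(np.sum(p**2)))
    return DiversityProfile(
        diversity=diversity, frequencies=freqs, states=states, alphabet=mode
    )


def window_average(
    values: Sequence[float], w: int = 11, edge_rule: str = "shrink"
) -> np.ndarray:
    """Centered sliding-window mean of a per-site scalar.

    ``w`` must be odd.  Interior sites get the plain centered mean; near the
    edges the window keeps its width but is clamped inside the sequence
    (``edge_rule="shrink"``, the only supported rule), shrinking only when
    the whole input is shorter than ``w``.  Output length equals input
    length, and a constant input is returned unchanged.
    """
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window width must be odd and >= 1, got {w}")
    if edge_rule != "shrink":
        raise ValueError(f"unsupported edge rule {edge_rule!r}")
    arr = np.asarray(values, dtype=float)
    n = len(arr)
    if n == 0:
        return arr.copy()
    width = min(w, n)
    half = w // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - width)
        out[i] = arr[lo : lo + width].mean()
    return out


# --- codon-level counting -----------------------------------------------------

_BASES = "ACGT"


@lru_cache(maxsize=None)
def ng_site_fractions(codon: str, genetic_code: int = 1) -> tuple[float, float]:
    """Nei–Gojobori-style synonymous/nonsynonymous site fractions of a codon.

    Each codon position contributes the fraction of its single-nucleotide
    changes that are synonymous, with changes to stop codons excluded from
    numerator and denominator; the three contributions sum to
    ``S_site + N_site = 3``.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or "-" in codon:
        raise ValueError(f"site fractions require an ungapped codon, got {codon!r}")
    aa = translate_codon(codon, genetic_code)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site fractions")
    if aa == "X":
        raise ValueError(f"ambiguous codon {codon!r}")
    s_site = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            alt_aa = translate_codon(alt, genetic_code)
            if alt_aa == "*":
                continue
            valid += 1
            if alt_aa == aa:
                syn += 1
        if valid:
            s_site += syn / valid
    return s_site, 3.0 - s_site


@lru_cache(maxsize=None)
def _pair_path_sn(a: str, b: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) steps over minimal paths a -> b.

    For codons differing at k positions, all k! orderings of the single-
    nucleotide steps are enumerated; orderings passing through a stop codon
    are dropped unless all do.  The averages satisfy s + n = k.
    """
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = a
        s = n = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            if translate_codon(nxt) == translate_codon(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        paths.append((blocked, s, n))
    usable = [p for p in paths if not p[0]] or paths
    s_avg = sum(p[1] for p in usable) / len(usable)
    n_avg = sum(p[2] for p in usable) / len(usable)
    return s_avg, n_avg


# --- per-site parsimony machinery --------------------------------------------

_INF = 10**9


class _ENode:
    """Node of the per-site effective tree (gap-bearing leaves pruned)."""

    __slots__ = ("label", "children", "state", "up_cost", "up_count", "in_min", "out_cost", "out_count")

    def __init__(self, label, children=None, state=None):
        self.label = label
        self.children = children or []
        self.state = state


def _effective_tree(node, codon_by_leaf) -> Optional[_ENode]:
    """Prune leaves without data; collapse single-child internals."""
    if node.is_leaf():
        label = node.taxon.label if node.taxon else node.label
        state = codon_by_leaf.get(label)
        if state is None:
            return None
        return _ENode(label=label, state=state)
    kids = [_effective_tree(ch, codon_by_leaf) for ch in node.child_nodes()]
    kids = [k for k in kids if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    return _ENode(label=getattr(node, "_vs_label", None), children=kids)


def _up_pass(root: _ENode, state_index: dict[str, int]) -> None:
    K = len(state_index)
    for node in _postorder(root):
        if not node.children:
            cost = [_INF] * K
            count = [0] * K
            i = state_index[node.state]
            cost[i] = 0
            count[i] = 1
            node.up_cost, node.up_count = cost, count
            continue
        cost = [0] * K
        count = [1] * K
        for ch in node.children:
            in_min_cost = []
            in_min_count = []
            for a in range(K):
                best = min(
                    ch.up_cost[b] + (0 if a == b else 1) for b in range(K)
                )
                cnt = sum(
                    ch.up_count[b]
                    for b in range(K)
                    if ch.up_cost[b] + (0 if a == b else 1) == best
                )
                in_min_cost.append(best)
                in_min_count.append(cnt)
            ch.in_min = (in_min_cost, in_min_count)
            for a in range(K):
                cost[a] += in_min_cost[a]
                count[a] *= in_min_count[a]
        node.up_cost, node.up_count = cost, count


def _postorder(root: _ENode) -> list[_ENode]:
    out = []
    stack = [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    out.reverse()
    return out


def _site_parsimony(
    root: _ENode, states: Sequence[str]
) -> tuple[int, list[tuple[_ENode, _ENode, float, float]], dict]:
    """Min-change score, per-branch averaged (s, n), and MPR state sets.

    The branch averages weight every (parent state, child state) pair by the
    number of minimum-change joint labelings realizing it, which is exactly
    a uniform average over all minimal resolutions of the ancestral
    ambiguity.
    """
    state_index = {s: i for i, s in enumerate(states)}
    K = len(states)
    _up_pass(root, state_index)
    M = min(root.up_cost)
    root.out_cost = [0] * K
    root.out_count = [1] * K
    branch_sn: list[tuple[_ENode, _ENode, float, float]] = []
    mpr: dict = {}
    mpr[root] = frozenset(
        states[a] for a in range(K) if root.up_cost[a] + root.out_cost[a] == M
    )
    stack = [root]
    while stack:
        u = stack.pop()
        if not u.children:
            continue
        for ch in u.children:
            # cost/count of everything outside ch's subtree, given u's state
            rest_cost = []
            rest_count = []
            for a in range(K):
                c = u.out_cost[a]
                n = u.out_count[a]
                for sib in u.children:
                    if sib is ch:
                        continue
                    c += sib.in_min[0][a]
                    n *= sib.in_min[1][a]
                rest_cost.append(min(c, _INF))
                rest_count.append(n)
            # minimal-labeling-weighted pair counts on the branch (u, ch)
            total = 0
            s_acc = 0.0
            n_acc = 0.0
            for a in range(K):
                if rest_cost[a] >= _INF:
                    continue
                for b in range(K):
                    cost = rest_cost[a] + (0 if a == b else 1) + ch.up_cost[b]
                    if cost != M:
                        continue
                    w = rest_count[a] * ch.up_count[b]
                    if w == 0:
                        continue
                    total += w
                    if a != b:
                        s_step, n_step = _pair_path_sn(states[a], states[b])
                        s_acc += w * s_step
                        n_acc += w * n_step
            branch_sn.append(
                (u, ch, s_acc / total if total else 0.0, n_acc / total if total else 0.0)
            )
            # child's outside scores
            out_cost = []
            out_count = []
            for b in range(K):
                best = min(
                    rest_cost[a] + (0 if a == b else 1) for a in range(K)
                )
                cnt = sum(
                    rest_count[a]
                    for a in range(K)
                    if rest_cost[a] + (0 if a == b else 1) == best
                )
                out_cost.append(best)
                out_count.append(cnt)
            ch.out_cost, ch.out_count = out_cost, out_count
            if ch.children:
                mpr[ch] = frozenset(
                    states[b]
                    for b in range(K)
                    if ch.up_cost[b] + ch.out_cost[b] == M
                )
                stack.append(ch)
    return M, branch_sn, mpr


def _label_internal_nodes(tree: Tree) -> None:
    """Attach deterministic preorder labels to unlabeled internal nodes."""
    i = 0
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node._vs_label = node.label if node.label else f"node{i}"
        i += 1


def _site_codons(caln: CodonAlignment, site: int) -> dict[str, str]:
    """Ungapped, unambiguous sense codons per record at one site."""
    out = {}
    for rec in caln.alignment.records:
        codon = rec.residues[3 * site : 3 * site + 3]
        if "-" in codon or any(b not in _BASES for b in codon):
            continue
        out[rec.id] = codon
    return out


def parsimony_ancestors(
    tree: Tree, codon_alignment: CodonAlignment
) -> list[dict[str, frozenset]]:
    """Per-site ancestral codon-state sets by parsimony (MPR sets).

    For each codon site, returns a mapping from internal-node label (the
    node's own label, or a deterministic preorder ``node<i>`` label) to the
    set of codon states attainable in at least one minimum-change labeling.
    Ambiguity is retained as sets.  Leaves with gapped codons are pruned for
    that site; internal nodes pruned away with them are omitted.
    """
    _check_tree_alignment(tree, codon_alignment)
    _label_internal_nodes(tree)
    results = []
    for site in range(codon_alignment.n_sites):
        codons = _site_codons(codon_alignment, site)
        site_map: dict[str, frozenset] = {}
        if codons:
            root = _effective_tree(tree.dendropy_tree.seed_node, codons)
            if root is not None and root.children:
                states = sorted(set(codons.values()))
                _, _, mpr = _site_parsimony(root, states)
                site_map = {
                    node.label: state_set
                    for node, state_set in mpr.items()
                    if node.label is not None
                }
        results.append(site_map)
    return results


def _check_tree_alignment(tree: Tree, caln: CodonAlignment) -> None:
    leaf_set = set(tree.leaf_labels())
    aln_set = set(caln.alignment.ids())
    if leaf_set != aln_set:
        only_tree = sorted(leaf_set - aln_set)
        only_aln = sorted(aln_set - leaf_set)
        raise ValueError(
            "tree leaves and alignment ids differ "
            f"(tree only: {only_tree}, alignment only: {only_aln})"
        )


@dataclass
class SiteSelectionResult:
    """Observed and expected substitution counts for one codon site."""

    site: int
    s_obs: float
    n_obs: float
    S_site: float  # mean synonymous site fraction of codons at the site
    N_site: float
    dn_minus_ds: float
    p_value: float
    call: str  # purifying | diversifying | none

    def __post_init__(self) -> None:
        if self.s_obs < 0 or self.n_obs < 0:
            raise ValueError("observed counts must be non-negative")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value out of [0, 1]")


def slac_site_test(
    tree: Tree,
    codon_alignment: CodonAlignment,
    alpha: float = 0.001,
    root_unrooted: str = "error",
) -> list[SiteSelectionResult]:
    """Counting-based per-site selection test over a tree.

    Per site: substitutions between parsimony-resolved parent/child codons
    are counted on every branch (averaged over all minimal resolutions and
    minimal mutational paths), the expected synonymous proportion comes from
    the mean Nei–Gojobori site fractions of the codons present, and an exact
    two-sided binomial test compares the observed synonymous count against
    it.  Calls: purifying (nonsynonymous deficit, p < alpha), diversifying
    (excess, p < alpha), none otherwise.

    An unrooted tree raises unless ``root_unrooted="midpoint"``, which
    midpoint-roots a copy first.
    """
    if len(codon_alignment.alignment) < 3:
        raise ValueError("selection test requires at least 3 sequences")
    if not tree.is_rooted:
        if root_unrooted == "midpoint":
            tree = tree.midpoint_rooted()
        else:
            raise ValueError(
                "tree is unrooted; pass root_unrooted='midpoint' to midpoint-root it"
            )
    _check_tree_alignment(tree, codon_alignment)
    results = []
    for site in range(codon_alignment.n_sites):
        codons = _site_codons(codon_alignment, site)
        if not codons:
            results.append(
                SiteSelectionResult(site, 0.0, 0.0, float("nan"), float("nan"), 0.0, 1.0, "none")
            )
            continue
        fractions = [ng_site_fractions(c) for c in codons.values()]
        s_bar = float(np.mean([f[0] for f in fractions]))
        n_bar = 3.0 - s_bar
        s_obs = n_obs = 0.0
        states = sorted(set(codons.values()))
        if len(states) > 1:
            root = _effective_tree(tree.dendropy_tree.seed_node, codons)
            if root is not None and root.children:
                _, branch_sn, _ = _site_parsimony(root, states)
                s_obs = sum(b[2] for b in branch_sn)
                n_obs = sum(b[3] for b in branch_sn)
        p_syn_expected = s_bar / 3.0
        n_total = int(round(s_obs + n_obs))
        k_syn = min(int(round(s_obs)), n_total)
        if n_total > 0:
            p_value = float(
                stats.binomtest(k_syn, n_total, p_syn_expected, alternative="two-sided").pvalue
            )
        else:
            p_value = 1.0
        dn = n_obs / n_bar if n_bar > 0 else 0.0
        ds = s_obs / s_bar if s_bar > 0 else 0.0
        dn_minus_ds = dn - ds
        if p_value < alpha and dn_minus_ds < 0:
            call = "purifying"
        elif p_value < alpha and dn_minus_ds > 0:
            call = "diversifying"
        else:
            call = "none"
        results.append(
            SiteSelectionResult(
                site=site,
                s_obs=s_obs,
                n_obs=n_obs,
                S_site=s_bar,
                N_site=n_bar,
                dn_minus_ds=dn_minus_ds,
                p_value=p_value,
                call=call,
            )
        )
    return results


def site_branch_counts(
    tree: Tree, codon_alignment: CodonAlignment, site: int
) -> dict[str, tuple[float, float]]:
    """Per-branch averaged (s, n) substitution counts at one codon site.

    Branches are keyed by the label of their child-side node (internal nodes
    get deterministic preorder labels).  Branches pruned away at the site
    (gapped leaves) are absent.  Exposed for oracle cross-checks.
    """
    _check_tree_alignment(tree, codon_alignment)
    _label_internal_nodes(tree)
    codons = _site_codons(codon_alignment, site)
    out: dict[str, tuple[float, float]] = {}
    if not codons:
        return out
    states = sorted(set(codons.values()))
    root = _effective_tree(tree.dendropy_tree.seed_node, codons)
    if root is None or not root.children:
        return out
    if len(states) == 1:
        return {}
    _, branch_sn, _ = _site_parsimony(root, states)
    for _, child, s, n in branch_sn:
        out[child.label] = (s, n)
    return out


def selection_to_frame(results: Sequence[SiteSelectionResult]) -> pd.DataFrame:
    """Tabulate per-site selection results (sites reported 1-based)."""
    return pd.DataFrame(
        [
            {
                "site": r.site + 1,
                "s_obs": r.s_obs,
                "n_obs": r.n_obs,
                "S_site": r.S_site,
                "N_site": r.N_site,
                "dN_minus_dS": r.dn_minus_ds,
                "p": r.p_value,
                "call": r.call,
            }
            for r in results
        ]
    )
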