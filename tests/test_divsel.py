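"""Diversity closed forms, NG site counting, parsimony counting vs brute force."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vegfsurvey.divsel import (
    ng_site_fractions,
    parsimony_ancestors,
    positional_diversity,
    site_branch_counts,
    slac_site_test,
    window_average,
)
from vegfsurvey.seqio import (
    Alignment,
    CodonAlignment,
    SENSE_CODONS,
    SequenceRecord,
    parse_newick,
    translate_codon,
)


def _protein_alignment(columns):
    """Build an alignment from a list of column strings."""
    n = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(n)]
    return Alignment(
        records=[SequenceRecord(id=f"r{i}", residues=row) for i, row in enumerate(rows)],
        alphabet="protein",
    )


class TestDiversity:
    def test_monomorphic_protein_column(self):
        aln = _protein_alignment(["A" * 20])
        profile = positional_diversity(aln)
        assert profile.diversity[0] == pytest.approx(0.05)

    def test_two_state_even_split(self):
        aln = _protein_alignment(["A" * 10 + "V" * 10])
        assert positional_diversity(aln).diversity[0] == pytest.approx(0.1)

    def test_uniform_protein_column_is_maximal(self):
        aln = _protein_alignment(["ACDEFGHIKLMNPQRSTVWY"])
        assert positional_diversity(aln).diversity[0] == pytest.approx(1.0)

    def test_uniform_nucleotide_with_gap_state(self):
        aln = Alignment(
            records=[
                SequenceRecord(id=f"r{i}", residues=ch) for i, ch in enumerate("ATGC-")
            ],
            alphabet="nucleotide",
        )
        assert positional_diversity(aln).diversity[0] == pytest.approx(1.0)

    def test_all_gap_protein_column_undefined(self):
        aln = Alignment(
            records=[SequenceRecord(id=f"r{i}", residues="-A") for i in range(4)],
            alphabet="protein",
        )
        profile = positional_diversity(aln)
        assert math.isnan(profile.diversity[0])
        assert profile.diversity[1] == pytest.approx(0.05)

    def test_gaps_excluded_in_protein_mode(self):
        aln = _protein_alignment(["AAAA----"])
        assert positional_diversity(aln).diversity[0] == pytest.approx(0.05)

    def test_mode_conflict_rejected(self):
        aln = _protein_alignment(["AAAA"])
        with pytest.raises(ValueError, match="conflict"):
            positional_diversity(aln, "nucleotide")

    @given(st.lists(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"), min_size=2, max_size=40))
    @settings(deadline=None, max_examples=100)
    def test_bounds_and_permutation_invariance(self, column):
        aln = _protein_alignment(["".join(column)])
        d = positional_diversity(aln).diversity[0]
        assert 0.05 - 1e-12 <= d <= 1.0 + 1e-12
        shuffled = list(column)
        shuffled.reverse()
        aln2 = _protein_alignment(["".join(shuffled)])
        assert positional_diversity(aln2).diversity[0] == pytest.approx(d)
        # extremes characterize monomorphic / uniform columns
        if len(set(column)) == 1:
            assert d == pytest.approx(0.05)


class TestWindowAverage:
    def test_width_one_is_identity(self, rng):
        values = rng.normal(size=30)
        np.testing.assert_allclose(window_average(values, w=1), values)

    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(window_average([2.5] * 40, w=11), [2.5] * 40)

    def test_truncated_window_at_edge(self):
        values = [0, 0, 0, 11, 0, 0, 0]
        out = window_average(values, w=11)
        assert out[0] == pytest.approx(11 / 7)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            window_average([1.0, 2.0], w=4)

    def test_delta_mass_conservation_interior(self):
        # an interior delta contributes value/w to each of the w windows
        # covering it
        n, w = 51, 11
        values = np.zeros(n)
        values[25] = 7.0
        out = window_average(values, w=w)
        assert out.sum() == pytest.approx(7.0)
        assert np.count_nonzero(out) == w


class TestNgSiteFractions:
    @pytest.mark.parametrize(
        "codon,s_expected",
        [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0)],
    )
    def test_hand_enumerated_values(self, codon, s_expected):
        s, n = ng_site_fractions(codon)
        assert s == pytest.approx(s_expected)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng_site_fractions("TGA")

    def test_gapped_codon_rejected(self):
        with pytest.raises(ValueError, match="ungapped"):
            ng_site_fractions("A-G")

    def test_matches_independent_enumeration(self, rng):
        # independent oracle: enumerate all 9 neighbors from scratch
        for codon in rng.choice(SENSE_CODONS, size=20, replace=False):
            syn = tot = 0
            for pos, base in itertools.product(range(3), "ACGT"):
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1 :]
                if translate_codon(alt) == "*":
                    continue
            # per-position normalization oracle
            s_oracle = 0.0
            for pos in range(3):
                neigh = [
                    codon[:pos] + b + codon[pos + 1 :]
                    for b in "ACGT"
                    if b != codon[pos]
                ]
                sense = [c for c in neigh if translate_codon(c) != "*"]
                if sense:
                    s_oracle += sum(
                        translate_codon(c) == translate_codon(codon) for c in sense
                    ) / len(sense)
            assert ng_site_fractions(codon)[0] == pytest.approx(s_oracle)


# --- brute-force oracle for parsimony counting --------------------------------


def _oracle_path_sn(a, b):
    """Independent minimal-path (s, n) average by direct enumeration."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    outcomes = []
    for order in itertools.permutations(diff):
        cur, s, n, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if translate_codon(nxt) == "*":
                blocked = True
            if translate_codon(nxt) == translate_codon(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        outcomes.append((blocked, s, n))
    usable = [o for o in outcomes if not o[0]] or outcomes
    return (
        sum(o[1] for o in usable) / len(usable),
        sum(o[2] for o in usable) / len(usable),
    )


def _oracle_branch_counts(topology, leaf_states):
    """Enumerate all internal labelings; average branch (s, n) over minimal ones.

    ``topology``: dict internal label -> (child labels); children may be leaf
    or internal labels.  Root is "node0".
    """
    internals = sorted(topology)
    states = sorted(set(leaf_states.values()))
    edges = [
        (parent, child) for parent in internals for child in topology[parent]
    ]

    def label_cost(assign):
        full = {**leaf_states, **dict(zip(internals, assign))}
        return sum(full[p] != full[c] for p, c in edges)

    best = None
    minimal = []
    for assign in itertools.product(states, repeat=len(internals)):
        cost = label_cost(assign)
        if best is None or cost < best:
            best, minimal = cost, [assign]
        elif cost == best:
            minimal.append(assign)
    branch = {}
    for parent, child in edges:
        s_acc = n_acc = 0.0
        for assign in minimal:
            full = {**leaf_states, **dict(zip(internals, assign))}
            s, n = _oracle_path_sn(full[parent], full[child])
            s_acc += s
            n_acc += n
        branch[child] = (s_acc / len(minimal), n_acc / len(minimal))
    return best, branch


_TOPOLOGIES = [
    # (newick with internal labels, internal adjacency, leaves)
    (
        "((A:1,B:1)node1:1,(C:1,D:1)node2:1)node0;",
        {"node0": ("node1", "node2"), "node1": ("A", "B"), "node2": ("C", "D")},
        ["A", "B", "C", "D"],
    ),
    (
        "(((A:1,B:1)node2:1,C:1)node1:1,D:1)node0;",
        {"node0": ("node1", "D"), "node1": ("node2", "C"), "node2": ("A", "B")},
        ["A", "B", "C", "D"],
    ),
    (
        "((A:1,B:1)node1:1,C:1)node0;",
        {"node0": ("node1", "C"), "node1": ("A", "B")},
        ["A", "B", "C"],
    ),
]


class TestParsimonyAncestors:
    def test_identical_leaves_fix_every_ancestor(self, four_taxon_tree):
        records = [SequenceRecord(id=i, residues="ACT") for i in "ABCD"]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        (site,) = parsimony_ancestors(four_taxon_tree, caln)
        assert all(s == frozenset({"ACT"}) for s in site.values())

    def test_two_state_cherry_root_is_union(self):
        tree = parse_newick("(A:1,B:1);")
        records = [
            SequenceRecord(id="A", residues="ACT"),
            SequenceRecord(id="B", residues="ACG"),
        ]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        (site,) = parsimony_ancestors(tree, caln)
        assert set(site.values()) == {frozenset({"ACT", "ACG"})}

    def test_leaf_mismatch_rejected(self, four_taxon_tree):
        records = [SequenceRecord(id=i, residues="ACT") for i in "ABCE"]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        with pytest.raises(ValueError, match="differ"):
            parsimony_ancestors(four_taxon_tree, caln)

    def test_mpr_sets_match_brute_force(self, rng):
        newick, topo, leaves = _TOPOLOGIES[0]
        tree = parse_newick(newick)
        pool = ["ACT", "ACA", "GCT", "TCT"]
        for _ in range(40):
            leaf_states = {l: pool[int(rng.integers(len(pool)))] for l in leaves}
            records = [SequenceRecord(id=l, residues=leaf_states[l]) for l in leaves]
            caln = CodonAlignment(
                alignment=Alignment(records=records, alphabet="nucleotide")
            )
            (site,) = parsimony_ancestors(tree, caln)
            # brute-force MPR sets: states appearing in some minimal labeling
            internals = sorted(topo)
            states = sorted(set(leaf_states.values()))
            edges = [(p, c) for p in internals for c in topo[p]]
            costs = {}
            for assign in itertools.product(states, repeat=len(internals)):
                full = {**leaf_states, **dict(zip(internals, assign))}
                costs[assign] = sum(full[p] != full[c] for p, c in edges)
            best = min(costs.values())
            expected = {
                node: frozenset(
                    assign[i]
                    for assign, c in costs.items()
                    if c == best
                    for i in [internals.index(node)]
                )
                for node in internals
            }
            assert site == expected


class TestBranchCountsOracle:
    """Implementation counts equal brute-force minimal-path enumeration."""

    def test_random_instances_match_brute_force(self, rng):
        n_checked = 0
        for trial in range(160):
            newick, topo, leaves = _TOPOLOGIES[trial % len(_TOPOLOGIES)]
            tree = parse_newick(newick)
            n_sites = int(rng.integers(1, 4))
            leaf_rows = {
                l: "".join(
                    SENSE_CODONS[int(i)]
                    for i in rng.integers(len(SENSE_CODONS), size=n_sites)
                )
                for l in leaves
            }
            caln = CodonAlignment(
                alignment=Alignment(
                    records=[
                        SequenceRecord(id=l, residues=leaf_rows[l]) for l in leaves
                    ],
                    alphabet="nucleotide",
                )
            )
            for site in range(n_sites):
                observed = site_branch_counts(tree, caln, site)
                leaf_states = {l: leaf_rows[l][3 * site : 3 * site + 3] for l in leaves}
                if len(set(leaf_states.values())) == 1:
                    assert observed == {}
                    continue
                _, expected = _oracle_branch_counts(topo, leaf_states)
                assert set(observed) == set(expected)
                for child in expected:
                    assert observed[child][0] == pytest.approx(expected[child][0]), (
                        newick,
                        leaf_states,
                        child,
                    )
                    assert observed[child][1] == pytest.approx(expected[child][1])
                n_checked += 1
        assert n_checked >= 100


class TestSlacSiteTest:
    def test_invariant_site_not_called(self, four_taxon_tree):
        records = [SequenceRecord(id=i, residues="GGG") for i in "ABCD"]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        (res,) = slac_site_test(four_taxon_tree, caln)
        assert res.s_obs == res.n_obs == 0
        assert res.p_value == 1.0
        assert res.call == "none"

    def test_two_codon_change_averages_paths(self, four_taxon_tree, toy_codon_alignment):
        res = slac_site_test(four_taxon_tree, toy_codon_alignment)
        # site 0: single ACT->GCA event on one branch, (1, 1) over both orders
        assert res[0].s_obs == pytest.approx(1.0)
        assert res[0].n_obs == pytest.approx(1.0)
        # site 1: GGG/GGA synonymous wobble
        assert res[1].s_obs == pytest.approx(1.0)
        assert res[1].n_obs == pytest.approx(0.0)

    def test_all_synonymous_changes_yield_small_p(self):
        # star-like tree: 8 leaves alternating between GGG and GGA (Gly),
        # expected synonymous proportion 1/3, all observed changes synonymous
        newick = "(" + ",".join(
            f"L{i}:1" for i in range(8)
        ) + ");"
        tree = parse_newick(newick)
        records = [
            SequenceRecord(id=f"L{i}", residues="GGG" if i % 2 else "GGA")
            for i in range(8)
        ]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        (res,) = slac_site_test(tree, caln)
        assert res.n_obs == 0
        assert res.s_obs == 4
        # exact two-sided binomial by hand: sum pmf over outcomes whose
        # probability does not exceed that of the observed k=4 of 4
        p0 = 1 / 3
        pmf = [math.comb(4, k) * p0**k * (1 - p0) ** (4 - k) for k in range(5)]
        expected_p = sum(p for p in pmf if p <= pmf[4] + 1e-12)
        assert res.p_value == pytest.approx(expected_p, rel=1e-9)
        assert res.call == ("purifying" if res.p_value < 0.001 else "none")

    def test_gapped_codons_skipped(self, four_taxon_tree):
        records = [
            SequenceRecord(id="A", residues="AC-"),
            SequenceRecord(id="B", residues="ACT"),
            SequenceRecord(id="C", residues="ACT"),
            SequenceRecord(id="D", residues="ACT"),
        ]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        (res,) = slac_site_test(four_taxon_tree, caln)
        assert res.s_obs == res.n_obs == 0

    def test_unrooted_tree_errors_with_midpoint_hint(self, toy_codon_alignment):
        tree = parse_newick("[&U] ((A:1,B:1):1,(C:1,D:1):1);", rooting="default-unrooted")
        with pytest.raises(ValueError, match="midpoint"):
            slac_site_test(tree, toy_codon_alignment)
        # and the midpoint option resolves it
        res = slac_site_test(tree, toy_codon_alignment, root_unrooted="midpoint")
        assert len(res) == 2

    def test_fewer_than_three_sequences_rejected(self):
        tree = parse_newick("(A:1,B:1);")
        records = [SequenceRecord(id=i, residues="ACT") for i in "AB"]
        caln = CodonAlignment(alignment=Alignment(records=records, alphabet="nucleotide"))
        with pytest.raises(ValueError, match="3 sequences"):
            slac_site_test(tree, caln)
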