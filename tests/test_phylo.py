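"""Neighbor-joining, Fitch parsimony, NNI search, bootstrap, rooting."""

import itertools

import numpy as np
import pytest

from itsphylo.align import Alignment
from itsphylo.distance import DistanceMatrix, distance_matrix
from itsphylo.phylo import (bootstrap, fitch_score, mp_search,
                            neighbor_joining, path_lengths, root_on_outgroup)
from itsphylo.simulate import SimConfig, simulate_alignment
from itsphylo.tree import Node, Tree, parse_newick


# ---------------------------------------------------------------------------
# helpers: tree enumeration and an independent parsimony oracle


def all_unrooted_topologies(leaves):
    """Every unrooted binary topology over the leaf names (3 for 4 leaves,
    15 for 5), built by inserting leaves on every edge."""
    base = Tree(Node(children=[]))
    root = base.root
    for name in leaves[:3]:
        root.add(Node(name=name))
    trees = [base]
    for name in leaves[3:]:
        grown = []
        for t in trees:
            edges = [n for n in t.root.walk() if n.parent is not None]
            for k in range(len(edges)):
                t2 = t.copy()
                target = [n for n in t2.root.walk() if n.parent is not None][k]
                parent = target.parent
                slot = parent.children.index(target)
                mid = Node()
                mid.add(target)
                mid.add(Node(name=name))
                mid.parent = parent
                parent.children[slot] = mid
                grown.append(t2)
        trees = grown
    return trees


def min_changes_by_assignment(tree, aln):
    """Minimum substitution count by brute-force enumeration of internal
    node states (independent of the Fitch implementation)."""
    leaves = {n.name: n for n in tree.root.walk() if n.is_leaf}
    internal = [n for n in tree.root.walk() if not n.is_leaf]
    total = 0
    for col in range(aln.column_count):
        obs = {t: aln.row(t)[col] for t in aln.taxa}
        best = None
        for assign in itertools.product("ACGT", repeat=len(internal)):
            state = {id(n): s for n, s in zip(internal, assign)}
            cost = 0
            for node in tree.root.walk():
                if node.parent is None:
                    continue
                child_state = (obs[node.name] if node.is_leaf
                               else state[id(node)])
                if child_state not in "ACGT":
                    continue  # missing: free
                parent_state = state[id(node.parent)]
                if child_state != parent_state:
                    cost += 1
            best = cost if best is None else min(best, cost)
        total += best
    return total


# ---------------------------------------------------------------------------
# neighbor-joining


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    lens = {leaf.name: leaf.length for leaf in tree.leaves()}
    assert lens["a"] == pytest.approx(0.1)
    assert lens["b"] == pytest.approx(0.2)
    assert lens["c"] == pytest.approx(0.3)


def random_binary_tree(names, rng):
    nodes = [Node(name=n, length=float(rng.uniform(0.05, 0.4))) for n in names]
    while len(nodes) > 3:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = Node(length=float(rng.uniform(0.05, 0.4)))
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


@pytest.mark.parametrize("n_taxa", [4, 6, 9])
def test_nj_recovers_additive_matrices_exactly(n_taxa, rng):
    names = [f"t{i}" for i in range(n_taxa)]
    true = random_binary_tree(names, rng)
    paths = path_lengths(true)
    d = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i != j:
                d[i, j] = paths[(min(a, b), max(a, b))]
    est = neighbor_joining(DistanceMatrix(names, d))
    assert est.bipartitions() == true.bipartitions()
    est_paths = path_lengths(est)
    for key, val in paths.items():
        assert est_paths[key] == pytest.approx(val, abs=1e-9)


def test_nj_matches_independent_implementation(sim14):
    skbio = pytest.importorskip("skbio")
    dm = distance_matrix(sim14.alignment)
    ours = neighbor_joining(dm)
    theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.d, ids=dm.taxa))
    theirs_mine = parse_newick(str(theirs).strip())
    assert ours.bipartitions() == theirs_mine.bipartitions()


def test_nj_rejects_nan():
    d3 = np.zeros((3, 3))
    d3[0, 1] = d3[1, 0] = np.nan
    with pytest.raises(ValueError, match="re-estimate"):
        neighbor_joining(DistanceMatrix(["a", "b", "c"], d3))


def test_nj_on_printed_fixture_topology(table3):
    tree = neighbor_joining(table3)
    bps = tree.bipartitions()
    assert frozenset({"D. williamsonii", "D. cariniferum"}) in bps
    assert frozenset({"D. jenkinsii", "D. lindleyi"}) in bps
    assert frozenset({"D. thyrsiflorum", "D. densiflorum"}) in bps


# ---------------------------------------------------------------------------
# Fitch parsimony


def test_fitch_invariant_alignment_zero():
    aln = Alignment(taxa=list("abcd"), rows=["AAAA"] * 4)
    tree = parse_newick("((a,b),(c,d));")
    assert fitch_score(tree, aln) == 0


def test_fitch_single_informative_column():
    aln = Alignment(taxa=list("abcd"), rows=["A", "A", "G", "G"])
    assert fitch_score(parse_newick("((a,b),(c,d));"), aln) == 1
    assert fitch_score(parse_newick("((a,c),(b,d));"), aln) == 2


def test_fitch_gap_is_missing():
    aln = Alignment(taxa=list("abcd"), rows=["A", "-", "G", "G"])
    assert fitch_score(parse_newick("((a,b),(c,d));"), aln) == 1


def test_fitch_label_mismatch_errors():
    aln = Alignment(taxa=list("abcd"), rows=["A"] * 4)
    with pytest.raises(ValueError, match="match"):
        fitch_score(parse_newick("((a,b),(c,x));"), aln)


def test_fitch_matches_state_enumeration_oracle(rng):
    names = list("abcde")
    aln = Alignment(taxa=names,
                    rows=["".join(rng.choice(list("ACGT-"), size=6))
                          for _ in names])
    for tree in all_unrooted_topologies(names)[::3]:
        assert fitch_score(tree, aln) == min_changes_by_assignment(tree, aln)


# ---------------------------------------------------------------------------
# parsimony search


def moderately_divergent_rows(rng, names, n_sites, p_mut=0.15):
    """Random rows mutated from a shared ancestor (K2P stays estimable)."""
    base = rng.choice(list("ACGT"), size=n_sites)
    rows = []
    for _ in names:
        row = base.copy()
        hit = rng.random(n_sites) < p_mut
        row[hit] = rng.choice(list("ACGT"), size=int(hit.sum()))
        rows.append("".join(row))
    return rows


def test_mp_search_finds_exhaustive_minimum(rng):
    names = list("abcde")
    for _ in range(3):
        aln = Alignment(taxa=names, rows=moderately_divergent_rows(rng, names, 20))
        best_exhaustive = min(fitch_score(t, aln)
                              for t in all_unrooted_topologies(names))
        _, score = mp_search(aln)
        assert score == best_exhaustive


def test_mp_search_invariant_alignment_keeps_start():
    aln = Alignment(taxa=list("abcd"), rows=["ACGTACGT"] * 4)
    start = parse_newick("((a,b),(c,d));")
    tree, score = mp_search(aln, start=start)
    assert score == 0
    assert tree.bipartitions() == start.bipartitions()


def test_mp_search_never_worse_than_start(rng):
    sim = simulate_alignment(SimConfig(n_taxa=8, seed=81))
    start = neighbor_joining(distance_matrix(sim.alignment))
    start_score = fitch_score(start, sim.alignment)
    _, score = mp_search(sim.alignment, start=start)
    assert score <= start_score


def test_mp_search_recovers_simulated_topology():
    newick = "((a:0.05,b:0.05):0.03,(c:0.05,d:0.05):0.03,(e:0.05,f:0.05):0.03);"
    sim = simulate_alignment(SimConfig(
        newick=newick, seed=7,
        sites={"ITS1": 500, "5.8S": 200, "ITS2": 500}))
    true = parse_newick(newick)
    tree, _ = mp_search(sim.alignment)
    assert tree.bipartitions() == true.bipartitions()


# ---------------------------------------------------------------------------
# bootstrap


def congruent_alignment():
    # 10 columns support {a,b} vs {c,d}; 30 are constant
    rows = {"a": "A" * 30 + "A" * 10, "b": "A" * 30 + "A" * 10,
            "c": "A" * 30 + "G" * 10, "d": "A" * 30 + "G" * 10}
    return Alignment(taxa=list(rows), rows=list(rows.values()))


def test_bootstrap_congruent_signal_gives_full_support():
    tree = bootstrap(congruent_alignment(), builder="nj", B=50, seed=3)
    supports = [n.support for n in tree.root.walk() if n.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_single_replicate_supports_are_binary(sim14):
    tree = bootstrap(sim14.alignment, builder="nj", B=1, seed=5)
    supports = [n.support for n in tree.root.walk() if n.support is not None]
    assert supports and set(supports) <= {0.0, 100.0}


def test_bootstrap_reproducible_and_bounded(sim14):
    t1 = bootstrap(sim14.alignment, builder="nj", B=20, seed=11)
    t2 = bootstrap(sim14.alignment, builder="nj", B=20, seed=11)
    assert t1.to_newick() == t2.to_newick()
    supports = [n.support for n in t1.root.walk() if n.support is not None]
    assert all(0.0 <= s <= 100.0 for s in supports)


def test_bootstrap_mp_builder():
    tree = bootstrap(congruent_alignment(), builder="mp", B=20, seed=3)
    supports = [n.support for n in tree.root.walk() if n.support is not None]
    assert supports and all(s == 100.0 for s in supports)


def test_bootstrap_rejects_bad_args(sim14):
    with pytest.raises(ValueError):
        bootstrap(sim14.alignment, B=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap(sim14.alignment, builder="ml", B=5, seed=1)


# ---------------------------------------------------------------------------
# rooting and Newick round trips


def test_root_on_leaf_of_three_taxon_tree():
    tree = neighbor_joining(DistanceMatrix(
        list("abc"), np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])))
    rooted = root_on_outgroup(tree, "a")
    assert rooted.rooted and len(rooted.root.children) == 2
    assert sorted(rooted.leaf_names()) == ["a", "b", "c"]


def test_root_missing_label_errors(table3):
    tree = neighbor_joining(table3)
    with pytest.raises(KeyError):
        root_on_outgroup(tree, "not-a-taxon")


def test_newick_round_trip_preserves_bipartitions(rng):
    names = [f"t{i}" for i in range(20)]
    tree = random_binary_tree(names, rng)
    back = parse_newick(tree.to_newick())
    assert back.bipartitions() == tree.bipartitions()
    back_lens = {l.name: l.length for l in back.leaves()}
    for leaf in tree.leaves():
        assert back_lens[leaf.name] == pytest.approx(leaf.length, abs=1e-6)


def test_rooting_preserves_unrooted_bipartitions(table3):
    tree = neighbor_joining(table3)
    rooted = root_on_outgroup(tree, "Pholidota yunnanensis")
    assert rooted.bipartitions() == tree.bipartitions()
    ingroup = [c for c in rooted.root.children if not c.is_leaf]
    assert len(ingroup) == 1
    assert len(ingroup[0].leaf_names()) == 13  # all species form one clade


@pytest.mark.parametrize("bad", ["(a,b", "(a,b));", "a,b;", ""])
def test_newick_parser_rejects_malformed(bad):
    with pytest.raises(ValueError):
        parse_newick(bad)
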