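"""Unrooted trees: newick I/O, NJ, bootstrap, clan analysis."""

import itertools
import random

import numpy as np
import pytest
from _oracles import (
    brute_is_clan,
    brute_smallest_clan,
    random_binary_tree,
)

from leechmine.msa import MultipleAlignment, progressive_msa
from leechmine.records import ProteinRecord
from leechmine.simulate import SimConfig, evolve, simulate_archetype
from leechmine.tree import (
    DistanceMatrix,
    adjacent_group,
    bootstrap_support,
    is_clan,
    nj_tree,
    poisson_distance,
    read_newick,
    smallest_clan,
    write_newick,
)


def test_read_newick_rooted_is_unrooted():
    tree = read_newick("((A:1,B:1)90:1,(C:1,D:1)90:1);")
    assert tree.leaves == {"A", "B", "C", "D"}
    internal = [(u, v, e) for u, v, e in tree.edges()
                if tree.is_internal_edge(u, v)]
    assert len(internal) == 1  # the root's two edges merged into one
    assert internal[0][2].support == 90
    assert internal[0][2].length == 2.0


def test_read_newick_star():
    tree = read_newick("(A,B,C);")
    assert tree.leaves == {"A", "B", "C"}
    assert not any(tree.is_internal_edge(u, v) for u, v, _ in tree.edges())


def test_newick_parse_error():
    with pytest.raises(ValueError, match="parse"):
        read_newick("((A,B,(C,D);")


def test_newick_round_trip():
    rnd = random.Random(17)
    labels = [f"L{k}" for k in range(8)]
    tree = random_binary_tree(labels, rnd)
    text = write_newick(tree)
    back = read_newick(text)
    assert back.leaves == tree.leaves
    for a, b in itertools.combinations(sorted(tree.leaves), 2):
        assert back.path_distance(a, b) == pytest.approx(
            tree.path_distance(a, b), abs=1e-9
        )


def test_poisson_distance_closed_forms(scheme):
    a = ProteinRecord(id="a", sequence="ACDEFGHIKLMNPQRSTVWY" * 5)
    assert poisson_distance(a, a, scheme) == 0.0
    # exactly 25% differing positions, substitutions kept alignable
    seq = list(a.sequence)
    for i in range(0, 100, 4):
        seq[i] = "A" if seq[i] != "A" else "G"
    b = ProteinRecord(id="b", sequence="".join(seq))
    d = poisson_distance(a, b, scheme)
    assert d == pytest.approx(-np.log(0.75), abs=1e-9)


def test_poisson_distance_cap(scheme, rng):
    a = ProteinRecord(id="a", sequence="".join(
        rng.choice(list("ACDE"), size=100)))
    b = ProteinRecord(id="b", sequence="".join(
        rng.choice(list("KLMN"), size=100)))
    assert poisson_distance(a, b, scheme) <= -np.log(0.05) + 1e-9


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(labels=["a", "b", "c"], d=d))
    # x = (d_ab + d_ac - d_bc)/2 etc.
    assert tree.path_distance("a", "b") == pytest.approx(5)
    assert tree.path_distance("a", "c") == pytest.approx(9)
    assert tree.path_distance("b", "c") == pytest.approx(10)


@pytest.mark.parametrize("n", [5, 6, 7, 8])
def test_nj_reconstructs_additive_matrices(n):
    """Path-length matrices of random trees are reproduced exactly."""
    rnd = random.Random(100 + n)
    labels = [f"T{k}" for k in range(n)]
    truth = random_binary_tree(labels, rnd, min_len=0.5, max_len=2.0)
    D = truth.distance_matrix()
    recovered = nj_tree(D)
    for a, b in itertools.combinations(labels, 2):
        assert recovered.path_distance(a, b) == pytest.approx(
            truth.path_distance(a, b), abs=1e-9
        )
    truth_clans = {frozenset(c) for c in truth.clans()}
    rec_clans = {frozenset(c) for c in recovered.clans()}
    assert truth_clans == rec_clans


def test_nj_label_permutation_invariant():
    rnd = random.Random(31)
    labels = [f"T{k}" for k in range(6)]
    truth = random_binary_tree(labels, rnd, min_len=0.5, max_len=2.0)
    D = truth.distance_matrix()
    base = {frozenset(c) for c in nj_tree(D).clans()}
    for _ in range(5):
        perm = rnd.sample(range(len(labels)), len(labels))
        D2 = DistanceMatrix(labels=[D.labels[i] for i in perm],
                            d=D.d[np.ix_(perm, perm)])
        assert {frozenset(c) for c in nj_tree(D2).clans()} == base


def test_nj_rejects_bad_matrix():
    with pytest.raises(ValueError):
        DistanceMatrix(labels=["a", "b", "c"],
                       d=np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(labels=["a", "b"], d=np.zeros((2, 2))))


def test_nj_matches_skbio():
    """Independent cross-check against scikit-bio's neighbor joining."""
    import skbio

    rng = np.random.default_rng(77)
    n = 7
    base = rng.uniform(0.2, 1.5, size=(n, n))
    d = (base + base.T) / 2
    np.fill_diagonal(d, 0.0)
    labels = [f"T{k}" for k in range(n)]
    mine = nj_tree(DistanceMatrix(labels=labels, d=d))
    ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
    ref_parts = set()
    for node in ref.non_tips():
        tips = frozenset(t.name for t in node.tips())
        ref_parts.add(min(tips, frozenset(labels) - tips, key=sorted))
    my_parts = set()
    leaves = frozenset(labels)
    for side, _, _ in mine.bipartitions():
        if 1 < len(side) < n - 1 or 1 < len(leaves - side) < n - 1:
            my_parts.add(min(side, leaves - side, key=sorted))
    internal_ref = {p for p in ref_parts if 1 < len(p) < n - 1}
    assert internal_ref <= my_parts | {min(p, leaves - p, key=sorted)
                                       for p in my_parts}


def _family_msa(rng, n_fams=2, members=3, length=120, within=0.05, sep=True):
    seqs = []
    cfg = SimConfig(seed=0, indel_rate=0.0)
    for f in range(n_fams):
        arch, cys = simulate_archetype(length, 4, rng, seq_id=f"f{f}m0")
        seqs.append(arch)
        parent = arch
        for m in range(1, members):
            child, _ = evolve(parent, within, cfg, rng,
                              child_id=f"f{f}m{m}")
            seqs.append(child)
            parent = child
    return seqs


def test_bootstrap_support_basics(scheme, rng):
    seqs = _family_msa(rng)
    msa = progressive_msa(seqs, scheme)
    t1 = bootstrap_support(msa, n_reps=1, seed=3)
    supports = [e.support for u, v, e in t1.edges() if e.support is not None]
    assert supports and all(s in (0.0, 100.0) for s in supports)
    t2 = bootstrap_support(msa, n_reps=25, seed=9)
    t3 = bootstrap_support(msa, n_reps=25, seed=9)
    s2 = sorted(e.support for _, _, e in t2.edges() if e.support is not None)
    s3 = sorted(e.support for _, _, e in t3.edges() if e.support is not None)
    assert s2 == s3
    with pytest.raises(ValueError):
        bootstrap_support(msa, n_reps=0, seed=1)


def test_bootstrap_separates_distant_families(scheme, rng):
    """The edge splitting two well-separated families gets full support."""
    seqs = _family_msa(rng, within=0.05)
    msa = progressive_msa(seqs, scheme)
    tree = bootstrap_support(msa, n_reps=100, seed=11)
    famA = frozenset(s.id for s in seqs if s.id.startswith("f0"))
    for side, e, _ in tree.bipartitions():
        if side == famA or frozenset(tree.leaves) - side == famA:
            assert e.support >= 95
            break
    else:
        pytest.fail("family bipartition not in tree")


def test_is_clan_quartet():
    tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
    assert is_clan(tree, {"A", "B"})
    assert not is_clan(tree, {"A", "C"})
    assert is_clan(tree, {"A"})  # any pendant leaf
    with pytest.raises(ValueError):
        is_clan(tree, set())
    with pytest.raises(ValueError):
        is_clan(tree, {"A", "B", "C", "D"})


def test_is_clan_matches_bruteforce_enumeration():
    rnd = random.Random(55)
    for _ in range(5):
        labels = [f"L{k}" for k in range(8)]
        tree = random_binary_tree(labels, rnd)
        for r in range(1, 8):
            for S in itertools.combinations(labels, r):
                assert is_clan(tree, set(S)) == brute_is_clan(tree, set(S))


def test_clan_count_formula():
    """A binary unrooted n-leaf tree has 2n-3 edges and 2(2n-3) clans."""
    rnd = random.Random(70)
    for n in range(4, 9):
        tree = random_binary_tree([f"L{k}" for k in range(n)], rnd)
        assert len(list(tree.edges())) == 2 * n - 3
        clans = tree.clans()
        assert len(clans) == 2 * (2 * n - 3)
        assert len(set(clans)) == 2 * (2 * n - 3)


def test_smallest_clan_quartet():
    tree = read_newick("((A:1,B:1)85:1,(C:1,D:1)85:1);")
    res = smallest_clan(tree, {"A", "B"}, query="A", archetype="B")
    assert res.smallest_clan == frozenset({"A", "B"})
    assert res.support == 85


def test_smallest_clan_matches_bruteforce():
    rnd = random.Random(81)
    for _ in range(5):
        labels = [f"L{k}" for k in range(10)]
        tree = random_binary_tree(labels, rnd)
        for _ in range(20):
            must = set(rnd.sample(labels, rnd.randint(2, 4)))
            got = smallest_clan(tree, must).smallest_clan
            assert got == brute_smallest_clan(tree, must)


def test_smallest_clan_trivial_flag():
    tree = read_newick("((A,B),(C,D));")
    res = smallest_clan(tree, {"A", "B", "C", "D"}, query="A", archetype="B")
    assert res.is_trivial


def test_clan_call_uses_family_labels():
    tree = read_newick("((q:1,arch:1)99:1,(x:1,y:1)99:1);")
    fams = {"q": "hirudin", "arch": "hirudin", "x": "eglin", "y": "eglin"}
    res = smallest_clan(tree, {"q", "arch"}, families=fams,
                        query="q", archetype="arch")
    assert res.call == "orthologue_supported"
    assert res.is_pair_clan
    # a foreign leaf inside the smallest clan blocks the orthology call
    tree2 = read_newick("(((q:1,x:1)40:1,arch:1)99:1,(y:1,z:1)99:1);")
    fams2 = {"q": "hirudin", "arch": "hirudin", "x": "eglin",
             "y": "other", "z": "other"}
    res2 = smallest_clan(tree2, {"q", "arch"}, families=fams2,
                         query="q", archetype="arch")
    assert res2.call == "not_orthologue"


def test_clan_call_support_threshold():
    tree = read_newick("((q:1,arch:1)60:1,(x:1,y:1)60:1);")
    fams = {"q": "f", "arch": "f", "x": "g", "y": "g"}
    res = smallest_clan(tree, {"q", "arch"}, families=fams,
                        query="q", archetype="arch")
    assert res.call == "orthologue_unsupported"


def test_adjacent_group_quartet():
    """Deleting the complement-side node yields the adjacent clans."""
    tree = read_newick("((A,B),(C,D));")
    adj = adjacent_group(tree, {"A", "B"})
    assert sorted(adj, key=sorted) == [frozenset({"C"}), frozenset({"D"})]
    with pytest.raises(ValueError):
        adjacent_group(tree, {"A", "C"})


def test_adjacent_group_of_pendant_leaf():
    rnd = random.Random(91)
    tree = random_binary_tree([f"L{k}" for k in range(6)], rnd)
    adj = adjacent_group(tree, {"L0"})
    assert len(adj) == 2
    assert frozenset().union(*adj) == frozenset(tree.leaves) - {"L0"}
    for group in adj:
        assert is_clan(tree, set(group))
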