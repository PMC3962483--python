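"""K2P distances, NJ reconstruction, Gower clustering and mitotyping."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from medpopgen.phylo import (
    DEFAULT_ENZYMES,
    assign_mitotype,
    dloop_typing,
    gower_cluster,
    gower_distances,
    insilico_pcr,
    k2p_distance,
    majority_vote_consensus,
    midpoint_root,
    neighbor_joining,
    restriction_digest,
)

from conftest import make_haps, make_table


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == pytest.approx(0.0)

    def test_single_transversion_closed_form(self):
        d = k2p_distance("ACGT", "ACGA")
        assert d == pytest.approx(-0.5 * np.log(0.75) - 0.25 * np.log(0.5))

    def test_saturation_flagged(self):
        # P = 0.5, Q = 0: log argument hits zero -> inestimable
        res = k2p_distance("AAAA", "GGAA", full=True)
        assert res.P == 0.5 and res.Q == 0.0
        assert res.saturated and np.isnan(res.distance)
        # P = 0.25 stays estimable
        assert not k2p_distance("AAAA", "GAAA", full=True).saturated

    def test_ambiguous_columns_dropped_pairwise(self):
        res = k2p_distance("ACGTN-", "ACGANC", full=True)
        assert res.n_sites == 4

    def test_closed_form_agreement_on_random_pairs(self):
        """Independent arithmetic (explicit P/Q counting + formula) to 1e-10
        on 1,000 random sequence pairs."""
        rng = np.random.default_rng(21)
        bases = np.array(list("ACGT"))
        transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
        for _ in range(1000):
            L = int(rng.integers(50, 300))
            a = rng.choice(bases, L)
            b = a.copy()
            mut = rng.random(L) < 0.15
            b[mut] = rng.choice(bases, mut.sum())
            sa, sb = "".join(a), "".join(b)
            P = sum((x, y) in transitions for x, y in zip(sa, sb)) / L
            Q = sum(x != y and (x, y) not in transitions for x, y in zip(sa, sb)) / L
            if 1 - 2 * P - Q <= 0 or 1 - 2 * Q <= 0:
                continue
            expect = -0.5 * np.log(1 - 2 * P - Q) - 0.25 * np.log(1 - 2 * Q)
            assert abs(k2p_distance(sa, sb) - expect) < 1e-10


class TestNeighborJoining:
    @staticmethod
    def _additive_matrix():
        """Four taxa on tree ((A:2,B:3):1,(C:4,D:5));, distances additive."""
        edges = {"A": 2.0, "B": 3.0, "C": 4.0, "D": 5.0}
        internal = 1.0
        labels = list(edges)
        mat = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    continue
                same_cherry = {x, y} in ({"A", "B"}, {"C", "D"})
                mat[i, j] = edges[x] + edges[y] + (0 if same_cherry else internal)
        return DistanceMatrix(mat, labels)

    def test_additive_matrix_exact_reconstruction(self):
        tree = neighbor_joining(self._additive_matrix())
        # topology: A-B form a cherry, C-D form a cherry
        names = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"A", "B"}) in names or frozenset({"C", "D"}) in names
        # additive distances reproduced exactly by path lengths
        for a, b in (("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")):
            got = tree.find(a).distance(tree.find(b))
            assert got == pytest.approx(self._additive_matrix()[a, b])

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(np.array([[0, 1], [1, 0]]), ["a", "b"]))

    def test_midpoint_root_splits_longest_path(self):
        tree = midpoint_root(neighbor_joining(self._additive_matrix()))
        tips = {t.name: t for t in tree.tips()}
        # longest path is B..D (3 + 1 + 5 = 9); midpoint puts both at 4.5
        db = tips["B"].accumulate_to_ancestor(tree)
        dd = tips["D"].accumulate_to_ancestor(tree)
        assert db == pytest.approx(4.5)
        assert dd == pytest.approx(4.5)

    def test_matches_independent_nj_on_random_matrices(self):
        """Topology agreement with dendropy's NJ on perturbed additive
        matrices (compared via quartet-free split sets)."""
        import dendropy
        rng = np.random.default_rng(31)
        agreements = 0
        n_cases = 40
        for case in range(n_cases):
            n = int(rng.integers(5, 9))
            labels = [f"t{k}" for k in range(n)]
            # random additive matrix from random points + noise
            coords = rng.uniform(0, 1, (n, 6))
            mat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
            mat += rng.uniform(0, 0.02, mat.shape)
            mat = (mat + mat.T) / 2
            np.fill_diagonal(mat, 0.0)
            ours = neighbor_joining(DistanceMatrix(mat, labels))
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_dm_csv(mat, labels), delimiter=",")
            theirs = pdm.nj_tree()
            if _split_set(ours) == _dendropy_split_set(theirs):
                agreements += 1
        assert agreements == n_cases


def _dm_csv(mat, labels):
    import io
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{v:.10f}" for v in mat[i]) + "\n")
    buf.seek(0)
    return buf


def _split_set(tree):
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        out.add(frozenset({side, tips - side}))
    return {s for s in out if all(len(x) > 1 for x in s)}


def _dendropy_split_set(tree):
    tips = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    out = set()
    for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        out.add(frozenset({side, tips - side}))
    return {s for s in out if all(len(x) > 1 for x in s)}


class TestConsensusAndGower:
    def test_majority_vote_and_tie_rule(self):
        mat = np.zeros((48, 3), dtype=np.uint8)
        mat[:30, 0] = 1       # 30/18 -> alt
        mat[:24, 1] = 1       # 24/24 tie -> ref, flagged
        mat[:10, 2] = 1       # 10/38 -> ref
        consensus, ties = majority_vote_consensus(make_haps(mat))
        assert consensus.tolist() == [1, 0, 0]
        assert ties.tolist() == [False, True, False]

    def test_identical_samples_distance_zero(self):
        geno = np.tile(np.array([[0, 1], [1, 1], [0, 0]], dtype=np.int16), (2, 1, 1))
        dm = gower_distances(make_table(geno))
        assert dm[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_distance_one(self):
        geno = np.stack([np.zeros((5, 2)), np.full((5, 2), 1)]).astype(np.int16)
        dm = gower_distances(make_table(geno))
        assert dm[0, 1] == pytest.approx(1.0)

    def test_four_sample_hand_fixture(self):
        # dosages per site:      s0 s1 s2 s3
        # site 0 (range 2):       0  1  2  2
        # site 1 (range 1):       0  0  1  1
        geno = np.array([
            [[0, 0], [0, 0]],
            [[0, 1], [0, 0]],
            [[1, 1], [0, 1]],
            [[1, 1], [1, 0]],
        ], dtype=np.int16)
        dm = gower_distances(make_table(geno))
        assert dm["s0", "s1"] == pytest.approx((0.5 / 1 + 0) / 2)
        assert dm["s0", "s2"] == pytest.approx((1.0 + 1.0) / 2)
        assert dm["s1", "s3"] == pytest.approx((0.5 + 1.0) / 2)
        _, linkage_matrix = gower_cluster(make_table(geno))
        assert linkage_matrix.shape == (3, 4)


class TestPcrAndDigest:
    FWD = "CCCAAAGCCAGGATTCTAA"
    REV = "AACCCCCACGATTTTTGTC"

    @staticmethod
    def _revcomp(s):
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    def _template(self, insert_len=500, seed=2, circular_offset=0):
        rng = np.random.default_rng(seed)
        insert = "".join(rng.choice(list("ACGT"), insert_len))
        seq = self.FWD + insert + self._revcomp(self.REV)
        pad = "".join(rng.choice(list("ACGT"), 300))
        template = seq + pad
        if circular_offset:
            template = template[-circular_offset:] + template[:-circular_offset]
        return template, len(seq)

    def test_planted_primers_give_designed_length(self):
        template, amp_len = self._template()
        amp = insilico_pcr(template, self.FWD, self.REV)
        assert len(amp) == amp_len
        assert amp.startswith(self.FWD)

    def test_missing_reverse_primer_errors(self):
        template, _ = self._template()
        with pytest.raises(ValueError, match="reverse"):
            insilico_pcr(template, self.FWD, "GGGGGGGGGGGGGGGGGG")

    def test_origin_spanning_amplicon_on_circular_template(self):
        # rotation point inside the amplicon (amplicon 538 bp of 838 total)
        template, amp_len = self._template(circular_offset=600)
        with pytest.raises(ValueError):
            insilico_pcr(template, self.FWD, self.REV, circular=False)
        amp = insilico_pcr(template, self.FWD, self.REV, circular=True)
        assert len(amp) == amp_len

    def test_mboi_cut_offset(self):
        # MboI cuts before the G of GATC
        frags = restriction_digest("AAGATCAA", {"MboI": DEFAULT_ENZYMES["MboI"]})
        assert frags["MboI"] == (2, 6)

    def test_no_site_single_fragment(self):
        frags = restriction_digest("AAAAAA", {"MspI": DEFAULT_ENZYMES["MspI"]})
        assert frags["MspI"] == (6,)

    def test_fragments_sum_to_amplicon_length(self):
        rng = np.random.default_rng(7)
        amp = "".join(rng.choice(list("ACGT"), 1241))
        for lengths in restriction_digest(amp).values():
            assert sum(lengths) == 1241

    def test_mitotype_equivalence_classes(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), 800))
        # variant differing only outside recognition sites -> same mitotype
        pos = 0
        while any(site in base[pos:pos + 4] or base[pos] != "A"
                  for site, _ in DEFAULT_ENZYMES.values()):
            pos += 1
        same = base[:pos] + "T" + base[pos + 1:]
        sites_removed = base.replace("GGCC", "GGAC")  # different HaeIII pattern
        patterns = {s: restriction_digest(seq) for s, seq in
                    {"a": base, "b": same, "c": sites_removed}.items()}
        types = assign_mitotype(patterns, bin_bp=1)
        assert types["a"] == types["b"]
        if "GGCC" in base:
            assert types["c"] != types["a"]


class TestDloopTyping:
    def test_single_variant_collapses(self):
        seqs = {f"fish{i}": "ACGT" * 127 for i in range(105)}
        table, membership = dloop_typing(seqs)
        assert len(table) == 1
        assert table["count"].iloc[0] == 105

    def test_eight_planted_variants_recovered(self):
        rng = np.random.default_rng(9)
        variants = []
        base = rng.choice(list("ACGT"), 520)
        for v in range(8):
            s = base.copy()
            s[v * 10] = "ACGT"[(("ACGT".index(s[v * 10])) + 1) % 4]
            variants.append("".join(s))
        seqs = {f"fish{i}": variants[i % 8] for i in range(105)}
        table, _ = dloop_typing(seqs)
        assert len(table) == 8
        assert table["count"].sum() == 105

    def test_short_sequence_excluded_with_warning(self):
        seqs = {"ok": "A" * 508, "short": "A" * 100}
        with pytest.warns(UserWarning, match="short"):
            table, membership = dloop_typing(seqs)
        assert "short" not in membership
        assert len(table) == 1
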