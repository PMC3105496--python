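"""Lexical profiles, the three similarity methods and the descriptor kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bioresnet as br

WORDS = [
    "gene", "protein", "sequence", "alignment", "expression", "tree",
    "motif", "cluster", "matrix", "chip-chip", "data", "profile",
]

word_lists = st.lists(st.sampled_from(WORDS), min_size=1, max_size=5)


class TestLexicalProfile:
    def test_three_token_enumeration(self):
        lp = br.lexical_profile("protein sequence alignment")
        expected = {
            ("protein",), ("sequence",), ("alignment",),
            ("protein", "sequence"), ("sequence", "alignment"),
            ("protein", "sequence", "alignment"),
        }
        assert lp.ngrams == expected

    def test_single_token(self):
        assert br.lexical_profile("motif").ngrams == {("motif",)}

    def test_hyphenated_token_kept_whole(self):
        lp = br.lexical_profile("chip-chip data")
        assert lp.ngrams == {("chip-chip",), ("data",), ("chip-chip", "data")}

    def test_lowercased(self):
        assert br.lexical_profile("ChIp-chip Data").ngrams == br.lexical_profile("chip-chip data").ngrams

    def test_whitespace_only_rejected(self):
        with pytest.raises(ValueError):
            br.lexical_profile("   ")

    @settings(derandomize=True, max_examples=50)
    @given(word_lists)
    def test_cardinality_bound(self, tokens):
        k = len(tokens)
        lp = br.lexical_profile(" ".join(tokens))
        assert len(lp.ngrams) <= k * (k + 1) // 2
        if len(set(tokens)) == k:
            assert len(lp.ngrams) == k * (k + 1) // 2
        assert tuple(tokens) in lp.ngrams  # the full term is its own n-gram


class TestSimLexical:
    def test_identical_names(self):
        assert br.sim_lexical("gene expression data", "gene expression data") == pytest.approx(1.0)

    def test_disjoint_names(self):
        assert br.sim_lexical("protein structure", "gene tree") == 0.0

    def test_pdb_vs_chip_chip(self):
        # profiles of sizes 6 and 3 share the single n-gram ("data",)
        assert br.sim_lexical("protein data bank", "chip-chip data") == pytest.approx(1 / math.sqrt(18))

    def test_blast_vs_pairwise_alignment(self):
        # profiles of sizes 15 and 3 share ("alignment",)
        v = br.sim_lexical("basic local alignment search tool", "pairwise alignment")
        assert v == pytest.approx(1 / math.sqrt(45))

    @settings(derandomize=True, max_examples=50)
    @given(word_lists, word_lists)
    def test_symmetry_and_range(self, t1, t2):
        a, b = " ".join(t1), " ".join(t2)
        v = br.sim_lexical(a, b)
        assert v == pytest.approx(br.sim_lexical(b, a))
        assert 0.0 <= v <= 1.0 + 1e-9


class TestSimShared:
    def _weighted(self, rows, descriptors):
        import pandas as pd
        from bioresnet.profile import ResourceInfo, WeightedProfileMatrix
        infos = [ResourceInfo(f"r{i}", br.ALGORITHM, 1) for i in range(len(rows))]
        return WeightedProfileMatrix(infos, pd.DataFrame(rows, columns=descriptors, dtype=float), "binary")

    def test_identical_rows(self):
        w = self._weighted([[1, 1, 0], [1, 1, 0]], ["a", "b", "c"])
        assert br.sim_shared(w, "r0", "r1") == pytest.approx(1.0)

    def test_half_overlap(self):
        w = self._weighted([[1, 1, 0], [1, 0, 1]], ["a", "b", "c"])
        assert br.sim_shared(w, "r0", "r1") == pytest.approx(0.5)

    def test_disjoint_rows(self):
        w = self._weighted([[1, 0], [0, 1]], ["a", "b"])
        assert br.sim_shared(w, "r0", "r1") == 0.0

    def test_empty_profile_gives_zero(self):
        w = self._weighted([[0, 0], [1, 1]], ["a", "b"])
        assert br.sim_shared(w, "r0", "r1") == 0.0

    def test_unknown_resource_raises(self):
        w = self._weighted([[1, 0]], ["a", "b"])
        with pytest.raises(KeyError):
            br.sim_shared(w, "r0", "nope")


class TestDescriptorKernel:
    def test_unit_diagonal_and_symmetry(self):
        A = br.descriptor_similarity_matrix(["gene expression", "gene expression data", "motif"])
        assert np.allclose(np.diag(A.entries), 1.0)
        assert np.allclose(A.entries, A.entries.T)

    def test_related_descriptors(self):
        A = br.descriptor_similarity_matrix(["gene expression", "gene expression data"])
        # profiles of sizes 3 and 6 share 3 n-grams
        assert A.entries[0, 1] == pytest.approx(3 / math.sqrt(18))

    def test_unrelated_descriptors(self):
        A = br.descriptor_similarity_matrix(["gene", "protein"])
        assert A.entries[0, 1] == 0.0

    def test_duplicate_descriptors_rejected(self):
        with pytest.raises(ValueError):
            br.descriptor_similarity_matrix(["gene", "gene"])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.lists(st.sampled_from(WORDS), min_size=1, max_size=3), min_size=1, max_size=12))
    def test_psd_on_random_dictionaries(self, token_lists):
        terms = sorted({" ".join(t) for t in token_lists})
        A = br.descriptor_similarity_matrix(terms)
        assert A.min_eigenvalue() >= -1e-9

    def test_csv_round_trip(self, tmp_path):
        A = br.descriptor_similarity_matrix(["gene expression", "expression data", "motif"])
        A.to_csv(tmp_path / "A.csv")
        back = br.DescriptorSimilarityMatrix.from_csv(tmp_path / "A.csv")
        assert back.descriptors == A.descriptors
        assert np.allclose(back.entries, A.entries)


def random_weighted(rng, n_resources=4, m=6, weighting="binary"):
    import pandas as pd
    from bioresnet.profile import ResourceInfo, WeightedProfileMatrix
    descriptors = [" ".join(rng.choice(WORDS, size=rng.integers(1, 3))) for _ in range(40)]
    descriptors = sorted(set(descriptors))[:m]
    if weighting == "binary":
        W = (rng.random((n_resources, len(descriptors))) < 0.5).astype(float)
    else:
        W = rng.random((n_resources, len(descriptors))) * (rng.random((n_resources, len(descriptors))) < 0.6)
    infos = [ResourceInfo(f"r{i}", br.ALGORITHM, 1) for i in range(n_resources)]
    return WeightedProfileMatrix(infos, pd.DataFrame(W, columns=descriptors), weighting)


class TestSimSmoothed:
    def test_identity_kernel_reduces_to_shared(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            w = random_weighted(rng, weighting="tfidf")
            A = br.identity_kernel(w.descriptors)
            for i in range(len(w.resources)):
                for j in range(len(w.resources)):
                    s2 = br.sim_shared(w, f"r{i}", f"r{j}")
                    s3 = br.sim_smoothed(w, A, f"r{i}", f"r{j}")
                    assert abs(s2 - s3) < 1e-12

    def test_two_descriptor_worked_case(self):
        import pandas as pd
        from bioresnet.profile import ResourceInfo, WeightedProfileMatrix
        descriptors = ["gene expression", "gene expression data"]
        W = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], columns=descriptors)
        infos = [ResourceInfo("r0", br.ALGORITHM, 1), ResourceInfo("r1", br.ALGORITHM, 1)]
        w = WeightedProfileMatrix(infos, W, "binary")
        A = br.descriptor_similarity_matrix(descriptors)
        assert br.sim_shared(w, "r0", "r1") == 0.0
        assert br.sim_smoothed(w, A, "r0", "r1") == pytest.approx(3 / math.sqrt(18))

    def test_identical_rows(self):
        rng = np.random.default_rng(3)
        w = random_weighted(rng, n_resources=2)
        w.weights.iloc[1] = w.weights.iloc[0]
        if not w.weights.iloc[0].any():
            w.weights.iloc[:, 0] = 1.0
        A = br.descriptor_similarity_matrix(w.descriptors)
        assert br.sim_smoothed(w, A, "r0", "r1") == pytest.approx(1.0)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(4)
        w = random_weighted(rng)
        A = br.identity_kernel(w.descriptors[:-1])
        with pytest.raises(ValueError):
            br.sim_smoothed(w, A, "r0", "r1")

    def test_smoothing_dominance_on_disjoint_supports(self):
        """Zero shared descriptors but lexically related ones: Sim3 > Sim2 = 0."""
        import pandas as pd
        from bioresnet.profile import ResourceInfo, WeightedProfileMatrix
        descriptors = ["protein sequence", "sequence alignment", "gene tree"]
        W = pd.DataFrame([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]], columns=descriptors)
        infos = [ResourceInfo("r0", br.ALGORITHM, 1), ResourceInfo("r1", br.ALGORITHM, 1)]
        w = WeightedProfileMatrix(infos, W, "binary")
        A = br.descriptor_similarity_matrix(descriptors)
        assert br.sim_shared(w, "r0", "r1") == 0.0
        assert br.sim_smoothed(w, A, "r0", "r1") > 0.0


class TestSimilarityMatrix:
    def test_single_resource(self):
        sim = br.similarity_matrix(["blast tool"], "lexical")
        assert sim.entries.tolist() == [[1.0]]

    def test_matches_pairwise_lexical(self):
        names = ["protein data bank", "chip-chip data", "pairwise alignment"]
        sim = br.similarity_matrix(names, "lexical")
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i != j:
                    assert sim.entries[i, j] == pytest.approx(br.sim_lexical(a, b))
        assert np.allclose(np.diag(sim.entries), 1.0)

    @pytest.mark.parametrize("method", ["shared", "smoothed"])
    @pytest.mark.parametrize("weighting", ["binary", "tfidf"])
    def test_matches_pairwise_profile_methods(self, planted_profiles, method, weighting):
        w = br.weight_profiles(planted_profiles, weighting)
        A = br.descriptor_similarity_matrix(w.descriptors) if method == "smoothed" else None
        sim = br.similarity_matrix(w, method, A=A)
        pairwise = br.sim_shared if method == "shared" else (
            lambda wm, a, b: br.sim_smoothed(wm, A, a, b)
        )
        for i, a in enumerate(sim.resources):
            for j, b in enumerate(sim.resources):
                assert sim.entries[i, j] == pytest.approx(pairwise(w, a, b), abs=1e-9)
        assert np.allclose(sim.entries, sim.entries.T)
        assert sim.entries.min() >= 0 and sim.entries.max() <= 1

    def test_csv_and_triplet_round_trip(self, planted_profiles, tmp_path):
        w = br.binarize(planted_profiles)
        sim = br.similarity_matrix(w, "shared")
        sim.to_csv(tmp_path / "sim.csv")
        back = br.SimilarityMatrix.from_csv(tmp_path / "sim.csv")
        assert back.resources == sim.resources
        assert np.allclose(back.entries, sim.entries)
        sim.to_triplets(tmp_path / "sim.tsv")
        lines = (tmp_path / "sim.tsv").read_text().splitlines()
        # every positive off-diagonal pair appears exactly once
        n_pos = int((np.triu(sim.entries, 1) > 0).sum())
        assert len(lines) - 1 == n_pos
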