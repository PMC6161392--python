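import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio.diversity.alpha import pielou_e

from clonecensus import repertoire as rep
from clonecensus.types import UsageProfile, ValidationError

STOP_CODONS = {"TAA", "TAG", "TGA"}


def make_clonotypes(rows):
    return pd.DataFrame(rows, columns=[
        "cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "frame_status",
        "template_count", "replicate_id",
    ])


class TestClassifyProductivity:
    @pytest.mark.parametrize("seq,expected", [
        ("TGTGCAAGC", "in_frame"),   # C-A-S
        ("TGTGCAAG", "frameshift"),  # 8 nt
        ("TGTTAAAGC", "stop"),       # TAA at codon 2
        ("TGA", "stop"),
        ("TGTGCTAGCTTT", "in_frame"),
    ])
    def test_examples(self, seq, expected):
        assert rep.classify_productivity(seq) == expected

    @pytest.mark.parametrize("seq", ["", "TGTXNAAGC", "tgtgca"])
    def test_non_dna_input_is_error(self, seq):
        with pytest.raises(ValidationError):
            rep.classify_productivity(seq)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(deadline=None, max_examples=200)
    def test_partition_matches_manual_codon_scan(self, seq):
        status = rep.classify_productivity(seq)
        if len(seq) % 3 != 0:
            assert status == "frameshift"
        else:
            codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
            has_stop = any(c in STOP_CODONS for c in codons)
            assert status == ("stop" if has_stop else "in_frame")


class TestRichness:
    def test_counts_unique_productive_nt(self):
        df = make_clonotypes([
            ("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 5, "R1"),
            ("TGTGCGAGC", "CAS", "V1", "J1", "in_frame", 1, "R1"),
            ("TGTGCCAGC", "CAS", "V2", "J1", "in_frame", 2, "R2"),
            ("TGTGCAAG", "", "V1", "J1", "frameshift", 9, "R1"),
            ("TGTTAAAGC", "", "V1", "J1", "stop", 3, "R1"),
        ])
        assert rep.richness(df) == 3
        assert rep.richness(df, productive_only=False) == 5
        assert rep.richness(df, identity="aa") == 1  # all translate to CAS

    def test_duplicates_across_replicates_count_once(self):
        df = make_clonotypes([
            ("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 5, "R1"),
            ("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 2, "R2"),
        ])
        assert rep.richness(df) == 1

    def test_invariant_to_relabeling_and_scaling(self):
        df = make_clonotypes([
            ("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 5, "R1"),
            ("TGTGCGAGC", "CAS", "V1", "J1", "in_frame", 1, "R2"),
        ])
        relabeled = df.assign(replicate_id=df["replicate_id"].map({"R1": "X", "R2": "Y"}))
        scaled = df.assign(template_count=df["template_count"] * 100)
        assert rep.richness(df) == rep.richness(relabeled) == rep.richness(scaled)

    def test_ground_truth_recovery_on_exhaustive_sampling(self, small_dataset):
        truth, _, clonotypes = small_dataset
        productive_truth = len({
            c.cdr3_nt for c in truth.clonotypes if c.frame_status == "in_frame"
        })
        assert rep.richness(clonotypes) <= productive_truth
        assert rep.richness(clonotypes) == clonotypes[
            clonotypes["frame_status"] == "in_frame"]["cdr3_nt"].nunique()

    def test_empty_table_has_zero_richness(self):
        assert rep.richness(make_clonotypes([])) == 0


class TestEvenness:
    def test_uniform_is_maximal(self):
        for s in (2, 5, 50):
            assert rep.shannon_evenness(np.full(s, 1 / s)) == pytest.approx(1.0)

    def test_hand_oracle_two_clones(self):
        expected = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1)) / np.log(2)
        assert rep.shannon_evenness([0.9, 0.1]) == pytest.approx(expected)
        assert rep.shannon_evenness([0.9, 0.1]) == pytest.approx(0.469, abs=5e-4)

    def test_single_clone_is_undefined(self):
        assert np.isnan(rep.shannon_evenness([1.0]))

    def test_matches_skbio_pielou(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 100, size=30)
        ours = rep.shannon_evenness(counts / counts.sum())
        assert ours == pytest.approx(pielou_e(counts))


class TestVjUsage:
    def test_single_gene_has_full_proportion(self):
        df = make_clonotypes([("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 7, "R1")])
        profile = rep.vj_usage(df, "V")
        assert profile.segments == ["V1"]
        assert profile.proportions[0] == 1.0

    def test_template_weighted_proportions(self):
        df = make_clonotypes([
            ("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 30, "R1"),
            ("TGTGCGAGC", "CAS", "V2", "J1", "in_frame", 10, "R1"),
        ])
        profile = rep.vj_usage(df, "V")
        assert profile.as_series().to_dict() == {"V1": 0.75, "V2": 0.25}
        by_clone = rep.vj_usage(df, "V", weight="clonotypes")
        assert by_clone.as_series().to_dict() == {"V1": 0.5, "V2": 0.5}

    def test_multinomial_sampling_recovers_generator_probabilities(self):
        rng = np.random.default_rng(1)
        probs = {"V1": 0.5, "V2": 0.3, "V3": 0.2}
        n = 20_000
        draws = rng.multinomial(n, list(probs.values()))
        df = make_clonotypes([
            (f"TGTGC{'ACGT'[i]}AGC".replace("X", ""), "", v, "J1", "in_frame", int(c), "R1")
            for i, (v, c) in enumerate(zip(probs, draws))
        ])
        profile = rep.vj_usage(df, "V", order=list(probs))
        for p_hat, p in zip(profile.proportions, probs.values()):
            assert abs(p_hat - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_vj_pair_usage(self):
        df = make_clonotypes([
            ("TGTGCAAGC", "CAS", "V1", "J1", "in_frame", 3, "R1"),
            ("TGTGCGAGC", "CAS", "V1", "J2", "in_frame", 1, "R1"),
        ])
        profile = rep.vj_usage(df, "VJ")
        assert profile.segments == ["V1|J1", "V1|J2"]


class TestCompareUsage:
    def ref(self, props):
        return UsageProfile("V", [f"V{i}" for i in range(len(props))],
                            np.asarray(props), 1)

    def obs(self, counts):
        counts = np.asarray(counts, dtype=float)
        return UsageProfile("V", [f"V{i}" for i in range(len(counts))],
                            counts / counts.sum(), int(counts.sum()), counts)

    def test_matching_distributions_give_zero(self):
        stat, df, p = rep.compare_usage(self.obs([50, 30, 20]), self.ref([0.5, 0.3, 0.2]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_oracle_two_categories(self):
        stat, df, p = rep.compare_usage(self.obs([30, 10]), self.ref([0.5, 0.5]))
        assert stat == pytest.approx(10.0)
        assert df == 1
        assert p == pytest.approx(0.0016, abs=2e-4)

    def test_low_expected_categories_are_pooled(self):
        # expected counts 20, 18, 2 -> third category pooled, df = 1
        stat, df, p = rep.compare_usage(self.obs([20, 18, 2]), self.ref([0.5, 0.45, 0.05]))
        assert df == 1
        assert stat == pytest.approx(0.0)

    def test_zero_reference_segment_pools_without_dividing(self):
        observed = self.obs([30, 10])
        reference = UsageProfile("V", ["V0"], np.array([1.0]), 1)
        stat, df, p = rep.compare_usage(observed, reference)
        assert np.isfinite(stat) and 0 <= p <= 1

    @given(st.lists(st.integers(min_value=20, max_value=200), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_statistic_nonnegative(self, counts):
        stat, df, p = rep.compare_usage(self.obs(counts), self.ref(
            np.full(len(counts), 1 / len(counts))))
        assert stat >= 0


class TestDissimilarity:
    def test_identical_samples_are_zero(self):
        s = pd.Series({"a": 2.0, "b": 1.0})
        d = rep.repertoire_dissimilarity({"x": s, "y": s.copy()})
        assert d.loc["x", "y"] == pytest.approx(0.0)

    def test_disjoint_samples_are_one(self):
        d = rep.repertoire_dissimilarity({
            "x": pd.Series({"a": 2.0}), "y": pd.Series({"b": 3.0}),
        })
        assert d.loc["x", "y"] == pytest.approx(1.0)

    def test_hand_oracle(self):
        d = rep.repertoire_dissimilarity({
            "x": pd.Series({"a": 2.0, "b": 0.0, "c": 4.0}),
            "y": pd.Series({"a": 1.0, "b": 1.0, "c": 2.0}),
        })
        assert d.loc["x", "y"] == pytest.approx(0.4)

    def test_zero_total_sample_is_error(self):
        with pytest.raises(ValidationError, match="zero total"):
            rep.repertoire_dissimilarity({
                "x": pd.Series({"a": 1.0}), "y": pd.Series({"a": 0.0}),
            })

    def test_matrix_properties(self):
        rng = np.random.default_rng(2)
        samples = {f"s{i}": pd.Series(rng.integers(0, 20, size=15).astype(float),
                                      index=[f"c{j}" for j in range(15)])
                   for i in range(5)}
        for s in samples.values():
            s.iloc[0] += 1  # no zero totals
        d = rep.repertoire_dissimilarity(samples)
        arr = d.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 0)
        assert ((arr >= 0) & (arr <= 1)).all()


class TestEmbedding:
    def test_same_seed_gives_identical_coordinates(self):
        rng = np.random.default_rng(3)
        pts = rng.random((10, 4))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        a = rep.embed_2d(d, seed=5, perplexity=3)
        b = rep.embed_2d(d, seed=5, perplexity=3)
        assert np.array_equal(a, b)

    def test_perplexity_must_be_below_sample_count(self):
        with pytest.raises(ValidationError, match="perplexity"):
            rep.embed_2d(np.zeros((4, 4)), perplexity=4)

    def test_separated_blocks_keep_neighbors(self):
        # two tight blocks far apart: nearest embedded neighbor should be a
        # block-mate for nearly every point
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.05, (10, 3)), rng.normal(5, 0.05, (10, 3))])
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        coords = rep.embed_2d(d, seed=0, perplexity=5)
        emb_d = squareform(pdist(coords))
        np.fill_diagonal(emb_d, np.inf)
        nn = emb_d.argmin(axis=1)
        labels = np.array([0] * 10 + [1] * 10)
        assert (labels[nn] == labels).mean() >= 0.9

    def test_identical_samples_embed_symmetrically(self):
        from scipy.spatial.distance import pdist
        coords = rep.embed_2d(np.zeros((3, 3)), seed=1, perplexity=2)
        dists = pdist(coords)
        assert dists.max() / dists.min() < 1.5
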