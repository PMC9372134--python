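import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from markwriter.binding_rf import BindingLabels
from markwriter.motif_svm import (
    KmerSVM,
    KmerWeightTable,
    MOTIF_FAMILIES,
    all_kmers,
    annotate_family,
    build_similarity_graph,
    compare_weight_tables,
    conservation_per_kmer,
    flanking_pwm,
    kmer_similarity,
    kmer_vectorize,
    positional_profile,
    retrain_on_subset,
    reverse_complement,
    select_kmers,
    vectorize_set,
)


class TestVectorize:
    def test_homopolymer_counts(self):
        v = kmer_vectorize("AAAAAAA", 6)
        assert v[0] == 2  # AAAAAA is the lexicographically first 6-mer
        assert v.sum() == 2

    def test_windows_with_n_skipped(self):
        assert kmer_vectorize("ACGTNACGT", 6).sum() == 0

    def test_short_sequence_zero_vector(self):
        assert kmer_vectorize("ACGTA", 6).sum() == 0

    def test_invalid_k_errors(self):
        with pytest.raises(ValueError):
            kmer_vectorize("ACGT", 0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=120))
    def test_count_conservation_on_clean_sequences(self, seq):
        v = kmer_vectorize(seq, 6)
        assert v.sum() == len(seq) - 5

    def test_counts_match_naive_scan(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        v = kmer_vectorize(seq, 6)
        kmers = all_kmers(6)
        for idx in np.flatnonzero(v):
            naive = sum(1 for i in range(len(seq) - 5) if seq[i:i + 6] == kmers[idx])
            assert v[idx] == naive


def oracle_similarity(a, b):
    """Independent four-test oracle, highest level first."""
    if b == reverse_complement(a):
        return "revcomp"
    if a[1:] == b[:-1] or b[1:] == a[:-1]:
        return "offset"
    rb = reverse_complement(b)
    if a[1:] == rb[:-1] or rb[1:] == a[:-1]:
        return "offset_revcomp"
    return "none"


class TestSimilarity:
    @pytest.mark.parametrize(
        "a,b,level",
        [
            ("GAGAGA", "TCTCTC", "revcomp"),
            ("AAGAGA", "AGAGAA", "offset"),
            ("AAGAGA", "TTCTCT", "offset_revcomp"),
            ("ACGTAC", "GGGGGG", "none"),
        ],
    )
    def test_worked_levels(self, a, b, level):
        assert kmer_similarity(a, b) == level

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            kmer_similarity("ACGTAC", "ACGTA")

    def test_500_random_pairs_match_oracle_and_are_symmetric(self):
        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            a = "".join(bases[rng.integers(0, 4, 6)])
            b = "".join(bases[rng.integers(0, 4, 6)])
            if a == b:
                continue
            assert kmer_similarity(a, b) == oracle_similarity(a, b)
            assert kmer_similarity(a, b) == kmer_similarity(b, a)


class TestSimilarityGraph:
    def test_revcomp_pair_plus_isolate(self):
        g = build_similarity_graph(["GAGAGA", "TCTCTC", "AAAAAA"])
        assert [(a, b, lv) for a, b, lv in g.edges] == [("GAGAGA", "TCTCTC", "revcomp")]
        assert len(g.components) == 2

    def test_singleton_has_no_edges(self):
        g = build_similarity_graph(["ACGTAC"])
        assert g.edges == []

    def test_self_revcomp_kmer_forms_no_self_edge(self):
        g = build_similarity_graph(["ACGCGT"])  # its own reverse complement
        assert g.edges == []

    def test_all_pairs_scored(self):
        kmers = ["AAGAGA", "AGAGAA", "GAGAGA", "TCTCTC"]
        g = build_similarity_graph(kmers)
        expected = sum(
            1 for a, b in itertools.combinations(kmers, 2)
            if oracle_similarity(a, b) != "none"
        )
        assert len(g.edges) == expected


def table_from_weights(weights: pd.Series) -> KmerWeightTable:
    return KmerWeightTable(
        kmers=list(weights.index),
        per_model=weights.to_numpy()[None, :].repeat(2, axis=0),
        means=np.zeros((2, len(weights))),
        sds=np.ones((2, len(weights))),
        best_C=1.0,
    )


class TestSelectKmers:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        return table_from_weights(pd.Series(rng.normal(0, 1, 4096), index=all_kmers(6)))

    def test_top_positive_order(self):
        w = pd.Series(0.0, index=all_kmers(6))
        w["AAAAAC"] = 3.0
        w["AAAAAG"] = 2.0
        sel = select_kmers(table_from_weights(w), n=2, mode="top_positive")
        assert list(sel.kmer) == ["AAAAAC", "AAAAAG"]
        assert list(sel["rank"]) == [1, 2]

    def test_positive_and_negative_sets_disjoint(self):
        t = self._table()
        pos = set(select_kmers(t, 60, "top_positive").kmer)
        neg = set(select_kmers(t, 60, "top_negative").kmer)
        assert pos.isdisjoint(neg)

    def test_near_zero_equals_sort_oracle(self):
        t = self._table(3)
        sel = select_kmers(t, 60, "near_zero")
        expected = t.averaged.abs().sort_values().head(60).index
        assert set(sel.kmer) == set(expected)

    def test_random_mode_is_seeded_and_without_replacement(self):
        t = self._table()
        a = select_kmers(t, 60, "random", seed=5)
        b = select_kmers(t, 60, "random", seed=5)
        assert list(a.kmer) == list(b.kmer)
        assert len(set(a.kmer)) == 60


class TestFlankedPWM:
    def test_single_occurrence_one_hot_flanks(self):
        pwm = flanking_pwm("GAGAGA", ["ACAGAGAGAGGT"])
        # flanks ACA / GGT; inner 6 one-hot for GAGAGA
        A, C, G, T = 0, 1, 2, 3
        assert pwm.matrix[0, A] == 1.0
        assert pwm.matrix[1, C] == 1.0
        assert pwm.matrix[2, A] == 1.0
        assert pwm.matrix[9, G] == 1.0
        assert pwm.matrix[11, T] == 1.0
        assert pwm.matrix[3, G] == 1.0  # first motif base
        np.testing.assert_allclose(pwm.matrix.sum(axis=1), 1.0)

    def test_two_occurrences_average_flank_frequencies(self):
        seqs = ["AAAGATACAGGG", "CAAGATACAGGG"]
        pwm = flanking_pwm("GATACA", seqs)
        np.testing.assert_allclose(pwm.matrix[0], [0.5, 0.5, 0, 0])
        assert pwm.n_occurrences == 2

    def test_truncated_flank_occurrence_excluded(self):
        # occurrence at position 1: left flank incomplete
        with pytest.raises(ValueError, match="GATACA"):
            flanking_pwm("GATACA", ["AGATACAGG"])

    def test_n_in_flank_drops_occurrence(self):
        seqs = ["NNNGATACAGGG", "AAAGATACAGGG"]
        pwm = flanking_pwm("GATACA", seqs)
        assert pwm.n_occurrences == 1


class TestFamilies:
    @pytest.mark.parametrize(
        "kmer,family",
        [("GAGAGA", "GAGA"), ("AAACCC", "telobox"), ("TATAAA", "TATA"),
         ("CCCATT", "ARGCCCAWT"), ("ACGTAC", None)],
    )
    def test_membership(self, kmer, family):
        assert annotate_family(kmer) == family

    def test_catalog_disjoint_and_valid(self):
        seen = set()
        for members in MOTIF_FAMILIES.values():
            assert seen.isdisjoint(members)
            seen |= members
            assert all(len(m) == 6 and set(m) <= set("ACGT") for m in members)


class TestPositionalProfile:
    def test_shared_offset_gives_unit_frequency(self):
        seqs = ["A" * 10 + "GAGAGA" + "C" * 10 for _ in range(5)]
        prof = positional_profile(seqs, ["GAGAGA"])
        assert prof[10] == 1.0
        assert prof[0] == 0.0

    def test_empty_family_all_zero(self):
        prof = positional_profile(["ACGTACGTAC"], [])
        assert prof.sum() == 0

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            positional_profile(["ACGTACGTA", "ACGT"], ["ACGTAC"])

    def test_matches_direct_scan(self):
        rng = np.random.default_rng(2)
        bases = np.array(list("ACGT"))
        seqs = ["".join(bases[rng.integers(0, 4, 50)]) for _ in range(40)]
        fam = ["GAGAGA", "TCTCTC", "ATATAT"]
        prof = positional_profile(seqs, fam)
        for off in range(45):
            direct = sum(
                1 for s in seqs if any(s[off:off + 6] == m for m in fam)
            ) / len(seqs)
            assert prof[off] == pytest.approx(direct)


class TestConservation:
    def test_constant_track_gives_constant(self):
        seqs = {"a": "AAGATACAGG"}
        scores = {"a": np.ones(10)}
        assert conservation_per_kmer("GATACA", seqs, scores) == 1.0

    def test_single_occurrence_average(self):
        seqs = {"a": "GATACA"}
        scores = {"a": np.array([0, 0, 0, 1, 1, 1.0])}
        assert conservation_per_kmer("GATACA", seqs, scores) == pytest.approx(0.5)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        seqs = {f"s{i}": "".join(bases[rng.integers(0, 4, 80)]) for i in range(30)}
        scores = {k: rng.random(80) for k in seqs}
        kmer = "ACGT"[0] * 3 + "C"  # AAAC, common enough at k=4
        vals = []
        for sid, s in seqs.items():
            for i in range(len(s) - 3):
                if s[i:i + 4] == kmer:
                    vals.extend(scores[sid][i:i + 4])
        if vals:
            expected = float(np.mean(vals))
            assert conservation_per_kmer(kmer, seqs, scores) == pytest.approx(expected)

    def test_nan_occurrence_dropped(self):
        seqs = {"a": "GATACATTGATACA"}
        scores = {"a": np.concatenate([np.full(6, np.nan), np.zeros(2), np.ones(6)])}
        assert conservation_per_kmer("GATACA", seqs, scores) == pytest.approx(1.0)

    def test_no_occurrence_errors(self):
        with pytest.raises(ValueError):
            conservation_per_kmer("GATACA", {"a": "CCCCCC"}, {"a": np.ones(6)})


class TestCompareTables:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        t = table_from_weights(pd.Series(rng.normal(0, 1, 4096), index=all_kmers(6)))
        assert compare_weight_tables(t, t) == pytest.approx(1.0)

    def test_negated_table_is_minus_one(self):
        rng = np.random.default_rng(0)
        w = pd.Series(rng.normal(0, 1, 4096), index=all_kmers(6))
        assert compare_weight_tables(
            table_from_weights(w), table_from_weights(-w)
        ) == pytest.approx(-1.0)

    def test_zero_variance_errors(self):
        w = pd.Series(0.0, index=all_kmers(6))
        with pytest.raises(ValueError):
            compare_weight_tables(table_from_weights(w), table_from_weights(w))


def planted_fixture(n=500, L=60, n_insert=3, seed=123, motif="GATACA"):
    """Labels determined exactly by presence of the planted 6-mer."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seqs, chroms, bound = {}, {}, []
    for i in range(n):
        gid = f"s{i:03d}"
        seq = "".join(bases[rng.integers(0, 4, L)])
        if i % 2 == 0:
            for _ in range(n_insert):
                pos = int(rng.integers(0, L - len(motif) + 1))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
            bound.append(gid)
        seqs[gid] = seq
        chroms[gid] = f"Chr{i % 5 + 1}"
    labels = BindingLabels(
        labels=pd.Series({g: g in set(bound) for g in seqs}, dtype=bool),
        n_bound=len(bound),
    )
    return seqs, labels, pd.Series(chroms)


class TestKmerSVM:
    def test_planted_motif_tops_weights(self):
        seqs, labels, chroms = planted_fixture()
        vec = vectorize_set(seqs, 6)
        res = KmerSVM(vec, labels, chroms).fit(0)
        assert res.table.averaged.idxmax() == "GATACA"
        assert res.auc_mean > 0.99

    def test_deterministic_two_point_classes_give_auc_one(self):
        """Bound and unbound promoters differing only by the motif block
        are perfectly separated."""
        background = ("ACGT" * 20)[:60]
        seqs, chroms = {}, {}
        bound = []
        for i in range(200):
            gid = f"s{i:03d}"
            if i % 2 == 0:
                seqs[gid] = background[:20] + "GATACA" + background[26:]
                bound.append(gid)
            else:
                seqs[gid] = background
            chroms[gid] = f"Chr{i % 5 + 1}"
        labels = BindingLabels(
            labels=pd.Series({g: g in set(bound) for g in seqs}, dtype=bool),
            n_bound=len(bound),
        )
        res = KmerSVM(vectorize_set(seqs, 6), labels, chroms).fit(0)
        assert np.all(res.aucs == 1.0)

    def test_permuted_labels_give_chance_auc(self):
        seqs, labels, chroms = planted_fixture(n_insert=0)
        rng = np.random.default_rng(9)
        ids = list(seqs)
        perm = rng.permutation(labels.labels.loc[ids].to_numpy())
        null = BindingLabels(
            labels=pd.Series(dict(zip(ids, perm)), dtype=bool), n_bound=int(perm.sum())
        )
        res = KmerSVM(vectorize_set(seqs, 6), null, chroms).fit(0)
        assert abs(res.auc_mean - 0.5) < 0.07

    def test_same_seed_identical_weights(self):
        seqs, labels, chroms = planted_fixture(n=200)
        vec = vectorize_set(seqs, 6)
        a = KmerSVM(vec, labels, chroms).fit(4)
        b = KmerSVM(vec, labels, chroms).fit(4)
        np.testing.assert_array_equal(a.table.per_model, b.table.per_model)

    def test_standardization_fit_on_training_rows_only(self):
        seqs, labels, chroms = planted_fixture(n=200)
        vec = vectorize_set(seqs, 6)
        model = KmerSVM(vec, labels, chroms)
        res = model.fit(7)
        trials = model._trials(7)
        for i, tr in enumerate(trials):
            X = vec.loc[tr["train"]].to_numpy(dtype=float)
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            np.testing.assert_allclose(res.table.means[i], mu)
            np.testing.assert_allclose(res.table.sds[i], sd)

    def test_subset_identity_and_informative_subset(self):
        seqs, labels, chroms = planted_fixture(n=300)
        vec = vectorize_set(seqs, 6)
        full = KmerSVM(vec, labels, chroms).fit(1)
        same = retrain_on_subset(full, list(vec.columns))
        np.testing.assert_allclose(full.table.per_model, same.table.per_model)
        only_motif = retrain_on_subset(full, ["GATACA"])
        assert abs(only_motif.auc_mean - full.auc_mean) < 0.05
        rng = np.random.default_rng(0)
        uninformative = [m for m in rng.choice(vec.columns, 130, replace=False)
                         if m != "GATACA"][:120]
        junk = retrain_on_subset(full, uninformative)
        assert junk.auc_mean < full.auc_mean

    def test_shared_planted_motif_correlates_weight_tables(self):
        """Models trained on fixtures sharing a planted motif have more
        correlated averaged weights than models with disjoint motifs."""
        from markwriter.simulate import SimConfig, simulate_promoter_dataset

        def table(seed, motif):
            cfg = SimConfig(seed=seed, n_genes=500, n_bound=250,
                            promoter_length=300, motif=motif)
            seqs, labels, chroms, _ = simulate_promoter_dataset(cfg)
            return KmerSVM(vectorize_set(seqs, 6), labels, chroms).fit(seed).table

        t1 = table(1, "GAGAGAGA")
        t2 = table(2, "GAGAGAGA")
        t3 = table(3, "CCGTTACC")
        assert compare_weight_tables(t1, t2) > compare_weight_tables(t1, t3)

    def test_empty_subset_errors(self):
        seqs, labels, chroms = planted_fixture(n=100)
        vec = vectorize_set(seqs, 6)
        with pytest.raises(ValueError):
            KmerSVM(vec, labels, chroms, kmer_subset=[])

    def test_unknown_kmer_in_subset_errors(self):
        seqs, labels, chroms = planted_fixture(n=100)
        vec = vectorize_set(seqs, 6)
        with pytest.raises(KeyError):
            KmerSVM(vec, labels, chroms, kmer_subset=["NOTAKMER"])
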