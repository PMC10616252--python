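import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from sehybrid import AbundanceTable, alpha_diversity, bray_curtis, chao1, \
    effect_size_scan, permanova, shannon, simpson, spearman, wilcoxon_rank_sum

from conftest import make_cohort


# ---------------------------------------------------------------------------
# independent PERMANOVA oracle (pure, naive, test-local)
# ---------------------------------------------------------------------------

def oracle_pseudo_f(d, labels):
    d = np.asarray(d, dtype=float)
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_total, ss_within


def oracle_exhaustive_p(d, labels):
    f_obs, _, _ = oracle_pseudo_f(d, labels)
    perms = sorted(set(itertools.permutations(labels)))
    hits = sum(oracle_pseudo_f(d, p)[0] >= f_obs - 1e-12 for p in perms)
    return hits / len(perms)


class TestAlphaDiversity:
    def test_shannon_uniform_closed_form(self):
        assert shannon([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)

    def test_shannon_single_genus_zero(self):
        assert shannon([1.0, 0.0, 0.0]) == 0.0

    def test_shannon_log2_option(self):
        assert shannon([0.25] * 4, base=2) == pytest.approx(2.0, abs=1e-12)

    def test_simpson_closed_forms(self):
        assert simpson([0.25] * 4) == pytest.approx(0.75, abs=1e-12)
        assert simpson([1.0]) == 0.0

    def test_chao1_closed_form(self):
        # 10 observed genera, 4 singletons, 2 doubletons
        counts = [1] * 4 + [2] * 2 + [5] * 4
        assert chao1(counts) == pytest.approx(14.0, abs=1e-12)

    def test_chao1_no_doubleton_fallback(self):
        counts = [1] * 4 + [5] * 6
        assert chao1(counts) == 10 + 4 * 3 / 2

    def test_chao1_at_least_observed_richness(self, rng):
        counts = rng.integers(0, 20, size=30)
        counts[0] = 1
        assert chao1(counts) >= (counts > 0).sum()

    def test_table_interface_matches_skbio(self, rng):
        from skbio.diversity.alpha import shannon as sk_shannon
        vals = rng.dirichlet(np.ones(8), size=5)
        t = AbundanceTable(vals, sample_ids=[f"S{i}" for i in range(5)],
                           genus_ids=[f"g__{i}" for i in range(8)])
        res = alpha_diversity(t)
        for i in range(5):
            assert res["shannon"].iloc[i] == pytest.approx(
                sk_shannon(vals[i], base=math.e), abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=20))
    def test_shannon_maximal_for_uniform(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        assert shannon(p) <= math.log(len(p)) + 1e-9


class TestBrayCurtis:
    def test_closed_forms(self):
        t = AbundanceTable([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5],
                            [0.5, 0.5, 0.0]],
                           sample_ids=["x", "y", "x2"],
                           genus_ids=["g__a", "g__b", "g__c"])
        dm = bray_curtis(t)
        assert dm["x", "y"] == pytest.approx(0.5, abs=1e-12)
        assert dm["x", "x2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        t = AbundanceTable([[1.0, 0.0], [0.0, 1.0]],
                           sample_ids=["x", "y"], genus_ids=["g__a", "g__b"])
        assert bray_curtis(t)["x", "y"] == pytest.approx(1.0, abs=1e-12)

    def test_bounded_symmetric_order_invariant(self, rng):
        vals = rng.dirichlet(np.ones(6), size=8)
        ids = [f"S{i}" for i in range(8)]
        t = AbundanceTable(vals, sample_ids=ids, genus_ids=[f"g__{i}" for i in range(6)])
        dm = bray_curtis(t)
        assert (dm.data >= 0).all() and (dm.data <= 1 + 1e-12).all()
        perm = rng.permutation(8)
        t2 = AbundanceTable(vals[perm], sample_ids=[ids[i] for i in perm],
                            genus_ids=t.genus_ids)
        dm2 = bray_curtis(t2)
        for i in ids:
            for j in ids:
                assert dm2[i, j] == pytest.approx(dm[i, j], abs=1e-12)


class TestPermanova:
    def test_equidistant_toy_hand_values(self):
        """Six mutually equidistant points in two groups of three: by the
        sums-of-squares decomposition R^2 = 0.2, pseudo-F = 1, and every
        relabeling gives the same F, so p = 1."""
        d = np.full((6, 6), 0.7)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(d, ids=list("abcdef"))
        res = permanova(dm, ["g1"] * 3 + ["g2"] * 3, n_permutations=199,
                        seed=0)
        assert res.r_squared == pytest.approx(0.2, abs=1e-12)
        assert res.pseudo_f == pytest.approx(1.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("labels", [
        ["a"] * 3 + ["b"] * 3,
        ["a"] * 2 + ["b"] * 4,
        ["a", "a", "b", "b", "c", "c"],
        ["a"] * 4 + ["b"] * 4,
    ])
    def test_exhaustive_p_matches_enumeration_oracle(self, labels, rng):
        n = len(labels)
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
        res = permanova(dm, labels, n_permutations="exhaustive")
        assert res.p_value == pytest.approx(oracle_exhaustive_p(d, labels),
                                            abs=1e-12)

    def test_monte_carlo_p_converges_to_exhaustive(self, rng):
        labels = ["a"] * 3 + ["b"] * 3
        pts = rng.normal(size=(6, 2))
        pts[3:] += 1.0
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(6)])
        p_ex = permanova(dm, labels, n_permutations="exhaustive").p_value
        p_mc = permanova(dm, labels, n_permutations=9999, seed=1).p_value
        assert abs(p_mc - p_ex) < 0.03

    def test_separated_clusters_minimum_p(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                         rng.normal(10, 0.1, size=(10, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(20)])
        res = permanova(dm, ["a"] * 10 + ["b"] * 10, n_permutations=999,
                        seed=0)
        assert res.p_value == pytest.approx(1 / 1000, abs=1e-15)

    def test_statistic_matches_skbio(self, rng):
        """Cross-check the pseudo-F statistic against the independent
        scikit-bio implementation on random instances."""
        for trial in range(5):
            n = 12
            pts = rng.normal(size=(n, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dm = DistanceMatrix(d, ids=[str(i) for i in range(n)])
            labels = ["a"] * 5 + ["b"] * 4 + ["c"] * 3
            ours = permanova(dm, labels, n_permutations=99, seed=0)
            theirs = skbio_permanova(dm, grouping=list(labels),
                                     permutations=99)
            assert ours.pseudo_f == pytest.approx(theirs["test statistic"],
                                                  abs=1e-9)

    def test_ss_decomposition_conserved(self, rng):
        from sehybrid.diversity import _ss_decomposition
        n = 15
        pts = rng.normal(size=(n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        codes = np.array([0] * 5 + [1] * 5 + [2] * 5)
        ss_total, ss_within, ss_between = _ss_decomposition(d ** 2, codes, 3)
        f, o_total, o_within = oracle_pseudo_f(d, codes.tolist())
        assert ss_total == pytest.approx(o_total, abs=1e-9)
        assert ss_within == pytest.approx(o_within, abs=1e-9)
        assert ss_between + ss_within == pytest.approx(ss_total, abs=1e-9)

    def test_single_group_rejected(self):
        dm = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])
        with pytest.raises(ValueError, match="2 groups"):
            permanova(dm, ["g", "g"], n_permutations=99)


class TestEffectSizeScan:
    def test_planted_age_effect_ranks_first(self):
        hits = 0
        for seed in range(10):
            table, meta, _, _ = make_cohort(
                seed=seed, n_samples_per_batch=[100], signal_effect=0.0,
                host_effect_sizes={"age_group": 2.5})
            meta = meta.copy()
            from sehybrid.encoding import bin_age, bin_bmi
            meta["age_group"] = [bin_age(a) for a in meta["age"]]
            meta["bmi_group"] = [bin_bmi(b) for b in meta["bmi"]]
            res = effect_size_scan(bray_curtis(table), meta,
                                   ["gender", "age_group", "bmi_group",
                                    "probiotics", "health_status"],
                                   n_permutations=99, seed=seed)
            hits += res[0].variable == "age_group"
        assert hits >= 8

    def test_shuffled_variable_is_null(self, rng):
        table, meta, _, _ = make_cohort(seed=5, n_samples_per_batch=[80])
        dm = bray_curtis(table)
        null_ok, r2s = 0, []
        for rep in range(100):
            fake = pd.Series(rng.permutation(meta["gender"].values),
                             index=meta.index)
            res = permanova(dm, fake, n_permutations=99, seed=rep)
            null_ok += res.p_value > 0.01
            r2s.append(res.r_squared)
        assert null_ok >= 95
        assert np.median(r2s) < 0.05

    def test_single_level_variable_skipped(self):
        table, meta, _, _ = make_cohort(seed=1, n_samples_per_batch=[30])
        meta = meta.copy()
        meta["constant"] = "x"
        res = effect_size_scan(bray_curtis(table), meta,
                               ["constant", "gender"], n_permutations=99,
                               seed=0)
        assert [r.variable for r in res] == ["gender"]


class TestRankStatistics:
    def test_spearman_perfect_monotone(self):
        assert spearman([1, 2, 3], [2, 4, 6]).rho == pytest.approx(1.0)
        assert spearman([1, 2, 3], [6, 4, 2]).rho == pytest.approx(-1.0)

    def test_spearman_constant_input_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert not res.valid and math.isnan(res.rho)

    def test_wilcoxon_exact_enumeration(self):
        # U = 0 for 3 vs 3; one-sided 1/C(6,3) = 0.05; two-sided 0.1
        assert wilcoxon_rank_sum([1, 2, 3], [101, 102, 103]) == \
            pytest.approx(0.1, abs=1e-12)

    def test_wilcoxon_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
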