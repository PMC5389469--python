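"""Null distributions, mutual information, the energy F-test and intersite
distances."""

import itertools

import numpy as np
import pytest
from scipy import stats

import ipwmkit as k
from ipwmkit.validation import fitted_transition_matrix


class TestCompositionPreservingSequence:
    def test_single_letter_source_emits_run(self):
        out = k.composition_preserving_sequence("A" * 500, length=100, seed=0)
        assert out == "A" * 100

    def test_transition_rows_sum_to_one(self, rng):
        src = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=2000))
        P = fitted_transition_matrix(src)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_long_output_reproduces_transitions(self):
        # source with a strongly asymmetric dinucleotide structure
        rng = np.random.default_rng(3)
        P_true = np.array(
            [[0.7, 0.1, 0.1, 0.1],
             [0.1, 0.7, 0.1, 0.1],
             [0.25, 0.25, 0.25, 0.25],
             [0.1, 0.1, 0.1, 0.7]]
        )
        codes = [0]
        for _ in range(20_000):
            codes.append(rng.choice(4, p=P_true[codes[-1]]))
        src = "".join("ACGT"[c] for c in codes)
        out = k.composition_preserving_sequence(src, length=100_000, seed=1)
        P_out = fitted_transition_matrix(out)
        assert np.max(np.abs(P_out - fitted_transition_matrix(src))) < 0.01

    def test_small_source_rejected(self):
        with pytest.raises(ValueError):
            k.composition_preserving_sequence("ACGT" * 10, length=100)


class TestNullDistribution:
    def _model(self, rng, bits=12.0):
        fm = k.matrix_with_information("TGACTCAGGC", bits)
        return k.build_ipwm(k.FrequencyMatrix(fm.freqs, n=500))

    def test_informative_model_has_negative_null_mean(self, rng):
        model = self._model(rng)
        spec = k.SimSpec(n_peaks=40, peak_length=250, primary=None,
                         carrier_fraction=0.0, seed=4)
        ds, _ = k.generate_peak_dataset(spec)
        nullseq = k.composition_preserving_sequence(ds, length=10_000, seed=5)
        nd = k.null_distribution(model, nullseq)
        assert nd.mean < 0
        assert nd.sd > 0
        assert nd.p_positive < 0.1

    def test_p_positive_is_gaussian_upper_tail(self, rng):
        model = self._model(rng)
        nullseq = k.composition_preserving_sequence(
            "".join(rng.choice(list("ACGT"), size=5000)), length=4000, seed=6
        )
        nd = k.null_distribution(model, nullseq)
        assert nd.p_positive == pytest.approx(
            stats.norm.sf(0.0, loc=nd.mean, scale=nd.sd), abs=1e-12
        )

    def test_zero_weight_model_degenerate(self):
        from ipwmkit.information import InformationWeightMatrix, position_entropies

        w = np.zeros((4, 4))
        m = InformationWeightMatrix(
            weights=w, freqs=np.full((4, 4), 0.25), n=10, e_n=0.0,
            rsequence=0.0, entropies=position_entropies(np.full((4, 4), 0.25)),
        )
        nd = k.null_distribution(m, "ACGT" * 20)
        assert nd.degenerate and nd.p_positive == 0.0


class TestMutualInformation:
    def _alignment_from_codes(self, mat):
        seqs = ["".join("ACGT"[c] for c in row) for row in mat]
        L = mat.shape[1]
        return k.AlignedSites(seqs, k.contiguous(L), [0] * len(seqs), ["+"] * len(seqs))

    def test_independent_positions_low_percent(self, rng):
        fm = k.matrix_with_information("TGACTCAGGC", 10.0)
        sites = k.sample_sites(fm, 400, 7)
        al = k.AlignedSites(sites, k.contiguous(10), [0] * 400, ["+"] * 400)
        res = k.mutual_information_total(al, n_permutations=50, seed=8)
        assert res.percent_of_rsequence < 5.0

    def test_perfectly_coupled_uniform_pair_two_bits_raw(self, rng):
        n = 200
        col = rng.integers(0, 4, size=n)
        mat = np.stack([col, col], axis=1)
        al = self._alignment_from_codes(mat)
        res = k.mutual_information_total(al, n_permutations=20, seed=9)
        # raw MI of a perfectly correlated pair equals the column entropy
        h = -sum(
            p * np.log2(p) for p in np.bincount(col, minlength=4) / n if p > 0
        )
        assert res.raw_pair_mi[0, 1] == pytest.approx(h, abs=1e-9)

    def test_one_bit_coupled_pair_in_ten_bit_motif(self):
        # 4 fixed positions (~2 bits each) + a coupled pair, each member
        # uniform over {A, C} (1 bit information), moving together:
        # Rsequence ~ 10 bits, MI of the pair = 1 bit -> ~10%
        n = 400
        rows = []
        for i in range(n):
            x = "A" if i % 2 == 0 else "C"
            rows.append("GGTT" + x + x)
        al = k.AlignedSites(rows, k.contiguous(6), [0] * n, ["+"] * n)
        res = k.mutual_information_total(al, n_permutations=100, seed=10)
        assert res.percent_of_rsequence == pytest.approx(10.0, abs=2.0)

    def test_invariant_to_site_order(self, rng):
        fm = k.matrix_with_information("TGACTC", 7.0)
        sites = k.sample_sites(fm, 100, 11)
        al1 = k.AlignedSites(sites, k.contiguous(6), [0] * 100, ["+"] * 100)
        perm = list(rng.permutation(100))
        al2 = k.AlignedSites([sites[i] for i in perm], k.contiguous(6),
                             [0] * 100, ["+"] * 100)
        r1 = k.mutual_information_total(al1, n_permutations=30, seed=12)
        r2 = k.mutual_information_total(al2, n_permutations=30, seed=12)
        assert np.allclose(r1.raw_pair_mi, r2.raw_pair_mi)

    def test_too_few_sites_rejected(self):
        al = k.AlignedSites(["ACGT"] * 10, k.contiguous(4), [0] * 10, ["+"] * 10)
        with pytest.raises(ValueError):
            k.mutual_information_total(al)


class TestRiEnergyFtest:
    def test_exactly_linear_relation_caps_f(self, rng):
        ri = rng.normal(8, 2, size=100)
        signals = 2.0 ** (ri + 3)  # E = -log2 s = -ri - 3 exactly
        res = k.ri_energy_ftest(ri, signals)
        assert res.slope == pytest.approx(-1.0)
        assert res.F == pytest.approx(1e12)

    def test_permuted_signals_give_small_f(self, rng):
        fs = []
        ri = rng.normal(8, 2, size=500)
        signals = 10 * 2.0**ri * rng.lognormal(0, 0.5, size=500)
        for _ in range(50):
            perm = rng.permutation(500)
            fs.append(k.ri_energy_ftest(ri, signals[perm]).F)
        assert np.median(fs) < 10

    def test_zero_variance_ri_rejected(self):
        with pytest.raises(ValueError):
            k.ri_energy_ftest(np.ones(50), np.arange(1, 51).astype(float))

    def test_nonpositive_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            k.ri_energy_ftest(rng.normal(size=50), np.zeros(50))


class TestCompareFDistributions:
    def test_identical_samples_p_near_one(self):
        f = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = k.compare_f_distributions(f, f)
        assert p > 0.9

    def test_fully_separated_maximal_u(self):
        u, p = k.compare_f_distributions([10, 11, 12], [1, 2, 3])
        assert u == 9.0  # n1 * n2
        assert p < 0.2

    def test_matches_exhaustive_rank_enumeration(self):
        x = [1.0, 4.0, 6.0, 7.0, 12.0]
        y = [2.0, 3.0, 5.0, 8.0, 9.0]
        u_obs, p_obs = k.compare_f_distributions(x, y)
        # oracle: U = number of (x, y) pairs with x > y (+0.5 for ties)
        u_direct = sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in x for b in y
        )
        assert u_obs == u_direct
        # exact null: enumerate all C(10,5) label assignments
        pooled = sorted(x + y)
        count = 0
        total = 0
        for combo in itertools.combinations(range(10), 5):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(10) if i not in combo]
            u = sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)
            total += 1
            if abs(u - 12.5) >= abs(u_direct - 12.5) - 1e-12:
                count += 1
        assert p_obs == pytest.approx(count / total, abs=1e-9)


class TestIntersiteDistances:
    def _sites(self, specs):
        return [k.BindingSite(pid, s, e, "+", ri) for pid, s, e, ri in specs]

    def test_planted_cofactors_at_short_distance(self, rng):
        prim, cof = [], []
        for i in range(100):
            pid = f"p{i}"
            prim.append((pid, 50, 60, 10.0))
            if i < 80:
                cof.append((pid, 70, 78, 9.0))  # 10 nt away
            else:
                cof.append((pid, 200, 208, 9.0))
        res = k.intersite_distance_distribution(
            self._sites(prim), self._sites(cof), 8.0, 8.0, "rsequence"
        )
        assert res.fraction_below == pytest.approx(0.8, abs=0.05)

    def test_overlapping_sites_distance_zero(self):
        res = k.intersite_distance_distribution(
            self._sites([("p", 10, 20, 5.0)]), self._sites([("p", 15, 25, 5.0)]),
            1.0, 1.0,
        )
        assert res.distances[0] == 0.0 and res.fraction_below == 1.0

    def test_threshold_filters_weak_sites(self):
        res = k.intersite_distance_distribution(
            self._sites([("p", 10, 20, 5.0)]), self._sites([("p", 30, 40, 2.0)]),
            5.0, 5.0, "rsequence",
        )
        assert res.n_peaks == 0
        res2 = k.intersite_distance_distribution(
            self._sites([("p", 10, 20, 5.0)]), self._sites([("p", 30, 40, 2.0)]),
            5.0, 4.0, "half-rsequence",
        )
        assert res2.n_peaks == 1 and res2.distances[0] == 10.0
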