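import math

import numpy as np
import pytest
from scipy import optimize

from direct_rna import dca
from direct_rna import synthetic
from direct_rna.io_formats import MSA


def make_msa(rows):
    return MSA([f"s{k}" for k in range(len(rows))], rows)


class TestPreprocess:
    def test_majority_gap_row_removed(self):
        msa = make_msa(["ACGU", "A---"])  # 75% gaps
        out = dca.preprocess_msa(msa)
        assert out.rows == ["ACGU"]

    def test_exactly_half_gaps_retained(self):
        msa = make_msa(["ACGU", "AC--"])
        assert dca.preprocess_msa(msa).n == 2

    def test_matches_counting_oracle(self, rng):
        letters = np.array(list("ACGU-"))
        rows = ["".join(letters[rng.integers(0, 5, 12)]) for _ in range(40)]
        out = dca.preprocess_msa(make_msa(rows), max_gap_fraction=0.5)
        expected = [r for r in rows if r.count("-") / len(r) <= 0.5]
        assert out.rows == expected

    def test_all_removed(self):
        with pytest.raises(ValueError, match="empty after filtering"):
            dca.preprocess_msa(make_msa(["----", "---A"]))


class TestSequenceWeights:
    def test_identical_rows(self):
        w = dca.sequence_weights(make_msa(["ACGU"] * 5))
        np.testing.assert_allclose(w, 0.2)
        assert w.sum() == pytest.approx(1.0)

    def test_all_dissimilar(self):
        w = dca.sequence_weights(make_msa(["AAAA", "CCCC", "GGGG", "UUUU"]))
        np.testing.assert_allclose(w, 1.0)

    def test_matches_brute_force(self, rng):
        letters = np.array(list("ACGU-"))
        rows = ["".join(letters[rng.integers(0, 5, 8)]) for _ in range(20)]
        w = dca.sequence_weights(make_msa(rows), identity_threshold=0.8)
        for s, row_s in enumerate(rows):
            neighbors = sum(
                1
                for row_t in rows
                if sum(a == b for a, b in zip(row_s, row_t)) / len(row_s) >= 0.8
            )
            assert w[s] == pytest.approx(1.0 / neighbors)


class TestFrequencies:
    def test_no_pseudocount_single_row(self):
        fm = dca.frequencies(make_msa(["AAAA"]), pseudocount_weight=0.0)
        np.testing.assert_allclose(fm.f_single[:, 0], 1.0)
        np.testing.assert_allclose(fm.f_single[:, 1:], 0.0)

    def test_uniform_limit(self):
        fm = dca.frequencies(make_msa(["AAAA", "ACGU"]), pseudocount_weight=0.99)
        np.testing.assert_allclose(fm.f_single, 0.2, atol=0.01)

    def test_matches_summation_oracle(self, rng):
        letters = np.array(list("ACGU-"))
        rows = ["".join(letters[rng.integers(0, 5, 6)]) for _ in range(15)]
        msa = make_msa(rows)
        weights = rng.uniform(0.2, 1.0, 15)
        lam = 0.5
        fm = dca.frequencies(msa, weights, pseudocount_weight=lam)
        enc = msa.encode()
        meff = weights.sum()
        state = {c: k for k, c in enumerate("ACGU-")}
        i, j, a, b = 2, 5, state["G"], state["-"]
        f_i = sum(w for w, r in zip(weights, rows) if state[r[i]] == a) / meff
        f_ij = sum(
            w for w, r in zip(weights, rows) if state[r[i]] == a and state[r[j]] == b
        ) / meff
        assert fm.f_single[i, a] == pytest.approx((1 - lam) * f_i + lam / 5)
        assert fm.f_pair[i, j, a, b] == pytest.approx((1 - lam) * f_ij + lam / 25)

    def test_marginal_consistency(self, rng):
        letters = np.array(list("ACGU-"))
        rows = ["".join(letters[rng.integers(0, 5, 7)]) for _ in range(12)]
        fm = dca.frequencies(make_msa(rows), pseudocount_weight=0.5)
        np.testing.assert_allclose(fm.f_single.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            fm.f_pair.sum(axis=3), np.broadcast_to(fm.f_single[:, None], fm.f_pair.shape[:3]),
            atol=1e-12,
        )

    def test_invalid_pseudocount(self):
        with pytest.raises(ValueError, match="invalid pseudocount"):
            dca.frequencies(make_msa(["ACGU"]), pseudocount_weight=1.0)


def independent_frequency_model(rng, L=4):
    """FrequencyModel with exactly factorized pair frequencies."""
    f1 = rng.dirichlet(np.ones(dca.Q) * 4, size=L)
    f2 = np.einsum("ia,jb->ijab", f1, f1)
    for i in range(L):
        f2[i, i] = np.diag(f1[i])
    return dca.FrequencyModel(f1, f2, np.ones(1), 1.0, 0.0)


class TestCouplings:
    def test_independent_columns_zero_couplings(self, rng):
        fm = independent_frequency_model(rng)
        cmodel = dca.mean_field_couplings(fm)
        off = cmodel.e.copy()
        for i in range(fm.length):
            off[i, i] = 0.0
        assert np.abs(off).max() < 1e-8

    def test_two_column_hand_inversion(self, rng):
        fm = dca.frequencies(
            make_msa(["AU", "UA", "AU", "GC", "CG", "AA", "UU", "GU"]),
            pseudocount_weight=0.5,
        )
        cmodel = dca.mean_field_couplings(fm)
        # independent route: build C explicitly and invert with solve
        qr = dca.Q - 1
        C = np.zeros((2 * qr, 2 * qr))
        for i in range(2):
            for j in range(2):
                C[i * qr : (i + 1) * qr, j * qr : (j + 1) * qr] = (
                    fm.f_pair[i, j, :qr, :qr]
                    - np.outer(fm.f_single[i, :qr], fm.f_single[j, :qr])
                )
        e01 = -np.linalg.inv(C)[0:qr, qr : 2 * qr]
        np.testing.assert_allclose(cmodel.e[0, 1, :qr, :qr], e01, atol=1e-10)

    def test_planted_pair_sign_pattern(self):
        msa = synthetic.synth_msa(None, [(1, 10)], n_sequences=400,
                                  coupling_strength=3.0, gap_rate=0.0, seed=8, length=12)
        fm = dca.frequencies(msa, dca.sequence_weights(msa))
        cmodel = dca.mean_field_couplings(fm)
        e = cmodel.e[0, 9]
        paired = [e[a, b] for a, b in synthetic.PAIRED_STATES]
        unpaired = [e[a, b] for a in range(4) for b in range(4)
                    if (a, b) not in synthetic.PAIRED_STATES]
        assert np.mean(paired) > np.mean(unpaired)


class TestTwoSiteFit:
    def test_zero_coupling_gives_product(self, rng):
        fm = independent_frequency_model(rng)
        cmodel = dca.CouplingModel(np.zeros((4, 4, dca.Q, dca.Q)))
        joint = dca.fit_two_site(cmodel, fm, 0, 2, tol=1e-12, max_iter=5000)
        np.testing.assert_allclose(
            joint, np.outer(fm.f_single[0], fm.f_single[2]), atol=1e-10
        )

    def test_marginal_constraints(self, rng):
        msa = synthetic.synth_msa(None, [(1, 6)], n_sequences=100,
                                  coupling_strength=2.0, gap_rate=0.1, seed=4, length=8)
        fm = dca.frequencies(msa, dca.sequence_weights(msa))
        cmodel = dca.mean_field_couplings(fm)
        for (i, j) in [(0, 5), (1, 3), (2, 7)]:
            joint = dca.fit_two_site(cmodel, fm, i, j, tol=1e-8)
            np.testing.assert_allclose(joint.sum(axis=1), fm.f_single[i], atol=1e-7)
            np.testing.assert_allclose(joint.sum(axis=0), fm.f_single[j], atol=1e-7)

    def test_matches_independent_solver(self, rng):
        q = dca.Q
        e = rng.normal(0, 0.8, (q, q))
        fi = rng.dirichlet(np.ones(q) * 3)
        fj = rng.dirichlet(np.ones(q) * 3)
        cmodel = dca.CouplingModel(np.tile(e, (2, 2, 1, 1)) * 0)
        cmodel.e[0, 1] = e
        fm = dca.FrequencyModel(np.stack([fi, fj]),
                                np.zeros((2, 2, q, q)), np.ones(1), 1.0, 0.0)
        joint = dca.fit_two_site(cmodel, fm, 0, 1, tol=1e-12, max_iter=20000)

        # independent oracle: solve for the fields with a generic root finder
        def resid(x):
            hi, hj = x[:q], x[q:]
            p = np.exp(e + hi[:, None] + hj[None, :])
            p /= p.sum()
            return np.concatenate([p.sum(1) - fi, p.sum(0) - fj])

        sol = optimize.least_squares(resid, np.zeros(2 * q), xtol=1e-15, ftol=1e-15)
        hi, hj = sol.x[:q], sol.x[q:]
        expected = np.exp(e + hi[:, None] + hj[None, :])
        expected /= expected.sum()
        np.testing.assert_allclose(joint, expected, atol=1e-8)


class TestDirectInformation:
    def test_zero_coupling_zero_di(self, rng):
        fm = independent_frequency_model(rng)
        cmodel = dca.CouplingModel(np.zeros((4, 4, dca.Q, dca.Q)))
        di = dca.direct_information(fm, cmodel, tol=1e-12, max_iter=5000)
        assert np.abs(di).max() < 1e-9

    def test_perfectly_correlated_pair_gives_ln2(self):
        # two-state pair, uniform marginals, coupling strong enough to
        # lock the joint onto the diagonal
        q = dca.Q
        e = np.zeros((q, q))
        e[0, 0] = e[1, 1] = 40.0
        eps = 1e-12
        f = np.array([0.5 - 1.5 * eps, 0.5 - 1.5 * eps, eps, eps, eps])
        cmodel = dca.CouplingModel(np.zeros((2, 2, q, q)))
        cmodel.e[0, 1] = e
        fm = dca.FrequencyModel(np.stack([f, f]), np.zeros((2, 2, q, q)), np.ones(1), 1.0, 0.0)
        joint = dca.fit_two_site(cmodel, fm, 0, 1, tol=1e-13, max_iter=50000)
        prod = np.outer(f, f)
        mask = joint > 0
        di = float(np.sum(joint[mask] * np.log(joint[mask] / prod[mask])))
        assert di == pytest.approx(math.log(2), abs=1e-6)

    def test_matches_brute_force_summation(self, rng):
        msa = synthetic.synth_msa(None, [(1, 5), (2, 8)], n_sequences=150,
                                  coupling_strength=2.0, gap_rate=0.05, seed=13, length=10)
        fm = dca.frequencies(msa, dca.sequence_weights(msa))
        cmodel = dca.mean_field_couplings(fm)
        di = dca.direct_information(fm, cmodel, tol=1e-10, max_iter=20000)
        pairs = [(int(a), int(b)) for a, b in zip(*np.triu_indices(10, 1))]
        for i, j in [pairs[k] for k in rng.choice(len(pairs), 10, replace=False)]:
            joint = dca.fit_two_site(cmodel, fm, i, j, tol=1e-10, max_iter=20000)
            total = 0.0
            for a in range(dca.Q):
                for b in range(dca.Q):
                    total += joint[a, b] * math.log(
                        joint[a, b] / (fm.f_single[i, a] * fm.f_single[j, b])
                    )
            assert di[i, j] == pytest.approx(total, abs=1e-9)

    def test_symmetry_and_nonnegativity(self, small_instance):
        di = dca.di_from_msa(small_instance.msa)
        np.testing.assert_allclose(di, di.T)
        assert di.min() > -1e-12

    def test_independent_msa_low_di(self):
        msa = synthetic.synth_msa(None, [], n_sequences=800,
                                  coupling_strength=0.0, gap_rate=0.05, seed=3, length=20)
        di = dca.di_from_msa(msa)
        assert di.max() < 0.05

    def test_planted_pairs_beat_background(self):
        planted = [(1, 11), (3, 14), (5, 17)]
        msa = synthetic.synth_msa(None, planted, n_sequences=500,
                                  coupling_strength=3.0, gap_rate=0.05, seed=6, length=20)
        di = dca.di_from_msa(msa)
        mask = np.zeros_like(di, dtype=bool)
        for i, j in planted:
            mask[i - 1, j - 1] = mask[j - 1, i - 1] = True
        np.fill_diagonal(di, np.nan)
        assert np.nanmean(di[mask]) > np.nanmean(di[~mask])

    def test_pipeline_determinism(self, small_instance):
        d1 = dca.di_from_msa(small_instance.msa)
        d2 = dca.di_from_msa(small_instance.msa)
        np.testing.assert_array_equal(d1, d2)
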