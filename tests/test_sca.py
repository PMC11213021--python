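import numpy as np
import pytest
from scipy import stats

from sectordyn.msa_io import Alignment, ProcessingParams, build_position_map, process_msa
from sectordyn.sca import (
    BACKGROUND_UNIFORM,
    assign_ic_positions,
    build_sca_matrix,
    compute_frequencies,
    compute_sequence_weights,
    eigendecompose,
    order_matrix_by_ic,
    positional_conservation,
    rotate_ica,
    sca_matrix_from_alignment,
    select_significant_eigenmodes,
)
from sectordyn.synthetic import SyntheticMSAParams, simulate_msa

PERMISSIVE = ProcessingParams(1.0, 1.0, 0.0)


def processed(aln: Alignment):
    return process_msa(aln, aln.seq_ids[0], PERMISSIVE)


def brute_force_meff(rows: list[str], cutoff: float) -> float:
    """Independent neighbour-count oracle for the effective sequence count."""
    total = 0.0
    for a in rows:
        neighbours = 0
        for b in rows:
            ident = sum(x == y for x, y in zip(a, b)) / len(a)
            if ident >= cutoff:
                neighbours += 1
        total += 1.0 / neighbours
    return total


class TestSequenceWeights:
    def test_identical_rows_share_weight(self):
        aln = Alignment([f"s{i}" for i in range(4)], ["ACDE"] * 4)
        w = compute_sequence_weights(processed(aln), 0.8)
        assert np.allclose(w.w, 0.25)
        assert w.m_eff == pytest.approx(1.0)

    def test_unrelated_rows_keep_unit_weight(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "CCCC", "DDDD"])
        w = compute_sequence_weights(processed(aln), 0.8)
        assert np.allclose(w.w, 1.0)
        assert w.m_eff == pytest.approx(3.0)

    def test_two_identical_plus_one_unrelated(self):
        # brute-force pairwise identity: the twins count each other
        aln = Alignment(["a", "b", "c"], ["ACDEF", "ACDEF", "MMMMM"])
        w = compute_sequence_weights(processed(aln), 0.8)
        assert np.allclose(w.w, [0.5, 0.5, 1.0])
        assert w.m_eff == pytest.approx(2.0)

    def test_meff_matches_neighbour_count_oracle(self, rng):
        letters = np.array(list("ACDG"))
        for _ in range(5):
            rows = ["".join(rng.choice(letters, size=8)) for _ in range(12)]
            aln = Alignment([f"s{i}" for i in range(12)], rows)
            w = compute_sequence_weights(processed(aln), 0.5)
            assert w.m_eff == pytest.approx(brute_force_meff(rows, 0.5))

    def test_bad_cutoff_rejected(self, toy_alignment):
        with pytest.raises(ValueError):
            compute_sequence_weights(processed(toy_alignment), 1.5)


class TestFrequencies:
    def test_pure_column_without_pseudocount(self):
        aln = Alignment(["a", "b"], ["A", "A"])
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        f = compute_frequencies(proc, w, pseudocount=0.0)
        assert f.f1[0, 0] == pytest.approx(1.0)  # 'A' is state 0
        assert f.f1[0, 1:].sum() == pytest.approx(0.0)

    def test_half_half_column_equal_weights(self):
        aln = Alignment(["a", "b"], ["AC", "SC"])  # col 0 half A half S
        proc = processed(aln)
        w = compute_sequence_weights(proc, 0.9)
        f = compute_frequencies(proc, w, pseudocount=0.0)
        a_idx = "ACDEFGHIKLMNPQRSTVWY".index("A")
        s_idx = "ACDEFGHIKLMNPQRSTVWY".index("S")
        assert f.f1[0, a_idx] == pytest.approx(0.5)
        assert f.f1[0, s_idx] == pytest.approx(0.5)

    def test_pseudocount_limit_approaches_uniform(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        f = compute_frequencies(proc, w, pseudocount=1.0 - 1e-9)
        assert np.allclose(f.f1, 1.0 / 21, atol=1e-8)

    def test_columns_sum_to_one_and_marginals_consistent(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        f = compute_frequencies(proc, w, pseudocount=0.03)
        assert np.allclose(f.f1.sum(axis=1), 1.0, atol=1e-9)
        # marginalising f2 over the partner column recovers f1
        marg = f.f2.sum(axis=3)  # (L, 21, L)
        for j in range(f.n_columns):
            assert np.allclose(marg[:, :, j], f.f1, atol=1e-9)
        # symmetry under (i,a) <-> (j,b)
        assert np.allclose(f.f2, f.f2.transpose(2, 3, 0, 1), atol=1e-12)

    def test_invalid_pseudocount_rejected(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        with pytest.raises(ValueError):
            compute_frequencies(proc, w, pseudocount=1.0)


class TestConservation:
    def _freqs(self, f_value: float):
        from sectordyn.sca import FrequencyModel, N_STATES

        f1 = np.full((1, N_STATES), (1 - f_value) / (N_STATES - 1))
        f1[0, 0] = f_value
        f2 = f1[:, :, None, None] * f1[None, None, :, :]
        return FrequencyModel(f1=f1, f2=f2.reshape(1, N_STATES, 1, N_STATES),
                              pseudocount=0.0)

    def test_background_frequency_gives_zero(self):
        q = np.full(20, 0.05)
        cons = positional_conservation(self._freqs(0.05), q)
        assert cons.d_per_residue[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert cons.phi[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_phi_formula_value(self):
        # ln(0.9 * 0.95 / (0.05 * 0.1)) = ln(171) = 5.1417...
        q = np.full(20, 0.05)
        cons = positional_conservation(self._freqs(0.9), q)
        assert cons.phi[0, 0] == pytest.approx(np.log(171.0), abs=1e-6)
        assert cons.phi[0, 0] == pytest.approx(5.1417, abs=1e-3)

    def test_relative_entropy_increases_away_from_background(self):
        q = np.full(20, 0.05)
        values = [
            positional_conservation(self._freqs(f), q).d_per_residue[0, 0]
            for f in (0.1, 0.3, 0.6, 0.9)
        ]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_invalid_background_rejected(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        f = compute_frequencies(proc, w)
        with pytest.raises(ValueError):
            positional_conservation(f, np.zeros(20))


def covarying_toy_alignment() -> Alignment:
    """200 x 10; columns 0 and 1 perfectly covary, the rest are iid."""
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    X = rng.choice(letters, size=(200, 10))
    state = rng.integers(2, size=200)
    X[:, 0] = np.where(state == 0, "A", "S")
    X[:, 1] = np.where(state == 0, "A", "S")
    return Alignment(
        [f"s{i}" for i in range(200)], ["".join(r) for r in X]
    )


class TestSCAMatrix:
    def test_symmetric_nonnegative(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        f = compute_frequencies(proc, w)
        sca = build_sca_matrix(f, positional_conservation(f))
        assert np.allclose(sca.c, sca.c.T)
        assert np.all(sca.c >= 0)

    def test_covarying_pair_dominates_independent_pairs(self):
        aln = covarying_toy_alignment()
        proc = processed(aln)
        w = compute_sequence_weights(proc, 0.9)
        f = compute_frequencies(proc, w, 0.03)
        sca = build_sca_matrix(f, positional_conservation(f))
        iu, ju = np.triu_indices(10, k=1)
        vals = sca.c[iu, ju]
        coupled = sca.c[0, 1]
        others = vals[~((iu == 0) & (ju == 1))]
        assert coupled > others.max()

    def test_column_shuffle_shrinks_planted_coupling(self):
        # label permutation collapses the planted couplings toward the null
        aln, truth = simulate_msa(seed=11)
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        X = proc.alignment.to_integer_matrix()
        c_true = sca_matrix_from_alignment(X, w).c
        rng = np.random.default_rng(0)
        Xs = X.copy()
        for j in range(Xs.shape[1]):
            rng.shuffle(Xs[:, j])
        c_null = sca_matrix_from_alignment(Xs, w).c
        sector = np.asarray(truth["sector_positions"]) - 1
        iu, ju = np.triu_indices(c_true.shape[0], k=1)
        in_sector = np.isin(iu, sector) & np.isin(ju, sector)
        res = stats.mannwhitneyu(
            c_true[iu, ju][in_sector],
            c_null[iu, ju][in_sector],
            alternative="greater",
        )
        assert res.pvalue < 0.01
        # and the shuffled matrix no longer separates sector from background
        assert np.median(c_null[iu, ju][in_sector]) < 0.5 * np.median(
            c_true[iu, ju][in_sector]
        )

    def test_eigendecomposition_reconstructs_matrix(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        f = compute_frequencies(proc, w)
        sca = build_sca_matrix(f, positional_conservation(f))
        vals, vecs = eigendecompose(sca)
        recon = (vecs * vals) @ vecs.T
        rel = np.linalg.norm(recon - sca.c) / max(np.linalg.norm(sca.c), 1e-30)
        assert rel < 1e-8


class TestEigenmodeSelection:
    def test_independent_columns_give_few_modes(self):
        rng = np.random.default_rng(3)
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        rows = ["".join(r) for r in rng.choice(letters, size=(300, 30))]
        aln = Alignment([f"s{i}" for i in range(300)], rows)
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        k = select_significant_eigenmodes(sca, proc, w, n_trials=10, seed=5)
        assert k <= 1

    def test_planted_sector_gives_at_least_one_mode(self):
        aln, _ = simulate_msa(seed=2)
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        k = select_significant_eigenmodes(sca, proc, w, n_trials=10, seed=5)
        assert k >= 1

    def test_deterministic_given_seed(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        k1 = select_significant_eigenmodes(sca, proc, w, n_trials=5, seed=9)
        k2 = select_significant_eigenmodes(sca, proc, w, n_trials=5, seed=9)
        assert k1 == k2


def two_sector_alignment(seed: int = 4):
    """Splice two independently planted sectors into one alignment."""
    p1 = SyntheticMSAParams(redundancy_rate=0.0)
    p2 = SyntheticMSAParams(
        sector_positions=(3, 9, 15, 28), redundancy_rate=0.0
    )
    a1, t1 = simulate_msa(p1, seed=seed)
    a2, t2 = simulate_msa(p2, seed=seed + 1)
    host = [list(r) for r in a1.rows]
    # graft sector 2's columns into positions unused by sector 1
    graft_at = [44, 46, 48, 50]  # 1-based target positions
    for tgt, src in zip(graft_at, t2["sector_positions"]):
        for i in range(len(host)):
            host[i][tgt - 1] = a2.rows[i][src - 1]
    aln = Alignment(a1.seq_ids, ["".join(r) for r in host])
    return aln, set(t1["sector_positions"]), set(graft_at)


class TestICARotation:
    def test_single_mode_returns_top_eigenvector(self, toy_alignment):
        proc = processed(toy_alignment)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        _, vecs = eigendecompose(sca)
        ica = rotate_ica(vecs[:, :1], seed=0)
        dot = abs(float(ica.ic_vectors[:, 0] @ vecs[:, 0]))
        assert dot == pytest.approx(1.0, abs=1e-9)

    def test_fixed_point_idempotence(self):
        aln, _, _ = two_sector_alignment()
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        _, vecs = eigendecompose(sca)
        once = rotate_ica(vecs[:, :2], seed=0)
        twice = rotate_ica(once.ic_vectors, seed=0)
        delta = np.abs(np.abs(twice.ic_vectors.T @ once.ic_vectors) - np.eye(2))
        assert delta.max() < 1e-6

    def test_two_planted_sectors_are_separated(self):
        aln, sector1, sector2 = two_sector_alignment()
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        _, vecs = eigendecompose(sca)
        ica = rotate_ica(vecs[:, :2], seed=0)
        resnum = proc.position_map.residue_numbers
        for j in range(2):
            v2 = ica.ic_vectors[:, j] ** 2
            frac1 = v2[np.isin(resnum, list(sector1))].sum()
            frac2 = v2[np.isin(resnum, list(sector2))].sum()
            assert max(frac1, frac2) >= 0.8

    def test_unit_norm_and_positive_peak(self):
        aln, _, _ = two_sector_alignment()
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        _, vecs = eigendecompose(sca)
        ica = rotate_ica(vecs[:, :2], seed=0)
        norms = np.linalg.norm(ica.ic_vectors, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-9)
        peaks = np.argmax(np.abs(ica.ic_vectors), axis=0)
        assert np.all(ica.ic_vectors[peaks, np.arange(2)] > 0)


class TestICAssignment:
    def test_dominant_entry_is_member(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 0.05, size=40)
        v[7] = 2.0
        ics = assign_ic_positions(v[:, None], 0.95)
        assert 8 in ics.memberships[0]  # position 8 in 1-based numbering

    def test_identical_loadings_have_no_members(self):
        with pytest.warns(UserWarning, match="identical"):
            ics = assign_ic_positions(np.full((20, 1), 0.3), 0.95)
        assert ics.memberships[0] == []

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_planted_outliers_recovered(self, seed):
        # all planted outliers land in the fitted tail; at most a couple of
        # background draws can straddle the 5% boundary (the fitted tail mass
        # equals the outlier count exactly, so the boundary is data-driven)
        rng = np.random.default_rng(seed)
        v = stats.t.rvs(df=5, loc=0.0, scale=0.03, size=100, random_state=rng)
        outliers = sorted([4, 17, 36, 58, 90])
        v[outliers] = 1.0 + 0.1 * rng.standard_normal(5)
        ics = assign_ic_positions(v[:, None], 0.95)
        members = ics.memberships[0]
        planted = [o + 1 for o in outliers]
        assert set(planted) <= set(members)
        assert len(set(members) - set(planted)) <= 2
        # the planted outliers are the top-ranked members
        top5 = sorted(np.argsort(v)[::-1][:5] + 1)
        assert top5 == planted

    def test_single_assignment_across_ics(self):
        aln, _, _ = two_sector_alignment()
        proc = processed(aln)
        w = compute_sequence_weights(proc)
        sca = sca_matrix_from_alignment(proc.alignment.to_integer_matrix(), w)
        _, vecs = eigendecompose(sca)
        ica = rotate_ica(vecs[:, :2], seed=0)
        ics = assign_ic_positions(ica.ic_vectors, 0.95, proc.position_map)
        flat = [r for m in ics.memberships for r in m]
        assert len(flat) == len(set(flat))

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            assign_ic_positions(np.zeros((10, 1)), 0.4)


class TestMatrixOrdering:
    def _sca_and_pmap(self, n=6):
        c = np.arange(n * n, dtype=float).reshape(n, n)
        c = (c + c.T) / 2
        c[c < 0] = 0
        from sectordyn.sca import SCAMatrix

        aln = Alignment(["r"], ["A" * n])
        return SCAMatrix(np.abs(c)), build_position_map(aln, "r", 1)

    def _assignment(self, memberships, n=6):
        from sectordyn.sca import ICAssignment

        k = len(memberships)
        return ICAssignment(
            ic_vectors=np.zeros((n, max(k, 1))),
            memberships=memberships,
            p_cutoff=0.95,
            fit_params=[None] * max(k, 1),
            loadings_cdf=np.zeros((n, max(k, 1))),
        )

    def test_no_ics_is_identity(self):
        sca, pmap = self._sca_and_pmap()
        _, perm = order_matrix_by_ic(sca, self._assignment([[]]), pmap)
        assert list(perm) == list(range(6))

    def test_members_ordered_numerically(self):
        sca, pmap = self._sca_and_pmap()
        _, perm = order_matrix_by_ic(sca, self._assignment([[5, 2]]), pmap)
        assert list(perm[:2]) == [1, 4]  # residues 2 then 5 (0-based cols)

    def test_permutation_roundtrip(self):
        sca, pmap = self._sca_and_pmap()
        ordered, perm = order_matrix_by_ic(
            sca, self._assignment([[5, 2], [6]]), pmap
        )
        inv = np.argsort(perm)
        assert np.allclose(ordered[np.ix_(inv, inv)], sca.c)
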