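"""Laplacian/Dirac assembly, spectra, and the polynomial invariants."""

import numpy as np
import pytest

from khovlap import (
    KhovanovComplex,
    betti_table,
    dirac,
    fixtures,
    jones_polynomial,
    kauffman_state_sum,
    laplacian,
    mirror,
    poincare_polynomial,
    spectrum,
    spectrum_table,
)
from khovlap.spectral import laurent_divide_by_q_plus_qinv, poincare_at_minus_one


class TestLaplacian:
    def test_trefoil_delta03(self, trefoil_cx):
        op = laplacian(trefoil_cx, 0, 3)
        assert np.array_equal(op.total, [[3, 3], [3, 3]])
        assert np.all(op.down == 0)  # r = 0 is the minimal degree here

    def test_trefoil_delta15(self, trefoil_cx):
        op = laplacian(trefoil_cx, 1, 5)
        assert np.array_equal(op.total, [[5, -1, -1], [-1, 5, -1], [-1, -1, 5]])

    def test_unknot_laplacian_is_zero(self, unknot):
        op = laplacian(KhovanovComplex(unknot), 0, 1)
        assert op.total.shape == (1, 1) and op.total[0, 0] == 0

    def test_empty_bin_gives_empty_operator(self, trefoil_cx):
        op = laplacian(trefoil_cx, 5, 3)
        assert op.dim == 0
        assert spectrum(op).eigenvalues.size == 0

    @pytest.mark.parametrize("name", ["trefoil_R", "figure8", "k8_12", "hopf+"])
    def test_symmetric_and_psd(self, name):
        cx = KhovanovComplex(fixtures(name))
        for r, q in cx.gradings:
            op = laplacian(cx, r, q)
            assert np.array_equal(op.total, op.total.T)
            for part in (op.up, op.down, op.total):
                if part.size:
                    assert np.linalg.eigvalsh(part.astype(float)).min() >= -1e-9


class TestSpectra:
    @pytest.mark.parametrize(
        "r,q,expected",
        [(0, 3, [0, 6]), (1, 5, [3, 6, 6]), (1, 3, [3, 3, 6]), (0, 1, [0]),
         (2, 5, [0, 2, 2, 5, 6, 6]), (3, 9, [0])],
    )
    def test_trefoil_spectra(self, trefoil_cx, r, q, expected):
        # (0,3), (1,5), (1,3) are the worked examples; the rest are frozen
        # regression values from the exact integer assembly
        sp = spectrum(laplacian(trefoil_cx, r, q))
        assert np.allclose(sp.eigenvalues, expected, atol=1e-9)

    def test_trefoil_least_nonzero(self, trefoil_cx):
        assert spectrum(laplacian(trefoil_cx, 0, 3)).least_nonzero == pytest.approx(6)
        assert spectrum(laplacian(trefoil_cx, 1, 5)).least_nonzero == pytest.approx(3)

    def test_zero_multiplicity_matches_exact_oracle_everywhere(self):
        for name in ("trefoil_R", "figure8", "k8_12", "hopf+", "trefoil_xy5"):
            cx = KhovanovComplex(fixtures(name))
            table = spectrum_table(cx)  # raises internally on any mismatch
            for (r, q), sp in table.items():
                assert sp.zero_multiplicity == cx.homology_rank(r, q)

    def test_supersymmetry_up_down(self):
        # nonzero spectrum of up at r equals nonzero spectrum of down at r+1
        for name in ("trefoil_R", "figure8", "hopf+"):
            cx = KhovanovComplex(fixtures(name))
            for r, q in cx.gradings:
                up = laplacian(cx, r, q).up
                down = laplacian(cx, r + 1, q).down
                eu = np.linalg.eigvalsh(up.astype(float)) if up.size else np.zeros(0)
                ed = np.linalg.eigvalsh(down.astype(float)) if down.size else np.zeros(0)
                eu, ed = np.sort(eu[eu > 1e-8]), np.sort(ed[ed > 1e-8])
                assert eu.shape == ed.shape
                if eu.size:
                    assert np.max(np.abs(eu - ed)) < 1e-8


class TestDirac:
    def test_trefoil_dirac13_matches_worked_matrix(self, trefoil_cx):
        printed = np.array(
            [
                [0, 0, 1, 1, 1, 0, 0, 0],
                [0, 0, 1, 1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0, 1, 1, 0],
                [1, 1, 0, 0, 0, -1, 0, 1],
                [1, 1, 0, 0, 0, 0, -1, -1],
                [0, 0, 1, -1, 0, 0, 0, 0],
                [0, 0, 1, 0, -1, 0, 0, 0],
                [0, 0, 0, 1, -1, 0, 0, 0],
            ]
        )
        op = dirac(trefoil_cx, 1, 3)
        assert op.block_dims == [2, 3, 3]
        assert np.array_equal(op.total, printed)

    def test_dirac_squared_is_block_diagonal_of_laplacians(self, trefoil_cx):
        op = dirac(trefoil_cx, 1, 3)
        blocks = op.squared_blocks()
        assert np.array_equal(blocks[0], laplacian(trefoil_cx, 0, 3).total)
        assert np.array_equal(blocks[1], laplacian(trefoil_cx, 1, 3).total)
        assert np.array_equal(blocks[2], laplacian(trefoil_cx, 2, 3).down)
        # and the off-diagonal part of the square vanishes identically
        sq = op.total @ op.total
        off = sq.copy()
        o = 0
        for d in op.block_dims:
            off[o : o + d, o : o + d] = 0
            o += d
        assert np.abs(off).max() == 0

    def test_trefoil_dirac13_eigenvalues(self, trefoil_cx):
        eigs = np.linalg.eigvalsh(dirac(trefoil_cx, 1, 3).total.astype(float))
        expected = [-np.sqrt(6), -np.sqrt(3), -np.sqrt(3), 0, 0,
                    np.sqrt(3), np.sqrt(3), np.sqrt(6)]
        assert np.allclose(np.sort(eigs), expected, atol=1e-8)

    @pytest.mark.parametrize("name", ["figure8", "hopf+", "trefoil_xy5"])
    def test_dirac_eigenvalues_are_pm_sqrt_of_block_eigenvalues(self, name):
        cx = KhovanovComplex(fixtures(name))
        qs = cx.q_values()
        r_lo, r_hi = cx.r_range
        for q in qs:
            op = dirac(cx, min(r_hi - 1, r_lo + 1), q)
            if op.dim == 0:
                continue
            d_eigs = np.sort(np.abs(np.linalg.eigvalsh(op.total.astype(float))))
            sq_eigs = np.sort(
                np.sqrt(np.abs(np.concatenate(
                    [np.linalg.eigvalsh(b.astype(float)) for b in op.squared_blocks()
                     if b.size] or [np.zeros(0)]
                )))
            )
            # sqrt amplifies numerically-zero eigenvalues of the squared
            # operator (sqrt(1e-14) ~ 1e-7), hence the 1e-6 tolerance
            assert np.allclose(d_eigs, sq_eigs, atol=1e-6)


class TestPolynomials:
    def test_unknot_jones_is_one(self, unknot):
        assert jones_polynomial(unknot) == {0: 1}
        assert poincare_polynomial(unknot) == {(0, -1): 1, (0, 1): 1}

    def test_trefoil_poincare_t0_coefficients(self, trefoil_cx):
        kh = poincare_polynomial(trefoil_cx)
        assert {q: c for (r, q), c in kh.items() if r == 0} == {1: 1, 3: 1}

    def test_poincare_at_minus_one_is_state_sum(self):
        for name in ("trefoil_R", "trefoil_L", "figure8", "hopf+", "hopf-",
                     "k8_12", "trefoil_xy5", "trefoil_xy7"):
            d = fixtures(name)
            assert poincare_at_minus_one(betti_table(d)) == kauffman_state_sum(d)

    def test_jones_of_mirror_substitutes_q_inverse(self):
        for name in ("trefoil_R", "figure8", "hopf+"):
            d = fixtures(name)
            j = jones_polynomial(d)
            jm = jones_polynomial(mirror(d))
            assert jm == {-p: c for p, c in j.items()}

    def test_exact_laurent_division(self):
        # (q + q^-1)(q^2 - 1 + q^-2) = q^3 + q^-3
        assert laurent_divide_by_q_plus_qinv({3: 1, -3: 1}) == {2: 1, 0: -1, -2: 1}
        with pytest.raises(RuntimeError, match="divisible"):
            laurent_divide_by_q_plus_qinv({0: 1})


class TestRelabelingInvariance:
    def test_spectra_invariant_under_crossing_permutation_and_relabeling(self):
        rng = np.random.default_rng(7)
        base = fixtures("trefoil_xy5")
        ref = {k: v.eigenvalues for k, v in spectrum_table(base).items()}
        for _ in range(3):
            # permute the crossing order
            perm = rng.permutation(base.n)
            pd = " ".join("X[%d,%d,%d,%d]" % base.crossings[i].edges for i in perm)
            # cyclically relabel edges within the single component
            lo, hi = base.components[0]
            size = hi - lo + 1
            shift = int(rng.integers(1, size))
            relabeled = __import__("khovlap").parse_pd(pd)
            tuples = [
                tuple((e - lo + shift) % size + lo for e in c.edges)
                for c in relabeled.crossings
            ]
            d2 = __import__("khovlap").parse_pd(
                " ".join("X[%d,%d,%d,%d]" % t for t in tuples)
            )
            table = {k: v.eigenvalues for k, v in spectrum_table(d2).items()}
            assert set(table) == set(ref)
            for k in ref:
                assert np.allclose(table[k], ref[k], atol=1e-8)
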