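"""Boundary matrices, persistent Laplacians, spectra, and Betti numbers."""

import numpy as np
import pytest

from pdfl.flag_complex import (
    FilteredDigraph,
    build_flag_complex,
    complex_at_filtration,
)
from pdfl.laplacian_spectra import (
    Spectrum,
    betti,
    boundary_matrix,
    persistent_boundary,
    persistent_laplacian,
    read_spectra,
    spectrum,
    write_spectra,
)
from pdfl.synthetic_fixtures import directed_cycle

from tests.oracles import persistent_betti_oracle, random_digraph


class TestBoundaryMatrix:
    def test_single_edge_column(self):
        g = FilteredDigraph()
        g.add_edge("a", "b", 0.0)
        k = build_flag_complex(g, max_dim=1)
        B1 = boundary_matrix(1, k).toarray()
        # rows are a, b in lexicographic order; d(a,b) = (b) - (a)
        assert B1.shape == (2, 1)
        assert B1[:, 0].tolist() == [-1.0, 1.0]

    def test_four_clique_b1_and_graph_laplacian(self, four_clique_complex):
        B1 = boundary_matrix(1, four_clique_complex).toarray()
        assert B1.shape == (4, 6)
        vals = np.linalg.eigvalsh(B1 @ B1.T)
        assert np.allclose(sorted(vals), [0, 4, 4, 4], atol=1e-9)

    def test_columns_have_k_plus_1_signed_entries(self, four_clique_complex):
        for k in (1, 2, 3):
            B = boundary_matrix(k, four_clique_complex).toarray()
            for col in B.T:
                nz = col[col != 0]
                assert len(nz) == k + 1
                assert set(np.abs(nz)) == {1.0}

    def test_chain_complex_identity(self, four_clique_complex):
        for k in (1, 2):
            Bk = boundary_matrix(k, four_clique_complex).toarray()
            Bk1 = boundary_matrix(k + 1, four_clique_complex).toarray()
            assert np.allclose(Bk @ Bk1, 0.0)

    def test_empty_dimensions_give_zero_shapes(self):
        k = build_flag_complex(FilteredDigraph(["a", "b"]), max_dim=2)
        assert boundary_matrix(1, k).shape == (2, 0)
        assert boundary_matrix(2, k).shape == (0, 0)


class TestFourCliqueSpectra:
    """The worked example: transitively oriented complete digraph on 4 vertices."""

    EXPECTED = {0: [0, 4, 4, 4], 1: [4, 4, 4, 4, 4, 4], 2: [4, 4, 4, 4], 3: [4]}
    BETTI = {0: 1, 1: 0, 2: 0, 3: 0}

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_spectrum_and_betti(self, four_clique_complex, k):
        s = persistent_laplacian(k, four_clique_complex).spectrum()
        assert np.allclose(s.eigenvalues, self.EXPECTED[k], atol=1e-9)
        assert betti(s) == self.BETTI[k]

    def test_fiedler_value(self, four_clique_complex):
        s = persistent_laplacian(0, four_clique_complex).spectrum()
        assert s.fiedler == pytest.approx(4.0)

    def test_euler_characteristic_equals_alternating_betti_sum(
        self, four_clique_complex
    ):
        alt = sum(
            (-1) ** k * persistent_laplacian(k, four_clique_complex).spectrum().betti
            for k in range(4)
        )
        assert four_clique_complex.euler_characteristic() == alt == 1


class TestPersistentLaplacian:
    def test_vertices_to_single_edge(self):
        g = FilteredDigraph()
        g.add_edge("a", "b", 0.5)
        k = build_flag_complex(g, max_dim=1)
        ca = complex_at_filtration(k, 0.0)  # vertices only
        cb = complex_at_filtration(k, 1.0)
        s = persistent_laplacian(0, ca, cb).spectrum()
        assert np.allclose(s.eigenvalues, [0, 2], atol=1e-9)

    def test_vertices_to_three_cycle(self):
        k = build_flag_complex(directed_cycle(3), max_dim=2)
        ca = build_flag_complex(
            FilteredDigraph(["a", "b", "c"]), max_dim=2
        )
        s = persistent_laplacian(0, ca, k).spectrum()
        assert np.allclose(s.eigenvalues, [0, 3, 3], atol=1e-9)

    def test_three_cycle_l1_betti_counts_the_loop(self):
        k = build_flag_complex(directed_cycle(3), max_dim=2)
        s = persistent_laplacian(1, k).spectrum()
        assert np.allclose(s.eigenvalues, [0, 3, 3], atol=1e-9)
        assert betti(s) == 1

    def test_no_k_simplices_gives_empty_spectrum(self):
        k = build_flag_complex(FilteredDigraph(["a", "b"]), max_dim=2)
        s = persistent_laplacian(1, k).spectrum()
        assert s.eigenvalues.size == 0
        assert betti(s) == 0

    def test_rejects_non_subcomplex(self):
        g1 = FilteredDigraph()
        g1.add_edge("a", "b", 0.0)
        g2 = FilteredDigraph()
        g2.add_edge("b", "c", 0.0)
        k1 = build_flag_complex(g1, max_dim=1)
        k2 = build_flag_complex(g2, max_dim=1)
        with pytest.raises(ValueError, match="subcomplex"):
            persistent_laplacian(0, k1, k2)

    def test_a_equals_b_reduces_to_ordinary_laplacian(self, rng):
        for _ in range(10):
            g = random_digraph(rng, n_max=6, edge_prob=0.5,
                               filtration_levels=(0.0, 0.5))
            k = build_flag_complex(g, max_dim=3)
            for dim in range(3):
                persistent = persistent_laplacian(dim, k, k).spectrum()
                B_up = boundary_matrix(dim + 1, k).toarray()
                B_dn = boundary_matrix(dim, k).toarray()
                plain = spectrum(B_up @ B_up.T + B_dn.T @ B_dn)
                assert np.allclose(
                    persistent.eigenvalues, plain.eigenvalues, atol=1e-8
                )

    def test_psd_and_chain_identity_on_random_inputs(self, rng):
        for _ in range(10):
            g = random_digraph(rng, n_max=7, edge_prob=0.45,
                               filtration_levels=(0.2, 0.6, 1.0))
            k = build_flag_complex(g, max_dim=3)
            for dim in (1, 2):
                Bk = boundary_matrix(dim, k).toarray()
                Bk1 = boundary_matrix(dim + 1, k).toarray()
                assert np.allclose(Bk @ Bk1, 0.0)
            a, b = sorted(rng.choice([0.2, 0.6, 1.0], size=2))
            ca, cb = complex_at_filtration(k, a), complex_at_filtration(k, b)
            for dim in range(3):
                L = persistent_laplacian(dim, ca, cb).matrix
                if L.size:
                    assert np.linalg.eigvalsh(L).min() >= -1e-8

    def test_zero_count_matches_exact_homology_oracle(self, rng):
        levels = (0.25, 0.5, 1.0)
        for _ in range(8):
            g = random_digraph(rng, n_max=6, edge_prob=0.45,
                               filtration_levels=levels)
            k = build_flag_complex(g, max_dim=3)
            a, b = sorted(rng.choice(levels, size=2))
            ca, cb = complex_at_filtration(k, a), complex_at_filtration(k, b)
            for dim in (0, 1):
                got = persistent_laplacian(dim, ca, cb).spectrum().betti
                expected = persistent_betti_oracle(g, dim, a, b, max_dim=3)
                assert got == expected


class TestPersistentBoundary:
    def test_a_equals_b_preserves_up_laplacian_spectrum(self, four_clique_complex):
        D = persistent_boundary(1, four_clique_complex, four_clique_complex)
        B1 = boundary_matrix(1, four_clique_complex).toarray()
        assert np.allclose(
            np.linalg.eigvalsh(D @ D.T), np.linalg.eigvalsh(B1 @ B1.T), atol=1e-9
        )

    def test_basis_is_orthonormal(self, rng):
        # spectra would be basis-dependent otherwise: D = B_in Z with Z^T Z = I
        g = random_digraph(rng, n_max=6, edge_prob=0.6,
                           filtration_levels=(0.3, 0.9))
        k = build_flag_complex(g, max_dim=2)
        ca = complex_at_filtration(k, 0.3)
        D = persistent_boundary(2, k, ca)
        B2 = boundary_matrix(2, k).toarray()
        if B2.shape[1]:
            inside = [s.vertices in ca.index(1) for s in k.simplices(1)]
            B_out = B2[~np.array(inside)]
            if B_out.shape[0]:
                from scipy.linalg import null_space

                Z = null_space(B_out)
                assert np.allclose(Z.T @ Z, np.eye(Z.shape[1]), atol=1e-10)
        assert D.shape[0] == ca.n_simplices(1)


class TestSpectrum:
    def test_rejects_nonsymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            spectrum(np.array([[0.0, 1.0], [0.0, 0.0]]))

    def test_zero_matrix_all_harmonic(self):
        s = spectrum(np.zeros((5, 5)))
        assert np.allclose(s.eigenvalues, 0.0)
        assert betti(s) == 5

    def test_bbt_and_btb_share_nonzero_spectrum(self, rng):
        B = rng.normal(size=(5, 8))
        s1 = np.linalg.eigvalsh(B @ B.T)
        s2 = np.linalg.eigvalsh(B.T @ B)
        nz1 = sorted(v for v in s1 if v > 1e-8)
        nz2 = sorted(v for v in s2 if v > 1e-8)
        assert np.allclose(nz1, nz2)

    def test_betti_of_empty_spectrum_is_zero(self):
        assert betti(Spectrum(np.empty(0), 1e-8)) == 0


def test_spectra_export_round_trip(tmp_path, four_clique_complex):
    entries = [
        (k, 0.0, 0.0, persistent_laplacian(k, four_clique_complex).spectrum())
        for k in range(4)
    ]
    path = tmp_path / "spectra.tsv"
    write_spectra(entries, path)
    back = read_spectra(path)
    assert len(back) == 4
    for (k, a, b, s), (k2, a2, b2, vals) in zip(entries, back):
        assert (k, a, b) == (k2, a2, b2)
        assert np.allclose(vals, s.eigenvalues, atol=1e-10)
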