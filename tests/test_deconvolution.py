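"""Matrix construction, component assignment, percentages, NNLS oracle."""

import numpy as np
import pandas as pd
import pytest

import glycounmix as g
from glycounmix.deconvolution import ROLE_MIXTURE, ROLE_REFERENCE


def make_mixtures(library, names, fractions_list, grid, snr=None, seed=0):
    specs, truth = [], {}
    for i, fracs in enumerate(fractions_list):
        noise = g.NoiseModel(snr, seed + i)
        s = g.simulate_mixture_spectrum(library, fracs, grid, noise)
        sid = f"mix{i}"
        s.meta["species"] = sid
        specs.append(s)
        truth[sid] = {n: 100.0 * fracs.get(n, 0.0) for n in names}
    return specs, truth


@pytest.fixture(scope="module")
def binary_setup():
    lib = g.default_library()
    pair = lib.subset(lib.names[:2])
    raw = g.WavenumberGrid(1000, 1150, 0.5)
    grid = g.fingerprint_grid()
    a, b = pair.names
    fractions = [
        {a: 0.5, b: 0.5},
        {a: 0.25, b: 0.75},
        {a: 0.1, b: 0.9},
        {a: 0.05, b: 0.95},
    ]
    mixtures, truth = make_mixtures(pair, pair.names, fractions, raw)
    references = [(n, g.render_fingerprint(pair[n], raw)) for n in pair.names]
    return pair, raw, grid, mixtures, references, truth


class TestBuildInputMatrix:
    def test_binary_matrix_shape(self, binary_setup):
        pair, raw, grid, mixtures, references, _ = binary_setup
        extra = g.simulate_mixture_spectrum(
            pair, {pair.names[0]: 0.01, pair.names[1]: 0.99}, raw
        )
        X = g.build_input_matrix(mixtures + [extra], references, grid)
        assert X.X.shape == (7, 76)  # 5 mixtures + 2 pure references
        assert X.row_roles.count(ROLE_MIXTURE) == 5
        assert X.row_roles.count(ROLE_REFERENCE) == 2

    def test_four_isomer_matrix_shape(self, library):
        raw = g.WavenumberGrid(1000, 1150, 0.5)
        designs = g.enumerate_mixture_designs(library.names)
        mixtures, _ = make_mixtures(
            library, library.names, [d.as_dict() for d in designs], raw
        )
        references = [
            (n, g.render_fingerprint(library[n], raw)) for n in library.names
        ]
        X = g.build_input_matrix(mixtures, references, g.fingerprint_grid())
        assert X.X.shape == (15, 76)  # 11 mixtures + 4 singles

    def test_extract_matrix_shape(self, library):
        raw = g.WavenumberGrid(952, 1150, 0.5)
        grid = g.extended_grid()
        a, b = library.names[2:]
        mixtures, _ = make_mixtures(
            library, library.names, [{a: 0.15, b: 0.85}, {b: 1.0}], raw
        )
        references = [
            (n, g.render_fingerprint(library[n], raw)) for n in library.names
        ]
        X = g.build_input_matrix(mixtures, references, grid)
        assert X.X.shape == (6, 100)  # 2 unknowns + 4 standards

    def test_negative_intensities_clipped(self, library):
        raw = g.WavenumberGrid(1000, 1150, 0.5)
        noisy = g.simulate_mixture_spectrum(
            library, {library.names[0]: 1.0}, raw, g.NoiseModel(snr=3, seed=0)
        )
        assert np.any(noisy.intensities < 0)  # generator keeps negatives
        X = g.build_input_matrix(
            [noisy],
            [(library.names[0], g.render_fingerprint(library.models[0], raw))],
            g.fingerprint_grid(),
        )
        assert np.all(X.X >= 0)

    def test_degenerate_row_rejected(self, analysis_grid):
        flat = g.Spectrum(
            np.arange(1000.0, 1151.0, 0.5),
            np.full(302, -1.0),  # all-negative -> clipped to zero area
        )
        with pytest.raises(ValueError, match="degenerate"):
            g.build_input_matrix([flat], [], analysis_grid)


class TestFactorizeAndAssign:
    def test_noise_free_binary_recovery_vs_truth_and_oracle(self, binary_setup):
        pair, raw, grid, mixtures, references, truth = binary_setup
        X, result, assignment, table = g.deconvolve_mixtures(
            mixtures, references, grid,
            config=g.NMFConfig(n_components=2, seed=0), truth=truth,
        )
        # recovered fractions match generating fractions to < 1 percent point
        assert table.max_abs_error() < 1.0
        # and agree with the NNLS oracle run on the same matrix rows
        refs = X.X[[X.reference_rows[n] for n in pair.names]]
        pivot = table.pivot()
        for row in X.mixture_rows:
            f = g.nnls_fractions(X.X[row], refs)
            for j, name in enumerate(pair.names):
                nmf_pct = pivot.loc[X.row_labels[row], name]
                assert nmf_pct == pytest.approx(100 * f[j], abs=0.1)

    def test_assignment_dominant_diagonal(self):
        result = g.NMFResult(
            W=np.array([[0.99, 0.01], [0.02, 0.98], [0.5, 0.5]]),
            H=np.ones((2, 4)),
            objective_trace=np.array([1.0]),
            n_iter=1, converged=False,
            config=g.NMFConfig(n_components=2),
        )
        X = g.SpectraMatrix(
            np.ones((3, 4)),
            ["A", "B", "mix"],
            [ROLE_REFERENCE, ROLE_REFERENCE, ROLE_MIXTURE],
            np.arange(4.0),
            (0.0, 3.0),
        )
        a = g.assign_components(result, X)
        assert a.mapping == {0: "A", 1: "B"}

    def test_assignment_inverts_permutation(self):
        W = np.array([[0.05, 0.95], [0.97, 0.03]])
        result = g.NMFResult(
            W=W, H=np.ones((2, 4)), objective_trace=np.array([1.0]),
            n_iter=1, converged=False, config=g.NMFConfig(n_components=2),
        )
        X = g.SpectraMatrix(
            np.ones((2, 4)), ["A", "B"],
            [ROLE_REFERENCE, ROLE_REFERENCE],
            np.arange(4.0), (0.0, 3.0),
        )
        a = g.assign_components(result, X)
        assert a.mapping == {1: "A", 0: "B"}

    def test_ambiguous_assignment_rejected(self):
        W = np.array([[0.5, 0.5], [0.5, 0.5]])
        result = g.NMFResult(
            W=W, H=np.ones((2, 4)), objective_trace=np.array([1.0]),
            n_iter=1, converged=False, config=g.NMFConfig(n_components=2),
        )
        X = g.SpectraMatrix(
            np.ones((2, 4)), ["A", "B"],
            [ROLE_REFERENCE, ROLE_REFERENCE],
            np.arange(4.0), (0.0, 3.0),
        )
        with pytest.raises(ValueError, match="ambiguous"):
            g.assign_components(result, X)

    def test_weak_reference_warns(self):
        # a pure row whose top component carries < 50% of its weight
        W = np.array(
            [[0.40, 0.30, 0.30], [0.1, 0.8, 0.1], [0.05, 0.05, 0.9]]
        )
        result = g.NMFResult(
            W=W, H=np.ones((3, 5)), objective_trace=np.array([1.0]),
            n_iter=1, converged=False, config=g.NMFConfig(n_components=3),
        )
        X = g.SpectraMatrix(
            np.ones((3, 5)), ["A", "B", "C"],
            [ROLE_REFERENCE] * 3, np.arange(5.0), (0.0, 4.0),
        )
        with pytest.warns(UserWarning, match="weak reference"):
            a = g.assign_components(result, X)
        assert a.mapping == {0: "A", 1: "B", 2: "C"}

    def test_four_component_assignment_matches_generator_labels(self, library):
        raw = g.WavenumberGrid(1000, 1150, 0.5)
        designs = g.enumerate_mixture_designs(library.names)
        mixtures, truth = make_mixtures(
            library, library.names, [d.as_dict() for d in designs], raw
        )
        references = [
            (n, g.render_fingerprint(library[n], raw)) for n in library.names
        ]
        # default (random-init) factorization: assignment is already correct
        _, _, assignment, _ = g.deconvolve_mixtures(
            mixtures, references, g.fingerprint_grid(),
            config=g.NMFConfig(n_components=4, seed=0), truth=truth,
        )
        assert sorted(assignment.mapping.values()) == sorted(library.names)
        # anchored semi-supervised mode: noise-free recovery is exact
        _, _, assignment, table = g.deconvolve_mixtures(
            mixtures, references, g.fingerprint_grid(),
            config=g.NMFConfig(n_components=4, seed=0, init="reference"),
            truth=truth,
        )
        assert sorted(assignment.mapping.values()) == sorted(library.names)
        assert table.max_abs_error() < 1.0


class TestPercentages:
    def _result_with_unit_area_basis(self, W):
        k = W.shape[1]
        H = np.tile(1.0 / 3.0, (k, 4))  # rows have unit trapezoid area on 0..3
        return g.NMFResult(
            W=W, H=H, objective_trace=np.array([1.0]), n_iter=1,
            converged=False, config=g.NMFConfig(n_components=k),
        )

    def _matrix(self, labels, roles):
        return g.SpectraMatrix(
            np.ones((len(labels), 4)), labels, roles, np.arange(4.0), (0.0, 3.0)
        )

    def test_row_normalization(self):
        result = self._result_with_unit_area_basis(
            np.array([[1.0, 0.0], [0.0, 1.0], [0.25, 0.75]])
        )
        X = self._matrix(
            ["A", "B", "mix"], [ROLE_REFERENCE, ROLE_REFERENCE, ROLE_MIXTURE]
        )
        a = g.assign_components(result, X)
        table = g.weights_to_percentages(result, a, X)
        pivot = table.pivot()
        assert pivot.loc["mix", "A"] == pytest.approx(25.0)
        assert pivot.loc["mix", "B"] == pytest.approx(75.0)

    def test_percentages_sum_to_100(self, binary_setup):
        pair, raw, grid, mixtures, references, truth = binary_setup
        _, _, _, table = g.deconvolve_mixtures(mixtures, references, grid)
        sums = table.table.groupby("spectrum_id")["percent"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 100.0, atol=1e-6)

    def test_table_validates_percent_sums(self):
        bad = pd.DataFrame(
            {"spectrum_id": ["m", "m"], "isomer": ["A", "B"],
             "percent": [30.0, 30.0]}
        )
        with pytest.raises(ValueError, match="sum to 100"):
            g.AbundanceTable(bad)


class TestNNLSOracle:
    def grid_search_pair(self, mixture, refs, resolution=1e-4):
        """Independent 1-D oracle for 2 components: scan the fraction f in
        [0, 1]; the overall scale s >= 0 of the fit s*(f*r0 + (1-f)*r1) is
        profiled out in closed form, matching the cone NNLS searches."""
        fs = np.arange(0.0, 1.0 + resolution, resolution)
        best, best_err = 0.0, np.inf
        for f in fs:
            d = f * refs[0] + (1 - f) * refs[1]
            s = max(float(mixture @ d) / float(d @ d), 0.0)
            err = np.sum((mixture - s * d) ** 2)
            if err < best_err:
                best, best_err = f, err
        return np.array([best, 1.0 - best])

    def test_exact_interpolation(self, rng):
        refs = rng.uniform(0.0, 1.0, size=(2, 40))
        mixture = 0.3 * refs[0] + 0.7 * refs[1]
        np.testing.assert_allclose(
            g.nnls_fractions(mixture, refs), [0.3, 0.7], atol=1e-9
        )

    def test_pure_component(self, rng):
        refs = rng.uniform(0.0, 1.0, size=(2, 40))
        np.testing.assert_allclose(
            g.nnls_fractions(refs[0], refs), [1.0, 0.0], atol=1e-9
        )

    def test_random_convex_combinations_of_four(self, rng):
        refs = rng.uniform(0.0, 1.0, size=(4, 60))
        for _ in range(5):
            f = rng.dirichlet(np.ones(4))
            mixture = f @ refs
            np.testing.assert_allclose(
                g.nnls_fractions(mixture, refs), f, atol=1e-6
            )

    def test_matches_grid_search_for_pairs(self, rng):
        refs = rng.uniform(0.0, 1.0, size=(2, 50))
        mixture = 0.37 * refs[0] + 0.63 * refs[1] + rng.normal(0, 0.01, 50)
        mixture = np.maximum(mixture, 0)
        nnls = g.nnls_fractions(mixture, refs)
        gs = self.grid_search_pair(mixture, refs)
        np.testing.assert_allclose(nnls, gs, atol=2e-4)

    def test_degenerate_references_rejected(self, rng):
        row = rng.uniform(0.0, 1.0, size=30)
        refs = np.vstack([row, 2 * row])
        with pytest.raises(ValueError, match="degenerate"):
            g.nnls_fractions(row, refs)
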