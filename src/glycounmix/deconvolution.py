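"""Semi-supervised spectral deconvolution of isomer mixtures.

The workflow mirrors how reference-aided NMF unmixing is done in practice:
mixture spectra and pure-isomer reference spectra are binned, clipped at
zero (IR intensities are inherently non-negative; negative excursions are
noise), area-normalized and stacked into one input matrix; the matrix is
factorized with k = number of isomers; each NMF component is assigned to an
isomer through the pure-reference rows (resolving the permutation
ambiguity); and the weighting factors of the mixture rows are converted to
percentages. A non-negative least-squares projection onto the reference
rows serves as an independent oracle for validating the quantification.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .nmf import MultiplicativeNMF
from .preprocess import WavenumberGrid, bin_spectrum, normalize_area
from .spectra import Spectrum

__all__ = [
    "SpectraMatrix",
    "NMFConfig",
    "NMFResult",
    "ComponentAssignment",
    "AbundanceTable",
    "build_input_matrix",
    "nmf_factorize",
    "assign_components",
    "weights_to_percentages",
    "nnls_fractions",
    "deconvolve_mixtures",
]

ROLE_MIXTURE = "mixture"
ROLE_REFERENCE = "pure-reference"


@dataclass
class SpectraMatrix:
    """Binned, normalized spectra stacked row-wise — the NMF input.

    ``row_labels`` carries a per-row identifier; ``row_roles`` flags each
    row as a mixture or a pure reference (for references the label is the
    isomer name).
    """

    X: np.ndarray
    row_labels: list[str]
    row_roles: list[str]
    bin_centers: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if np.any(self.X < 0):
            raise ValueError("X must be non-negative")
        if np.any(self.X.sum(axis=1) <= 0):
            raise ValueError("every row must have positive sum")
        if len(self.row_labels) != self.X.shape[0] or len(self.row_roles) != self.X.shape[0]:
            raise ValueError("row labels/roles must match the number of rows")

    @property
    def mixture_rows(self) -> list[int]:
        return [i for i, r in enumerate(self.row_roles) if r == ROLE_MIXTURE]

    @property
    def reference_rows(self) -> dict[str, int]:
        return {
            self.row_labels[i]: i
            for i, r in enumerate(self.row_roles)
            if r == ROLE_REFERENCE
        }


@dataclass(frozen=True)
class NMFConfig:
    """Factorization settings.

    Defaults follow the fixed-iteration setup used for spectral unmixing:
    run the multiplicative updates for ``max_iter`` iterations (``tol=0``
    disables early stopping; the convergence flag is still reported).
    ``alpha`` splits into L1/L2 via ``l1_ratio`` (0 = pure L2).

    ``init='random'`` (the default, matching the standard unsupervised
    setup) starts both factors from seeded uniform noise. Congested,
    overlapping fingerprints admit alternative near-exact factorizations
    with "sharpened" bases, so a random start can settle on a stationary
    point whose mixture weights deviate by a few percent even on
    noise-free data — the practical face of NMF's non-uniqueness, and the
    main reason multicomponent quantification is less exact than binary.
    ``init='reference'`` instead anchors the initial basis at the
    pure-reference rows (weights warm-started against that fixed basis,
    then ordinary alternating updates); this semi-supervised mode removes
    the non-uniqueness drift and recovers noise-free mixtures essentially
    exactly.
    """

    n_components: int
    seed: int = 0
    max_iter: int = 2000
    alpha: float = 0.0
    l1_ratio: float = 0.0
    tol: float = 0.0
    init: str = "random"
    warm_start_max_iter: int = 20000  # coefficient fit to the anchored basis

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.max_iter < 1:
            raise ValueError("n_components and max_iter must be >= 1")
        if self.alpha < 0 or not (0 <= self.l1_ratio <= 1) or self.tol < 0:
            raise ValueError("invalid alpha / l1_ratio / tol")
        if self.init not in ("random", "reference"):
            raise ValueError("init must be 'random' or 'reference'")


@dataclass
class NMFResult:
    """Factorization output: weighting factors W, basis vectors H, trace."""

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    config: NMFConfig

    @property
    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ComponentAssignment:
    """Bijective mapping from NMF component index to isomer name."""

    mapping: dict[int, str]
    scores: np.ndarray  # (n_isomers, k) row-normalized reference weights

    @property
    def isomer_to_component(self) -> dict[str, int]:
        return {v: k for k, v in self.mapping.items()}


@dataclass
class AbundanceTable:
    """Long-form per-spectrum isomer percentages, with truth when known.

    Columns: spectrum_id, isomer, percent, truth_percent, abs_error
    (the latter two are NaN when no ground truth is attached).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"spectrum_id", "isomer", "percent"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table must contain columns {sorted(required)}")
        sums = self.table.groupby("spectrum_id")["percent"].sum()
        if not np.allclose(sums.to_numpy(), 100.0, atol=1e-6):
            raise ValueError("per-spectrum percentages must sum to 100")

    def pivot(self) -> pd.DataFrame:
        return self.table.pivot(index="spectrum_id", columns="isomer", values="percent")

    def max_abs_error(self) -> float:
        return float(self.table["abs_error"].max())

    def mean_abs_error(self) -> float:
        return float(self.table["abs_error"].mean())

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
def build_input_matrix(
    mixtures: Sequence[Spectrum],
    references: Sequence[tuple[str, Spectrum]],
    grid: WavenumberGrid,
    window: tuple[float, float] | None = None,
) -> SpectraMatrix:
    """Bin, clip, normalize and stack mixtures plus pure references.

    Each spectrum is binned onto `grid`, negative bin values are clipped to
    zero, and the row is normalized to unit trapezoidal area over `window`
    (default: the grid's own span). Mixture rows come first, then the
    reference rows flagged by role.
    """
    window = window or grid.window
    rows, labels, roles = [], [], []
    entries = [(s.meta.get("species", f"mixture-{i}"), ROLE_MIXTURE, s)
               for i, s in enumerate(mixtures)]
    entries += [(name, ROLE_REFERENCE, s) for name, s in references]
    for label, role, spectrum in entries:
        binned = bin_spectrum(spectrum, grid)
        clipped = binned.with_intensities(np.maximum(binned.intensities, 0.0))
        normed = normalize_area(clipped, window)  # raises for degenerate rows
        rows.append(normed.intensities)
        labels.append(str(label))
        roles.append(role)
    return SpectraMatrix(
        np.vstack(rows), labels, roles, grid.centers.copy(), window
    )


def nmf_factorize(X: SpectraMatrix | np.ndarray, config: NMFConfig) -> NMFResult:
    """Run the multiplicative-update NMF on a spectra matrix.

    ``config.init='reference'`` requires a `SpectraMatrix` with exactly
    ``n_components`` pure-reference rows; those rows become the starting
    basis.
    """
    data = X.X if isinstance(X, SpectraMatrix) else np.asarray(X, float)
    H0 = None
    if config.init == "reference":
        if not isinstance(X, SpectraMatrix):
            raise ValueError(
                "init='reference' needs a SpectraMatrix with flagged "
                "pure-reference rows"
            )
        refs = X.reference_rows
        if len(refs) != config.n_components:
            raise ValueError(
                f"init='reference' needs exactly {config.n_components} "
                f"pure-reference rows, got {len(refs)}"
            )
        H0 = data[list(refs.values())]
    est = MultiplicativeNMF(
        n_components=config.n_components,
        init="random" if H0 is None else "custom",
        alpha=config.alpha,
        l1_ratio=config.l1_ratio,
        max_iter=config.max_iter,
        tol=config.tol,
        warm_start_max_iter=0 if H0 is None else config.warm_start_max_iter,
        random_state=config.seed,
    )
    W = est.fit_transform(data, H=H0)
    return NMFResult(
        W=W,
        H=est.components_,
        objective_trace=est.objective_trace_,
        n_iter=est.n_iter_,
        converged=est.converged_,
        config=config,
    )


def assign_components(result: NMFResult, X: SpectraMatrix) -> ComponentAssignment:
    """Resolve the NMF permutation ambiguity via pure-reference rows.

    For each isomer's reference row the component weights are row-
    normalized; the bijection maximizing the total score is found by
    exhaustive search over permutations (k is small here). An ambiguous
    optimum (within 1e-9) raises; a reference row whose top component
    carries < 50% of its weight emits a "weak reference" warning.
    """
    refs = X.reference_rows
    if not refs:
        raise ValueError("no pure-reference rows to assign components with")
    k = result.W.shape[1]
    if len(refs) != k:
        raise ValueError(
            f"bijective assignment needs exactly {k} pure-reference rows "
            f"(one per isomer), got {len(refs)}"
        )
    isomers = list(refs)
    scores = np.zeros((len(isomers), k))
    for i, name in enumerate(isomers):
        w = result.W[refs[name]]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"reference row {name!r} has zero total weight")
        scores[i] = w / total
        if scores[i].max() < 0.5:
            warnings.warn(f"weak reference: {name!r}", stacklevel=2)

    best, best_score, second = None, -np.inf, -np.inf
    for perm in itertools.permutations(range(k), len(isomers)):
        s = sum(scores[i, c] for i, c in enumerate(perm))
        if s > best_score:
            best, best_score, second = perm, s, best_score
        elif s > second:
            second = s
    if best_score - second < 1e-9 and len(isomers) > 1:
        raise ValueError("ambiguous assignment")
    mapping = {c: isomers[i] for i, c in enumerate(best)}
    return ComponentAssignment(mapping=mapping, scores=scores)


def _rescale_to_unit_basis_area(
    result: NMFResult, bin_centers: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pin the per-component scale: H rows to unit area, W columns inversely.

    NMF leaves the split of scale between W column i and H row i free; the
    package's convention is to rescale each basis spectrum to unit
    trapezoidal area so that mixture-row weights are directly comparable
    spectral-area contributions. A collapsed (all-zero) component keeps
    zero weight.
    """
    W = result.W.copy()
    H = result.H.copy()
    for c in range(H.shape[0]):
        area = float(np.trapezoid(H[c], bin_centers))
        if area > 0:
            H[c] /= area
            W[:, c] *= area
    return W, H


def weights_to_percentages(
    result: NMFResult,
    assignment: ComponentAssignment,
    X: SpectraMatrix,
    truth: Mapping[str, Mapping[str, float]] | None = None,
) -> AbundanceTable:
    """Convert mixture-row weighting factors into isomer percentages.

    Basis rows are first rescaled to unit window area (see
    `_rescale_to_unit_basis_area`); each mixture row's assigned weights are
    then normalized to sum to 100. When `truth` maps spectrum_id ->
    {isomer: percent}, truth and absolute error columns are attached.
    """
    W, _ = _rescale_to_unit_basis_area(result, X.bin_centers)
    records = []
    for row in X.mixture_rows:
        sid = X.row_labels[row]
        weights = {iso: W[row, c] for c, iso in assignment.mapping.items()}
        total = sum(weights.values())
        if total <= 0:
            raise ValueError(f"mixture row {sid!r} has zero total weight")
        for iso, w in weights.items():
            pct = 100.0 * w / total
            t = truth.get(sid, {}).get(iso) if truth else None
            records.append(
                {
                    "spectrum_id": sid,
                    "isomer": iso,
                    "percent": pct,
                    "truth_percent": np.nan if t is None else float(t),
                    "abs_error": np.nan if t is None else abs(pct - float(t)),
                }
            )
    return AbundanceTable(pd.DataFrame.from_records(records))


def nnls_fractions(
    mixture_row: np.ndarray, reference_rows: np.ndarray
) -> np.ndarray:
    """Non-negative least-squares fractions of a mixture onto references.

    Solves min ||mixture - f^T R||^2 subject to f >= 0 (active-set NNLS),
    then normalizes f to sum 1. This is the independent oracle against
    which the NMF quantification is validated.
    """
    R = np.asarray(reference_rows, dtype=float)
    b = np.asarray(mixture_row, dtype=float)
    if R.ndim != 2 or b.ndim != 1 or R.shape[1] != b.size:
        raise ValueError("shape mismatch between mixture and references")
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("degenerate references: rows not linearly independent")
    f, _ = _scipy_nnls(R.T, b)
    total = f.sum()
    if total <= 0:
        raise ValueError("NNLS produced an all-zero solution")
    return f / total


def deconvolve_mixtures(
    mixtures: Sequence[Spectrum],
    references: Sequence[tuple[str, Spectrum]],
    grid: WavenumberGrid,
    config: NMFConfig | None = None,
    truth: Mapping[str, Mapping[str, float]] | None = None,
    window: tuple[float, float] | None = None,
):
    """End-to-end deconvolution: matrix, NMF, assignment, percentages.

    Returns (SpectraMatrix, NMFResult, ComponentAssignment, AbundanceTable).
    """
    X = build_input_matrix(mixtures, references, grid, window)
    config = config or NMFConfig(n_components=len(references))
    result = nmf_factorize(X, config)
    assignment = assign_components(result, X)
    table = weights_to_percentages(result, assignment, X, truth)
    return X, result, assignment, table
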