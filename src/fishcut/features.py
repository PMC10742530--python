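"""Demarcation-line extraction, resampling and correlation-matrix PCA.

The ventral–dorsal demarcation line is the curve of per-frame maximum
heights above the belt along the fish — the ridge separating back from
belly, which carries the head-cut signal.  Lines of different fish have
different numbers of frames, so they are linearly resampled onto ``p``
equally spaced positions (default 60) before being stacked into a feature
matrix.  The matrix is Z-score standardized column-wise and reduced with
PCA on the correlation matrix; components are kept up to a cumulative
explained-variance target (default 95%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PointCloud
from .errors import DegenerateColumnError, InvalidArgumentError

__all__ = [
    "DemarcationLine",
    "PCAModel",
    "DEFAULT_FEATURE_LENGTH",
    "extract_demarcation_line",
    "resample_line",
    "build_feature_matrix",
    "standardize",
    "pca_fit",
    "pca_transform",
]

# Fixed feature length after resampling.  For correlation-matrix PCA the
# eigenvalue sum equals the number of variables, and the first-eigenvalue /
# variance-share ratio of the emulated study pins that number at 60.
DEFAULT_FEATURE_LENGTH = 60


@dataclass
class DemarcationLine:
    """Per-frame maximum height above belt vs conveyor position (both mm)."""

    x: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.x.size != self.h.size or self.x.size < 2:
            raise InvalidArgumentError("demarcation line needs >= 2 (x, h) pairs")
        if not np.all(np.diff(self.x) > 0):
            raise InvalidArgumentError("demarcation line x must be strictly increasing")
        if np.any(self.h < 0):
            raise InvalidArgumentError("demarcation heights must be >= 0")

    @property
    def n_points(self) -> int:
        return int(self.x.size)

    def __len__(self) -> int:
        return self.n_points


@dataclass
class PCAModel:
    """Standardization statistics + eigenstructure of the feature matrix.

    ``components`` holds the orthonormal loading vectors (columns, all ``p``
    of them); ``coefficient_matrix`` the selected columns scaled to
    ``P_i / sqrt(lambda_i)`` so scores have unit variance on the training
    set (the literal ``P_i / lambda_i`` convention is available through
    ``pca_fit(..., coefficient_scaling="lambda")``).
    """

    column_means: np.ndarray
    column_sds: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    n_selected: int
    coefficient_matrix: np.ndarray
    variance_target: float

    @property
    def p(self) -> int:
        return int(self.column_means.size)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def cumulative_variance(self, m: int | None = None) -> float:
        m = self.n_selected if m is None else m
        return float(self.explained_variance_ratio[:m].sum())


def extract_demarcation_line(cloud: PointCloud,
                             across_frame_filter=None) -> DemarcationLine:
    """Ridge of per-frame maxima: h[k] = max(frame k heights) − belt level.

    Uses each frame's own belt-level estimate when preprocessing recorded
    one (this also removes per-frame vibration offsets), falling back to the
    cloud-wide belt height.  Requires at least two usable frames.

    ``across_frame_filter`` optionally takes a :class:`FilterConfig` to run
    the same Kalman recursion along the ridge itself (across frames) — off
    by default, since the per-frame profiles are already filtered.
    """
    if cloud.belt_height is None and any(f.belt_level is None for f in cloud):
        raise InvalidArgumentError("no belt level available to reference heights")
    xs, hs = [], []
    for frame in cloud:
        if frame.n_points == 0:
            continue
        belt = frame.belt_level if frame.belt_level is not None else cloud.belt_height
        xs.append(frame.x)
        hs.append(max(float(np.max(frame.z)) - belt, 0.0))
    if len(xs) < 2:
        raise InvalidArgumentError(
            f"need >= 2 frames with fish points, got {len(xs)}"
        )
    hs = np.asarray(hs)
    if across_frame_filter is not None:
        from .preprocessing import kalman_filter

        hs = np.maximum(kalman_filter(hs, across_frame_filter), 0.0)
    return DemarcationLine(np.asarray(xs), hs)


def resample_line(line: DemarcationLine, p: int = DEFAULT_FEATURE_LENGTH) -> np.ndarray:
    """Linear interpolation of ``h`` onto ``p`` equally spaced positions.

    Targets span ``[min(x), max(x)]`` inclusive, so the endpoints are
    preserved exactly.
    """
    if p < 2:
        raise InvalidArgumentError("p must be >= 2")
    targets = np.linspace(line.x[0], line.x[-1], p)
    out = np.interp(targets, line.x, line.h)
    out[0] = line.h[0]
    out[-1] = line.h[-1]
    return out


def build_feature_matrix(lines: list[DemarcationLine],
                         p: int = DEFAULT_FEATURE_LENGTH) -> np.ndarray:
    """Stack resampled demarcation lines into an (n_samples, p) matrix."""
    if not lines:
        raise InvalidArgumentError("no demarcation lines given")
    return np.vstack([resample_line(line, p) for line in lines])


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise Z-score with sample (n−1) standard deviation.

    Returns ``(standardized, column_means, column_sds)``.  Raises
    :class:`DegenerateColumnError` naming the first zero-variance column.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise InvalidArgumentError("need a 2-D matrix with >= 2 rows")
    means = matrix.mean(axis=0)
    sds = matrix.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        raise DegenerateColumnError(f"column {int(bad[0])} has zero variance")
    return (matrix - means) / sds, means, sds


def pca_fit(matrix: np.ndarray, variance_target: float = 0.95,
            coefficient_scaling: str = "sqrt") -> PCAModel:
    """Correlation-matrix PCA of a feature matrix.

    The matrix is standardized internally; ``D = Z^T Z / (n-1)`` is the
    correlation matrix, whose eigenvalues (descending) sum to ``p``.  The
    number of retained components is the smallest ``m`` whose cumulative
    explained-variance fraction reaches ``variance_target``.  Loading signs
    are fixed by making each component's largest-magnitude entry positive.
    """
    if not 0 < variance_target <= 1:
        raise InvalidArgumentError("variance_target must be in (0, 1]")
    if coefficient_scaling not in ("sqrt", "lambda"):
        raise InvalidArgumentError("coefficient_scaling must be 'sqrt' or 'lambda'")
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise InvalidArgumentError("feature matrix contains non-finite entries")
    Z, means, sds = standardize(matrix)
    n = Z.shape[0]
    D = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(D)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(eigvecs.shape[1]):
        k = int(np.argmax(np.abs(eigvecs[:, j])))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    ratios = eigvals / eigvals.sum()
    cum = np.cumsum(ratios)
    n_selected = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_selected = min(n_selected, eigvals.size)

    lam_sel = np.clip(eigvals[:n_selected], 1e-12, None)
    if coefficient_scaling == "sqrt":
        coef = eigvecs[:, :n_selected] / np.sqrt(lam_sel)
    else:
        coef = eigvecs[:, :n_selected] / lam_sel
    return PCAModel(
        column_means=means,
        column_sds=sds,
        eigenvalues=eigvals,
        components=eigvecs,
        n_selected=n_selected,
        coefficient_matrix=coef,
        variance_target=variance_target,
    )


def pca_transform(model: PCAModel, matrix: np.ndarray,
                  n_components: int | None = None) -> np.ndarray:
    """Project (raw) feature rows onto the model's selected components.

    Rows are standardized with the model's stored means/sds first; scores of
    the training matrix therefore have zero mean per component.
    ``n_components`` can override the model's selection (capped at ``p``),
    e.g. to fix three components regardless of the variance rule.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] != model.p:
        raise InvalidArgumentError(
            f"feature dimension {matrix.shape[1]} != model p {model.p}"
        )
    Z = (matrix - model.column_means) / model.column_sds
    if n_components is None:
        return Z @ model.coefficient_matrix
    m = min(int(n_components), model.p)
    if m <= model.n_selected:
        return Z @ model.coefficient_matrix[:, :m]
    lam = np.clip(model.eigenvalues[:m], 1e-12, None)
    coef = model.components[:, :m] / np.sqrt(lam)
    return Z @ coef
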