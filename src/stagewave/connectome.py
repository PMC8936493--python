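"""Structural connectomes: loading, validation, thresholding, normalization, delays.

A connectome is a pair of symmetric non-negative matrices over ``R`` cortical
regions: fiber *weights* (density of streamlines between regions, entering the
model as the coupling matrix ``A``) and fiber *lengths* in millimetres, from
which inter-region transmission delays are derived as length / conduction
velocity. The tractography that produces such matrices is out of scope; this
module consumes plain-text matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "StructuralConnectome",
    "ConnectomeValidationError",
    "load_connectome",
    "write_connectome",
    "threshold_by_cv",
    "normalize_weights",
    "compute_delays",
    "desikan_killiany_labels",
]

_SYMMETRY_TOL = 1e-9


class ConnectomeValidationError(ValueError):
    """A connectivity matrix violates a structural invariant."""


@dataclass
class StructuralConnectome:
    """Weights, fiber lengths, delays and labels of an ``R``-region network.

    ``delays_s`` is all-zero until :func:`compute_delays` is applied.
    """

    region_labels: list[str]
    weights: np.ndarray
    lengths_mm: np.ndarray
    delays_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        if self.delays_s is None:
            self.delays_s = np.zeros_like(self.weights)
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        _validate_square_symmetric(self.weights, "weights")
        _validate_square_symmetric(self.lengths_mm, "lengths_mm")
        _validate_square_symmetric(self.delays_s, "delays_s")
        shapes = {self.weights.shape, self.lengths_mm.shape, self.delays_s.shape}
        if len(shapes) != 1:
            raise ConnectomeValidationError(
                f"matrix dimensions differ: {sorted(shapes)}"
            )
        if len(self.region_labels) != self.weights.shape[0]:
            raise ConnectomeValidationError(
                f"{len(self.region_labels)} labels for "
                f"{self.weights.shape[0]} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def _validate_square_symmetric(m: np.ndarray, name: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeValidationError(f"{name} is not square: shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ConnectomeValidationError(f"{name} contains non-finite entries")
    if np.any(m < 0):
        raise ConnectomeValidationError(f"{name} contains negative entries")
    if np.abs(m - m.T).max(initial=0.0) > _SYMMETRY_TOL:
        raise ConnectomeValidationError(f"{name} is asymmetric beyond tolerance")
    if np.any(np.diag(m) != 0):
        raise ConnectomeValidationError(f"{name} has a nonzero diagonal")


def _read_matrix(path: str | Path) -> np.ndarray:
    # whitespace-delimited square matrix, '#' comments allowed
    return np.loadtxt(path, comments="#", dtype=float, ndmin=2)


def load_connectome(
    weights_path: str | Path,
    lengths_path: str | Path,
    labels_path: str | Path | None = None,
) -> StructuralConnectome:
    """Read weights/lengths matrices (plain text) into a validated connectome.

    Delays are left at zero; call :func:`compute_delays` to fill them in.
    """
    weights = _read_matrix(weights_path)
    lengths = _read_matrix(lengths_path)
    if labels_path is not None:
        labels = [
            line.strip()
            for line in Path(labels_path).read_text().splitlines()
            if line.strip()
        ]
    else:
        labels = [f"region_{i:03d}" for i in range(weights.shape[0])]
    return StructuralConnectome(labels, weights, lengths)


def write_connectome(
    connectome: StructuralConnectome,
    weights_path: str | Path,
    lengths_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write matrices in the plain-text dialect read by :func:`load_connectome`.

    Uses ``%.17g`` so a load/write cycle round-trips float64 bit-identically.
    """
    np.savetxt(weights_path, connectome.weights, fmt="%.17g")
    np.savetxt(lengths_path, connectome.lengths_mm, fmt="%.17g")
    if labels_path is not None:
        Path(labels_path).write_text("\n".join(connectome.region_labels) + "\n")


def threshold_by_cv(weight_stack: np.ndarray, fraction: float) -> np.ndarray:
    """Average a stack of subject matrices, zeroing the least consistent links.

    The links (upper-triangle entries nonzero in at least one subject) are
    ranked by across-subject coefficient of variation (std/mean, population
    std); the top ``fraction`` of that pool is set to zero symmetrically in the
    across-subject mean. Ties are broken by stable sort on (CV descending,
    link index ascending), so the result is deterministic.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    stack = np.asarray(weight_stack, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError(f"expected S x R x R stack, got shape {stack.shape}")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 subjects to compute a CV")
    mean = stack.mean(axis=0)
    std = stack.std(axis=0)
    iu, ju = np.triu_indices(stack.shape[1], k=1)
    pool = mean[iu, ju] > 0  # links zero in every subject are excluded
    cv = np.zeros(iu.size)
    cv[pool] = std[iu, ju][pool] / mean[iu, ju][pool]
    pool_idx = np.flatnonzero(pool)
    n_cut = int(round(fraction * pool_idx.size))
    if n_cut > 0:
        order = np.argsort(-cv[pool_idx], kind="stable")
        cut = pool_idx[order[:n_cut]]
        mean[iu[cut], ju[cut]] = 0.0
        mean[ju[cut], iu[cut]] = 0.0
    return mean


def normalize_weights(connectome: StructuralConnectome) -> StructuralConnectome:
    """Scale weights so the mean over all R^2 entries equals one."""
    total = connectome.weights.sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero weight matrix")
    scale = connectome.weights.size / total
    return replace(connectome, weights=connectome.weights * scale)


def compute_delays(
    connectome: StructuralConnectome, velocity_m_per_s: float
) -> StructuralConnectome:
    """Fill in transmission delays: delay = fiber length / conduction velocity."""
    if velocity_m_per_s <= 0:
        raise ValueError(f"velocity must be positive, got {velocity_m_per_s}")
    delays = (connectome.lengths_mm / 1000.0) / velocity_m_per_s
    return replace(connectome, delays_s=delays)


def desikan_killiany_labels() -> list[str]:
    """The 68 cortical region labels of the Desikan-Killiany atlas (lh then rh)."""
    text = resources.files("stagewave").joinpath("data/dk_labels.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]
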