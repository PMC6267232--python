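"""Phase lag index connectivity and its RSN / global summaries.

The phase lag index of two phase series is::

    PLI = | mean_t sign( wrap(phi_i(t) - phi_j(t)) ) |

with differences wrapped into (-pi, pi].  Samples whose wrapped difference
is exactly 0 or pi carry sign 0, so strictly zero-lag (volume-conduction
like) coupling contributes nothing and the PLI of a channel with itself is
0.  Values lie in [0, 1]: 0 means no consistently-signed lag, 1 a perfectly
consistent nonzero lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ValidationError
from .io import AtlasDefinition
from .spectral import BandDefinition, PhaseEpoch

#: fraction of each epoch edge dropped from the PLI average to suppress
#: analytic-signal edge artefacts (each side)
EDGE_TRIM_FRACTION = 1.0 / 16.0


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Symmetric PLI matrix over ROIs, per epoch or epoch-averaged."""

    values: np.ndarray
    band: BandDefinition
    roi_labels: tuple[str, ...]
    level: str = "per-epoch"  # or "epoch-averaged"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"adjacency must be square, got {v.shape}")
        if len(self.roi_labels) != v.shape[0]:
            raise ValidationError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("diagonal must be exactly 0")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValidationError("PLI values must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


def wrap_phase(d: np.ndarray | float) -> np.ndarray:
    """Wrap phase differences into (-pi, pi]."""
    d = np.asarray(d, dtype=float)
    w = d - 2.0 * np.pi * np.floor((d + np.pi) / (2.0 * np.pi))  # [-pi, pi)
    return np.where(w == -np.pi, np.pi, w)


def pli_pair(phase_i: np.ndarray, phase_j: np.ndarray) -> float:
    """PLI of two equal-length phase vectors."""
    phase_i = np.asarray(phase_i, dtype=float)
    phase_j = np.asarray(phase_j, dtype=float)
    if phase_i.shape != phase_j.shape or phase_i.ndim != 1:
        raise ValidationError(
            f"phase vectors must be 1-D and equal length, got "
            f"{phase_i.shape} vs {phase_j.shape}"
        )
    if phase_i.size < 2:
        raise ValidationError("need at least 2 samples")
    d = wrap_phase(phase_i - phase_j)
    s = np.sign(d)
    s[np.abs(d) == np.pi] = 0.0
    return float(np.abs(s.mean()))


def _trim(phases: np.ndarray, edge_trim: bool) -> np.ndarray:
    if not edge_trim:
        return phases
    k = int(phases.shape[1] * EDGE_TRIM_FRACTION)
    return phases[:, k : phases.shape[1] - k] if k else phases


def pli_matrix(
    epoch: PhaseEpoch,
    roi_labels: tuple[str, ...] | None = None,
    edge_trim: bool = True,
) -> AdjacencyMatrix:
    """PLI for all unordered ROI pairs of one phase epoch."""
    phases = np.ascontiguousarray(epoch.phases, dtype=float)
    n = phases.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 ROIs")
    if roi_labels is None:
        roi_labels = tuple(f"roi{i}" for i in range(n))
    values = _kernels.pli_all(_trim(phases, edge_trim))
    return AdjacencyMatrix(
        values=values, band=epoch.band, roi_labels=roi_labels, level="per-epoch"
    )


def average_epochs(mats: list[AdjacencyMatrix]) -> AdjacencyMatrix:
    """Entrywise arithmetic mean of per-epoch matrices."""
    if not mats:
        raise ValidationError("need at least one matrix")
    first = mats[0]
    for m in mats[1:]:
        if m.roi_labels != first.roi_labels:
            raise ValidationError("epoch matrices have mismatched ROI labels")
        if m.band.name != first.band.name:
            raise ValidationError("epoch matrices have mismatched bands")
    mean = np.mean([m.values for m in mats], axis=0)
    return AdjacencyMatrix(
        values=mean, band=first.band, roi_labels=first.roi_labels,
        level="epoch-averaged",
    )


def rsn_mean(adj: AdjacencyMatrix, atlas: AtlasDefinition, rsn: str) -> float:
    """Mean PLI over unordered ROI pairs *within* one resting-state network."""
    if tuple(atlas.roi_labels) != adj.roi_labels:
        raise ValidationError("atlas labels do not match adjacency labels")
    idx = atlas.rsn_indices(rsn)
    if idx.size < 2:
        raise ValidationError(f"RSN {rsn!r} has fewer than 2 members")
    sub = adj.values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def global_mean(adj: AdjacencyMatrix) -> float:
    """Mean PLI over all unordered ROI pairs."""
    if adj.n_rois < 2:
        raise ValidationError("need at least 2 ROIs")
    iu = np.triu_indices(adj.n_rois, k=1)
    return float(adj.values[iu].mean())
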