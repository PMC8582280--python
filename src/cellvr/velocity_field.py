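"""RNA-velocity visualization fields.

Two display modes: per-cell arrows (tip = position + t * velocity) and, for
large datasets, a kernel-smoothed field on a regular 3-D lattice around the
embedding.  The latent-time scale t multiplies displacement linearly; the
packaged scene stores raw vectors plus a default t, never baked animation
frames, so the viewer can re-scale on the fly.

The grid estimator is a Gaussian-kernel weighted mean (Nadaraya–Watson):
for lattice point g, weights ``w_i = exp(-||c_i - g||^2 / (2 sigma^2))``
over cells c_i, mass ``m(g) = sum_i w_i`` and field
``V(g) = sum_i w_i v_i / m(g)``.  Lattice points with mass below a fraction
of the maximum are dropped so no arrows float in empty space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CellVRError
from .scene_model import GridField


@dataclass
class GridConfig:
    """Parameters of the lattice velocity-field estimator.

    resolution
        Lattice points per axis (r >= 2); the lattice is r x r x r.
    bandwidth
        Gaussian kernel sigma in scene units.  ``None`` (default) uses the
        mean lattice spacing, so smoothing adapts to the chosen resolution.
    min_mass_fraction
        Retain lattice points with mass >= this fraction of the maximum
        mass over the lattice.
    bbox_pad
        Bounding box expansion per side, as a fraction of each axis extent.
    """

    resolution: int = 8
    bandwidth: float | None = None
    min_mass_fraction: float = 0.01
    bbox_pad: float = 0.05

    def __post_init__(self) -> None:
        if self.resolution < 2:
            raise ValueError("grid resolution must be >= 2")
        if self.bandwidth is not None and not self.bandwidth > 0:
            raise ValueError("bandwidth must be > 0")
        if not (0.0 <= self.min_mass_fraction < 1.0):
            raise ValueError("min_mass_fraction must be in [0, 1)")
        if self.bbox_pad < 0:
            raise ValueError("bbox_pad must be >= 0")


def cell_arrows(positions: np.ndarray, vectors: np.ndarray,
                t: float) -> list[dict]:
    """Per-cell arrows: each cell's arrow runs from its position to
    ``position + t * vector``; arrow length is ``t * |vector|``.
    """
    if t < 0:
        raise ValueError("latent-time scale t must be >= 0")
    pos = np.asarray(positions, dtype=float)
    vec = np.asarray(vectors, dtype=float)
    if pos.shape != vec.shape:
        raise ValueError("positions and vectors must align")
    tips = pos + t * vec
    return [{"origin": o, "tip": p} for o, p in zip(pos, tips)]


def make_lattice(positions: np.ndarray, resolution: int,
                 bbox_pad: float) -> tuple[np.ndarray, float]:
    """Regular r x r x r lattice over the padded bounding box of positions.

    Returns the (r^3, 3) lattice points and the mean per-axis spacing
    (axes with zero extent are excluded from the mean; 1.0 if all extents
    are zero).
    """
    pos = np.asarray(positions, dtype=float)
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    extent = hi - lo
    lo = lo - bbox_pad * extent
    hi = hi + bbox_pad * extent
    axes = [np.linspace(lo[d], hi[d], resolution) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    spacing = (hi - lo) / (resolution - 1)
    pos_spacing = spacing[spacing > 0]
    mean_spacing = float(pos_spacing.mean()) if pos_spacing.size else 1.0
    return points, mean_spacing


def estimate_grid_field(positions: np.ndarray, vectors: np.ndarray,
                        config: GridConfig | None = None) -> GridField:
    """Kernel-smooth per-cell velocities onto a regular lattice.

    See the module docstring for the estimator.  Raises
    :class:`CellVRError` when every lattice point has zero mass (bandwidth
    pathologically small relative to the point spacing).
    """
    config = config or GridConfig()
    pos = np.asarray(positions, dtype=float)
    vec = np.asarray(vectors, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape != vec.shape:
        raise ValueError("positions and vectors must be aligned (n, 3) arrays")
    if pos.shape[0] == 0:
        raise ValueError("need at least one cell")

    r = config.resolution
    grid, spacing = make_lattice(pos, r, config.bbox_pad)
    sigma = config.bandwidth if config.bandwidth is not None else spacing
    if not sigma > 0:
        sigma = 1.0

    # (m, n) squared distances; m = r^3 lattice points, n cells.
    d2 = ((grid[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", over="ignore", under="ignore"):
        w = np.exp(-d2 / (2.0 * sigma * sigma))
    mass = w.sum(axis=1)
    max_mass = float(mass.max())
    if max_mass <= 0.0:
        raise CellVRError(
            "all grid masses are zero; increase the kernel bandwidth")
    min_mass = config.min_mass_fraction * max_mass
    keep = mass >= min_mass
    with np.errstate(invalid="ignore"):
        field = (w @ vec) / mass[:, None]
    return GridField(
        resolution=(r, r, r),
        points=grid[keep],
        vectors=field[keep],
        mass=mass[keep],
        min_mass=float(min_mass),
    )


def preview_arrow_scale(field: GridField, positions: np.ndarray,
                        bbox_pad: float = 0.05) -> float:
    """Display scale such that the longest grid arrow spans half a lattice
    spacing.  Metadata only — stored vectors stay unscaled."""
    _, spacing = make_lattice(positions, field.resolution[0], bbox_pad)
    norms = np.linalg.norm(np.asarray(field.vectors, dtype=float), axis=1)
    longest = float(norms.max()) if norms.size else 0.0
    if longest == 0.0:
        return 1.0
    return 0.5 * spacing / longest


def animate_displacement(field_or_arrows, t: float) -> np.ndarray:
    """Arrow tips displaced by latent time t (linear in t).

    Accepts a :class:`GridField` or the output of :func:`cell_arrows`.
    """
    if t < 0:
        raise ValueError("latent-time scale t must be >= 0")
    if isinstance(field_or_arrows, GridField):
        origins = np.asarray(field_or_arrows.points, dtype=float)
        vectors = np.asarray(field_or_arrows.vectors, dtype=float)
    else:
        origins = np.asarray([a["origin"] for a in field_or_arrows], float)
        tips = np.asarray([a["tip"] for a in field_or_arrows], float)
        vectors = tips - origins  # arrows built at t=1 carry raw vectors
    return origins + t * vectors
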