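"""Grid evaluation of fitted models and desirability on ternary and
process-plane slices, with long-form CSV export and optional rendering.

A *source* is anything exposing ``evaluate_batch(p80, us, blends)`` —
either a :class:`~mixproc.model.FitResult` (predicted response) or a
:class:`~mixproc.desirability.DesirabilityObjective` (global desirability).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .dataset import P80_DOMAIN, US_DOMAIN
from .errors import ArgumentError, DomainError

__all__ = ["TernaryGrid", "ProcessGrid", "ternary_slice", "process_slice"]


@dataclass(frozen=True)
class TernaryGrid:
    """Values over barycentric blend points at a fixed process setting."""

    setting: tuple[float, float]
    points: np.ndarray  # (n, 3) blend triples
    values: np.ndarray  # (n,)

    def to_csv(self, path_or_buffer) -> None:
        p80, us = self.setting
        rows = (
            (b[0], b[1], b[2], p80, us, v)
            for b, v in zip(self.points, self.values)
        )
        _write_long_csv(path_or_buffer, rows)


@dataclass(frozen=True)
class ProcessGrid:
    """Values over a p80 × ultrasound-time grid at a fixed blend."""

    blend: tuple[float, float, float]
    p80_values: np.ndarray
    us_values: np.ndarray
    values: np.ndarray  # (len(p80_values), len(us_values))

    def to_csv(self, path_or_buffer) -> None:
        cw, gb, gds = self.blend
        rows = (
            (cw, gb, gds, p, u, self.values[i, j])
            for i, p in enumerate(self.p80_values)
            for j, u in enumerate(self.us_values)
        )
        _write_long_csv(path_or_buffer, rows)


def _write_long_csv(path_or_buffer, rows) -> None:
    def write(fh):
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("cw", "gb", "gds", "p80_pct", "us_time_min", "value"))
        for row in rows:
            writer.writerow([repr(float(v)) for v in row])

    if hasattr(path_or_buffer, "write"):
        write(path_or_buffer)
    else:
        with open(path_or_buffer, "w", newline="", encoding="utf-8") as fh:
            write(fh)


def barycentric_points(resolution: int) -> np.ndarray:
    """All blend triples with denominator ``resolution`` (C(r+2, 2) points)."""
    if resolution < 2:
        raise ArgumentError(f"resolution must be >= 2, got {resolution}")
    r = resolution
    return np.array(
        [(i / r, j / r, (r - i - j) / r) for i in range(r + 1) for j in range(r + 1 - i)],
        dtype=float,
    )


def ternary_slice(source, setting: tuple[float, float], resolution: int) -> TernaryGrid:
    """Evaluate ``source`` on a barycentric grid at a fixed process setting."""
    p80, us = float(setting[0]), float(setting[1])
    if not (P80_DOMAIN[0] <= p80 <= P80_DOMAIN[1]):
        raise DomainError(f"p80 setting {p80} outside {P80_DOMAIN}")
    if not (US_DOMAIN[0] <= us <= US_DOMAIN[1]):
        raise DomainError(f"ultrasound setting {us} outside {US_DOMAIN}")
    points = barycentric_points(resolution)
    n = len(points)
    values = source.evaluate_batch(np.full(n, p80), np.full(n, us), points)
    return TernaryGrid(setting=(p80, us), points=points, values=np.asarray(values))


def process_slice(
    source, blend: tuple[float, float, float], resolution: int | tuple[int, int]
) -> ProcessGrid:
    """Evaluate ``source`` on a uniform p80 × time grid at a fixed blend."""
    blend = tuple(float(b) for b in blend)
    if len(blend) != 3 or any(b < 0 for b in blend) or abs(sum(blend) - 1.0) > 1e-9:
        raise ArgumentError(f"invalid blend {blend}: components must be >= 0 and sum to 1")
    res_p, res_u = (resolution, resolution) if isinstance(resolution, int) else resolution
    if res_p < 2 or res_u < 2:
        raise ArgumentError(f"resolution must be >= 2 per axis, got {(res_p, res_u)}")
    p80_values = np.linspace(P80_DOMAIN[0], P80_DOMAIN[1], res_p)
    us_values = np.linspace(US_DOMAIN[0], US_DOMAIN[1], res_u)
    P, U = np.meshgrid(p80_values, us_values, indexing="ij")
    blends = np.broadcast_to(np.asarray(blend), (P.size, 3))
    values = source.evaluate_batch(P.ravel(), U.ravel(), blends).reshape(P.shape)
    return ProcessGrid(
        blend=blend, p80_values=p80_values, us_values=us_values, values=values
    )


def render_ternary(grid: TernaryGrid, path, *, levels: int = 12, cmap: str = "viridis"):
    """Optional contour rendering of a ternary grid (CW top, GB left, GDS right)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cw, gb, gds = grid.points.T
    # planar embedding: GB lower-left, GDS lower-right, CW apex
    x = gds + cw / 2.0
    y = cw * np.sqrt(3.0) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4.5))
    tc = ax.tricontourf(x, y, grid.values, levels=levels, cmap=cmap)
    fig.colorbar(tc, ax=ax)
    ax.set_title(f"p80={grid.setting[0]:g}%, us={grid.setting[1]:g} min")
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def render_process(grid: ProcessGrid, path, *, levels: int = 12, cmap: str = "viridis"):
    """Optional contour rendering of a process-plane grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    P, U = np.meshgrid(grid.p80_values, grid.us_values, indexing="ij")
    tc = ax.contourf(P, U, grid.values, levels=levels, cmap=cmap)
    fig.colorbar(tc, ax=ax)
    ax.set_xlabel("% polysorbate 80 in surfactant couple")
    ax.set_ylabel("ultrasound time (min)")
    cw, gb, gds = grid.blend
    ax.set_title(f"blend cw={cw:g}, gb={gb:g}, gds={gds:g}")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
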