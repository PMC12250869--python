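"""Desirability transforms and multi-response optimization.

Each response is mapped onto [0, 1] by a piecewise-linear ramp (exponent 1):

``bilateral``
    0 at/below ``min`` and at/above ``max``, 1 at ``target``, linear between;
``left_unilateral``
    larger-is-better: 0 at/below ``min``, 1 at/above ``target``;
``right_unilateral``
    smaller-is-better: 1 at/below ``target``, 0 at/above ``max``.

The global desirability is the weighted geometric mean
``D = (prod d_i^w_i)^(1/sum w_i)``; it is 0 whenever any partial is 0.
"""

from __future__ import annotations

import itertools
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

from .dataset import P80_DOMAIN, US_DOMAIN, RunCondition
from .errors import ArgumentError
from .model import FitResult

__all__ = [
    "DesirabilitySpec",
    "OptimumResult",
    "DesirabilityObjective",
    "default_specs",
    "partial_desirability",
    "global_desirability",
    "optimize_desirability",
]

SHAPES = ("bilateral", "left_unilateral", "right_unilateral")


@dataclass(frozen=True)
class DesirabilitySpec:
    """Shape, anchors, and weight of one response's desirability ramp."""

    shape: str
    minimum: float | None = None
    maximum: float | None = None
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ArgumentError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if not self.weight > 0:
            raise ArgumentError(f"weight must be positive, got {self.weight}")
        if self.target is None:
            raise ArgumentError("target is required for every shape")
        if self.shape == "bilateral":
            if self.minimum is None or self.maximum is None:
                raise ArgumentError("bilateral requires min, target, and max")
            if not (self.minimum < self.target < self.maximum):
                raise ArgumentError("bilateral requires min < target < max")
        elif self.shape == "left_unilateral":
            if self.minimum is None or not (self.minimum < self.target):
                raise ArgumentError("left_unilateral requires min < target")
        else:  # right_unilateral
            if self.maximum is None or not (self.target < self.maximum):
                raise ArgumentError("right_unilateral requires target < max")

    def to_dict(self) -> dict:
        d = {"shape": self.shape, "target": float(self.target), "weight": float(self.weight)}
        if self.minimum is not None:
            d["min"] = float(self.minimum)
        if self.maximum is not None:
            d["max"] = float(self.maximum)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesirabilitySpec":
        known = {"shape", "min", "max", "target", "weight"}
        extra = set(d) - known
        if extra:
            raise ArgumentError(f"unknown desirability keys: {sorted(extra)}")
        return cls(
            shape=d.get("shape"),
            minimum=d.get("min"),
            maximum=d.get("max"),
            target=d.get("target"),
            weight=d.get("weight", 1.0),
        )


def default_specs() -> dict[str, DesirabilitySpec]:
    """The study's three response specifications (unit weights)."""
    return {
        "ps_nm": DesirabilitySpec("bilateral", minimum=50.0, maximum=200.0, target=100.0),
        "pdi": DesirabilitySpec("right_unilateral", maximum=0.4, target=0.0),
        "zp_abs_mv": DesirabilitySpec("left_unilateral", minimum=25.0, target=40.0),
    }


def partial_desirability(y, spec: DesirabilitySpec):
    """Piecewise-linear ramp of one response onto [0, 1]; vectorized over ``y``."""
    y = np.asarray(y, dtype=float)
    if spec.shape == "bilateral":
        lo, t, hi = spec.minimum, spec.target, spec.maximum
        up = (y - lo) / (t - lo)
        down = (hi - y) / (hi - t)
        d = np.where(y <= t, up, down)
        d = np.clip(d, 0.0, 1.0)
    elif spec.shape == "left_unilateral":
        lo, t = spec.minimum, spec.target
        d = np.clip((y - lo) / (t - lo), 0.0, 1.0)
    else:  # right_unilateral
        t, hi = spec.target, spec.maximum
        d = np.clip((hi - y) / (hi - t), 0.0, 1.0)
    return d if d.ndim else float(d)


def global_desirability(ds, ws):
    """Weighted geometric mean of partial desirabilities.

    ``ds`` may be a 1-D vector (one point) or a 2-D array with one row per
    point and one column per response.
    """
    ds = np.asarray(ds, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if ds.shape[-1] != ws.shape[0]:
        raise ArgumentError(
            f"{ds.shape[-1]} desirabilities but {ws.shape[0]} weights"
        )
    if np.any(ws <= 0):
        raise ArgumentError("weights must be positive")
    if np.any((ds < 0) | (ds > 1)):
        raise ArgumentError("partial desirabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        logs = np.where(ds > 0, np.log(np.where(ds > 0, ds, 1.0)), -np.inf)
    out = np.exp((logs * ws).sum(axis=-1) / ws.sum())
    out = np.where(np.any(ds == 0, axis=-1), 0.0, out)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class OptimumResult:
    """Argmax of the global desirability with its diagnostics."""

    condition: RunCondition
    global_d: float
    partial_ds: dict[str, float]
    predicted: dict[str, float]
    feasible: bool = True


class DesirabilityObjective:
    """Global desirability as a function of the run condition.

    Wraps per-response fits and their desirability specs; response order is
    the order of the ``fits`` mapping.
    """

    def __init__(
        self,
        fits: Mapping[str, FitResult],
        specs: Mapping[str, DesirabilitySpec],
    ) -> None:
        missing = set(fits) - set(specs)
        if missing:
            raise ArgumentError(f"no desirability spec for responses: {sorted(missing)}")
        self.responses = tuple(fits)
        self.fits = dict(fits)
        self.specs = {r: specs[r] for r in self.responses}
        self.weights = np.array([self.specs[r].weight for r in self.responses])

    def predict_batch(self, p80, us, blends) -> dict[str, np.ndarray]:
        return {
            r: self.fits[r].evaluate_batch(p80, us, blends) for r in self.responses
        }

    def evaluate_batch(self, p80, us, blends) -> np.ndarray:
        """Global desirability on parallel condition arrays."""
        preds = self.predict_batch(p80, us, blends)
        ds = np.stack(
            [partial_desirability(preds[r], self.specs[r]) for r in self.responses],
            axis=-1,
        )
        return global_desirability(ds, self.weights)

    def at_condition(self, condition: RunCondition) -> OptimumResult:
        p80 = np.array([condition.p80_pct])
        us = np.array([condition.us_time_min])
        blends = np.array([condition.blend])
        preds = self.predict_batch(p80, us, blends)
        partial = {
            r: float(partial_desirability(preds[r][0], self.specs[r]))
            for r in self.responses
        }
        d = float(
            global_desirability(np.array([list(partial.values())]), self.weights)[0]
        )
        return OptimumResult(
            condition=condition,
            global_d=d,
            partial_ds=partial,
            predicted={r: float(preds[r][0]) for r in self.responses},
            feasible=d > 0.0,
        )


def _barycentric_grid(q: int) -> np.ndarray:
    pts = [
        (i / q, j / q, (q - i - j) / q)
        for i in range(q + 1)
        for j in range(q + 1 - i)
    ]
    return np.array(pts, dtype=float)


def optimize_desirability(
    fits: Mapping[str, FitResult],
    specs: Mapping[str, DesirabilitySpec],
    seed: int = 0,
    grid_step: float = 0.01,
    n_starts: int = 10,
    refine_tol: float = 1e-4,
    _blend_chunk: int = 32,
) -> OptimumResult:
    """Maximize global desirability over the simplex × process box.

    A dense scan (barycentric step ``grid_step`` on the simplex, the same
    relative step on each process axis) seeds a multi-start local refinement
    by simplex-projected coordinate descent from the ``n_starts`` best grid
    cells.  Deterministic given ``seed`` and ``grid_step``.  When the whole
    domain scores 0 the best grid point is returned flagged infeasible.
    """
    if not (0.0 < grid_step <= 0.25):
        raise ArgumentError(f"grid_step must lie in (0, 0.25], got {grid_step}")
    objective = DesirabilityObjective(fits, specs)
    rng = np.random.default_rng(seed)

    q = max(2, round(1.0 / grid_step))
    blends = _barycentric_grid(q)
    p80_axis = np.linspace(P80_DOMAIN[0], P80_DOMAIN[1], q + 1)
    us_axis = np.linspace(US_DOMAIN[0], US_DOMAIN[1], q + 1)
    P, U = np.meshgrid(p80_axis, us_axis, indexing="ij")
    p_flat, u_flat = P.ravel(), U.ravel()
    n_proc = len(p_flat)

    # Chunked dense scan, keeping the n_starts best cells overall.
    top_scores = np.full(n_starts, -1.0)
    top_points = np.zeros((n_starts, 5))
    for lo in range(0, len(blends), _blend_chunk):
        chunk = blends[lo : lo + _blend_chunk]
        nb = len(chunk)
        b_rep = np.repeat(chunk, n_proc, axis=0)
        p_rep = np.tile(p_flat, nb)
        u_rep = np.tile(u_flat, nb)
        d = objective.evaluate_batch(p_rep, u_rep, b_rep)
        k = min(n_starts, len(d))
        idx = np.argpartition(d, -k)[-k:]
        scores = np.concatenate([top_scores, d[idx]])
        points = np.vstack(
            [top_points, np.column_stack([p_rep[idx], u_rep[idx], b_rep[idx]])]
        )
        keep = np.argsort(scores)[-n_starts:]
        top_scores, top_points = scores[keep], points[keep]

    order = np.argsort(top_scores)[::-1]
    starts = top_points[order]
    best_score = float(top_scores[order[0]])
    best_point = starts[0]

    # Multi-start refinement; the rng only breaks exact ties between starts.
    tie_break = rng.permutation(len(starts))
    for rank, start in enumerate(starts):
        if top_scores[order[rank]] < 0:
            continue
        point, score = _coordinate_descent(objective, start, grid_step, refine_tol)
        if score > best_score or (
            score == best_score and tie_break[rank] < tie_break[0] and rank > 0
        ):
            best_score, best_point = score, point

    condition = RunCondition(
        p80_pct=float(np.clip(best_point[0], *P80_DOMAIN)),
        us_time_min=float(np.clip(best_point[1], *US_DOMAIN)),
        blend=tuple(_project_simplex(best_point[2:])),
    )
    result = objective.at_condition(condition)
    if result.global_d <= 0.0:
        return OptimumResult(
            condition=result.condition,
            global_d=result.global_d,
            partial_ds=result.partial_ds,
            predicted=result.predicted,
            feasible=False,
        )
    return result


def _project_simplex(b: np.ndarray) -> np.ndarray:
    b = np.maximum(np.asarray(b, float), 0.0)
    s = b.sum()
    return b / s if s > 0 else np.array([1 / 3, 1 / 3, 1 / 3])


def _eval_point(objective: DesirabilityObjective, point: np.ndarray) -> float:
    p = np.clip(point[0], *P80_DOMAIN)
    u = np.clip(point[1], *US_DOMAIN)
    b = _project_simplex(point[2:])
    return float(
        objective.evaluate_batch(np.array([p]), np.array([u]), b[None, :])[0]
    )


def _coordinate_descent(
    objective: DesirabilityObjective,
    start: np.ndarray,
    grid_step: float,
    tol: float,
) -> tuple[np.ndarray, float]:
    """Step-halving coordinate descent; blends move by pairwise transfers."""
    point = np.array(start, dtype=float)
    score = _eval_point(objective, point)
    step_p = grid_step * (P80_DOMAIN[1] - P80_DOMAIN[0])
    step_u = grid_step * (US_DOMAIN[1] - US_DOMAIN[0])
    step_b = grid_step
    pairs = list(itertools.permutations(range(3), 2))
    while max(step_p / 100.0, step_u / 9.0, step_b) > tol:
        improved = True
        while improved:
            improved = False
            moves = []
            for delta in (step_p, -step_p):
                cand = point.copy()
                cand[0] = np.clip(cand[0] + delta, *P80_DOMAIN)
                moves.append(cand)
            for delta in (step_u, -step_u):
                cand = point.copy()
                cand[1] = np.clip(cand[1] + delta, *US_DOMAIN)
                moves.append(cand)
            for i, j in pairs:
                cand = point.copy()
                shift = min(step_b, cand[2 + i])
                if shift <= 0:
                    continue
                cand[2 + i] -= shift
                cand[2 + j] += shift
                moves.append(cand)
            for cand in moves:
                s = _eval_point(objective, cand)
                if s > score:
                    point, score = cand, s
                    improved = True
        step_p /= 2.0
        step_u /= 2.0
        step_b /= 2.0
    point[0] = np.clip(point[0], *P80_DOMAIN)
    point[1] = np.clip(point[1], *US_DOMAIN)
    point[2:] = _project_simplex(point[2:])
    return point, score
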