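"""Design construction: simplex-centroid blends, factorial process grids,
model-matrix expansion, and D-optimal subset selection by point exchange.

Process factors are coded to [-1, 1] before any monomial is evaluated;
mixture proportions enter the model raw.  The three built-in model forms are

``process_quadratic``
    intercept + linear + quadratic + interaction in the two coded process
    factors (6 terms),
``scheffe_reduced_cubic``
    linear + binary-blend + ternary-blend terms in the three mixture
    proportions, no intercept (7 terms),
``multiplicative_deg3``
    the crossed form: every mixture monomial, plus mixture monomials
    multiplied by process monomials up to total process degree 2, truncated
    to overall degree 3 (28 terms, no intercept — the mixture sum-to-one
    constraint absorbs it).
"""

from __future__ import annotations


import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .dataset import P80_DOMAIN, US_DOMAIN, RunCondition
from .errors import ArgumentError, DomainError, FittingError

__all__ = [
    "Term",
    "ModelSpec",
    "Design",
    "MODEL_NAMES",
    "simplex_centroid_points",
    "process_grid",
    "cross_design",
    "code_process",
    "model_matrix",
    "matrix_from_arrays",
    "d_optimal_exchange",
    "log_det_information",
]

FACTORS = ("x1", "x2", "x3", "x4", "x5")
MIXTURE_FACTORS = ("x3", "x4", "x5")

#: A monomial: tuple of (factor, exponent) pairs, e.g. (("x1", 2), ("x3", 1)).
Term = tuple[tuple[str, int], ...]


def _term(*factors: str | tuple[str, int]) -> Term:
    exps: dict[str, int] = {}
    for f in factors:
        name, e = f if isinstance(f, tuple) else (f, 1)
        exps[name] = exps.get(name, 0) + e
    return tuple(sorted(exps.items()))


def term_label(term: Term) -> str:
    """Human-readable monomial label, ``1`` for the empty (intercept) term."""
    if not term:
        return "1"
    return "*".join(f if e == 1 else f"{f}^{e}" for f, e in term)


@dataclass(frozen=True)
class ModelSpec:
    """An ordered list of monomials over the coded/raw factors."""

    name: str
    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        for t in self.terms:
            for f, e in t:
                if f not in FACTORS:
                    raise ArgumentError(f"unknown factor {f!r} in term {t}")
                if e < 1:
                    raise ArgumentError(f"exponent must be >= 1 in term {t}")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(term_label(t) for t in self.terms)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        try:
            return _BUILTIN_SPECS[name]
        except KeyError:
            raise ArgumentError(
                f"unknown model {name!r}; expected one of {sorted(_BUILTIN_SPECS)}"
            ) from None


def _process_quadratic() -> ModelSpec:
    terms = (
        _term(),
        _term("x1"),
        _term("x2"),
        _term(("x1", 2)),
        _term(("x2", 2)),
        _term("x1", "x2"),
    )
    return ModelSpec("process_quadratic", terms)


def _scheffe_reduced_cubic() -> ModelSpec:
    terms = (
        _term("x3"),
        _term("x4"),
        _term("x5"),
        _term("x3", "x4"),
        _term("x3", "x5"),
        _term("x4", "x5"),
        _term("x3", "x4", "x5"),
    )
    return ModelSpec("scheffe_reduced_cubic", terms)


def _multiplicative_deg3() -> ModelSpec:
    # Column order follows the coefficient listing of the crossed model:
    # pure mixture block, then x1-, x2-, x1^2-, x2^2-, and x1*x2-crossed blocks.
    mix_lin = [_term("x3"), _term("x4"), _term("x5")]
    mix_bin = [_term("x3", "x4"), _term("x3", "x5"), _term("x4", "x5")]
    terms: list[Term] = []
    terms += mix_lin + mix_bin + [_term("x3", "x4", "x5")]
    for p in ("x1", "x2"):
        terms += [_term(p, *[f for f, _ in m]) for m in mix_lin]
        terms += [_term(p, *[f for f, _ in m]) for m in mix_bin]
    for p in ("x1", "x2"):
        terms += [_term((p, 2), *[f for f, _ in m]) for m in mix_lin]
    terms += [_term("x1", "x2", *[f for f, _ in m]) for m in mix_lin]
    return ModelSpec("multiplicative_deg3", tuple(terms))


_BUILTIN_SPECS = {
    s.name: s
    for s in (_process_quadratic(), _scheffe_reduced_cubic(), _multiplicative_deg3())
}
MODEL_NAMES = tuple(sorted(_BUILTIN_SPECS))


@dataclass(frozen=True)
class Design:
    """An ordered collection of run conditions with provenance metadata."""

    runs: tuple[RunCondition, ...]
    provenance: str = "full_cross"
    seed: int | None = None
    log_det: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "runs", tuple(self.runs))
        if self.provenance not in ("full_cross", "d_optimal"):
            raise ArgumentError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.runs)

    def __iter__(self):
        return iter(self.runs)


# --------------------------------------------------------------- candidates


def simplex_centroid_points() -> tuple[tuple[float, float, float], ...]:
    """The 7 simplex-centroid blends: vertices, 50/50 binaries, centroid."""
    third = 1.0 / 3.0
    return (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
        (0.5, 0.5, 0.0),
        (0.5, 0.0, 0.5),
        (0.0, 0.5, 0.5),
        (third, third, third),
    )


def process_grid(
    p80_levels: Sequence[float], us_levels: Sequence[float]
) -> tuple[tuple[float, float], ...]:
    """Full Cartesian product of process-factor levels, lexicographic order."""
    for v in p80_levels:
        if not (P80_DOMAIN[0] <= v <= P80_DOMAIN[1]):
            raise DomainError(f"p80 level {v} outside {P80_DOMAIN}")
    for v in us_levels:
        if not (US_DOMAIN[0] <= v <= US_DOMAIN[1]):
            raise DomainError(f"ultrasound level {v} outside {US_DOMAIN}")
    return tuple(
        (float(p), float(u)) for p in sorted(p80_levels) for u in sorted(us_levels)
    )


def cross_design(
    blends: Sequence[tuple[float, float, float]],
    settings: Sequence[tuple[float, float]],
) -> Design:
    """Cross every blend with every process setting (settings vary slowest)."""
    if not blends or not settings:
        raise ArgumentError("blends and settings must both be nonempty")
    runs = tuple(
        RunCondition(p80_pct=p, us_time_min=u, blend=tuple(b))
        for (p, u) in settings
        for b in blends
    )
    return Design(runs=runs, provenance="full_cross")


# ------------------------------------------------------------------- coding


def code_process(
    p80_pct: float, us_time_min: float, *, allow_extrapolation: bool = False
) -> tuple[float, float]:
    """Affine coding of the process factors onto [-1, 1]^2.

    Domain midpoints map to 0 and endpoints to +/-1:
    ``x1 = (p80 - 50) / 50``, ``x2 = (us - 5.5) / 4.5``.
    """
    if not allow_extrapolation:
        if not (P80_DOMAIN[0] <= p80_pct <= P80_DOMAIN[1]):
            raise DomainError(f"p80_pct {p80_pct} outside {P80_DOMAIN}")
        if not (US_DOMAIN[0] <= us_time_min <= US_DOMAIN[1]):
            raise DomainError(f"us_time_min {us_time_min} outside {US_DOMAIN}")
    x1 = (p80_pct - 50.0) / 50.0
    x2 = (us_time_min - 5.5) / 4.5
    return (x1, x2)


# ------------------------------------------------------------- model matrix


def matrix_from_arrays(
    x1: np.ndarray,
    x2: np.ndarray,
    x3: np.ndarray,
    x4: np.ndarray,
    x5: np.ndarray,
    spec: ModelSpec,
) -> np.ndarray:
    """Evaluate the spec's monomials on already-coded factor arrays."""
    x1 = np.asarray(x1, dtype=float)
    values = {"x1": x1, "x2": np.asarray(x2, float), "x3": np.asarray(x3, float),
              "x4": np.asarray(x4, float), "x5": np.asarray(x5, float)}
    cols = []
    for term in spec.terms:
        col = np.ones_like(x1)
        for f, e in term:
            col = col * values[f] ** e
        cols.append(col)
    return np.column_stack(cols)


def model_matrix(runs: Sequence[RunCondition], spec: ModelSpec) -> np.ndarray:
    """Model matrix with one row per run and one column per spec term.

    Process factors are coded to [-1, 1] before evaluation; mixture
    proportions are used raw.
    """
    runs = list(runs)
    coded = np.array([code_process(r.p80_pct, r.us_time_min) for r in runs], float)
    blend = np.array([r.blend for r in runs], float)
    if not runs:
        return np.empty((0, len(spec.terms)))
    return matrix_from_arrays(
        coded[:, 0], coded[:, 1], blend[:, 0], blend[:, 1], blend[:, 2], spec
    )


# -------------------------------------------------------- D-optimal exchange

_REL_IMPROVEMENT = 1e-10  # log-det gain required to accept a swap
_MAX_START_DRAWS = 100


def log_det_information(X: np.ndarray) -> float:
    """log det(X'X); -inf when singular."""
    sign, logdet = np.linalg.slogdet(X.T @ X)
    return logdet if sign > 0 else -math.inf


def d_optimal_exchange(
    candidates: Sequence[RunCondition],
    spec: ModelSpec,
    n_runs: int,
    seed: int = 0,
    max_iter: int = 100,
) -> Design:
    """Select an ``n_runs``-subset of candidates maximizing det(X'X).

    Greedy Fedorov-style point exchange: starting from a seeded random
    full-rank subset, repeatedly perform the first swap (design point for an
    out-of-design candidate, scanned in candidate order) that improves
    log det(X'X) by a relative margin; stop at a fixed point or after
    ``max_iter`` full passes.  The returned design's log-det never falls
    below the starting subset's.
    """
    candidates = list(candidates)
    m = len(candidates)
    p = len(spec.terms)
    if n_runs < p:
        raise ArgumentError(f"n_runs ({n_runs}) must be >= the term count ({p})")
    if n_runs > m:
        raise ArgumentError(f"n_runs ({n_runs}) exceeds the candidate count ({m})")
    F = model_matrix(candidates, spec)
    if np.linalg.matrix_rank(F) < p:
        raise FittingError(
            f"candidate set is rank-deficient for model {spec.name!r}; "
            "the model cannot be fitted on any subset"
        )
    if n_runs == m:
        return Design(
            runs=tuple(candidates),
            provenance="d_optimal",
            seed=seed,
            log_det=log_det_information(F),
        )

    rng = np.random.default_rng(seed)
    subset: np.ndarray | None = None
    for _ in range(_MAX_START_DRAWS):
        trial = rng.choice(m, size=n_runs, replace=False)
        if np.linalg.matrix_rank(F[trial]) == p:
            subset = np.sort(trial)
            break
    if subset is None:
        raise FittingError(
            f"no full-rank starting subset of size {n_runs} found in "
            f"{_MAX_START_DRAWS} seeded draws"
        )

    current = log_det_information(F[subset])
    in_design = np.zeros(m, dtype=bool)
    in_design[subset] = True
    for _ in range(max_iter):
        improved = False
        for pos in range(n_runs):
            for j in range(m):
                if in_design[j]:
                    continue
                old = subset[pos]
                subset[pos] = j
                trial_ld = log_det_information(F[subset])
                if trial_ld > current + _REL_IMPROVEMENT * max(1.0, abs(current)):
                    in_design[old] = False
                    in_design[j] = True
                    current = trial_ld
                    improved = True
                    break
                subset[pos] = old
            if improved:
                break
        if not improved:
            break

    order = np.sort(subset)
    return Design(
        runs=tuple(candidates[i] for i in order),
        provenance="d_optimal",
        seed=seed,
        log_det=current,
    )
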