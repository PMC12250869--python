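"""Study dataset: run conditions, response records, CSV I/O, and a seeded simulator.

The packaged fixture holds the 66 formulation runs (63 distinct design points
plus 3 replicates) with particle size (nm), polydispersity index, and zeta
potential stored as a magnitude in mV.  Replicate run ids carry a trailing
``r`` in files (``51r``); :attr:`ResponseRecord.display_id` renders the prime
form (``51′``).
"""

from __future__ import annotations

import csv
import hashlib
import io
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ArgumentError, DataError, DomainError, FixtureError

__all__ = [
    "RESPONSES",
    "CSV_COLUMNS",
    "P80_DOMAIN",
    "US_DOMAIN",
    "BLEND_TOL",
    "RunCondition",
    "ResponseRecord",
    "StudyDataset",
    "load_study_dataset",
    "simulate_responses",
]

#: Response column names, in canonical order.
RESPONSES = ("ps_nm", "pdi", "zp_abs_mv")

#: Column order of the CSV dialect used everywhere in the package.
CSV_COLUMNS = (
    "run_id",
    "p80_pct",
    "us_time_min",
    "cw",
    "gb",
    "gds",
    "ps_nm",
    "pdi",
    "zp_abs_mv",
)

P80_DOMAIN = (0.0, 100.0)
US_DOMAIN = (1.0, 10.0)
BLEND_TOL = 1e-9

_FIXTURE_CSV = "sln_runs.csv"
_FIXTURE_SHA256 = "sln_runs.sha256"


@dataclass(frozen=True)
class RunCondition:
    """One experimental setting: two process factors plus a lipid blend.

    Parameters
    ----------
    p80_pct
        Percentage of polysorbate 80 in the surfactant couple, 0-100.
    us_time_min
        Ultrasound treatment time in minutes, 1-10.
    blend
        Proportions ``(cw, gb, gds)`` of the three lipids; each in [0, 1]
        and summing to 1 within ``BLEND_TOL``.
    """

    p80_pct: float
    us_time_min: float
    blend: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "p80_pct", float(self.p80_pct))
        object.__setattr__(self, "us_time_min", float(self.us_time_min))
        object.__setattr__(self, "blend", tuple(float(b) for b in self.blend))
        if not (P80_DOMAIN[0] <= self.p80_pct <= P80_DOMAIN[1]):
            raise DomainError(f"p80_pct {self.p80_pct} outside {P80_DOMAIN}")
        if not (US_DOMAIN[0] <= self.us_time_min <= US_DOMAIN[1]):
            raise DomainError(f"us_time_min {self.us_time_min} outside {US_DOMAIN}")
        if len(self.blend) != 3:
            raise ArgumentError("blend must have exactly three components")
        if any(b < -BLEND_TOL for b in self.blend):
            raise ArgumentError(f"blend components must be nonnegative: {self.blend}")
        if abs(sum(self.blend) - 1.0) > BLEND_TOL:
            raise ArgumentError(f"blend must sum to 1 within {BLEND_TOL}: {self.blend}")

    @property
    def cw(self) -> float:
        return self.blend[0]

    @property
    def gb(self) -> float:
        return self.blend[1]

    @property
    def gds(self) -> float:
        return self.blend[2]


@dataclass(frozen=True)
class ResponseRecord:
    """A run condition with its (possibly missing) measured responses."""

    run_id: str
    condition: RunCondition
    ps_nm: float | None = None
    pdi: float | None = None
    zp_abs_mv: float | None = None

    def __post_init__(self) -> None:
        if self.ps_nm is not None and not self.ps_nm > 0:
            raise ArgumentError(f"ps_nm must be positive, got {self.ps_nm}")
        if self.pdi is not None and self.pdi < 0:
            raise ArgumentError(f"pdi must be nonnegative, got {self.pdi}")
        if self.zp_abs_mv is not None and self.zp_abs_mv < 0:
            raise ArgumentError(
                f"zp_abs_mv is a magnitude and must be nonnegative, got {self.zp_abs_mv}"
            )

    @property
    def display_id(self) -> str:
        """Run id with replicate marker rendered as a prime (``51r`` -> ``51′``)."""
        if self.run_id.endswith("r"):
            return self.run_id[:-1] + "′"
        return self.run_id

    def response(self, name: str) -> float | None:
        if name not in RESPONSES:
            raise ArgumentError(f"unknown response {name!r}; expected one of {RESPONSES}")
        return getattr(self, name)


@dataclass(frozen=True)
class StudyDataset:
    """An ordered collection of :class:`ResponseRecord`."""

    records: tuple[ResponseRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ResponseRecord]:
        return iter(self.records)

    def get(self, run_id: str) -> ResponseRecord:
        for rec in self.records:
            if rec.run_id == run_id:
                return rec
        raise KeyError(run_id)

    def conditions(self) -> tuple[RunCondition, ...]:
        return tuple(rec.condition for rec in self.records)

    def response_values(self, name: str) -> np.ndarray:
        """Response column as a float array with NaN for missing values."""
        if name not in RESPONSES:
            raise ArgumentError(f"unknown response {name!r}; expected one of {RESPONSES}")
        return np.array(
            [np.nan if rec.response(name) is None else rec.response(name) for rec in self],
            dtype=float,
        )

    def replicate_groups(self) -> list[list[ResponseRecord]]:
        """Groups of two or more records sharing an identical condition."""
        groups: dict[RunCondition, list[ResponseRecord]] = {}
        for rec in self.records:
            groups.setdefault(rec.condition, []).append(rec)
        return [g for g in groups.values() if len(g) >= 2]

    def drop_replicates(self) -> "StudyDataset":
        """Keep only the first record observed for each distinct condition."""
        seen: set[RunCondition] = set()
        kept = []
        for rec in self.records:
            if rec.condition in seen:
                continue
            seen.add(rec.condition)
            kept.append(rec)
        return StudyDataset(tuple(kept))

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path_or_buffer) -> None:
        """Write the module CSV dialect (header ``run_id,p80_pct,...``)."""
        if hasattr(path_or_buffer, "write"):
            _write_csv(self, path_or_buffer)
        else:
            with open(path_or_buffer, "w", newline="", encoding="utf-8") as fh:
                _write_csv(self, fh)

    @classmethod
    def from_csv(cls, path_or_buffer) -> "StudyDataset":
        if hasattr(path_or_buffer, "read"):
            return _read_csv(path_or_buffer)
        with open(path_or_buffer, newline="", encoding="utf-8") as fh:
            return _read_csv(fh)


def _fmt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def _write_csv(dataset: StudyDataset, fh) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for rec in dataset:
        c = rec.condition
        writer.writerow(
            [rec.run_id, _fmt(c.p80_pct), _fmt(c.us_time_min)]
            + [_fmt(b) for b in c.blend]
            + [_fmt(rec.ps_nm), _fmt(rec.pdi), _fmt(rec.zp_abs_mv)]
        )


def _read_csv(fh) -> StudyDataset:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise DataError("empty CSV input") from None
    if tuple(h.strip() for h in header) != CSV_COLUMNS:
        raise DataError(f"unexpected CSV header {header!r}; expected {list(CSV_COLUMNS)}")
    records = []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not cell.strip() for cell in row):
            continue
        if len(row) != len(CSV_COLUMNS):
            raise DataError(f"line {lineno}: expected {len(CSV_COLUMNS)} fields, got {len(row)}")
        try:
            condition = RunCondition(
                p80_pct=float(row[1]),
                us_time_min=float(row[2]),
                blend=(float(row[3]), float(row[4]), float(row[5])),
            )
            responses = {
                name: (float(cell) if cell.strip() else None)
                for name, cell in zip(RESPONSES, row[6:9])
            }
        except (ValueError, ArgumentError) as exc:
            raise DataError(f"line {lineno}: {exc}") from exc
        records.append(ResponseRecord(run_id=row[0], condition=condition, **responses))
    return StudyDataset(tuple(records))


def load_study_dataset() -> StudyDataset:
    """Load the packaged 66-run fixture, verifying its checksum.

    Raises
    ------
    FixtureError
        If the packaged CSV does not match its recorded SHA-256 digest.
    """
    pkg = resources.files("mixproc") / "data"
    raw = (pkg / _FIXTURE_CSV).read_bytes()
    expected = (pkg / _FIXTURE_SHA256).read_text().strip()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise FixtureError(
            f"packaged dataset checksum mismatch: expected {expected}, got {digest}"
        )
    dataset = StudyDataset.from_csv(io.StringIO(raw.decode("utf-8")))
    if len(dataset) != 66:
        raise FixtureError(f"packaged dataset has {len(dataset)} records, expected 66")
    return dataset


def simulate_responses(
    design: Sequence[RunCondition],
    spec,
    true_coeffs: Mapping[str, Iterable[float]],
    noise_sd: float | Mapping[str, float],
    seed: int,
) -> StudyDataset:
    """Generate synthetic responses ``X @ beta + Gaussian(0, sd)`` for a design.

    Parameters
    ----------
    design
        Run conditions to simulate at.
    spec
        A :class:`~mixproc.design.ModelSpec`; its model matrix defines the
        noise-free response surface.
    true_coeffs
        Mapping from response name (a subset of :data:`RESPONSES`) to a
        coefficient vector of length ``len(spec.terms)``.
    noise_sd
        Gaussian noise standard deviation; a scalar applies to every
        response, a mapping sets it per response.
    seed
        Seed for :func:`numpy.random.default_rng`; identical seeds give
        identical datasets.
    """
    from .design import model_matrix  # local import: avoids a module cycle

    if not true_coeffs:
        raise ArgumentError("true_coeffs must name at least one response")
    sds: dict[str, float] = {}
    for name in true_coeffs:
        if name not in RESPONSES:
            raise ArgumentError(f"unknown response {name!r}; expected one of {RESPONSES}")
        sd = float(noise_sd[name] if isinstance(noise_sd, Mapping) else noise_sd)
        if sd < 0:
            raise ArgumentError(f"noise_sd for {name!r} must be nonnegative, got {sd}")
        sds[name] = sd

    X = model_matrix(design, spec)
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    for name in RESPONSES:  # fixed order so the rng stream is reproducible
        if name not in true_coeffs:
            continue
        beta = np.asarray(list(true_coeffs[name]), dtype=float)
        if beta.shape != (X.shape[1],):
            raise ArgumentError(
                f"true_coeffs[{name!r}] has length {beta.size}, spec has {X.shape[1]} terms"
            )
        y = X @ beta
        if sds[name] > 0:
            y = y + rng.normal(0.0, sds[name], size=len(y))
        if name == "ps_nm":
            y = np.maximum(y, np.finfo(float).tiny)  # records require ps_nm > 0
        elif name in ("pdi", "zp_abs_mv"):
            y = np.maximum(y, 0.0)
        columns[name] = y

    records = []
    for i, cond in enumerate(design):
        values = {name: float(col[i]) for name, col in columns.items()}
        records.append(ResponseRecord(run_id=str(i + 1), condition=cond, **values))
    return StudyDataset(tuple(records))
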