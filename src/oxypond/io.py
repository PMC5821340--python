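"""Tabular I/O, canonical data model, train/test split and feature scaling.

The sample table follows the field-survey schema
``Time, X (m), Y (m), Z (m), Dissolved oxygen (mg/L)``: one row per probe
reading, where ``Time`` is either a clock time (``H:MM`` or ``H:MM:SS``)
or a plain number of minutes, ``x`` runs along the pond length, ``y``
along the width, and ``z`` is depth in metres measured downward from the
surface.  Clock times are converted to minutes since the earliest time in
the file, which makes the time feature commensurable with the spatial
coordinates once everything is min-max scaled.

The train/test split is strictly positional (first ``n_train`` rows),
mirroring the fixed survey protocol: no shuffling, ever.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    ParseError,
    SchemaError,
    ValidationError,
)

SAMPLE_COLUMNS = ("t", "x", "y", "z", "do")

#: canonical sample header as written by :func:`write_samples`
SAMPLE_HEADER = ("Time", "X (m)", "Y (m)", "Z (m)", "Dissolved oxygen (mg/L)")

METEO_FIELDS = (
    "timestamp",
    "rainfall",
    "wind_speed",
    "wind_direction",
    "solar_radiation",
    "air_temperature",
    "relative_humidity",
    "atmos_pressure",
)


@dataclass(frozen=True)
class Sample:
    """One probe reading: time (minutes), position (m), DO (mg/L)."""

    t: float
    x: float
    y: float
    z: float
    do: float

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "z", "do"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"Sample field {name!r} is not finite: {v}")
        if self.do < 0:
            raise ValidationError(f"dissolved oxygen must be >= 0, got {self.do}")
        if self.z < 0:
            raise ValidationError(f"depth must be >= 0, got {self.z}")


class SampleSet:
    """An ordered collection of samples; order is part of the contract.

    Internally a pandas DataFrame with columns ``t, x, y, z, do``.  The
    positional order is preserved exactly as read because the train/test
    split is positional.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = ""):
        missing = [c for c in SAMPLE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"SampleSet frame missing columns: {missing}")
        if len(frame) < 1:
            raise EmptyInputError("a SampleSet must contain at least one sample")
        self._frame = frame.loc[:, list(SAMPLE_COLUMNS)].reset_index(drop=True).astype(float)
        if not np.isfinite(self._frame.to_numpy()).all():
            raise ValidationError("SampleSet contains non-finite values")
        if (self._frame["do"] < 0).any():
            raise ValidationError("SampleSet contains negative dissolved oxygen")
        if (self._frame["z"] < 0).any():
            raise ValidationError("SampleSet contains negative depth")
        self.provenance = provenance

    # -- construction -------------------------------------------------
    @classmethod
    def from_samples(cls, samples: Sequence[Sample], provenance: str = "") -> "SampleSet":
        frame = pd.DataFrame([dataclasses.asdict(s) for s in samples])
        return cls(frame, provenance)

    @classmethod
    def from_arrays(cls, t, x, y, z, do, provenance: str = "") -> "SampleSet":
        frame = pd.DataFrame({"t": t, "x": x, "y": y, "z": z, "do": do})
        return cls(frame, provenance)

    # -- access --------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def X(self) -> np.ndarray:
        """(n, 4) matrix of raw features (t, x, y, z)."""
        return self._frame[["t", "x", "y", "z"]].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """(n,) vector of dissolved-oxygen targets in mg/L."""
        return self._frame["do"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[Sample]:
        for row in self._frame.itertuples(index=False):
            yield Sample(t=row.t, x=row.x, y=row.y, z=row.z, do=row.do)

    def __getitem__(self, i: int) -> Sample:
        row = self._frame.iloc[i]
        return Sample(t=row["t"], x=row["x"], y=row["y"], z=row["z"], do=row["do"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleSet):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        return f"SampleSet(n={len(self)}, provenance={self.provenance!r})"


# ---------------------------------------------------------------------
# header matching


def _norm_header(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


_SAMPLE_HEADER_PREFIXES = {
    "t": ("time",),
    "x": ("x",),
    "y": ("y",),
    "z": ("z", "depth"),
    "do": ("dissolvedoxygen", "do"),
}

_METEO_HEADER_PREFIXES = {
    "timestamp": ("time",),
    "rainfall": ("rainfall", "rain"),
    "wind_speed": ("windspeed",),
    "wind_direction": ("winddirection",),
    "solar_radiation": ("solarradiation",),
    "air_temperature": ("airtemperature",),
    "relative_humidity": ("relativehumidity", "airhumidity", "humidity"),
    "atmos_pressure": ("atmospressure", "atmosphericpressure", "pressure"),
}


def _match_columns(columns, prefixes, what: str) -> dict:
    mapping = {}
    used = set()
    for canon, prefs in prefixes.items():
        hit = None
        for col in columns:
            if col in used:
                continue
            n = _norm_header(col)
            if any(n.startswith(p) for p in prefs):
                hit = col
                break
        if hit is None:
            raise SchemaError(f"{what}: missing required column {canon!r} "
                              f"(header was {list(columns)})")
        mapping[canon] = hit
        used.add(hit)
    return mapping


# ---------------------------------------------------------------------
# time parsing

_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):(\d{2})(?::(\d{2}))?\s*$")


def _parse_time_cell(value, row: int) -> tuple[float, bool]:
    """Return (minutes, is_clock). Clock times are minutes since midnight."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if not math.isfinite(float(value)):
            raise ParseError(f"row {row}: non-finite time value {value!r}")
        return float(value), False
    s = str(value)
    m = _CLOCK_RE.match(s)
    if m:
        h, mi, se = int(m.group(1)), int(m.group(2)), int(m.group(3) or 0)
        return 60.0 * h + mi + se / 60.0, True
    try:
        return float(s), False
    except ValueError:
        raise ParseError(f"row {row}: cannot parse time cell {value!r}") from None


def _to_float(value, row: int, col: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ParseError(f"row {row}: non-numeric value {value!r} in column {col!r}") from None
    if not math.isfinite(v):
        raise ParseError(f"row {row}: non-finite value in column {col!r}")
    return v


# ---------------------------------------------------------------------
# readers / writers


def _read_raw_table(path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "xlsx":
        # first worksheet only, header in row 1
        return pd.read_excel(path, sheet_name=0, header=0)
    return pd.read_csv(path, header=0, skipinitialspace=True)


def read_samples(path, dialect: str | None = None) -> SampleSet:
    """Read a sample table (CSV or XLSX) into a :class:`SampleSet`.

    Clock times are converted to minutes elapsed since the earliest time
    in the file; numeric times are taken as minutes verbatim.  Row order
    is preserved.
    """
    raw = _read_raw_table(path, dialect)
    mapping = _match_columns(raw.columns, _SAMPLE_HEADER_PREFIXES, "sample table")
    raw = raw.dropna(how="all")
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    times, clock_flags = [], []
    for i, v in enumerate(raw[mapping["t"]], start=2):
        minutes, is_clock = _parse_time_cell(v, i)
        times.append(minutes)
        clock_flags.append(is_clock)
    t = np.asarray(times, dtype=float)
    if any(clock_flags):
        t = t - t.min()  # minutes since window start

    data = {"t": t}
    for canon in ("x", "y", "z", "do"):
        col = mapping[canon]
        data[canon] = [_to_float(v, i, col) for i, v in enumerate(raw[col], start=2)]
    return SampleSet(pd.DataFrame(data), provenance=str(path))


def write_samples(data: SampleSet, path) -> None:
    """Write a SampleSet as CSV with the canonical survey header.

    Time is written numerically (minutes since window start) so that
    ``read_samples(write_samples(s)) == s`` cell for cell.
    """
    out = data.frame.copy()
    out.columns = list(SAMPLE_HEADER)
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class MeteoRecord:
    """One weather-station record accompanying a sampling window."""

    timestamp: pd.Timestamp
    rainfall: float
    wind_speed: float
    wind_direction: float
    solar_radiation: float
    air_temperature: float
    relative_humidity: float
    atmos_pressure: float

    def __post_init__(self) -> None:
        if not 0 <= self.wind_direction < 360:
            raise ValidationError(
                f"wind_direction must lie in [0, 360), got {self.wind_direction}")
        if not 0 <= self.relative_humidity <= 100:
            raise ValidationError(
                f"relative_humidity must lie in [0, 100], got {self.relative_humidity}")


def read_meteo(path) -> list[MeteoRecord]:
    """Read a meteorological CSV into validated records, file order kept."""
    raw = _read_raw_table(path, "csv")
    mapping = _match_columns(raw.columns, _METEO_HEADER_PREFIXES, "meteo table")
    raw = raw.dropna(how="all")
    if len(raw) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    records = []
    for i, (_, row) in enumerate(raw.iterrows(), start=2):
        try:
            ts = pd.Timestamp(row[mapping["timestamp"]])
        except (ValueError, TypeError):
            raise ParseError(f"row {i}: cannot parse timestamp "
                             f"{row[mapping['timestamp']]!r}") from None
        kwargs = {"timestamp": ts}
        for canon in METEO_FIELDS[1:]:
            kwargs[canon] = _to_float(row[mapping[canon]], i, canon)
        records.append(MeteoRecord(**kwargs))
    return records


# ---------------------------------------------------------------------
# split


def split_train_test(data: SampleSet, n_train: int) -> tuple[SampleSet, SampleSet]:
    """Positional split: first ``n_train`` rows train, the rest test."""
    if not 1 <= n_train < len(data):
        raise ValueError(
            f"n_train must satisfy 1 <= n_train < {len(data)}, got {n_train}")
    train = SampleSet(data.frame.iloc[:n_train], provenance=f"{data.provenance}[:{n_train}]")
    test = SampleSet(data.frame.iloc[n_train:], provenance=f"{data.provenance}[{n_train}:]")
    return train, test


# ---------------------------------------------------------------------
# normalization


@dataclass
class Normalizer:
    """Per-feature min-max scaling of (t, x, y, z) fitted on training data.

    Features with fewer than two distinct values keep scale 1 (mapped to a
    constant 0) and are flagged rather than failing.
    """

    offset: np.ndarray
    scale: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=bool))
    method: str = "min-max"

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if (self.scale <= 0).any():
            raise ValidationError("Normalizer scales must be > 0")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("cannot normalize non-finite coordinates")
        return (X - self.offset) / self.scale

    def inverse(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        return U * self.scale + self.offset

    # persistence (used by the RBF model file)
    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "offset": self.offset.tolist(),
            "scale": self.scale.tolist(),
            "degenerate": self.degenerate.astype(int).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            offset=np.asarray(d["offset"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
            method=d.get("method", "min-max"),
        )

    @classmethod
    def identity(cls, dim: int = 4) -> "Normalizer":
        """No-op scaling, for computing in raw units."""
        return cls(offset=np.zeros(dim), scale=np.ones(dim), method="identity")


def fit_normalizer(data: SampleSet) -> Normalizer:
    """Fit min-max scaling of the four features on (training) data."""
    X = data.X
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    scale = hi - lo
    degenerate = scale <= 0
    scale = np.where(degenerate, 1.0, scale)
    return Normalizer(offset=lo, scale=scale, degenerate=degenerate)
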