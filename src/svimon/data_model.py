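"""Domain types and I/O for activated-sludge plant records.

A plant record is a daily time series of the sludge volume index (SVI,
mL/g) together with eight operating covariates: dissolved oxygen, COD,
influent flow, solids retention time, MLSS, settled-volume fractions in
the oxidation ditch and the recycle line, and temperature.  This module
provides the validated container (:class:`ProcessSeries`), RFC-4180 CSV
round-trip, the lag embedding used by the autoregressive multi-step
model, and the column standardizer shared by the GP fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical covariate column names, in fixed order (units in docstring above).
COVARIATE_NAMES: tuple[str, ...] = (
    "do",
    "cod",
    "qin",
    "srt",
    "mlss",
    "sv_od",
    "sv_recycle",
    "temperature",
)

#: All canonical CSV columns.
CANONICAL_COLUMNS: tuple[str, ...] = ("t", "svi") + COVARIATE_NAMES


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class SviMonError(Exception):
    """Base class for all package errors."""


class SchemaError(SviMonError):
    """A required column is missing or the schema map is inconsistent."""


class ParseError(SviMonError):
    """A cell could not be parsed as a number."""


class ValidationError(SviMonError):
    """A domain invariant is violated (ordering, sign, duplicates...)."""


class SizeError(SviMonError):
    """An input is too short for the requested operation."""


class DegenerateScaleError(SviMonError):
    """A column has zero variance and cannot be standardized."""


class FitError(SviMonError):
    """Model fitting failed on every attempt."""


class NumericalError(SviMonError):
    """A linear-algebra step failed beyond recoverable jitter."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcessSample:
    """One daily observation: day index, SVI and named covariates.

    Covariates may be missing (NaN).  ``t`` is a 0-based integer day
    index; calendar dates are mapped to indices at load time.
    """

    t: int
    svi: float
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svi < 0:
            raise ValidationError(f"svi must be non-negative, got {self.svi}")
        unknown = set(self.covariates) - set(COVARIATE_NAMES)
        if unknown:
            raise ValidationError(f"unknown covariate names: {sorted(unknown)}")


class ProcessSeries:
    """Time-ordered plant record backed by a :class:`pandas.DataFrame`.

    The frame always has columns ``t`` (strictly increasing ints) and
    ``svi``, plus any subset of :data:`COVARIATE_NAMES`.  Missing
    covariate values are NaN.
    """

    def __init__(self, frame: pd.DataFrame, sampling_interval: int = 1):
        frame = frame.copy()
        if "t" not in frame.columns or "svi" not in frame.columns:
            raise SchemaError("ProcessSeries frame needs 't' and 'svi' columns")
        extra = set(frame.columns) - set(CANONICAL_COLUMNS)
        if extra:
            raise SchemaError(f"unknown columns: {sorted(extra)}")
        if len(frame) < 1:
            raise ValidationError("series must contain at least one sample")
        frame = frame.sort_values("t").reset_index(drop=True)
        t = frame["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            dup = int(t[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise ValidationError(f"time indices must be strictly increasing (at t={dup})")
        if (frame["svi"].to_numpy() < 0).any():
            raise ValidationError("svi values must be non-negative")
        if sampling_interval < 1:
            raise ValidationError("sampling_interval must be a positive integer")
        # canonical column order
        cols = [c for c in CANONICAL_COLUMNS if c in frame.columns]
        self.frame = frame[cols]
        self.sampling_interval = int(sampling_interval)

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __getitem__(self, i: int) -> ProcessSample:
        row = self.frame.iloc[i]
        cov = {c: float(row[c]) for c in self.covariate_names}
        return ProcessSample(t=int(row["t"]), svi=float(row["svi"]), covariates=cov)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProcessSeries):
            return NotImplemented
        return (
            self.sampling_interval == other.sampling_interval
            and self.frame.columns.tolist() == other.frame.columns.tolist()
            and self.frame.equals(other.frame)
        )

    # -- accessors ---------------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.frame["t"].to_numpy(dtype=int)

    @property
    def svi(self) -> np.ndarray:
        return self.frame["svi"].to_numpy(dtype=float)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c for c in COVARIATE_NAMES if c in self.frame.columns)

    def covariate_matrix(
        self,
        names: Sequence[str] | None = None,
        forward_fill: bool = False,
    ) -> np.ndarray:
        """Return an (n, k) matrix of the requested covariates.

        Missing values are a hard error unless ``forward_fill`` is set,
        in which case gaps are filled from the most recent observation.
        """
        names = tuple(names) if names is not None else self.covariate_names
        missing_cols = [c for c in names if c not in self.frame.columns]
        if missing_cols:
            raise SchemaError(f"covariates not present in series: {missing_cols}")
        block = self.frame[list(names)]
        if block.isna().any().any():
            if not forward_fill:
                bad = [c for c in names if block[c].isna().any()]
                raise ValidationError(
                    f"missing covariate values in columns {bad}; "
                    "pass forward_fill=True to impute"
                )
            block = block.ffill()
            if block.isna().any().any():
                raise ValidationError("leading missing values cannot be forward-filled")
        return block.to_numpy(dtype=float)

    def slice(self, start: int, stop: int) -> "ProcessSeries":
        """Positional sub-series (like list slicing, end-exclusive)."""
        return ProcessSeries(self.frame.iloc[start:stop], self.sampling_interval)

    @classmethod
    def from_arrays(
        cls,
        svi: Sequence[float],
        covariates: Mapping[str, Sequence[float]] | None = None,
        t: Sequence[int] | None = None,
        sampling_interval: int = 1,
    ) -> "ProcessSeries":
        n = len(svi)
        data: dict = {"t": np.arange(n) if t is None else np.asarray(t, dtype=int)}
        data["svi"] = np.asarray(svi, dtype=float)
        for name, vals in (covariates or {}).items():
            data[name] = np.asarray(vals, dtype=float)
        return cls(pd.DataFrame(data), sampling_interval)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def read_series(path, schema: Mapping[str, str] | None = None) -> ProcessSeries:
    """Read a plant record from CSV.

    ``schema`` maps file headers onto the canonical names in
    :data:`CANONICAL_COLUMNS` (e.g. ``{"SVI (mL/g)": "svi"}``).  A ``t``
    column of calendar dates is converted to 0-based day indices; an
    absent ``t`` column is generated from row order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        df = df.rename(columns=dict(schema))
    df = df[[c for c in df.columns if c in CANONICAL_COLUMNS]]
    if "svi" not in df.columns:
        raise SchemaError("required column 'svi' not found (after schema mapping)")
    if "t" in df.columns and not pd.api.types.is_numeric_dtype(df["t"]):
        dates = pd.to_datetime(df["t"], errors="coerce")
        if dates.isna().any():
            row = int(dates.index[dates.isna()][0])
            raise ParseError(f"cannot parse 't' as date or number at row {row}")
        df["t"] = (dates - dates.min()).dt.days
    if "t" not in df.columns:
        df.insert(0, "t", np.arange(len(df)))
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(df.index[bad][0])
                raise ParseError(f"non-numeric value in column '{col}' at row {row}")
            df[col] = coerced
    if df["t"].duplicated().any():
        dup = int(df["t"][df["t"].duplicated()].iloc[0])
        raise ValidationError(f"duplicate timestamp t={dup}")
    return ProcessSeries(df)


def write_series(series: ProcessSeries, path) -> None:
    """Write an RFC-4180 CSV with header at full (repr) precision.

    Missing covariates become empty cells; ``read_series`` restores the
    identical series bit-for-bit.
    """
    series.frame.to_csv(path, index=False, lineterminator="\r\n")


# ---------------------------------------------------------------------------
# Lag embedding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LagDesign:
    """Autoregressive design: rows pair a lag window with the next value.

    Each input row is ``[y(t), y(t-1), ..., y(t-n_lags)]`` (most recent
    first) and the target is ``y(t+1)``; with a series of length ``n``
    there are ``n - n_lags - 1`` rows.
    """

    n_lags: int
    X: np.ndarray  # (rows, n_lags + 1)
    y: np.ndarray  # (rows,)

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.y), self.n_lags + 1):
            raise ValidationError("lag design shape mismatch")


def make_lag_design(values, n_lags: int) -> LagDesign:
    """Build the lag embedding of a 1-D series (or a ProcessSeries' SVI)."""
    if isinstance(values, ProcessSeries):
        values = values.svi
    v = np.asarray(values, dtype=float)
    if n_lags < 0:
        raise ValidationError("n_lags must be >= 0")
    n = len(v)
    if n < n_lags + 2:
        raise SizeError(
            f"series of length {n} too short for n_lags={n_lags}; "
            f"need at least {n_lags + 2}"
        )
    rows = n - n_lags - 1
    X = np.empty((rows, n_lags + 1))
    for j in range(n_lags + 1):
        # column j holds y(t - j); t runs from n_lags to n-2
        X[:, j] = v[n_lags - j : n - 1 - j]
    y = v[n_lags + 1 :]
    return LagDesign(n_lags=n_lags, X=X, y=y.copy())


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

class Standardizer:
    """Per-column z-scoring learned from training rows.

    ``transform`` maps each column to mean 0 / unit variance on the
    fitted rows; ``inverse_transform`` is its exact inverse.  Variances
    are also mapped (a variance scales by ``scale**2``).
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, rows: np.ndarray) -> "Standardizer":
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.ndim != 2 or rows.shape[0] < 2:
            raise SizeError("need at least 2 rows to fit a standardizer")
        self.mean_ = rows.mean(axis=0)
        self.scale_ = rows.std(axis=0, ddof=0)
        if np.any(self.scale_ <= 0):
            col = int(np.flatnonzero(self.scale_ <= 0)[0])
            raise DegenerateScaleError(f"column {col} is constant; cannot standardize")
        return self

    def _check(self) -> None:
        if self.mean_ is None:
            raise ValidationError("standardizer is not fitted")

    def transform(self, rows: np.ndarray) -> np.ndarray:
        self._check()
        return (np.asarray(rows, dtype=float) - self.mean_) / self.scale_

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(rows, dtype=float) * self.scale_ + self.mean_

    def transform_variance(self, var: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(var, dtype=float) / self.scale_**2

    def inverse_transform_variance(self, var: np.ndarray) -> np.ndarray:
        self._check()
        return np.asarray(var, dtype=float) * self.scale_**2

    def to_dict(self) -> dict:
        self._check()
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Standardizer":
        s = cls()
        s.mean_ = np.asarray(d["mean"], dtype=float)
        s.scale_ = np.asarray(d["scale"], dtype=float)
        return s


def fit_standardizer(rows: np.ndarray) -> Standardizer:
    """Convenience wrapper: fit and return a :class:`Standardizer`."""
    return Standardizer().fit(rows)
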