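"""Spectra containers, file I/O and pre-model preprocessing.

A reflectance spectrum is a vector of values in (0, 1] on a regular
wavelength grid (350-2500 nm at 1 nm by default, matching a field
spectroradiometer with three internal detectors).  Two preprocessing steps
are applied before any modelling:

* replicate averaging — each leaf is scanned several times on the same spot
  and the scans are averaged;
* splice correction — the instrument's detectors meet at fixed wavelengths
  and leave small artificial steps there; later segments are additively
  shifted so the spectrum is continuous across each boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    FormatError,
    GridMismatchError,
    SpectraValidationError,
)

logger = logging.getLogger(__name__)

#: Admissible leaf states for a spectrum.
STATES = ("fresh", "dried", "treated", "rescanned")

#: Lower clip bound applied after splice correction so log/absorbance
#: transforms downstream stay defined.
MIN_REFLECTANCE = 1e-6

_META_COLUMNS = ["sample_id", "replicate", "state", "group"]


@dataclass(frozen=True)
class SpectralGrid:
    """Regular wavelength grid with detector splice points.

    Parameters
    ----------
    start_nm, end_nm, step_nm
        Arithmetic grid ``start, start+step, ..., end`` (inclusive).
    splice_points_nm
        Wavelengths of the detector boundaries, strictly increasing and
        strictly inside ``(start_nm, end_nm)``.  Defaults are the
        conventional boundaries of a three-detector VNIR/SWIR instrument.
    """

    start_nm: float = 350.0
    end_nm: float = 2500.0
    step_nm: float = 1.0
    splice_points_nm: tuple[float, ...] = (1000.0, 1800.0)

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ConfigurationError("grid start must be below grid end")
        if self.step_nm <= 0:
            raise ConfigurationError("grid step must be positive")
        span = self.end_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"grid span {span} is not a multiple of step {self.step_nm}"
            )
        sp = tuple(float(s) for s in self.splice_points_nm)
        if any(not (self.start_nm < s < self.end_nm) for s in sp):
            raise ConfigurationError("splice points must lie strictly inside the grid")
        if any(b <= a for a, b in zip(sp, sp[1:])):
            raise ConfigurationError("splice points must be strictly increasing")
        object.__setattr__(self, "splice_points_nm", sp)

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points)

    def index_of(self, wavelength_nm: float) -> int:
        """Index of a wavelength on the grid; raises if off-grid."""
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        if not (0 <= pos <= self.n_points - 1) or abs(pos - round(pos)) > 1e-9:
            raise ConfigurationError(f"wavelength {wavelength_nm} nm is not on the grid")
        return int(round(pos))


@dataclass(frozen=True)
class Spectrum:
    """A single scan of one leaf in one state."""

    sample_id: str
    replicate: int
    state: str
    values: np.ndarray
    group: str | None = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise SpectraValidationError(
                f"state {self.state!r} not one of {STATES}"
            )
        if self.replicate < 1:
            raise SpectraValidationError("replicate must be >= 1")
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        _check_reflectance(v, f"spectrum {self.sample_id}/{self.state}/r{self.replicate}")


def _check_reflectance(v: np.ndarray, label: str) -> None:
    if not np.all(np.isfinite(v)):
        raise SpectraValidationError(f"{label}: non-finite reflectance")
    if np.any(v <= 0) or np.any(v > 1):
        bad = float(v[(v <= 0) | (v > 1)][0])
        raise SpectraValidationError(
            f"{label}: reflectance {bad} outside (0, 1]"
        )


class SpectraSet:
    """Aligned collection of spectra sharing one grid.

    Internally a metadata frame (``sample_id, replicate, state, group``) plus
    an ``(n_spectra, n_wavelengths)`` reflectance matrix; one row per
    ``(sample_id, replicate, state)``, which must be unique.
    """

    def __init__(self, grid: SpectralGrid, meta: pd.DataFrame, values: np.ndarray):
        meta = meta.reset_index(drop=True)[_META_COLUMNS].copy()
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != len(meta):
            raise GridMismatchError("meta and values are not row-aligned")
        if values.shape[1] != grid.n_points:
            raise GridMismatchError(
                f"{values.shape[1]} columns do not match grid length {grid.n_points}"
            )
        bad_state = set(meta["state"]) - set(STATES)
        if bad_state:
            raise SpectraValidationError(f"unknown states {sorted(bad_state)}")
        key = meta[["sample_id", "replicate", "state"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise SpectraValidationError(
                f"duplicate spectrum key {tuple(dup)}"
            )
        _check_reflectance(values, "SpectraSet")
        self.grid = grid
        self.meta = meta
        self.values = values

    # -- construction -----------------------------------------------------
    @classmethod
    def from_spectra(cls, grid: SpectralGrid, spectra: Iterable[Spectrum]) -> "SpectraSet":
        spectra = list(spectra)
        meta = pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in spectra],
                "replicate": [s.replicate for s in spectra],
                "state": [s.state for s in spectra],
                "group": [s.group for s in spectra],
            }
        )
        values = np.vstack([s.values for s in spectra]) if spectra else np.empty((0, grid.n_points))
        return cls(grid, meta, values)

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.meta)

    def equals(self, other: "SpectraSet") -> bool:
        return (
            self.grid == other.grid
            and self.meta.fillna("").equals(other.meta.fillna(""))
            and np.array_equal(self.values, other.values)
        )

    # -- views ------------------------------------------------------------
    def matrix(self) -> pd.DataFrame:
        """Reflectance as a DataFrame with float wavelength columns."""
        return pd.DataFrame(self.values, columns=self.grid.wavelengths())

    def select(self, mask: np.ndarray) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(self.grid, self.meta[mask], self.values[mask])

    def for_state(self, state: str) -> "SpectraSet":
        return self.select((self.meta["state"] == state).to_numpy())

    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.meta["sample_id"]))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _format_wavelength(w: float) -> str:
    return str(int(w)) if float(w).is_integer() else repr(float(w))


def write_spectra(s: SpectraSet, path: str | Path, layout: str = "wide") -> None:
    """Write a SpectraSet as CSV in ``wide`` or ``long`` layout."""
    path = Path(path)
    if layout == "wide":
        wl_cols = [_format_wavelength(w) for w in s.grid.wavelengths()]
        df = pd.concat(
            [s.meta, pd.DataFrame(s.values, columns=wl_cols)], axis=1
        )
        df.to_csv(path, index=False, float_format="%.17g")
    elif layout == "long":
        wl = s.grid.wavelengths()
        n, p = s.values.shape
        long = pd.DataFrame(
            {
                "sample_id": np.repeat(s.meta["sample_id"].to_numpy(), p),
                "replicate": np.repeat(s.meta["replicate"].to_numpy(), p),
                "state": np.repeat(s.meta["state"].to_numpy(), p),
                "group": np.repeat(s.meta["group"].to_numpy(), p),
                "wavelength_nm": np.tile(wl, n),
                "reflectance": s.values.ravel(),
            }
        )
        long.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")


def read_spectra(
    path: str | Path,
    layout: str = "wide",
    splice_points_nm: Sequence[float] = (1000.0, 1800.0),
) -> SpectraSet:
    """Read a spectra CSV written in ``wide`` or ``long`` layout.

    The wavelength grid is inferred from the file and must be arithmetic;
    ``splice_points_nm`` annotates the instrument's detector boundaries on
    the resulting grid (they are not stored in the file).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    if layout == "wide":
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"wide layout missing columns {missing}")
        wl_cols = [c for c in df.columns if c not in _META_COLUMNS]
        try:
            wl = np.array([float(c) for c in wl_cols])
        except ValueError as exc:
            raise FormatError(f"non-numeric wavelength column: {exc}") from None
        if wl.size < 2:
            raise FormatError("wide layout needs at least two wavelength columns")
        meta = df[_META_COLUMNS]
        values = df[wl_cols].to_numpy(dtype=float)
    elif layout == "long":
        needed = _META_COLUMNS + ["wavelength_nm", "reflectance"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise FormatError(f"long layout missing columns {missing}")
        df = df.copy()
        df["group"] = df["group"].where(pd.notna(df["group"]), "__none__")
        pivot = df.pivot(
            index=_META_COLUMNS, columns="wavelength_nm", values="reflectance"
        )
        # restore file appearance order (pivot sorts its index)
        first_seen = df[_META_COLUMNS].drop_duplicates()
        pivot = pivot.reindex(pd.MultiIndex.from_frame(first_seen))
        if pivot.isna().any().any():
            raise GridMismatchError("spectra do not share one wavelength grid")
        wl = pivot.columns.to_numpy(dtype=float)
        order = np.argsort(wl)
        wl = wl[order]
        values = pivot.to_numpy(dtype=float)[:, order]
        meta = pivot.index.to_frame(index=False)
        meta["group"] = meta["group"].where(meta["group"] != "__none__", None)
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")

    steps = np.diff(wl)
    if not np.allclose(steps, steps[0], atol=1e-9):
        raise GridMismatchError("wavelengths do not form an arithmetic grid")
    grid = SpectralGrid(
        start_nm=float(wl[0]),
        end_nm=float(wl[-1]),
        step_nm=float(steps[0]),
        splice_points_nm=tuple(
            s for s in splice_points_nm if wl[0] < s < wl[-1]
        ),
    )
    meta = meta.copy()
    meta["replicate"] = meta["replicate"].astype(int)
    meta["group"] = meta["group"].where(pd.notna(meta["group"]), None)
    _validate_rows(meta, values)
    return SpectraSet(grid, meta, values)


def _validate_rows(meta: pd.DataFrame, values: np.ndarray) -> None:
    """Per-row reflectance validation with a row-naming error message."""
    bad = ~(np.isfinite(values) & (values > 0) & (values <= 1))
    if bad.any():
        i = int(np.argwhere(bad.any(axis=1))[0][0])
        row = meta.iloc[i]
        raise SpectraValidationError(
            f"reflectance outside (0, 1] in row sample_id={row['sample_id']!r} "
            f"replicate={row['replicate']} state={row['state']!r}"
        )


# ---------------------------------------------------------------------------
# reference table
# ---------------------------------------------------------------------------

FERT_N_LEVELS = (5.0, 20.0, 100.0, 200.0)
FERT_P_LEVELS = (1.0, 4.0, 20.0, 40.0)


class ReferenceTable:
    """Wet-lab trait values and experimental factors per sample.

    Columns: ``sample_id, species, leaf_N, leaf_P, fert_N_level,
    fert_P_level``.  Leaf N is in % dry mass, leaf P in mg g^-1 dry mass;
    fertilization levels (kg ha^-1 yr^-1) are drawn from the factorial
    design's level sets when present (NaN for non-fertilization material).
    """

    COLUMNS = ["sample_id", "species", "leaf_N", "leaf_P", "fert_N_level", "fert_P_level"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"reference table missing columns {missing}")
        table = table[self.COLUMNS].reset_index(drop=True).copy()
        for col in ("leaf_N", "leaf_P", "fert_N_level", "fert_P_level"):
            table[col] = table[col].astype(float)
        if table["sample_id"].duplicated().any():
            raise SpectraValidationError("duplicate sample_id in reference table")
        for trait in ("leaf_N", "leaf_P"):
            v = table[trait].to_numpy(dtype=float)
            if np.any(~np.isfinite(v)) or np.any(v <= 0):
                raise SpectraValidationError(f"{trait} must be finite and > 0")
        for col, levels in (("fert_N_level", FERT_N_LEVELS), ("fert_P_level", FERT_P_LEVELS)):
            v = table[col].to_numpy(dtype=float)
            present = np.isfinite(v)
            if present.any() and not np.isin(v[present], levels).all():
                raise SpectraValidationError(
                    f"{col} values must be drawn from {levels}"
                )
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def trait(self, name: str) -> pd.Series:
        if name not in ("leaf_N", "leaf_P"):
            raise ConfigurationError(f"unknown trait {name!r}")
        return self.table.set_index("sample_id")[name]

    def equals(self, other: "ReferenceTable") -> bool:
        return self.table.equals(other.table)


def write_reference(ref: ReferenceTable, path: str | Path) -> None:
    ref.table.to_csv(path, index=False, float_format="%.17g")


def read_reference(path: str | Path) -> ReferenceTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return ReferenceTable(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def average_replicates(s: SpectraSet) -> SpectraSet:
    """Average replicate scans of each ``(sample_id, state)``.

    Returns one spectrum per leaf and state with ``replicate`` set to 1.
    Idempotent: averaging an already-averaged set is the identity.
    """
    key = ["sample_id", "state"]
    frame = s.meta.copy()
    frame["_row"] = np.arange(len(frame))
    out_meta = []
    out_vals = []
    for (sid, state), g in frame.groupby(key, sort=False):
        rows = g["_row"].to_numpy()
        out_meta.append(
            {
                "sample_id": sid,
                "replicate": 1,
                "state": state,
                "group": g["group"].iloc[0],
            }
        )
        out_vals.append(s.values[rows].mean(axis=0))
    return SpectraSet(s.grid, pd.DataFrame(out_meta), np.vstack(out_vals))


def splice_correct(s: SpectraSet, splice_points_nm: Sequence[float] | None = None) -> SpectraSet:
    """Remove detector steps by additive per-segment offsets.

    For each splice point the segment *after* the boundary is shifted so its
    first value equals the last value before the boundary; the first segment
    anchors the spectrum and corrections compose left to right.  Within each
    segment only a constant is added, so band shapes are preserved.  Values
    pushed outside ``(0, 1]`` by a shift are clipped into
    ``(MIN_REFLECTANCE, 1]`` and the clip count is logged.
    """
    points = s.grid.splice_points_nm if splice_points_nm is None else tuple(splice_points_nm)
    wl = s.grid.wavelengths()
    v = s.values.copy()
    for sp in points:
        idx = s.grid.index_of(sp)  # raises ConfigurationError off-grid
        if idx >= len(wl) - 1:
            raise ConfigurationError(f"splice point {sp} nm has no following segment")
        offset = v[:, idx + 1] - v[:, idx]
        v[:, idx + 1 :] -= offset[:, None]
    n_clipped = int(np.sum((v <= 0) | (v > 1)))
    if n_clipped:
        logger.warning("splice_correct clipped %d values into (0, 1]", n_clipped)
        v = np.clip(v, MIN_REFLECTANCE, 1.0)
    return SpectraSet(s.grid, s.meta, v)
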