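"""Optimized NIRS calibration: randomized region search around a PLS1 core.

The calibration procedure mirrors common chemometric practice for
reflectance spectra of leaf material:

1. the response may be transformed (natural log for right-skewed traits
   such as leaf N under a factorial fertilization design);
2. a Kennard-Stone split fixes calibration and validation sets once;
3. many candidate predictor subsets are drawn as random unions of up to
   ``max_regions`` wavelength intervals, a PLS1 model (component count
   chosen by validation RMSEP) is fit on each, and the candidate with the
   lowest validation RMSEP wins — the full spectrum is always evaluated as
   iteration 0, so the winner can never do worse than the baseline;
4. an F-statistic screen flags calibration samples with unusually large
   residuals; flagged samples are only removed on explicit confirmation,
   standing in for the operator's manual re-evaluation, and removal
   triggers a refit of the winning configuration.

Model quality is reported as validation-set R^2 (coefficient of
determination) and RMSEP on the transformed scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from . import __version__ as _pkg_version
from .exceptions import (
    ConfigurationError,
    DataSizeError,
    DegenerateInputError,
    GridMismatchError,
    SpectraValidationError,
)
from .pls import PLS1Regression, _as_matrix
from .sampling import KennardStoneSplitter, SplitResult
from .spectra import ReferenceTable, SpectralGrid, SpectraSet

TRANSFORMS = ("identity", "natural_log")


# ---------------------------------------------------------------------------
# response transform
# ---------------------------------------------------------------------------

def transform_response(y, transform: str):
    """Apply the configured response transform elementwise."""
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y.copy()
    if transform == "natural_log":
        if np.any(y <= 0):
            i = int(np.argwhere(y <= 0)[0][0])
            raise SpectraValidationError(
                f"natural_log transform requires positive responses; "
                f"sample at position {i} has value {y[i]}"
            )
        return np.log(y)
    raise ConfigurationError(f"unknown transform {transform!r}")


def back_transform_response(y, transform: str):
    """Inverse of :func:`transform_response`."""
    y = np.asarray(y, dtype=float)
    if transform == "identity":
        return y.copy()
    if transform == "natural_log":
        return np.exp(y)
    raise ConfigurationError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# wavelength regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSet:
    """Union of wavelength intervals defining a model's predictor subset.

    Intervals are closed, sorted, and merged on construction (overlapping or
    boundary-sharing intervals collapse into one), so membership is
    unambiguous and no column is selected twice.
    """

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = sorted((float(a), float(b)) for a, b in self.intervals)
        if not ivs:
            raise ConfigurationError("RegionSet needs at least one interval")
        if any(b <= a for a, b in ivs):
            raise ConfigurationError("interval end must exceed start")
        merged = [ivs[0]]
        for a, b in ivs[1:]:
            la, lb = merged[-1]
            if a <= lb:  # overlap or shared boundary
                merged[-1] = (la, max(lb, b))
            else:
                merged.append((a, b))
        object.__setattr__(self, "intervals", tuple(merged))

    def mask(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        m = np.zeros(wl.shape, dtype=bool)
        for a, b in self.intervals:
            m |= (wl >= a) & (wl <= b)
        return m

    def label(self) -> str:
        return ";".join(f"{a:g}-{b:g}" for a, b in self.intervals)

    @classmethod
    def full(cls, grid: SpectralGrid) -> "RegionSet":
        return cls(((grid.start_nm, grid.end_nm),))


def sample_region_set(
    rng: np.random.Generator,
    grid: SpectralGrid,
    max_regions: int = 8,
    min_width: float = 20.0,
    max_width: float = 250.0,
) -> RegionSet:
    """Draw a random RegionSet: a uniform 1..max_regions count of windows,
    each with a uniform width in [min_width, max_width] and a uniform
    on-grid start, merged where windows overlap.

    Bounding the window width keeps the union of up to eight windows a
    genuine subset of the spectrum (unbounded widths would almost always
    merge into one near-full-span interval).
    """
    if max_regions < 1:
        raise ConfigurationError("max_regions must be >= 1")
    wl = grid.wavelengths()
    min_pts = int(np.ceil(min_width / grid.step_nm))
    if min_pts >= grid.n_points:
        raise ConfigurationError("min_width exceeds the grid span")
    max_pts = min(int(np.floor(max_width / grid.step_nm)), grid.n_points - 1)
    if max_pts < min_pts:
        raise ConfigurationError("max_width must be >= min_width")
    count = int(rng.integers(1, max_regions + 1))
    intervals = []
    for _ in range(count):
        width = int(rng.integers(min_pts, max_pts + 1))
        start_idx = int(rng.integers(0, grid.n_points - width))
        intervals.append((float(wl[start_idx]), float(wl[start_idx + width])))
    return RegionSet(tuple(intervals))


def subset_by_regions(s, regions: RegionSet) -> pd.DataFrame:
    """Columns of a SpectraSet (or wavelength-labelled DataFrame) inside the
    region union, in wavelength order, labels retained."""
    if isinstance(s, SpectraSet):
        df = s.matrix()
    elif isinstance(s, pd.DataFrame):
        df = s
    else:
        raise ConfigurationError("expected SpectraSet or DataFrame")
    wl = np.asarray(df.columns, dtype=float)
    m = regions.mask(wl)
    if not m.any():
        raise ConfigurationError(
            f"regions {regions.label()} select no wavelength column"
        )
    return df.loc[:, m]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricReport:
    """Validation metrics: coefficient of determination, RMSEP, and (as an
    auxiliary) the squared Pearson correlation of predicted vs observed."""

    r_squared: float
    rmsep: float
    n_validation: int
    r_pearson_squared: float | None = None

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "rmsep": self.rmsep,
            "n_validation": self.n_validation,
            "r_pearson_squared": self.r_pearson_squared,
        }


def evaluate_model(y_observed, y_predicted) -> MetricReport:
    """RMSEP and R^2 of predictions against observations.

    ``rmsep = sqrt(mean((obs - pred)^2))``;
    ``r_squared = 1 - SS_res / SS_tot`` with SS_tot about the observed mean.
    """
    obs = np.asarray(y_observed, dtype=float).ravel()
    pred = np.asarray(y_predicted, dtype=float).ravel()
    if obs.shape != pred.shape:
        raise ConfigurationError("observed and predicted lengths differ")
    if obs.size < 2:
        raise ConfigurationError("need at least 2 observations")
    rmsep = float(np.sqrt(np.mean((obs - pred) ** 2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError(
            f"observed values are constant; r_squared undefined (rmsep={rmsep})"
        )
    r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot
    if np.ptp(pred) > 0:
        r = float(np.corrcoef(obs, pred)[0, 1])
        rp2 = r * r
    else:
        rp2 = None
    return MetricReport(r_squared=r2, rmsep=rmsep, n_validation=obs.size, r_pearson_squared=rp2)


# ---------------------------------------------------------------------------
# outlier screen
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Per-sample F statistics from the calibration-residual screen.

    ``table`` columns: sample_id, residual, f_value, flagged, removed.
    Samples are flagged when their F value exceeds the configured quantile
    of F(1, n-2); removal requires :meth:`confirm_removal`.
    """

    table: pd.DataFrame
    percentile: float
    threshold: float

    @property
    def flagged_ids(self) -> list:
        return list(self.table.loc[self.table["flagged"], "sample_id"])

    @property
    def removed_ids(self) -> list:
        return list(self.table.loc[self.table["removed"], "sample_id"])

    def confirm_removal(self, sample_ids: Sequence | None = None) -> "OutlierReport":
        """Mark flagged samples as removed (all flagged by default);
        non-flagged ids are rejected."""
        ids = self.flagged_ids if sample_ids is None else list(sample_ids)
        bad = set(ids) - set(self.flagged_ids)
        if bad:
            raise ConfigurationError(f"cannot remove non-flagged samples {sorted(bad)}")
        t = self.table.copy()
        t["removed"] = t["sample_id"].isin(ids) & t["flagged"]
        return OutlierReport(table=t, percentile=self.percentile, threshold=self.threshold)

    def to_dict(self) -> dict:
        return {
            "percentile": self.percentile,
            "threshold": self.threshold,
            "samples": self.table.to_dict(orient="records"),
        }


def detect_outliers(
    X,
    y,
    model: PLS1Regression,
    percentile: float = 0.999,
    sample_ids: Sequence | None = None,
) -> OutlierReport:
    """Univariate F screen on calibration residuals.

    For each sample ``F_i = e_i^2 / s^2_(-i)`` where ``s^2_(-i)`` is the
    mean squared residual excluding sample i; samples with ``F_i`` above the
    ``percentile`` quantile of F(1, n-2) are flagged.  With all residuals
    zero nothing is flagged.
    """
    X, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n < 5:
        raise DataSizeError("outlier screen needs at least 5 samples")
    if not (0.0 < percentile < 1.0):
        raise ConfigurationError("percentile must be in (0, 1)")
    e = y - model.predict(X)
    e2 = e**2
    total = float(e2.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        s2_loo = (total - e2) / (n - 1)
        f = np.where(
            s2_loo > 0.0,
            e2 / s2_loo,
            np.where(e2 > 0.0, np.inf, 0.0),
        )
    threshold = float(stats.f.ppf(percentile, 1, n - 2))
    flagged = f > threshold
    ids = list(range(n)) if sample_ids is None else list(sample_ids)
    table = pd.DataFrame(
        {
            "sample_id": ids,
            "residual": e,
            "f_value": f,
            "flagged": flagged,
            "removed": False,
        }
    )
    return OutlierReport(table=table, percentile=percentile, threshold=threshold)


# ---------------------------------------------------------------------------
# region-search calibrator (estimator)
# ---------------------------------------------------------------------------

class RegionSearchCalibrator(RegressorMixin, BaseEstimator):
    """PLS1 calibration with randomized spectral-region optimization.

    ``fit`` expects ``X`` as a DataFrame whose columns are wavelengths (nm)
    on an arithmetic grid (e.g. ``SpectraSet.matrix()``) and ``y`` as the
    trait vector in natural units.  ``predict`` returns back-transformed
    trait values.

    Parameters
    ----------
    transform : {"identity", "natural_log"}
        Response transform; fitting and model selection happen on the
        transformed scale.
    n_iterations : int
        Number of random region draws; 0 fits the full-spectrum baseline
        only.  The baseline is always evaluated as iteration 0.
    max_regions, min_width_nm, max_width_nm
        Region-draw geometry: up to ``max_regions`` windows with widths in
        ``[min_width_nm, max_width_nm]``.
    split_fraction : float
        Kennard-Stone calibration fraction, computed once on the full
        spectrum and reused for every candidate.
    max_components : int
        Ceiling on PLS components; the count per candidate minimizes
        validation RMSEP.
    outlier_percentile : float
        Quantile of F(1, n-2) for the calibration-residual screen.
    remove_outliers : bool
        Auto-confirm removal of flagged samples and refit (default: report
        only).
    random_state : int or numpy Generator
        Seed for the region draws.

    Attributes
    ----------
    split_ : SplitResult (positional row ids)
    regions_ : winning RegionSet
    pls_ : fitted PLS1Regression on the winning regions
    metrics_ : MetricReport on the validation set (transformed scale)
    iteration_log_ : DataFrame (iteration, regions, n_components, rmsep, r_squared)
    outlier_report_ : OutlierReport from the winning model's calibration residuals
    """

    def __init__(
        self,
        transform: str = "identity",
        n_iterations: int = 200,
        max_regions: int = 8,
        min_width_nm: float = 20.0,
        max_width_nm: float = 250.0,
        split_fraction: float = 0.5,
        max_components: int = 10,
        outlier_percentile: float = 0.999,
        remove_outliers: bool = False,
        random_state=None,
    ):
        self.transform = transform
        self.n_iterations = n_iterations
        self.max_regions = max_regions
        self.min_width_nm = min_width_nm
        self.max_width_nm = max_width_nm
        self.split_fraction = split_fraction
        self.max_components = max_components
        self.outlier_percentile = outlier_percentile
        self.remove_outliers = remove_outliers
        self.random_state = random_state

    # -----------------------------------------------------------------
    def fit(self, X, y, sample_ids: Sequence | None = None) -> "RegionSearchCalibrator":
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")
        if self.n_iterations < 0:
            raise ConfigurationError("n_iterations must be >= 0")
        if not isinstance(X, pd.DataFrame):
            raise ConfigurationError("X must be a DataFrame with wavelength columns")
        wl = np.asarray(X.columns, dtype=float)
        steps = np.diff(wl)
        if wl.size < 2 or not np.allclose(steps, steps[0], atol=1e-9):
            raise GridMismatchError("X columns must form an arithmetic wavelength grid")
        grid = SpectralGrid(
            start_nm=float(wl[0]),
            end_nm=float(wl[-1]),
            step_nm=float(steps[0]),
            splice_points_nm=(),
        )
        Xv = X.to_numpy(dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = Xv.shape[0]
        if y.shape[0] != n:
            raise ConfigurationError("X and y are not row-aligned")
        if n < 8:
            raise DataSizeError(f"need at least 8 usable samples, got {n}")
        ids = list(range(n)) if sample_ids is None else list(sample_ids)
        yt = transform_response(y, self.transform)

        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        split = KennardStoneSplitter(fraction=self.split_fraction).select(Xv)
        cal = np.asarray(split.calibration_ids, dtype=int)
        val = np.asarray(split.validation_ids, dtype=int)

        candidates = [(0, RegionSet.full(grid))]
        candidates += [
            (
                i,
                sample_region_set(
                    rng, grid, self.max_regions, self.min_width_nm, self.max_width_nm
                ),
            )
            for i in range(1, self.n_iterations + 1)
        ]

        log_rows = []
        best = None  # (rmsep, -r2, iteration, regions, k, mask)
        for it, regions in candidates:
            mask = regions.mask(wl)
            Xi = Xv[:, mask]
            k = _choose_components_arrays(Xi, yt, self.max_components, cal, val)
            model = PLS1Regression(n_components=k).fit(Xi[cal], yt[cal])
            pred = model.predict(Xi[val])
            rep = evaluate_model(yt[val], pred)
            log_rows.append(
                {
                    "iteration": it,
                    "regions": regions.label(),
                    "n_components": model.n_components_,
                    "rmsep": rep.rmsep,
                    "r_squared": rep.r_squared,
                }
            )
            key = (rep.rmsep, -rep.r_squared, it)
            if best is None or key < best[0]:
                best = (key, regions, model.n_components_, mask)

        _, regions, k, mask = best
        self.iteration_log_ = pd.DataFrame(log_rows)
        self.split_ = SplitResult(
            fraction=self.split_fraction,
            calibration_ids=[ids[i] for i in cal],
            validation_ids=[ids[i] for i in val],
        )
        self.regions_ = regions
        self.wavelengths_ = wl
        self.grid_ = grid

        cal_final = cal
        pls = PLS1Regression(n_components=k).fit(
            X.loc[:, mask].iloc[cal_final], yt[cal_final]
        )
        report = detect_outliers(
            Xv[cal_final][:, mask],
            yt[cal_final],
            pls,
            percentile=self.outlier_percentile,
            sample_ids=[ids[i] for i in cal_final],
        )
        if self.remove_outliers and report.flagged_ids:
            report = report.confirm_removal()
            keep = ~report.table["removed"].to_numpy()
            cal_final = cal_final[keep]
            k = _choose_components_arrays(
                Xv[:, mask], yt, self.max_components, cal_final, val
            )
            pls = PLS1Regression(n_components=k).fit(
                X.loc[:, mask].iloc[cal_final], yt[cal_final]
            )
        self.outlier_report_ = report
        self.pls_ = pls
        self.n_components_ = pls.n_components_
        self.metrics_ = evaluate_model(yt[val], pls.predict(Xv[val][:, mask]))
        return self

    # -----------------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            Xm = subset_by_regions(X, self.regions_).to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            if Xv.shape[1] == self.pls_.x_mean_.shape[0]:
                Xm = Xv
            elif Xv.shape[1] == self.wavelengths_.shape[0]:
                Xm = Xv[:, self.regions_.mask(self.wavelengths_)]
            else:
                raise GridMismatchError("X columns match neither grid nor regions")
        return back_transform_response(self.pls_.predict(Xm), self.transform)


def _choose_components_arrays(Xi, yt, max_components, cal, val) -> int:
    """Validation-RMSEP component choice on plain arrays (hot path)."""
    max_allowed = min(cal.shape[0] - 1, Xi.shape[1])
    k_max = min(max_components, max_allowed)
    model = PLS1Regression(n_components=k_max).fit(Xi[cal], yt[cal])
    Xc = (Xi[val] - model.x_mean_) / model.x_std_
    best_k, best_rmsep = 1, np.inf
    for k in range(1, model.n_components_ + 1):
        pred = model.y_mean_ + Xc @ model._coefficients(k)
        rmsep = float(np.sqrt(np.mean((yt[val] - pred) ** 2)))
        if rmsep < best_rmsep:
            best_k, best_rmsep = k, rmsep
    return best_k


# ---------------------------------------------------------------------------
# persisted calibration model
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


@dataclass
class CalibrationModel:
    """A fitted calibration with its full provenance.

    Bundles the winning PLS1 model, its wavelength regions, response
    transform, the calibration/validation split, validation metrics, the
    outlier report, and the run's seed/iteration settings, and serializes
    to a single JSON document.
    """

    trait: str
    state: str
    transform: str
    regions: RegionSet
    plsr: PLS1Regression
    split: SplitResult
    metrics: MetricReport
    provenance: dict = field(default_factory=dict)
    outliers: OutlierReport | None = None
    grid: SpectralGrid | None = None

    # -- application ---------------------------------------------------
    def predict(self, s: SpectraSet) -> pd.DataFrame:
        """Apply the calibration to spectra; returns one prediction per row
        in natural trait units (plus the transformed-scale prediction)."""
        if self.grid is not None and (
            s.grid.start_nm != self.grid.start_nm
            or s.grid.end_nm != self.grid.end_nm
            or s.grid.step_nm != self.grid.step_nm
        ):
            raise GridMismatchError("spectra grid differs from the model's grid")
        Xm = subset_by_regions(s, self.regions).to_numpy(dtype=float)
        pred_t = self.plsr.predict(Xm)
        out = s.meta.copy()
        out[f"predicted_{self.trait}_transformed"] = pred_t
        out[f"predicted_{self.trait}"] = back_transform_response(pred_t, self.transform)
        return out

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "trait": self.trait,
            "state": self.state,
            "transform": self.transform,
            "regions": [list(iv) for iv in self.regions.intervals],
            "grid": None
            if self.grid is None
            else {
                "start_nm": self.grid.start_nm,
                "end_nm": self.grid.end_nm,
                "step_nm": self.grid.step_nm,
                "splice_points_nm": list(self.grid.splice_points_nm),
            },
            "plsr": self.plsr.to_arrays(),
            "split": json.loads(self.split.to_json()),
            "metrics": self.metrics.to_dict(),
            "provenance": self.provenance,
            "outliers": None if self.outliers is None else self.outliers.to_dict(),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, doc: str | Path) -> "CalibrationModel":
        text = Path(doc).read_text() if isinstance(doc, (Path,)) or (
            isinstance(doc, str) and "\n" not in doc and Path(doc).exists()
        ) else doc
        d = json.loads(text)
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported schema version {d.get('schema_version')}"
            )
        grid = None
        if d.get("grid") is not None:
            g = d["grid"]
            grid = SpectralGrid(
                start_nm=g["start_nm"],
                end_nm=g["end_nm"],
                step_nm=g["step_nm"],
                splice_points_nm=tuple(g["splice_points_nm"]),
            )
        outliers = None
        if d.get("outliers") is not None:
            o = d["outliers"]
            outliers = OutlierReport(
                table=pd.DataFrame(o["samples"]),
                percentile=o["percentile"],
                threshold=o["threshold"],
            )
        m = d["metrics"]
        return cls(
            trait=d["trait"],
            state=d["state"],
            transform=d["transform"],
            regions=RegionSet(tuple(tuple(iv) for iv in d["regions"])),
            plsr=PLS1Regression.from_arrays(d["plsr"]),
            split=SplitResult.from_json(json.dumps(d["split"])),
            metrics=MetricReport(
                r_squared=m["r_squared"],
                rmsep=m["rmsep"],
                n_validation=m["n_validation"],
                r_pearson_squared=m.get("r_pearson_squared"),
            ),
            provenance=d.get("provenance", {}),
            outliers=outliers,
            grid=grid,
        )


# ---------------------------------------------------------------------------
# top-level calibration entry points
# ---------------------------------------------------------------------------

def optimize_calibration(
    s: SpectraSet,
    ref: ReferenceTable,
    trait: str,
    state: str,
    transform: str = "identity",
    n_iterations: int = 200,
    max_regions: int = 8,
    min_width_nm: float = 20.0,
    max_width_nm: float = 250.0,
    split_fraction: float = 0.5,
    max_components: int = 10,
    outlier_percentile: float = 0.999,
    remove_outliers: bool = False,
    seed=None,
) -> CalibrationModel:
    """Fit the optimized calibration for one trait on one leaf state.

    Spectra are matched to reference samples by ``sample_id`` (spectra
    should already be replicate-averaged and splice-corrected).  Returns a
    :class:`CalibrationModel` with provenance.
    """
    sub = s.for_state(state)
    if len(sub) == 0:
        raise DataSizeError(f"no spectra in state {state!r}")
    y_by_id = ref.trait(trait)
    usable = sub.meta["sample_id"].isin(y_by_id.index).to_numpy()
    sub = sub.select(usable)
    if len(sub) < 8:
        raise DataSizeError(
            f"only {len(sub)} spectra have reference {trait} values; need >= 8"
        )
    ids = list(sub.meta["sample_id"])
    y = y_by_id.loc[ids].to_numpy(dtype=float)
    est = RegionSearchCalibrator(
        transform=transform,
        n_iterations=n_iterations,
        max_regions=max_regions,
        min_width_nm=min_width_nm,
        max_width_nm=max_width_nm,
        split_fraction=split_fraction,
        max_components=max_components,
        outlier_percentile=outlier_percentile,
        remove_outliers=remove_outliers,
        random_state=seed,
    ).fit(sub.matrix(), y, sample_ids=ids)
    model = CalibrationModel(
        trait=trait,
        state=state,
        transform=transform,
        regions=est.regions_,
        plsr=est.pls_,
        split=est.split_,
        metrics=est.metrics_,
        provenance={
            "seed": None if seed is None else int(seed),
            "n_iterations": int(n_iterations),
            "max_regions": int(max_regions),
            "min_width_nm": float(min_width_nm),
            "max_width_nm": float(max_width_nm),
            "split_fraction": float(split_fraction),
            "max_components": int(max_components),
            "outlier_percentile": float(outlier_percentile),
            "remove_outliers": bool(remove_outliers),
            "software_version": _pkg_version,
        },
        outliers=est.outlier_report_,
        grid=s.grid,
    )
    model.iteration_log = est.iteration_log_  # not serialized; saved as CSV by callers
    return model


def apply_model(model: CalibrationModel, s: SpectraSet) -> pd.DataFrame:
    """Predict trait values for new spectra with a saved calibration."""
    return model.predict(s)
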