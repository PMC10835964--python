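"""Synthetic leaf spectra and reference tables for the three experiments.

The generator produces data with the statistical structure a NIRS trait
calibration assumes, so the full workflow can be exercised and validated
without instrument data:

* traits respond to fertilization through a saturating (Michaelis-Menten
  style) curve with multiplicative lognormal individual variation — leaf N
  responds more strongly than leaf P, motivating the log transform for N;
* spectra follow a Beer-Lambert-style forward model: absorbance is a smooth
  baseline plus Gaussian absorption bands whose depths scale with trait
  values (weak bands for P, strong water bands at 1450/1940 nm in the fresh
  state), converted to reflectance with per-scan multiplicative scatter,
  additive noise and small detector-boundary steps;
* wet-lab reference values are the ground-truth traits times independent
  assay noise, so calibration quality is bounded below 1 even with perfect
  spectra;
* experiment designs mirror a greenhouse fertilization factorial
  (3 species x 16 N-by-P levels x 5 individuals, paired fresh/dried scans),
  a conservation-treatment trial (6 treated groups of 5 plus controls, null
  chemical effect by default) and a storage re-scan with per-specimen
  operator drift in one session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .spectra import (
    ReferenceTable,
    SpectralGrid,
    Spectrum,
    SpectraSet,
    MIN_REFLECTANCE,
)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band.

    ``amplitude_per_unit`` is absorbance per unit of the driver value
    (per %N, per mg g^-1 P, per water unit, or absolute for ``constant``).
    """

    center_nm: float
    width_nm: float
    amplitude_per_unit: float
    driver: str  # leaf_N | leaf_P | water | constant

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigurationError("band width must be positive")
        if self.amplitude_per_unit < 0:
            raise ConfigurationError("band amplitude must be >= 0")
        if self.driver not in ("leaf_N", "leaf_P", "water", "constant"):
            raise ConfigurationError(f"unknown band driver {self.driver!r}")


@dataclass(frozen=True)
class TraitCurve:
    """Saturating trait response to a fertilization level:
    ``trait = baseline + gain * F / (half_sat + F)``."""

    baseline: float
    gain: float
    half_sat: float


@dataclass(frozen=True)
class SpeciesTraitParams:
    leaf_N: TraitCurve
    leaf_P: TraitCurve


def _default_trait_params() -> dict:
    return {
        "Centaurea jacea": SpeciesTraitParams(
            leaf_N=TraitCurve(1.30, 2.40, 60.0), leaf_P=TraitCurve(1.60, 1.90, 9.0)
        ),
        "Plantago lanceolata": SpeciesTraitParams(
            leaf_N=TraitCurve(1.20, 2.60, 55.0), leaf_P=TraitCurve(1.50, 2.00, 8.0)
        ),
        "Poa annua": SpeciesTraitParams(
            leaf_N=TraitCurve(1.10, 2.20, 65.0), leaf_P=TraitCurve(1.40, 1.70, 10.0)
        ),
    }


def _default_bands() -> tuple:
    # Conventional NIR assignments: protein/N-H combination bands near 1510,
    # 2054 and 2180 nm; weaker P-associated bands at 1680 and 2380 nm (lower
    # signal-to-noise, so P calibrates worse than N); O-H water bands at 1450
    # and 1940 nm; two broad constant bands shaping the dry-matter baseline.
    return (
        BandSpec(1510.0, 25.0, 0.0030, "leaf_N"),
        BandSpec(2054.0, 20.0, 0.00345, "leaf_N"),
        BandSpec(2180.0, 25.0, 0.0030, "leaf_N"),
        BandSpec(1680.0, 25.0, 0.0025, "leaf_P"),
        BandSpec(2380.0, 25.0, 0.002125, "leaf_P"),
        BandSpec(1450.0, 35.0, 0.055, "water"),
        BandSpec(1940.0, 45.0, 0.075, "water"),
        BandSpec(1200.0, 400.0, 0.080, "constant"),
        BandSpec(2100.0, 350.0, 0.100, "constant"),
    )


TREATMENT_GROUPS = (
    "freezing",
    "drying",
    "freezing+drying",
    "freezing+pesticide",
    "freezing+drying+pesticide",
    "pesticide",
)


@dataclass
class SimConfig:
    """Full parameterization of the synthetic experiments.

    Defaults reproduce the study conditions: a 3-species x 4x4 factorial
    with 80 individuals per species scanned thrice in fresh and dried
    states; 40 specimens in six 5-sample conservation-treatment groups plus
    10 controls with zero chemical effect; and a storage re-scan with
    operator drift on the first session.
    """

    seed: int | None = None
    grid: SpectralGrid = field(default_factory=SpectralGrid)
    species: tuple = ("Centaurea jacea", "Plantago lanceolata", "Poa annua")
    individuals_per_species: int = 80
    fert_N_levels: tuple = (5.0, 20.0, 100.0, 200.0)
    fert_P_levels: tuple = (1.0, 4.0, 20.0, 40.0)
    trait_params: Mapping[str, SpeciesTraitParams] = field(default_factory=_default_trait_params)
    trait_noise_sd_N: float = 0.10  # lognormal sd of individual variation, ln scale
    trait_noise_sd_P: float = 0.12
    assay_noise_sd_N: float = 0.10  # wet-lab error incl. tissue-subsampling mismatch (ln scale)
    assay_noise_sd_P: float = 0.10
    bands: tuple = field(default_factory=_default_bands)
    baseline_offset: float = 0.35  # absorbance baseline at 350 nm
    baseline_slope: float = 0.12  # absorbance increase across the grid
    water_fresh: float = 6.0  # water driver value for fresh leaves
    water_dried: float = 0.5
    water_leaf_sd: float = 0.18  # per-leaf lognormal variation of water
    noise_sd: float = 0.006  # additive reflectance noise per scan point
    scatter_slope_sd: float = 0.020  # per-scan multiplicative scatter
    scatter_offset_sd: float = 0.020
    splice_step_sd: float = 0.003  # per-scan detector-boundary step sd
    replicate_count: int = 3
    # treatment experiment (conservation)
    treatment_species: str = "Plantago lanceolata"
    n_treatment_specimens: int = 40
    treatment_groups: tuple = TREATMENT_GROUPS
    per_group_n: int = 5
    treatment_effect_size: float = 0.0  # leaf-N shift (% dry mass) in the affected group
    treatment_effect_group: str = "freezing+drying+pesticide"
    leaf_perturbation_sd: float = 0.008  # per-leaf reflectance distortion, treated state
    # field material (experiments 2 and 3)
    ambient_fert_N: float = 20.0
    ambient_fert_P: float = 4.0
    field_noise_multiplier: float = 1.5  # field material varies more than greenhouse
    # storage experiment
    n_storage_specimens: int = 50
    session_drift_sd: float = 0.15  # sd of log path-length factor in drifted session
    drift_session: str = "t0"  # which session the drifting operator scanned

    def rng(self, seed=None) -> np.random.Generator:
        return np.random.default_rng(self.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# trait response
# ---------------------------------------------------------------------------

def trait_response(fert_N, fert_P, species: str, cfg: SimConfig, rng: np.random.Generator):
    """Ground-truth (leaf_N, leaf_P) for given fertilization levels.

    Saturating in the fertilization level with multiplicative lognormal
    individual variation; leaf P has a smaller relative gain than leaf N.
    Vectorized over array-valued levels.
    """
    params = cfg.trait_params[species]
    fn = np.asarray(fert_N, dtype=float)
    fp = np.asarray(fert_P, dtype=float)
    cN, cP = params.leaf_N, params.leaf_P
    mu_N = cN.baseline + cN.gain * fn / (cN.half_sat + fn)
    mu_P = cP.baseline + cP.gain * fp / (cP.half_sat + fp)
    leaf_N = mu_N * np.exp(rng.normal(0.0, cfg.trait_noise_sd_N, size=mu_N.shape))
    leaf_P = mu_P * np.exp(rng.normal(0.0, cfg.trait_noise_sd_P, size=mu_P.shape))
    return leaf_N, leaf_P


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _absorbance(leaf_N, leaf_P, water, cfg: SimConfig) -> np.ndarray:
    """Noiseless absorbance matrix (n_samples, n_wavelengths)."""
    wl = cfg.grid.wavelengths()
    leaf_N = np.atleast_1d(np.asarray(leaf_N, dtype=float))
    leaf_P = np.atleast_1d(np.asarray(leaf_P, dtype=float))
    water = np.atleast_1d(np.asarray(water, dtype=float))
    n = leaf_N.shape[0]
    x = (wl - cfg.grid.start_nm) / (cfg.grid.end_nm - cfg.grid.start_nm)
    A = np.tile(cfg.baseline_offset + cfg.baseline_slope * x, (n, 1))
    drivers = {
        "leaf_N": leaf_N,
        "leaf_P": leaf_P,
        "water": water,
        "constant": np.ones(n),
    }
    for band in cfg.bands:
        gauss = np.exp(-0.5 * ((wl - band.center_nm) / band.width_nm) ** 2)
        A += np.outer(drivers[band.driver], band.amplitude_per_unit * gauss)
    return A


def _scan(A: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """One scan of each sample: reflectance with per-scan scatter, noise and
    detector-boundary steps, clipped into (MIN_REFLECTANCE, 1]."""
    n, p = A.shape
    wl = cfg.grid.wavelengths()
    x = (wl - wl.mean()) / (wl[-1] - wl[0])
    R = 10.0 ** (-A)
    slope = rng.normal(0.0, cfg.scatter_slope_sd, size=(n, 1))
    offset = rng.normal(0.0, cfg.scatter_offset_sd, size=(n, 1))
    R = R * (1.0 + slope * x + offset)
    for sp in cfg.grid.splice_points_nm:
        idx = cfg.grid.index_of(sp)
        step = rng.normal(0.0, cfg.splice_step_sd, size=(n, 1))
        R[:, idx + 1 :] += step
    R += rng.normal(0.0, cfg.noise_sd, size=(n, p))
    return np.clip(R, MIN_REFLECTANCE, 1.0)


def render_spectrum(
    leaf_N: float,
    leaf_P: float,
    state: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    sample_id: str = "S0",
    replicate: int = 1,
    water: float | None = None,
) -> Spectrum:
    """Render a single replicate scan of one leaf.

    ``water`` defaults to the state's nominal water driver value
    (``water_fresh`` for fresh material, ``water_dried`` otherwise); with
    all noise terms zero the render is deterministic.
    """
    if water is None:
        water = cfg.water_fresh if state == "fresh" else cfg.water_dried
    A = _absorbance([leaf_N], [leaf_P], [water], cfg)
    values = _scan(A, cfg, rng)[0]
    return Spectrum(
        sample_id=sample_id, replicate=replicate, state=state, values=values
    )


def _scan_set(
    A: np.ndarray,
    state: str,
    sample_ids,
    groups,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> SpectraSet:
    """Replicate scans of every sample, sample-major row order."""
    n = A.shape[0]
    reps = cfg.replicate_count
    blocks = [_scan(A, cfg, rng) for _ in range(reps)]
    # interleave so rows are (sample 0 rep 1..k, sample 1 rep 1..k, ...)
    values = np.stack(blocks, axis=1).reshape(n * reps, A.shape[1])
    meta = pd.DataFrame(
        {
            "sample_id": np.repeat(np.asarray(sample_ids, dtype=object), reps),
            "replicate": np.tile(np.arange(1, reps + 1), n),
            "state": state,
            "group": np.repeat(np.asarray(groups, dtype=object), reps),
        }
    )
    return SpectraSet(cfg.grid, meta, values)


def _reference(
    sample_ids, species, leaf_N, leaf_P, fert_N, fert_P, cfg: SimConfig, rng
) -> ReferenceTable:
    """Wet-lab style table: ground truth times independent assay noise."""
    n = len(sample_ids)
    assay_N = leaf_N * np.exp(rng.normal(0.0, cfg.assay_noise_sd_N, size=n))
    assay_P = leaf_P * np.exp(rng.normal(0.0, cfg.assay_noise_sd_P, size=n))
    return ReferenceTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "species": species,
                "leaf_N": assay_N,
                "leaf_P": assay_P,
                "fert_N_level": fert_N,
                "fert_P_level": fert_P,
            }
        )
    )


# ---------------------------------------------------------------------------
# experiment generators
# ---------------------------------------------------------------------------

def generate_fertilization_experiment(
    cfg: SimConfig, seed=None
) -> tuple[SpectraSet, SpectraSet, ReferenceTable]:
    """Greenhouse fertilization factorial: paired fresh and dried spectra.

    Individuals of each species are assigned evenly to the 16 N-by-P level
    combinations; every individual is scanned ``replicate_count`` times in
    the fresh state and again after drying, and assayed in the wet lab.
    """
    rng = cfg.rng(seed)
    combos = [(fn, fp) for fn in cfg.fert_N_levels for fp in cfg.fert_P_levels]
    n_combos = len(combos)
    per_combo, rem = divmod(cfg.individuals_per_species, n_combos)
    if rem:
        raise ConfigurationError(
            f"{cfg.individuals_per_species} individuals not divisible across "
            f"{n_combos} level combinations"
        )
    species_col, fert_N, fert_P = [], [], []
    for sp in cfg.species:
        for fn, fp in combos:
            species_col += [sp] * per_combo
            fert_N += [fn] * per_combo
            fert_P += [fp] * per_combo
    n = len(species_col)
    sample_ids = [f"GH{i + 1:03d}" for i in range(n)]
    fert_N = np.array(fert_N)
    fert_P = np.array(fert_P)

    leaf_N = np.empty(n)
    leaf_P = np.empty(n)
    for sp in cfg.species:
        m = np.array([s == sp for s in species_col])
        leaf_N[m], leaf_P[m] = trait_response(fert_N[m], fert_P[m], sp, cfg, rng)

    water_f = cfg.water_fresh * np.exp(rng.normal(0.0, cfg.water_leaf_sd, size=n))
    water_d = cfg.water_dried * np.exp(rng.normal(0.0, cfg.water_leaf_sd, size=n))
    groups = [None] * n
    fresh = _scan_set(
        _absorbance(leaf_N, leaf_P, water_f, cfg), "fresh", sample_ids, groups, cfg, rng
    )
    dried = _scan_set(
        _absorbance(leaf_N, leaf_P, water_d, cfg), "dried", sample_ids, groups, cfg, rng
    )
    ref = _reference(sample_ids, species_col, leaf_N, leaf_P, fert_N, fert_P, cfg, rng)
    return fresh, dried, ref


def generate_treatment_experiment(
    cfg: SimConfig, seed=None
) -> tuple[SpectraSet, SpectraSet, SpectraSet, ReferenceTable]:
    """Conservation-treatment trial on field specimens of one species.

    Six treated groups of ``per_group_n`` specimens plus untreated controls
    (seven groups in total).  Treated-state spectra are the dried-state
    scans plus a smooth per-leaf perturbation; the chemical treatment
    effect defaults to zero, and a positive ``treatment_effect_size``
    shifts leaf N in ``treatment_effect_group`` only.
    """
    rng = cfg.rng(seed)
    n = cfg.n_treatment_specimens
    n_treated = len(cfg.treatment_groups) * cfg.per_group_n
    if n_treated > n:
        raise ConfigurationError(
            f"{n_treated} treated specimens exceed {n} available"
        )
    groups = [g for g in cfg.treatment_groups for _ in range(cfg.per_group_n)]
    groups += ["control"] * (n - n_treated)
    sample_ids = [f"TR{i + 1:03d}" for i in range(n)]
    sp = cfg.treatment_species

    noisy = _field_config(cfg)
    leaf_N, leaf_P = trait_response(
        np.full(n, cfg.ambient_fert_N), np.full(n, cfg.ambient_fert_P), sp, noisy, rng
    )
    water_f = cfg.water_fresh * np.exp(rng.normal(0.0, cfg.water_leaf_sd, size=n))
    water_d = cfg.water_dried * np.exp(rng.normal(0.0, cfg.water_leaf_sd, size=n))

    fresh = _scan_set(
        _absorbance(leaf_N, leaf_P, water_f, cfg), "fresh", sample_ids, groups, cfg, rng
    )
    dried = _scan_set(
        _absorbance(leaf_N, leaf_P, water_d, cfg), "dried", sample_ids, groups, cfg, rng
    )

    # treated scans start from the measured dried scans: same chemistry,
    # plus a smooth per-leaf distortion (surface change, probe placement)
    wl = cfg.grid.wavelengths()
    x = (wl - wl.mean()) / (wl[-1] - wl[0])
    delta = np.zeros((n, wl.size))
    if cfg.leaf_perturbation_sd > 0:
        off = rng.normal(0.0, cfg.leaf_perturbation_sd, size=(n, 1))
        slo = rng.normal(0.0, cfg.leaf_perturbation_sd, size=(n, 1))
        centers = rng.uniform(cfg.grid.start_nm, cfg.grid.end_nm, size=(n, 1))
        widths = rng.uniform(100.0, 300.0, size=(n, 1))
        amps = rng.normal(0.0, cfg.leaf_perturbation_sd, size=(n, 1))
        delta = off + slo * x + amps * np.exp(-0.5 * ((wl - centers) / widths) ** 2)

    ratio = np.ones((n, wl.size))
    if cfg.treatment_effect_size != 0.0:
        affected = np.array([g == cfg.treatment_effect_group for g in groups])
        if affected.any():
            A0 = _absorbance(leaf_N[affected], leaf_P[affected], water_d[affected], cfg)
            A1 = _absorbance(
                leaf_N[affected] + cfg.treatment_effect_size,
                leaf_P[affected],
                water_d[affected],
                cfg,
            )
            ratio[affected] = 10.0 ** (-(A1 - A0))

    reps = cfg.replicate_count
    treated_values = np.clip(
        dried.values * np.repeat(ratio, reps, axis=0) + np.repeat(delta, reps, axis=0),
        MIN_REFLECTANCE,
        1.0,
    )
    treated_meta = dried.meta.copy()
    treated_meta["state"] = "treated"
    treated = SpectraSet(cfg.grid, treated_meta, treated_values)

    ref = _reference(
        sample_ids, [sp] * n, leaf_N, leaf_P, [np.nan] * n, [np.nan] * n, cfg, rng
    )
    return fresh, dried, treated, ref


def generate_storage_experiment(
    cfg: SimConfig, seed=None
) -> tuple[SpectraSet, SpectraSet, ReferenceTable]:
    """Storage-duration re-scan: the same dried specimens scanned twice.

    Chemistry is unchanged between sessions; each session draws fresh scan
    noise, and the session named by ``drift_session`` additionally applies
    a per-specimen path-length distortion (operator scan-placement drift:
    reflectance raised to a lognormal power with sd ``session_drift_sd``),
    which scales apparent band depths and so biases trait predictions.
    """
    rng = cfg.rng(seed)
    n = cfg.n_storage_specimens
    species_col = [cfg.species[i % len(cfg.species)] for i in range(n)]
    sample_ids = [f"HB{i + 1:03d}" for i in range(n)]

    noisy = _field_config(cfg)
    leaf_N = np.empty(n)
    leaf_P = np.empty(n)
    for sp in cfg.species:
        m = np.array([s == sp for s in species_col])
        if m.any():
            leaf_N[m], leaf_P[m] = trait_response(
                np.full(m.sum(), cfg.ambient_fert_N),
                np.full(m.sum(), cfg.ambient_fert_P),
                sp,
                noisy,
                rng,
            )
    water_d = cfg.water_dried * np.exp(rng.normal(0.0, cfg.water_leaf_sd, size=n))
    A = _absorbance(leaf_N, leaf_P, water_d, cfg)

    scan_t0 = _scan_set(A, "dried", sample_ids, [None] * n, cfg, rng)
    scan_t1 = _scan_set(A, "rescanned", sample_ids, [None] * n, cfg, rng)

    if cfg.session_drift_sd > 0:
        if cfg.drift_session not in ("t0", "t1"):
            raise ConfigurationError(f"unknown drift session {cfg.drift_session!r}")
        gamma = np.exp(rng.normal(0.0, cfg.session_drift_sd, size=(n, 1)))
        drifted = scan_t0 if cfg.drift_session == "t0" else scan_t1
        # path-length change: absorbance scales by gamma, i.e. R -> R**gamma
        g = np.repeat(gamma, cfg.replicate_count, axis=0)
        values = np.clip(drifted.values**g, MIN_REFLECTANCE, 1.0)
        if cfg.drift_session == "t0":
            scan_t0 = SpectraSet(cfg.grid, scan_t0.meta, values)
        else:
            scan_t1 = SpectraSet(cfg.grid, scan_t1.meta, values)

    ref = _reference(
        sample_ids, species_col, leaf_N, leaf_P, [np.nan] * n, [np.nan] * n, cfg, rng
    )
    return scan_t0, scan_t1, ref


def _field_config(cfg: SimConfig) -> SimConfig:
    """Copy of cfg with field-material trait variability."""
    import dataclasses

    return dataclasses.replace(
        cfg,
        trait_noise_sd_N=cfg.trait_noise_sd_N * cfg.field_noise_multiplier,
        trait_noise_sd_P=cfg.trait_noise_sd_P * cfg.field_noise_multiplier,
    )


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI
# ---------------------------------------------------------------------------

def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["grid"] = {
        "start_nm": cfg.grid.start_nm,
        "end_nm": cfg.grid.end_nm,
        "step_nm": cfg.grid.step_nm,
        "splice_points_nm": list(cfg.grid.splice_points_nm),
    }
    d["bands"] = [asdict(b) for b in cfg.bands]
    d["trait_params"] = {
        sp: {"leaf_N": asdict(p.leaf_N), "leaf_P": asdict(p.leaf_P)}
        for sp, p in cfg.trait_params.items()
    }
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "grid" in d:
        g = d["grid"]
        d["grid"] = SpectralGrid(
            start_nm=g["start_nm"],
            end_nm=g["end_nm"],
            step_nm=g["step_nm"],
            splice_points_nm=tuple(g.get("splice_points_nm", ())),
        )
    if "bands" in d:
        d["bands"] = tuple(BandSpec(**b) for b in d["bands"])
    if "trait_params" in d:
        d["trait_params"] = {
            sp: SpeciesTraitParams(
                leaf_N=TraitCurve(**p["leaf_N"]), leaf_P=TraitCurve(**p["leaf_P"])
            )
            for sp, p in d["trait_params"].items()
        }
    for key in ("species", "fert_N_levels", "fert_P_levels", "treatment_groups"):
        if key in d:
            d[key] = tuple(d[key])
    return SimConfig(**d)
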