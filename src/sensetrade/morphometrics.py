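"""Derived sensory traits from raw morphometric measurements.

Linear head/eye/antenna measurements (in µm) are turned into the traits the
downstream comparative analyses consume: half-ellipsoid eye surface area,
ovoid funiculus surface area (base circle removed), the eye-to-funiculus
ratio (EF ratio), per-µm² sensillum densities, imaginal-disc and neuropil
ratios, and two-choice attraction indices.  Size-scaling (allometry) checks
on the log-log scale live here as well.

Units are fixed: lengths µm, areas µm², volumes µm³; ratios dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .exceptions import (
    GeometryError,
    InvalidMeasurementError,
    RankDeficiencyError,
    UndefinedStatisticError,
)

__all__ = [
    "SpecimenMeasurement",
    "SensillumCounts",
    "DiscMeasurement",
    "NeuropilVolumes",
    "eye_surface_area",
    "funiculus_surface_area",
    "ef_ratio",
    "sensilla_density",
    "aggregate_species",
    "build_species_table",
    "allometry_fit",
    "multiple_regression",
    "disc_ratio",
    "volume_ratios",
    "trait_correlation",
    "attraction_index",
    "read_specimens_csv",
    "read_sensilla_csv",
    "read_discs_csv",
    "read_volumes_csv",
    "write_species_table_csv",
]

#: Columns of the specimen input CSV, in order.
SPECIMEN_COLUMNS = [
    "species", "replicate", "body_length", "head_width",
    "eye_width", "eye_height", "funiculus_length", "funiculus_width",
]
SENSILLA_COLUMNS = ["species", "replicate", "side", "trichoid", "basiconic", "coeloconic"]
DISC_COLUMNS = ["species", "replicate", "eye_portion_area", "antennal_portion_area"]
VOLUME_COLUMNS = ["species", "optic_lobe", "antennal_lobe", "central_brain"]

#: Columns of the species trait table, in deterministic output order.
SPECIES_TABLE_COLUMNS = [
    "species", "eye_area", "funiculus_area", "ef_ratio", "ommatidia",
    "trichoid_total", "sensilla_density", "wing_pigmentation_female",
    "wing_pigmentation_male", "light_courtship", "n_replicates",
]


@dataclass(frozen=True)
class SpecimenMeasurement:
    """One photographed female: linear head/body/eye/antenna measurements (µm)."""

    species_id: str
    replicate_id: str
    body_length: float
    head_width: float
    eye_width: float
    eye_height: float
    funiculus_length: float
    funiculus_width: float

    def __post_init__(self) -> None:
        for name in ("body_length", "head_width", "eye_width", "eye_height",
                     "funiculus_length", "funiculus_width"):
            if not getattr(self, name) > 0:
                raise InvalidMeasurementError(
                    f"{name}={getattr(self, name)!r} must be strictly positive "
                    f"({self.species_id}/{self.replicate_id})"
                )


@dataclass(frozen=True)
class SensillumCounts:
    """Manual sensillum counts for one antennal surface of one specimen."""

    species_id: str
    replicate_id: str
    side: str  # anterior | posterior | whole
    trichoid: int
    basiconic: int
    coeloconic: int

    def __post_init__(self) -> None:
        if self.side not in ("anterior", "posterior", "whole"):
            raise InvalidMeasurementError(f"unknown side {self.side!r}")
        for name in ("trichoid", "basiconic", "coeloconic"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise InvalidMeasurementError(f"{name}={v!r} must be a non-negative integer")

    @property
    def total(self) -> int:
        return int(self.trichoid + self.basiconic + self.coeloconic)


@dataclass(frozen=True)
class DiscMeasurement:
    """Eye and antennal portion areas of one eye-antennal imaginal disc (µm²)."""

    species_id: str
    replicate_id: str
    eye_portion_area: float
    antennal_portion_area: float

    def __post_init__(self) -> None:
        if not (self.eye_portion_area > 0 and self.antennal_portion_area > 0):
            raise InvalidMeasurementError("disc portion areas must be strictly positive")


@dataclass(frozen=True)
class NeuropilVolumes:
    """Per-species neuropil volumes (µm³); central brain excludes the AL."""

    species_id: str
    optic_lobe: float
    antennal_lobe: float
    central_brain: float

    def __post_init__(self) -> None:
        for name in ("optic_lobe", "antennal_lobe", "central_brain"):
            if not getattr(self, name) > 0:
                raise InvalidMeasurementError(f"{name} must be strictly positive")


# ---------------------------------------------------------------------------
# geometry


def eye_radius(eye_width: float, eye_height: float, rule: str = "width-and-half-height") -> float:
    """Radius of the sphere whose half-surface approximates the compound eye.

    ``"width-and-half-height"`` (default) averages the eye width with half
    the eye height, r = (w + h/2)/2.  ``"semi-axes"`` averages the two
    semi-axes instead, r = (w/2 + h/2)/2; the source sentence admits both
    readings, so the convention is configurable and recorded in reports.
    """
    if not (eye_width > 0 and eye_height > 0):
        raise InvalidMeasurementError("eye width/height must be strictly positive")
    if rule == "width-and-half-height":
        return (eye_width + eye_height / 2.0) / 2.0
    if rule == "semi-axes":
        return (eye_width / 2.0 + eye_height / 2.0) / 2.0
    raise ValueError(f"unknown eye radius rule {rule!r}")


def eye_surface_area(eye_width: float, eye_height: float,
                     rule: str = "width-and-half-height") -> float:
    """Half-ellipsoid eye surface: sphere area 4πr² divided by 2.

    The visible compound eye is treated as half of an ellipsoid of
    revolution with radius :func:`eye_radius`.
    """
    r = eye_radius(eye_width, eye_height, rule)
    return 2.0 * math.pi * r * r


def funiculus_surface_area(funiculus_length: float, funiculus_width: float,
                           hemisphere: bool = False) -> float:
    """Ovoid funiculus surface with the pedicel contact circle removed.

    The funiculus (third antennal segment) is treated as a full ellipsoid of
    revolution with radius r = (length/2 + width/2)/2; the circular base
    area π(width/2)² where it joins the pedicel is subtracted.  With
    ``hemisphere=True`` only half the ellipsoid surface is used before the
    subtraction (alternative reading of the construction).
    """
    if not (funiculus_length > 0 and funiculus_width > 0):
        raise InvalidMeasurementError("funiculus length/width must be strictly positive")
    r = (funiculus_length / 2.0 + funiculus_width / 2.0) / 2.0
    sphere = 4.0 * math.pi * r * r
    if hemisphere:
        sphere /= 2.0
    area = sphere - math.pi * (funiculus_width / 2.0) ** 2
    if area <= 0:
        raise GeometryError(
            f"non-positive funiculus surface ({area:.4g} µm²) for "
            f"length={funiculus_length}, width={funiculus_width}"
        )
    return area


def ef_ratio(eye_area: float, funiculus_area: float) -> float:
    """Eye-to-funiculus surface ratio; the central sensory-allocation trait."""
    if not (eye_area > 0 and funiculus_area > 0):
        raise InvalidMeasurementError("areas must be strictly positive")
    return eye_area / funiculus_area


def sensilla_density(sensilla_number: float, funiculus_surface: float) -> float:
    """Sensilla per µm² of one antennal side: count / (½ · funiculus surface)."""
    if sensilla_number < 0:
        raise InvalidMeasurementError("sensilla count must be non-negative")
    if not funiculus_surface > 0:
        raise InvalidMeasurementError("funiculus surface must be strictly positive")
    return sensilla_number / (0.5 * funiculus_surface)


def disc_ratio(disc: DiscMeasurement) -> float:
    """Eye portion divided by antennal portion of one imaginal disc."""
    return disc.eye_portion_area / disc.antennal_portion_area


def volume_ratios(v: NeuropilVolumes) -> dict:
    """OL:AL, OL:central and AL:central neuropil volume ratios."""
    return {
        "ol_al": v.optic_lobe / v.antennal_lobe,
        "ol_central": v.optic_lobe / v.central_brain,
        "al_central": v.antennal_lobe / v.central_brain,
    }


def attraction_index(n_test: float, n_control: float) -> float:
    """Symmetric two-choice preference index (t − c)/(t + c) in [−1, 1]."""
    if n_test < 0 or n_control < 0:
        raise InvalidMeasurementError("capture counts must be non-negative")
    total = n_test + n_control
    if total == 0:
        raise UndefinedStatisticError("attraction index undefined: no flies captured")
    return (n_test - n_control) / total


# ---------------------------------------------------------------------------
# aggregation


def aggregate_species(
    specimens: Sequence[SpecimenMeasurement],
    counts: Sequence[SensillumCounts] = (),
    ommatidia: float | None = None,
    binary_traits: dict | None = None,
    eye_rule: str = "width-and-half-height",
) -> dict:
    """Collapse one species' replicates into a single trait-table row.

    Raw linear measurements are averaged arithmetically across replicates
    first and the derived areas/ratios computed from the means (not the
    mean of per-replicate areas), which keeps the result order-invariant.
    Sensillum totals are replicate means; the anterior-surface density uses
    the density formula with the species' derived funiculus area.
    """
    if len(specimens) == 0:
        raise InvalidMeasurementError("aggregate_species: empty species group")
    species = {s.species_id for s in specimens} | {c.species_id for c in counts}
    if len(species) != 1:
        raise InvalidMeasurementError(f"aggregate_species: mixed species ids {sorted(species)}")
    (species_id,) = species
    reps = [s.replicate_id for s in specimens]
    if len(set(reps)) != len(reps):
        raise InvalidMeasurementError(f"duplicate replicate ids within {species_id}")

    def mean(attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in specimens]))

    eye_area = eye_surface_area(mean("eye_width"), mean("eye_height"), rule=eye_rule)
    fun_area = funiculus_surface_area(mean("funiculus_length"), mean("funiculus_width"))

    trichoid_total = math.nan
    density = math.nan
    anterior = [c for c in counts if c.side == "anterior"]
    posterior = [c for c in counts if c.side == "posterior"]
    whole = [c for c in counts if c.side == "whole"]
    if whole:
        trichoid_total = float(np.mean([c.trichoid for c in whole]))
    elif anterior and posterior:
        trichoid_total = float(np.mean([c.trichoid for c in anterior])
                               + np.mean([c.trichoid for c in posterior]))
    elif anterior:
        trichoid_total = float(np.mean([c.trichoid for c in anterior]))
    if anterior:
        density = sensilla_density(float(np.mean([c.total for c in anterior])), fun_area)

    binary_traits = binary_traits or {}
    return {
        "species": species_id,
        "eye_area": eye_area,
        "funiculus_area": fun_area,
        "ef_ratio": ef_ratio(eye_area, fun_area),
        "ommatidia": math.nan if ommatidia is None else float(ommatidia),
        "trichoid_total": trichoid_total,
        "sensilla_density": density,
        "wing_pigmentation_female": binary_traits.get("wing_pigmentation_female", math.nan),
        "wing_pigmentation_male": binary_traits.get("wing_pigmentation_male", math.nan),
        "light_courtship": binary_traits.get("light_courtship", math.nan),
        "n_replicates": len(specimens),
    }


def build_species_table(
    specimens: Iterable[SpecimenMeasurement],
    counts: Iterable[SensillumCounts] = (),
    binary_table: pd.DataFrame | None = None,
    eye_rule: str = "width-and-half-height",
) -> pd.DataFrame:
    """Aggregate every species in the input into the species trait table."""
    by_species: dict[str, list[SpecimenMeasurement]] = {}
    for s in specimens:
        by_species.setdefault(s.species_id, []).append(s)
    counts_by_species: dict[str, list[SensillumCounts]] = {}
    for c in counts:
        counts_by_species.setdefault(c.species_id, []).append(c)
    rows = []
    for species_id in sorted(by_species):
        binary = None
        if binary_table is not None and species_id in binary_table.index:
            binary = {
                k: binary_table.loc[species_id, k]
                for k in ("wing_pigmentation_female", "wing_pigmentation_male", "light_courtship")
                if k in binary_table.columns
            }
        rows.append(aggregate_species(
            by_species[species_id],
            counts_by_species.get(species_id, ()),
            binary_traits=binary,
            eye_rule=eye_rule,
        ))
    return pd.DataFrame(rows, columns=SPECIES_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# regression checks


@dataclass(frozen=True)
class AllometryFit:
    """Log-log OLS slope with its 95% CI and a t-test against a reference slope."""

    slope: float
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    expected_slope: float
    t_isometry: float
    p_isometry: float
    n: int
    r_squared: float

    @property
    def is_isometric(self) -> bool:
        """True when the reference slope is not rejected at the 5% level."""
        return self.p_isometry >= 0.05


def allometry_fit(size: np.ndarray, trait: np.ndarray, expected_slope: float) -> AllometryFit:
    """OLS of ln(trait) on ln(size) with a two-sided t-test of the slope.

    The reference slope encodes isometry: 2 for an area regressed on a
    linear size, 1 for length-on-length, 0 for a size-independent ratio.
    """
    size = np.asarray(size, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if size.shape != trait.shape or size.ndim != 1:
        raise ValueError("size and trait must be equal-length 1-D vectors")
    if size.size < 3:
        raise InvalidMeasurementError("allometry_fit needs at least 3 points")
    if np.any(size <= 0) or np.any(trait <= 0):
        raise InvalidMeasurementError("allometry_fit needs strictly positive data")
    X = sm.add_constant(np.log(size))
    res = sm.OLS(np.log(trait), X).fit()
    slope, se = res.params[1], res.bse[1]
    df = res.df_resid
    tcrit = scipy.stats.t.ppf(0.975, df)
    t_iso = (slope - expected_slope) / se
    p_iso = 2.0 * scipy.stats.t.sf(abs(t_iso), df)
    return AllometryFit(
        slope=float(slope), intercept=float(res.params[0]), slope_se=float(se),
        ci_low=float(slope - tcrit * se), ci_high=float(slope + tcrit * se),
        expected_slope=float(expected_slope), t_isometry=float(t_iso),
        p_isometry=float(p_iso), n=int(size.size), r_squared=float(res.rsquared),
    )


def multiple_regression(response: np.ndarray, predictors: pd.DataFrame):
    """OLS of a response on several predictors (intercept added if absent).

    Returns a statsmodels results object (coefficients, SEs, t and two-sided
    p-values with df = n − p).  Rank deficiency raises an error naming the
    collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(predictors).astype(float)
    if "const" not in X.columns and not np.allclose(X.iloc[:, 0], 1.0):
        X = sm.add_constant(X)
    if len(y) < X.shape[1] + 1:
        raise InvalidMeasurementError(
            f"need at least {X.shape[1] + 1} rows for {X.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        _, R, piv = scipy.linalg.qr(X.values, pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [X.columns[j] for j in piv[len(diag):]]
        raise RankDeficiencyError(f"collinear design columns: {sorted(map(str, bad))}")
    return sm.OLS(y, X).fit()


def trait_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson product-moment correlation with its t-based two-sided p (df = n−2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("trait_correlation needs equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# CSV I/O


def _require_columns(df: pd.DataFrame, columns: list, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_specimens_csv(path) -> list[SpecimenMeasurement]:
    df = pd.read_csv(path)
    _require_columns(df, SPECIMEN_COLUMNS, path)
    return [
        SpecimenMeasurement(
            species_id=str(r.species), replicate_id=str(r.replicate),
            body_length=float(r.body_length), head_width=float(r.head_width),
            eye_width=float(r.eye_width), eye_height=float(r.eye_height),
            funiculus_length=float(r.funiculus_length),
            funiculus_width=float(r.funiculus_width),
        )
        for r in df.itertuples()
    ]


def read_sensilla_csv(path) -> list[SensillumCounts]:
    df = pd.read_csv(path)
    _require_columns(df, SENSILLA_COLUMNS, path)
    return [
        SensillumCounts(
            species_id=str(r.species), replicate_id=str(r.replicate), side=str(r.side),
            trichoid=int(r.trichoid), basiconic=int(r.basiconic), coeloconic=int(r.coeloconic),
        )
        for r in df.itertuples()
    ]


def read_discs_csv(path) -> list[DiscMeasurement]:
    df = pd.read_csv(path)
    _require_columns(df, DISC_COLUMNS, path)
    return [
        DiscMeasurement(
            species_id=str(r.species), replicate_id=str(r.replicate),
            eye_portion_area=float(r.eye_portion_area),
            antennal_portion_area=float(r.antennal_portion_area),
        )
        for r in df.itertuples()
    ]


def read_volumes_csv(path) -> list[NeuropilVolumes]:
    df = pd.read_csv(path)
    _require_columns(df, VOLUME_COLUMNS, path)
    return [
        NeuropilVolumes(
            species_id=str(r.species), optic_lobe=float(r.optic_lobe),
            antennal_lobe=float(r.antennal_lobe), central_brain=float(r.central_brain),
        )
        for r in df.itertuples()
    ]


def write_species_table_csv(table: pd.DataFrame, path) -> None:
    """Write the species trait table with fixed column order, 6 significant digits."""
    out = table[SPECIES_TABLE_COLUMNS]
    out.to_csv(path, index=False, float_format="%.6g")
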