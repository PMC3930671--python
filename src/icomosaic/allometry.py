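"""Species-specific crown-width prediction.

Crown width (CW, metres, crown radius = CW/2) is predicted from stem
measurements with the linear form used by the western-US largest-crown-width
regression models:

    CW = b0 + b1·DBH + b2·DBH² + b3·CR + b4·BA + b5·HI

where DBH is stem diameter (cm), CR the live-crown ratio (fraction of total
height, 0–1), BA the plot-level basal area (m²/ha), and HI the Hopkins
bioclimatic index — an affine function of elevation, latitude and longitude
expressing phenological displacement from a western-US reference point
(1 unit per 100 ft of elevation, 4 per degree latitude, 1.25 per degree
longitude).  A predictor enters a species' model only where its inclusion
flag is set.

The shipped per-species coefficient table
(``data/crown_coefficients_synthetic.csv``) is a constructed synthetic
default: the regression form above is the published one, but the
species-level coefficients are plausibility-tuned stand-ins (crown radii
~1–6 m over 5–100 cm DBH), not transcribed fits.  The table is plain CSV
and user-replaceable via :meth:`CrownModel.from_csv`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .core import StemMap

__all__ = [
    "SiteGeography",
    "SpeciesCoefficients",
    "CrownModel",
    "hopkins_index",
    "crown_width",
    "assign_crowns",
]

FT_PER_M = 3.280839895

#: Hopkins reference point (elevation ft, latitude °N, longitude °E).
HOPKINS_REF_ELEV_FT = 5449.0
HOPKINS_REF_LAT = 42.16
HOPKINS_REF_LON = -116.39

#: Minimum admissible predicted crown width (m); negative extrapolations clamp here.
CW_FLOOR_DEFAULT = 0.5

#: Sanity cap on crown radius (m).
MAX_CROWN_RADIUS = 30.0


@dataclass(frozen=True)
class SiteGeography:
    """Site location: elevation (m), latitude and longitude (decimal degrees)."""

    elevation: float
    latitude: float
    longitude: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.latitude <= 90.0):
            raise ValueError("latitude out of range")
        if not (-180.0 <= self.longitude <= 180.0):
            raise ValueError("longitude out of range")


def hopkins_index(geo: SiteGeography) -> float:
    """Hopkins bioclimatic index (affine in elevation, latitude, longitude).

    HI = (E_ft − 5449)/100 · 1.0 + (LAT − 42.16) · 4.0 + (−116.39 − LON) · 1.25

    with elevation converted from metres to feet.  HI = 0 at the reference
    point, and the function is affine, so it averages exactly.
    """
    e_ft = geo.elevation * FT_PER_M
    return (
        (e_ft - HOPKINS_REF_ELEV_FT) / 100.0
        + (geo.latitude - HOPKINS_REF_LAT) * 4.0
        + (HOPKINS_REF_LON - geo.longitude) * 1.25
    )


@dataclass(frozen=True)
class SpeciesCoefficients:
    species: str
    b: tuple[float, float, float, float, float, float]  # b0..b5
    use_dbh: bool = True
    use_dbh2: bool = True
    use_cr: bool = False
    use_ba: bool = False
    use_hi: bool = False
    provenance: str = ""


class CrownModel:
    """Per-species crown-width coefficient sets with fallback rows.

    Unknown species fall back to ``CONIFER_DEFAULT`` (with a warning)
    when ``fallback`` is enabled on the prediction calls.
    """

    def __init__(self, rows: dict[str, SpeciesCoefficients],
                 default_crown_ratio: float = 0.5,
                 cw_floor: float = CW_FLOOR_DEFAULT):
        if not rows:
            raise ValueError("empty coefficient table")
        self.rows = dict(rows)
        self.default_crown_ratio = default_crown_ratio
        self.cw_floor = cw_floor

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CrownModel":
        rows = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows[rec["species"]] = SpeciesCoefficients(
                    species=rec["species"],
                    b=tuple(float(rec[f"b{i}"]) for i in range(6)),
                    use_dbh=bool(int(rec["use_dbh"])),
                    use_dbh2=bool(int(rec["use_dbh2"])),
                    use_cr=bool(int(rec["use_cr"])),
                    use_ba=bool(int(rec["use_ba"])),
                    use_hi=bool(int(rec["use_hi"])),
                    provenance=rec.get("provenance", ""),
                )
        return cls(rows, **kwargs)

    @classmethod
    def load_default(cls, **kwargs) -> "CrownModel":
        """The shipped synthetic default table (see module docstring)."""
        ref = resources.files("icomosaic.data") / "crown_coefficients_synthetic.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path, **kwargs)

    def lookup(self, species: str, fallback: bool = True) -> SpeciesCoefficients:
        if species in self.rows:
            return self.rows[species]
        if not fallback:
            raise KeyError(f"no crown coefficients for species {species!r}")
        fb = "CONIFER_DEFAULT" if "CONIFER_DEFAULT" in self.rows else next(iter(self.rows))
        warnings.warn(f"species {species!r} not in crown table; using {fb}")
        return self.rows[fb]


def crown_width(
    model: CrownModel,
    species: str,
    dbh: float,
    cr: float | None = None,
    ba: float | None = None,
    geo: SiteGeography | None = None,
    fallback: bool = True,
) -> float:
    """Predicted crown width (m) for one stem; crown radius is CW/2.

    ``cr`` defaults to the model's species default when the stem lacks
    height measurements; ``ba`` and ``geo`` are required only by species
    whose BA/HI inclusion flags are set.  Negative extrapolations clamp to
    the configured floor with a warning.
    """
    row = model.lookup(species, fallback=fallback)
    b = row.b
    cw = b[0]
    if row.use_dbh:
        cw += b[1] * dbh
    if row.use_dbh2:
        cw += b[2] * dbh * dbh
    if row.use_cr:
        if cr is None:
            cr = model.default_crown_ratio
        if not (0.0 < cr <= 1.0):
            raise ValueError(f"species {species}: crown ratio must be in (0, 1]")
        cw += b[3] * cr
    if row.use_ba:
        if ba is None:
            raise ValueError(f"species {species}: predictor 'ba' is required")
        cw += b[4] * ba
    if row.use_hi:
        if geo is None:
            raise ValueError(f"species {species}: predictor 'hi' (geo) is required")
        cw += b[5] * hopkins_index(geo)
    if cw < model.cw_floor:
        warnings.warn(
            f"species {species}, dbh {dbh:.1f}: predicted CW {cw:.2f} m below "
            f"floor; clamped to {model.cw_floor} m"
        )
        cw = model.cw_floor
    if cw / 2.0 > MAX_CROWN_RADIUS:
        raise ValueError(f"species {species}: crown radius {cw / 2:.1f} m "
                         "exceeds sanity cap")
    return cw


def plot_basal_area(stemmap: StemMap, live_only: bool = True) -> float:
    """Plot-level basal area in m²/ha."""
    trees = stemmap.live().trees if live_only else stemmap.trees
    ba_m2 = sum(t.basal_area for t in trees)
    return ba_m2 / (stemmap.window.area / 1e4)


def assign_crowns(
    stemmap: StemMap,
    model: CrownModel | None = None,
    geo: SiteGeography | None = None,
    ba: float | None = None,
    fallback: bool = True,
) -> StemMap:
    """Fill ``crown_radius`` on every live tree (in place on copies).

    Snags are excluded: patches and gaps are canopy constructs and snag
    analyses treat snags as points.  Plot-level basal area is computed
    from the map itself when not given.  With ``fallback`` disabled an
    unknown species raises, listing the offending codes.
    """
    model = model or CrownModel.load_default()
    if geo is None:
        needs_hi = {t.species for t in stemmap.trees
                    if t.species in model.rows and model.rows[t.species].use_hi}
        if needs_hi:
            warnings.warn(
                f"no site geography given; species {sorted(needs_hi)} use the "
                "Hopkins index — evaluating at the reference point (HI = 0)"
            )
            geo = SiteGeography(HOPKINS_REF_ELEV_FT / FT_PER_M,
                                HOPKINS_REF_LAT, HOPKINS_REF_LON)
    if ba is None:
        ba = plot_basal_area(stemmap)
    if not fallback:
        unknown = sorted({t.species for t in stemmap.trees
                          if t.species not in model.rows})
        if unknown:
            raise KeyError(f"no crown coefficients for species: {unknown}")
    trees = []
    for t in stemmap.trees:
        t = type(t)(**{**t.__dict__})
        if t.status == "live":
            cw = crown_width(model, t.species, t.dbh, cr=t.crown_ratio,
                             ba=ba, geo=geo, fallback=fallback)
            t.crown_radius = cw / 2.0
        else:
            t.crown_radius = None
        trees.append(t)
    return StemMap(stemmap.window, trees, site_label=stemmap.site_label)
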