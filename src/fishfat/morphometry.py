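"""Per-fish anthropometrics, adipocyte polygon morphometry and diet energy.

Covers the desk-computable measurements of a zebrafish diet-induced
obesity study: body condition indices (BMI in g/cm^2 and Fulton's K),
whole-body fat percentage from a fat-mass readout, adipocyte counts and
areas from manually traced outlines on histology fields of view, and the
Atwater energy content of the daily rations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from statistics import mean, median

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "FishRecord",
    "AdipocyteFieldOfView",
    "DepotSummary",
    "DietComponent",
    "DIET_GROUPS",
    "bmi",
    "fulton_k",
    "body_fat_percent",
    "polygon_area",
    "adipocyte_summary",
    "diet_energy",
    "fish_table",
    "read_fish_csv",
    "read_roi_csv",
    "default_diets",
]

DIET_GROUPS = ("control", "NFD-OF", "HFD-OF")
DEPOTS = ("subcutaneous", "visceral")

#: Atwater energy coefficients (kcal per g) for fat, protein, carbohydrate.
ATWATER_KCAL_PER_G = (9.0, 4.0, 4.0)


def bmi(weight_g: float, length_cm: float) -> float:
    """Fish body mass index: weight / standard length^2 (g/cm^2)."""
    if weight_g <= 0 or length_cm <= 0:
        raise ValueError("weight and length must be positive")
    return weight_g / length_cm**2


def fulton_k(weight_g: float, length_cm: float) -> float:
    """Fulton's condition index, the fisheries convention
    ``K = 100 * W / L^3`` with W in g and L in cm."""
    if weight_g <= 0 or length_cm <= 0:
        raise ValueError("weight and length must be positive")
    return 100.0 * weight_g / length_cm**3


def body_fat_percent(fat_mass_mg: float, weight_g: float) -> float:
    """Whole-body fat percentage from a fat-mass readout (mg) and body
    weight (g)."""
    if weight_g <= 0:
        raise ValueError("weight must be positive")
    if not 0 <= fat_mass_mg <= 1000.0 * weight_g:
        raise ValueError(
            f"fat mass {fat_mass_mg} mg is outside [0, body weight] "
            f"for a {weight_g} g fish"
        )
    return 100.0 * (fat_mass_mg / 1000.0) / weight_g


@dataclass(frozen=True)
class FishRecord:
    """One animal's morphometric measurements."""

    fish_id: str
    group: str
    weight_g: float
    length_cm: float
    fat_mass_mg: float | None = None

    def __post_init__(self) -> None:
        if self.group not in DIET_GROUPS:
            raise ValueError(f"group must be one of {DIET_GROUPS}, got {self.group!r}")
        if self.weight_g <= 0 or self.length_cm <= 0:
            raise ValueError("weight and length must be positive")
        if self.fat_mass_mg is not None and not (
            0 <= self.fat_mass_mg <= 1000.0 * self.weight_g
        ):
            raise ValueError("fat mass must be in [0, body weight]")

    @property
    def bmi(self) -> float:
        return bmi(self.weight_g, self.length_cm)

    @property
    def fulton_k(self) -> float:
        return fulton_k(self.weight_g, self.length_cm)

    @property
    def body_fat_percent(self) -> float | None:
        if self.fat_mass_mg is None:
            return None
        return body_fat_percent(self.fat_mass_mg, self.weight_g)


def polygon_area(outline, pixel_size_um: float = 1.0) -> float:
    """Area of a traced cell outline in um^2.

    ``outline`` is a sequence of (x, y) vertices in pixel coordinates
    (open or closed); the shoelace area is scaled by ``pixel_size_um**2``
    and is independent of vertex order/orientation.  Rejects outlines
    with fewer than 3 distinct vertices or self-intersections.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("outline must be an (n, 2) sequence of vertices")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]  # drop explicit closure
    if len(pts) < 3:
        raise ValueError(f"outline needs at least 3 vertices, got {len(pts)}")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("outline is self-intersecting or degenerate")
    if poly.area == 0:
        raise ValueError("outline encloses zero area")
    return float(poly.area) * pixel_size_um**2


@dataclass
class AdipocyteFieldOfView:
    """One histology field of view with manually traced adipocyte outlines."""

    depot: str
    pixel_size_um: float
    outlines: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.depot not in DEPOTS:
            raise ValueError(f"depot must be one of {DEPOTS}, got {self.depot!r}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        for outline in self.outlines:
            polygon_area(outline, self.pixel_size_um)  # validates

    @property
    def count(self) -> int:
        return len(self.outlines)

    def areas_um2(self) -> list[float]:
        return [polygon_area(o, self.pixel_size_um) for o in self.outlines]


@dataclass(frozen=True)
class DepotSummary:
    """Adipocyte morphometry aggregated over the fields of view of one depot."""

    depot: str
    n_fovs: int
    counts_per_fov: tuple
    total_count: int
    areas_um2: tuple
    mean_area_um2: float | None
    median_area_um2: float | None


def adipocyte_summary(fovs) -> dict[str, DepotSummary]:
    """Per-depot adipocyte count per field of view and area statistics.

    Totals are exact sums over the per-field values, so they are invariant
    under re-partitioning the same outlines among fields of view.
    """
    fovs = list(fovs)
    if not fovs:
        raise ValueError("need at least one field of view")
    out: dict[str, DepotSummary] = {}
    for depot in DEPOTS:
        sel = [f for f in fovs if f.depot == depot]
        counts = tuple(f.count for f in sel)
        areas: list[float] = []
        for f in sel:
            areas.extend(f.areas_um2())
        out[depot] = DepotSummary(
            depot=depot,
            n_fovs=len(sel),
            counts_per_fov=counts,
            total_count=sum(counts),
            areas_um2=tuple(areas),
            mean_area_um2=mean(areas) if areas else None,
            median_area_um2=median(areas) if areas else None,
        )
    return out


@dataclass(frozen=True)
class DietComponent:
    """One feed component of a daily ration with its macronutrient mass
    fractions."""

    name: str
    daily_amount_mg: float
    fat_fraction: float
    protein_fraction: float
    carb_fraction: float

    def __post_init__(self) -> None:
        if self.daily_amount_mg < 0:
            raise ValueError("daily amount must be non-negative")
        fracs = (self.fat_fraction, self.protein_fraction, self.carb_fraction)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("macronutrient fractions must each be in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("macronutrient fractions must sum to at most 1")


def diet_energy(components, atwater=ATWATER_KCAL_PER_G) -> float:
    """Daily ration energy in kcal: sum over components of amount (g)
    times the Atwater-weighted macronutrient content (default 9/4/4
    kcal/g for fat/protein/carbohydrate)."""
    e_fat, e_prot, e_carb = atwater
    if min(atwater) <= 0:
        raise ValueError("Atwater factors must be positive")
    total = 0.0
    for c in components:
        grams = c.daily_amount_mg / 1000.0
        total += grams * (
            c.fat_fraction * e_fat
            + c.protein_fraction * e_prot
            + c.carb_fraction * e_carb
        )
    return total


def default_diets() -> dict[str, tuple[DietComponent, ...]]:
    """The three experimental rations: maintenance artemia (control),
    artemia overfeeding (NFD-OF), and artemia + egg-yolk powder (HFD-OF).

    Artemia cysts are 22% fat / 44% protein / 16% carbohydrate; egg yolk
    powder is 59% fat / 32% protein / 2% carbohydrate.
    """
    artemia = dict(fat_fraction=0.22, protein_fraction=0.44, carb_fraction=0.16)
    yolk = dict(fat_fraction=0.59, protein_fraction=0.32, carb_fraction=0.02)
    return {
        "control": (DietComponent("artemia", 5.0, **artemia),),
        "NFD-OF": (DietComponent("artemia", 60.0, **artemia),),
        "HFD-OF": (
            DietComponent("artemia", 5.0, **artemia),
            DietComponent("egg yolk powder", 30.0, **yolk),
        ),
    }


# ---------------------------------------------------------------------------
# tables

def fish_table(records) -> pd.DataFrame:
    """Per-fish table with derived indices (one row per animal)."""
    rows = []
    for r in records:
        rows.append(
            {
                "fish_id": r.fish_id,
                "group": r.group,
                "weight_g": r.weight_g,
                "length_cm": r.length_cm,
                "fat_mass_mg": r.fat_mass_mg,
                "bmi_g_cm2": r.bmi,
                "fulton_k": r.fulton_k,
                "body_fat_percent": r.body_fat_percent,
            }
        )
    return pd.DataFrame(rows)


def read_fish_csv(path: str | Path) -> list[FishRecord]:
    """Read per-fish measurements from CSV with columns
    ``id, group, weight_g, length_cm[, fat_mass_mg]``."""
    df = pd.read_csv(path)
    required = {"id", "group", "weight_g", "length_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fish table is missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        fat = row.get("fat_mass_mg")
        records.append(
            FishRecord(
                fish_id=str(row["id"]),
                group=str(row["group"]),
                weight_g=float(row["weight_g"]),
                length_cm=float(row["length_cm"]),
                fat_mass_mg=None if fat is None or pd.isna(fat) else float(fat),
            )
        )
    return records


def read_roi_csv(path: str | Path) -> list[AdipocyteFieldOfView]:
    """Read adipocyte outline tables from CSV.

    Long format, one vertex per row, with columns ``fish_id, depot,
    fov_id, polygon_id, vertex_index, x_px, y_px, pixel_size_um``; the
    pixel size must be constant within each field of view.
    """
    df = pd.read_csv(path)
    required = {
        "fish_id", "depot", "fov_id", "polygon_id",
        "vertex_index", "x_px", "y_px", "pixel_size_um",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI table is missing columns {sorted(missing)}")
    fovs = []
    for (fish, depot, fov), g in df.groupby(["fish_id", "depot", "fov_id"], sort=True):
        px = g["pixel_size_um"].unique()
        if len(px) != 1:
            raise ValueError(
                f"field of view {fov!r} of fish {fish!r} has multiple pixel sizes"
            )
        outlines = []
        for _, poly in g.groupby("polygon_id", sort=True):
            poly = poly.sort_values("vertex_index")
            outlines.append(poly[["x_px", "y_px"]].to_numpy(dtype=float))
        fovs.append(
            AdipocyteFieldOfView(
                depot=str(depot), pixel_size_um=float(px[0]), outlines=outlines
            )
        )
    return fovs
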