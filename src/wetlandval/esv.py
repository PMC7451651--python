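"""Ecosystem-service valuation and ecological-storage accounting.

The valuation follows the benefit-transfer scheme of Costanza-type
equivalent-value tables: ESV = sum_i A_i * VC_i, with A_i the area of
land-use class i (hm^2) and VC_i its per-hectare-per-year service-value
coefficient (yuan/hm^2/a). Coefficients may be negative for built and
industrial classes whose net service balance is a cost.

Reporting unit is 万元 (10^4 yuan), the unit in which per-class ESV tables
for county-scale study areas are interpretable; helpers convert explicitly.

The ecological storage state (ESS) is the total ESV per unit area per unit
time, ESS = (1/h) * sum(ESV_i) / sum(A_i) in 万元/hm^2, with h the number
of years the state summarizes (h = 1 for a single year's state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .landcover import LandscapeAreaTable, round_half_up

__all__ = [
    "ValueCoefficientTable",
    "EsvReport",
    "EsvChangeReport",
    "EcoStorageState",
    "builtin_coefficients",
    "DEFAULT_CLASS_BINDING",
    "compute_esv",
    "esv_change",
    "compute_ess",
    "ess_conversion",
    "wanyuan_to_yuan",
    "yuan_to_wanyuan",
]

YUAN_PER_WANYUAN = 10_000.0

#: The eight individual service functions tabulated for water bodies.
SERVICE_FUNCTIONS = (
    "climate_regulation",
    "water_conservation",
    "soil_formation_and_conservation",
    "waste_treatment",
    "biodiversity_maintenance",
    "food_production",
    "raw_material",
    "recreation_and_culture",
)


def wanyuan_to_yuan(x: float) -> float:
    return x * YUAN_PER_WANYUAN


def yuan_to_wanyuan(x: float) -> float:
    return x / YUAN_PER_WANYUAN


@dataclass
class ValueCoefficientTable:
    """Per-class service-value coefficients in yuan/hm^2/a.

    ``breakdown`` optionally gives the per-service composition of a class
    total (provided here for the two water classes, where reclamation
    changes which functions operate: a subsided water body polluted by mine
    drainage performs no soil-formation or recreation function).
    """

    coefficients: dict[str, float]
    breakdown: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, parts in self.breakdown.items():
            if cls not in self.coefficients:
                raise ValueError(f"breakdown for unknown class {cls!r}")
            total = sum(parts.values())
            if abs(total - self.coefficients[cls]) > 1e-6:
                raise ValueError(
                    f"{cls}: breakdown sums to {total}, coefficient is "
                    f"{self.coefficients[cls]}"
                )

    def lookup(self, cls: str) -> float:
        try:
            return self.coefficients[cls]
        except KeyError:
            raise KeyError(f"no value coefficient for class {cls!r}") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, vc in self.coefficients.items():
            row = {"class": cls, "vc_yuan_per_hm2_a": vc}
            row.update(self.breakdown.get(cls, {}))
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ValueCoefficientTable":
        service_cols = [c for c in df.columns
                        if c not in ("class", "vc_yuan_per_hm2_a")]
        coefficients: dict[str, float] = {}
        breakdown: dict[str, dict[str, float]] = {}
        for _, row in df.iterrows():
            name = str(row["class"])
            coefficients[name] = float(row["vc_yuan_per_hm2_a"])
            parts = {c: float(row[c]) for c in service_cols if pd.notna(row[c])}
            if parts:
                breakdown[name] = parts
        return cls(coefficients=coefficients, breakdown=breakdown)

    @classmethod
    def from_csv(cls, path) -> "ValueCoefficientTable":
        return cls.from_frame(pd.read_csv(path))


def builtin_coefficients() -> ValueCoefficientTable:
    """The coefficient scheme for a North China Plain mining-subsidence area.

    Terrestrial classes use the China ecosystem equivalent-value system
    (with mining-city corrections for the industrial and urban classes,
    whose coefficients are negative); the subsided-water column discounts
    the natural-water services degraded by mine-water pollution and zeroes
    soil formation and recreation.
    """
    natural_water = {
        "climate_regulation": 407.0,
        "water_conservation": 18033.2,
        "soil_formation_and_conservation": 8.8,
        "waste_treatment": 16086.6,
        "biodiversity_maintenance": 2203.3,
        "food_production": 88.5,
        "raw_material": 8.8,
        "recreation_and_culture": 3840.2,
    }
    subsided_water = {
        "climate_regulation": 407.0,
        "water_conservation": 4508.3,
        "soil_formation_and_conservation": 0.0,
        "waste_treatment": 4021.65,
        "biodiversity_maintenance": 1101.65,
        "food_production": 88.5,
        "raw_material": 8.8,
        "recreation_and_culture": 0.0,
    }
    return ValueCoefficientTable(
        coefficients={
            "cultivated": 6114.3,
            "woodland": 19334.0,
            "grassland": 6406.5,
            "natural_water": 40676.4,
            "subsided_water": 10135.9,
            "industry_transportation": -5372.1,
            "urban": -1760.5,
        },
        breakdown={"natural_water": natural_water, "subsided_water": subsided_water},
    )


#: Land-cover class -> coefficient class. Transportation land is valued with
#: the industry/transportation coefficient, built-up land with the urban one.
DEFAULT_CLASS_BINDING = {
    "cultivated": "cultivated",
    "woodland": "woodland",
    "grassland": "grassland",
    "transportation": "industry_transportation",
    "natural_water": "natural_water",
    "subsided_water": "subsided_water",
    "built_up": "urban",
}


@dataclass
class EsvReport:
    """Per-class ecosystem-service values in 万元 with contribution ratios."""

    values: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))

    @property
    def contributions(self) -> dict[str, float]:
        """Percent of total per class; negative entries are meaningful."""
        tot = self.total
        if tot == 0:
            return {k: 0.0 for k in self.values}
        return {k: 100.0 * v / tot for k, v in self.values.items()}

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        contrib = self.contributions
        rows = [
            {"class": k, "esv_wanyuan": round_half_up(v, ndigits),
             "contribution_pct": round_half_up(contrib[k], ndigits)}
            for k, v in self.values.items()
        ]
        rows.append({"class": "total", "esv_wanyuan": round_half_up(self.total, ndigits),
                     "contribution_pct": 100.0})
        return pd.DataFrame(rows)


@dataclass
class EsvChangeReport:
    """Per-class and total ESV change (万元) and signed change rate (%)."""

    before: dict[str, float]
    after: dict[str, float]

    @property
    def change(self) -> dict[str, float]:
        return {k: self.after[k] - self.before[k] for k in self.before}

    @property
    def rate(self) -> dict[str, float | None]:
        """(after - before)/before * 100 with the denominator's sign kept.

        A negative-valued class whose cost shrinks therefore prints a
        negative rate (the burden decreased), matching the convention of
        published ESV change tables. None when before == 0.
        """
        out: dict[str, float | None] = {}
        for k, b in self.before.items():
            out[k] = None if b == 0 else (self.after[k] - b) / b * 100.0
        return out

    @property
    def total_change(self) -> float:
        return sum(self.after.values()) - sum(self.before.values())

    @property
    def total_rate(self) -> float | None:
        tot_b = sum(self.before.values())
        return None if tot_b == 0 else self.total_change / tot_b * 100.0

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        change, rate = self.change, self.rate
        rows = [
            {"class": k,
             "esv_before": round_half_up(self.before[k], ndigits),
             "esv_after": round_half_up(self.after[k], ndigits),
             "change_wanyuan": round_half_up(change[k], ndigits),
             "change_rate_pct": None if rate[k] is None else round_half_up(rate[k], ndigits)}
            for k in self.before
        ]
        rows.append({
            "class": "total",
            "esv_before": round_half_up(sum(self.before.values()), ndigits),
            "esv_after": round_half_up(sum(self.after.values()), ndigits),
            "change_wanyuan": round_half_up(self.total_change, ndigits),
            "change_rate_pct": None if self.total_rate is None
            else round_half_up(self.total_rate, ndigits),
        })
        return pd.DataFrame(rows)


@dataclass
class EcoStorageState:
    """Ecological storage state: ESV density in 万元 per hm^2 per year-window."""

    ess: float
    h: int
    total_area_hm2: float

    @property
    def ess_yuan_per_hm2(self) -> float:
        return wanyuan_to_yuan(self.ess)


def compute_esv(
    areas: LandscapeAreaTable,
    coeffs: ValueCoefficientTable | None = None,
    class_binding: dict[str, str] | None = None,
) -> EsvReport:
    """Value each land-cover class: area (hm^2) x coefficient (yuan/hm^2) / 10^4."""
    if coeffs is None:
        coeffs = builtin_coefficients()
    if class_binding is None:
        class_binding = DEFAULT_CLASS_BINDING
    values: dict[str, float] = {}
    for cls, area in areas.areas.items():
        bound = class_binding.get(cls, cls)
        if bound not in coeffs.coefficients:
            if area > 0:
                raise ValueError(
                    f"class {cls!r} has area {area:.2f} hm^2 but no coefficient binding"
                )
            values[cls] = 0.0
            continue
        values[cls] = area * coeffs.lookup(bound) / YUAN_PER_WANYUAN
    return EsvReport(values=values)


def esv_change(before: EsvReport, after: EsvReport) -> EsvChangeReport:
    if set(before.values) != set(after.values):
        raise ValueError("before/after reports have different class universes")
    return EsvChangeReport(before=dict(before.values), after=dict(after.values))


def compute_ess(total_esv_wanyuan: float, total_area_hm2: float, h: int = 1) -> EcoStorageState:
    """Ecological storage state over an h-year window (h = 1: a single year)."""
    if total_area_hm2 <= 0:
        raise ValueError(f"total area must be positive, got {total_area_hm2}")
    if h < 1:
        raise ValueError(f"estimation window h must be >= 1 year, got {h}")
    return EcoStorageState(ess=total_esv_wanyuan / (h * total_area_hm2), h=h,
                           total_area_hm2=total_area_hm2)


def ess_conversion(
    ess_before: EcoStorageState, ess_after: EcoStorageState, years: int
) -> tuple[float, float]:
    """Storage conversion between two states.

    Returns ``(quantity, percent_per_annum)``: the ESS difference in
    万元/hm^2 and its linear annualization, quantity / years x 100. The
    linear (not geometric) annualization is the convention under which
    published conversion-percent tables reproduce.
    """
    if years < 1:
        raise ValueError(f"years must be >= 1, got {years}")
    quantity = ess_after.ess - ess_before.ess
    return quantity, quantity / years * 100.0
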