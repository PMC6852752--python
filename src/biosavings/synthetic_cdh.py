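"""Synthetic purchase-audit generator.

The real audit data behind this kind of analysis is proprietary, so this
module generates purchase records with the statistical structure the
analysis assumes: region-weighted volumes, a fixed percent discount of the
biosimilar against the originator unit price, and a biosimilar share of
units that rises over the study window. Every downstream stage (comparator
matching, collapsing, prices, savings, uptake) is testable against known
ground truth.

Noise model (the audit itself states none, so the generator must):
multiplicative lognormal price noise with a stated coefficient of
variation, mean-corrected so the expected price equals the nominal one; and
negative-binomial unit counts with variance mu * (1 + dispersion * mu), so
dispersion 0 degenerates to deterministic expected counts. Deterministic
counts are apportioned by largest remainder, which conserves configured
monthly totals exactly. Realized unit prices are quantized to whole cents
(audit dollars are cents), the only way cell dollars stay exact integers.
"""

from __future__ import annotations

import math
import zlib
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from ._money import div_round_half_up
from .cdh_data import SECTORS, PurchaseRecord, StudyWindow, load_table1_fixture

#: Default region unit-volume weights, roughly proportional to population.
DEFAULT_REGION_WEIGHTS: Mapping[str, float] = {
    "BC": 0.135,
    "AB": 0.115,
    "SK": 0.030,
    "MB": 0.035,
    "ON": 0.390,
    "QC": 0.230,
    "NB": 0.020,
    "NS": 0.025,
    "PEI/NL": 0.020,
}


class UptakeCurve(BaseModel):
    """Biosimilar unit share over the window, interpolating start -> end."""

    model_config = ConfigDict(frozen=True)

    start_share: float = Field(ge=0.0, le=1.0)
    end_share: float = Field(ge=0.0, le=1.0)
    shape: str = "linear"
    steepness: float = Field(default=8.0, gt=0.0)  # logistic only

    @field_validator("shape")
    @classmethod
    def _shape(cls, v: str) -> str:
        if v not in ("linear", "logistic"):
            raise ValueError("shape must be 'linear' or 'logistic'")
        return v

    def share(self, x: float) -> float:
        """Share at relative time x in [0, 1]; endpoints map exactly to the
        configured start/end shares under both shapes."""
        if self.shape == "linear":
            f = x
        else:
            k = self.steepness
            lo = 1.0 / (1.0 + math.exp(k / 2))
            hi = 1.0 / (1.0 + math.exp(-k / 2))
            f = (1.0 / (1.0 + math.exp(-k * (x - 0.5))) - lo) / (hi - lo)
        return self.start_share + (self.end_share - self.start_share) * f


class MoleculeConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    originator_brand: str
    biosimilar_brand: str
    base_price: float = Field(gt=0.0)  #: originator CAD/unit before multipliers
    discount: float = Field(ge=0.0, lt=1.0)  #: biosimilar price = base x (1 - discount)
    monthly_units: int = Field(gt=0)  #: total units (both products) per month
    uptake: UptakeCurve
    region_price_multipliers: Mapping[str, float] = Field(default_factory=dict)
    form: str = "vial"
    strength: str = "std"

    @field_validator("region_price_multipliers")
    @classmethod
    def _positive(cls, v: Mapping[str, float]) -> Mapping[str, float]:
        if any(m <= 0 for m in v.values()):
            raise ValueError("region price multipliers must be positive")
        return dict(v)


class NoiseConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    price_cv: float = Field(default=0.0, ge=0.0)
    unit_dispersion: float = Field(default=0.0, ge=0.0)


class SynthConfig(BaseModel):
    """Full generator parameterization; see module docstring for the model."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    regions: Mapping[str, float] = Field(default_factory=lambda: dict(DEFAULT_REGION_WEIGHTS))
    window: StudyWindow = Field(default_factory=StudyWindow)
    molecules: Mapping[str, MoleculeConfig]
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    drugstore_fraction: float = Field(default=0.7, ge=0.0, le=1.0)
    seed: int = 0

    @field_validator("window", mode="before")
    @classmethod
    def _window(cls, v):
        if isinstance(v, StudyWindow):
            return v
        if isinstance(v, Mapping):
            return StudyWindow(**v)
        if isinstance(v, str) and ":" in v:
            start, end = v.split(":", 1)
            return StudyWindow(start, end)
        raise ValueError("window must be a StudyWindow, mapping, or 'YYYY-MM:YYYY-MM'")

    @model_validator(mode="after")
    def _weights(self) -> "SynthConfig":
        total = sum(self.regions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region weights must sum to 1 (got {total})")
        if any(w < 0 for w in self.regions.values()):
            raise ValueError("region weights must be non-negative")
        return self


def default_config(seed: int = 0) -> SynthConfig:
    """The studied market at its published scale: three molecules at their
    national average unit prices and discounts, monthly unit volumes equal
    to the published two-year national totals divided by 24 months, and
    uptake rising between the published first- and last-quarter shares."""
    return SynthConfig(
        molecules={
            "insulin glargine": MoleculeConfig(
                originator_brand="Lantus",
                biosimilar_brand="Basaglar",
                base_price=19.26,
                discount=0.211,
                monthly_units=331_134,
                uptake=UptakeCurve(start_share=0.018, end_share=0.148),
            ),
            "filgrastim": MoleculeConfig(
                originator_brand="Neupogen",
                biosimilar_brand="Grastofil",
                base_price=197.53,
                discount=0.178,
                monthly_units=58_990,
                uptake=UptakeCurve(start_share=0.015, end_share=0.436),
            ),
            "infliximab": MoleculeConfig(
                originator_brand="Remicade",
                biosimilar_brand="Inflectra",
                base_price=1001.07,
                discount=0.448,
                monthly_units=94_075,
                uptake=UptakeCurve(start_share=0.003, end_share=0.034),
            ),
        },
        seed=seed,
    )


def apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of an integer total.

    Quotas are total x weight / sum(weights); each cell gets its floor and
    remaining items go to the largest fractional parts (ties to the earlier
    cell). Zero-weight cells never receive items; the result sums to total.
    """
    wsum = float(sum(weights))
    if total < 0 or wsum <= 0:
        raise ValueError("total must be >= 0 and weights must have positive sum")
    quotas = [total * w / wsum for w in weights]
    floors = [int(q) for q in quotas]
    short = total - sum(floors)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - floors[i]), i))
    for i in order[:short]:
        floors[i] += 1
    return floors


def _substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Independent RNG keyed by (seed, *keys): adding a region, month or
    molecule never perturbs draws for the others."""
    hashed = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, *hashed]))


def _price_cents(nominal: float, rng: np.random.Generator | None, cv: float) -> int:
    if cv > 0 and rng is not None:
        sigma = math.sqrt(math.log1p(cv * cv))
        nominal *= rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma)
    return div_round_half_up(round(nominal * 10000), 100)


def _cell_units(expected: float, rng: np.random.Generator | None, dispersion: float) -> int:
    if dispersion <= 0 or rng is None or expected <= 0:
        raise AssertionError("deterministic counts are apportioned, not drawn")
    # NB with mean mu, var mu(1 + dispersion*mu): n = 1/dispersion, p = n/(n+mu)
    n = 1.0 / dispersion
    return int(rng.negative_binomial(n, n / (n + expected)))


def generate_purchases(config: SynthConfig) -> list[PurchaseRecord]:
    """Generate one record per (region, sector, month, product).

    Identical config and seed give identical output. With zero noise the
    monthly totals, the configured uptake shares, and the configured
    discount are reproduced exactly (up to cent quantization of prices).
    """
    months = config.window.months()
    n_months = len(months)
    region_names = list(config.regions)
    cell_weights = [
        config.regions[r] * s
        for r in region_names
        for s in (config.drugstore_fraction, 1.0 - config.drugstore_fraction)
    ]
    disp, cv = config.noise.unit_dispersion, config.noise.price_cv

    records: list[PurchaseRecord] = []
    for molecule in sorted(config.molecules):
        mol = config.molecules[molecule]
        for t, month in enumerate(months):
            x = t / (n_months - 1) if n_months > 1 else 0.0
            share = mol.uptake.share(x)
            biosim_total, orig_total = apportion(mol.monthly_units, [share, 1.0 - share])
            role_cells = {
                "originator": apportion(orig_total, cell_weights),
                "biosimilar": apportion(biosim_total, cell_weights),
            }
            wsum = sum(cell_weights)
            for ri, region in enumerate(region_names):
                rng = _substream(config.seed, molecule, region, t) if (disp > 0 or cv > 0) else None
                mult = mol.region_price_multipliers.get(region, 1.0)
                for si, sector in enumerate(SECTORS):
                    ci = ri * 2 + si
                    for role, role_total in (("originator", orig_total), ("biosimilar", biosim_total)):
                        if disp > 0:
                            expected = role_total * cell_weights[ci] / wsum
                            units = _cell_units(expected, rng, disp) if expected > 0 else 0
                        else:
                            units = role_cells[role][ci]
                        nominal = mol.base_price * mult * (1.0 - (mol.discount if role == "biosimilar" else 0.0))
                        price_cents = _price_cents(nominal, rng, cv)
                        records.append(
                            PurchaseRecord(
                                region=region,
                                sector=sector,
                                month=month,
                                molecule=molecule,
                                brand=mol.biosimilar_brand if role == "biosimilar" else mol.originator_brand,
                                role=role,
                                form=mol.form,
                                strength=mol.strength,
                                dollars_cents=price_cents * units,
                                units=units,
                            )
                        )
    return records


def _ramp_weights(n_months: int, increasing: bool) -> list[float]:
    if increasing:
        return [float(t + 1) for t in range(n_months)]
    return [1.0] * n_months


def generate_paperlike(scenario: str = "table1_national") -> list[PurchaseRecord]:
    """Deterministically spread the packaged national aggregates over
    regions, sectors and months so every aggregation code path is exercised,
    while re-aggregation restores the published national totals exactly.

    Units are apportioned (largest remainder) over region x sector x month
    cells — default region weights, 70/30 drugstore/hospital, flat months
    for originators and a linearly rising ramp for biosimilars — and each
    product's dollars are then apportioned proportionally to cell units, so
    zero-unit cells carry zero dollars.
    """
    if scenario != "table1_national":
        raise ValueError(f"unknown scenario {scenario!r}")
    window = StudyWindow()
    months = window.months()
    region_names = list(DEFAULT_REGION_WEIGHTS)
    cell_meta: list[tuple[str, str, str]] = [
        (r, s, m) for r in region_names for s in SECTORS for m in months
    ]

    records: list[PurchaseRecord] = []
    for rec in load_table1_fixture():
        ramp = _ramp_weights(len(months), increasing=rec.role == "biosimilar")
        weights = [
            DEFAULT_REGION_WEIGHTS[r]
            * (0.7 if s == "drugstore" else 0.3)
            * ramp[months.index(m)]
            for (r, s, m) in cell_meta
        ]
        units = apportion(rec.units, weights)
        dollars = apportion(rec.dollars_cents, [float(u) for u in units])
        for (region, sector, month), u, d in zip(cell_meta, units, dollars):
            if u == 0 and d == 0:
                continue
            records.append(
                PurchaseRecord(
                    region=region,
                    sector=sector,
                    month=month,
                    molecule=rec.molecule,
                    brand=rec.brand,
                    role=rec.role,
                    form=rec.form,
                    strength=rec.strength,
                    dollars_cents=d,
                    units=u,
                )
            )
    return records


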