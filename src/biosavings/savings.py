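"""Realized and unrealized biosimilar cost savings.

The central quantity is the per-unit price delta between an originator
biologic and its biosimilar within a stratum:

    delta = p_originator - p_biosimilar          [CAD per unit]

from which

    realized   = delta x biosimilar units purchased
    unrealized = delta x originator units purchased
    potential  = realized + unrealized           (full-conversion savings)

Two delta conventions are supported. ``cent_rounded`` (default) rounds each
pooled unit price to cents before differencing — the published savings
figures are recoverable only under this convention. ``exact`` differences
the unrounded quotients.

Two stratification conventions are supported and deliberately both kept:
``pooled`` computes one national delta per molecule and applies it to
national unit totals; ``stratified`` computes a delta per region and sums
region savings. The two totals differ slightly whenever regional prices
differ, and published analyses of this kind print both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._money import cents_to_dollars_half_up, div_round_half_up, round_half_down
from .aggregate import unit_price, unit_price_cents
from .cdh_data import ComparatorMap

logger = logging.getLogger(__name__)

CONVENTIONS = ("exact", "cent_rounded")
FALLBACKS = ("national_delta", "skip_region")

TOTAL = "TOTAL"


class DomainError(ValueError):
    """Argument outside the operation's domain."""


@dataclass(frozen=True)
class DiscountSummary:
    """Per-unit price comparison for one molecule in one stratum."""

    molecule: str
    scope: str
    originator_price: float
    biosimilar_price: float
    delta: float  #: originator - biosimilar, CAD/unit; sign preserved
    percent: float  #: delta / originator price
    convention: str = "cent_rounded"


@dataclass(frozen=True)
class SavingsSummary:
    """Savings for one molecule (or the TOTAL row), whole CAD."""

    molecule: str
    realized: int
    unrealized: int
    delta: float | None = None  #: CAD/unit used; None for TOTAL rows
    no_comparator_price: bool = False

    @property
    def potential(self) -> int:
        return self.realized + self.unrealized

    @property
    def percent_realized(self) -> float:
        return self.realized / self.potential if self.potential else 0.0


@dataclass(frozen=True)
class StratifiedSavings:
    """Per-region savings plus cross-region totals."""

    by_region: Mapping[str, tuple[SavingsSummary, ...]]
    totals: tuple[SavingsSummary, ...]
    #: (region, molecule) pairs where the biosimilar sold nothing and the
    #: configured fallback delta was applied.
    fallbacks_used: tuple[tuple[str, str], ...] = field(default_factory=tuple)


def discount(
    originator_price: float,
    biosimilar_price: float,
    convention: str = "cent_rounded",
    molecule: str = "",
    scope: str = "national",
) -> DiscountSummary:
    """Price delta and percent discount of a biosimilar vs its originator.

    ``cent_rounded`` rounds each price half-up to cents before differencing;
    the percent is computed from the rounded values. A biosimilar priced
    above its originator yields a negative delta, preserved as-is.
    """
    if convention not in CONVENTIONS:
        raise DomainError(f"convention must be one of {CONVENTIONS}")
    if originator_price <= 0 or biosimilar_price <= 0:
        raise DomainError("prices must be positive")
    if convention == "cent_rounded":
        o = div_round_half_up(round(originator_price * 10000), 100) / 100
        b = div_round_half_up(round(biosimilar_price * 10000), 100) / 100
    else:
        o, b = float(originator_price), float(biosimilar_price)
    delta = o - b
    if delta < 0:
        logger.warning("%s: biosimilar priced above originator (delta %.4f)", molecule or "product", delta)
    return DiscountSummary(
        molecule=molecule,
        scope=scope,
        originator_price=o,
        biosimilar_price=b,
        delta=delta,
        percent=delta / o,
        convention=convention,
    )


def _molecule_totals(table: pd.DataFrame, molecule: str, role: str) -> tuple[int, int]:
    sub = table[(table["molecule"] == molecule) & (table["role"] == role)]
    return int(sub["dollars_cents"].sum()), int(sub["units"].sum())


def _delta(
    o_cents: int, o_units: int, b_cents: int, b_units: int, convention: str
) -> Fraction:
    """Price delta in cents (exact Fraction; integral under cent_rounded)."""
    if convention == "cent_rounded":
        return Fraction(unit_price_cents(o_cents, o_units) - unit_price_cents(b_cents, b_units))
    return (unit_price(o_cents, o_units) - unit_price(b_cents, b_units)) * 100


def _dollars(delta_cents: Fraction, units: int) -> int:
    """delta x units, rounded half-up to whole dollars."""
    cents = delta_cents * units
    return cents_to_dollars_half_up(div_round_half_up(cents.numerator, cents.denominator))


def _total_row(rows: Sequence[SavingsSummary]) -> SavingsSummary:
    return SavingsSummary(
        molecule=TOTAL,
        realized=sum(r.realized for r in rows),
        unrealized=sum(r.unrealized for r in rows),
    )


def savings_national(
    national_table: pd.DataFrame,
    comparator_maps: Mapping[str, ComparatorMap],
    convention: str = "cent_rounded",
    delta_overrides: Mapping[str, Fraction] | None = None,
) -> list[SavingsSummary]:
    """Savings per molecule from nationally pooled prices, plus a TOTAL row.

    ``national_table`` is a collapse() result at national/full_window scope
    with excluded presentation keys already dropped. ``delta_overrides``
    substitutes an externally computed per-molecule delta (in cents, e.g.
    an unweighted cross-province mean from :func:`province_mean_deltas`)
    for the pooled one.
    """
    if convention not in CONVENTIONS:
        raise DomainError(f"convention must be one of {CONVENTIONS}")
    rows: list[SavingsSummary] = []
    for molecule in sorted(comparator_maps):
        o_cents, o_units = _molecule_totals(national_table, molecule, "originator")
        b_cents, b_units = _molecule_totals(national_table, molecule, "biosimilar")
        if delta_overrides is not None and molecule in delta_overrides:
            delta_cents = Fraction(delta_overrides[molecule])
        elif o_units == 0 or b_units == 0:
            logger.warning("%s: no %s price in window; savings undefined", molecule, "biosimilar" if b_units == 0 else "originator")
            rows.append(SavingsSummary(molecule, 0, 0, delta=None, no_comparator_price=True))
            continue
        else:
            delta_cents = _delta(o_cents, o_units, b_cents, b_units, convention)
        if delta_cents < 0:
            logger.warning("%s: negative delta %s cents/unit propagated", molecule, float(delta_cents))
        rows.append(
            SavingsSummary(
                molecule=molecule,
                realized=_dollars(delta_cents, b_units),
                unrealized=_dollars(delta_cents, o_units),
                delta=float(delta_cents) / 100,
            )
        )
    rows.append(_total_row(rows))
    return rows


def province_mean_deltas(
    region_table: pd.DataFrame,
    comparator_maps: Mapping[str, ComparatorMap],
    convention: str = "cent_rounded",
) -> dict[str, Fraction]:
    """Unweighted mean of per-region price deltas, in cents per unit.

    The alternative reading of an 'average price difference amongst all
    provinces'; regions lacking a price for either product are skipped.
    """
    out: dict[str, Fraction] = {}
    for molecule in sorted(comparator_maps):
        deltas: list[Fraction] = []
        for _, grp in region_table[region_table["molecule"] == molecule].groupby("region"):
            o_cents, o_units = _molecule_totals(grp, molecule, "originator")
            b_cents, b_units = _molecule_totals(grp, molecule, "biosimilar")
            if o_units and b_units:
                deltas.append(_delta(o_cents, o_units, b_cents, b_units, convention))
        if deltas:
            out[molecule] = sum(deltas, Fraction(0)) / len(deltas)
    return out


def savings_stratified(
    region_table: pd.DataFrame,
    comparator_maps: Mapping[str, ComparatorMap],
    convention: str = "cent_rounded",
    fallback: str = "national_delta",
) -> StratifiedSavings:
    """Savings with deltas computed per region, then summed.

    Where a region bought no biosimilar units a price delta is still needed
    (regions with ~0% uptake carry most of the unrealized savings).
    ``fallback='national_delta'`` (default) applies the molecule's pooled
    national delta there; ``'skip_region'`` drops the region for that
    molecule. Fallback use is logged and reported.
    """
    if fallback not in FALLBACKS:
        raise DomainError(f"fallback must be one of {FALLBACKS}")
    if convention not in CONVENTIONS:
        raise DomainError(f"convention must be one of {CONVENTIONS}")

    national_deltas: dict[str, Fraction] = {}
    for molecule in sorted(comparator_maps):
        o_cents, o_units = _molecule_totals(region_table, molecule, "originator")
        b_cents, b_units = _molecule_totals(region_table, molecule, "biosimilar")
        if o_units and b_units:
            national_deltas[molecule] = _delta(o_cents, o_units, b_cents, b_units, convention)

    by_region: dict[str, tuple[SavingsSummary, ...]] = {}
    fallbacks_used: list[tuple[str, str]] = []
    for region in sorted(region_table["region"].unique()):
        sub = region_table[region_table["region"] == region]
        rows: list[SavingsSummary] = []
        for molecule in sorted(comparator_maps):
            o_cents, o_units = _molecule_totals(sub, molecule, "originator")
            b_cents, b_units = _molecule_totals(sub, molecule, "biosimilar")
            if o_units == 0 and b_units == 0:
                continue
            if o_units == 0 or b_units == 0:
                if fallback == "skip_region" or molecule not in national_deltas:
                    logger.warning("%s/%s: no regional price delta; region skipped", region, molecule)
                    rows.append(SavingsSummary(molecule, 0, 0, delta=None, no_comparator_price=True))
                    continue
                delta_cents = national_deltas[molecule]
                fallbacks_used.append((region, molecule))
                logger.warning(
                    "%s/%s: no %s purchases; national delta applied",
                    region, molecule, "biosimilar" if b_units == 0 else "originator",
                )
            else:
                delta_cents = _delta(o_cents, o_units, b_cents, b_units, convention)
            if delta_cents < 0:
                logger.warning("%s/%s: negative delta propagated", region, molecule)
            rows.append(
                SavingsSummary(
                    molecule=molecule,
                    realized=_dollars(delta_cents, b_units),
                    unrealized=_dollars(delta_cents, o_units),
                    delta=float(delta_cents) / 100,
                )
            )
        rows.append(_total_row(rows))
        by_region[region] = tuple(rows)

    totals = []
    for molecule in sorted(comparator_maps):
        per_region = [
            r for rows in by_region.values() for r in rows if r.molecule == molecule
        ]
        if per_region:
            totals.append(
                SavingsSummary(
                    molecule=molecule,
                    realized=sum(r.realized for r in per_region),
                    unrealized=sum(r.unrealized for r in per_region),
                )
            )
    totals.append(_total_row(totals))
    return StratifiedSavings(
        by_region=by_region,
        totals=tuple(totals),
        fallbacks_used=tuple(fallbacks_used),
    )


def scenario_table(
    potentials: Mapping[str, int] | StratifiedSavings,
    fractions: Sequence[float] = (0.25, 0.50, 0.75, 1.00),
) -> pd.DataFrame:
    """Market-share scenario table: cell(f, region) = f x full-conversion
    potential, rounded to whole dollars (exact halves toward zero, matching
    the published tables). Rows are fractions; columns are regions plus a
    'Total' column summing the region cells.
    """
    if isinstance(potentials, StratifiedSavings):
        potentials = {
            region: next(r for r in rows if r.molecule == TOTAL).potential
            for region, rows in potentials.by_region.items()
        }
    for f in fractions:
        if not 0 < f <= 1:
            raise DomainError(f"market-share fraction must be in (0, 1], got {f}")
    regions = list(potentials)
    rows = []
    for f in fractions:
        cells = {region: round_half_down(f * potentials[region]) for region in regions}
        cells["Total"] = sum(cells.values())
        rows.append({"fraction": f, **cells})
    return pd.DataFrame(rows).set_index("fraction")


def sensitivity_eligibility(unrealized_total: float, eligible_fraction: float) -> float:
    """Potential savings when only a fraction of originator units is
    clinically eligible for conversion: eligible_fraction x unrealized."""
    if not 0 <= eligible_fraction <= 1:
        raise DomainError(f"eligible fraction must be in [0, 1], got {eligible_fraction}")
    return eligible_fraction * unrealized_total
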