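from __future__ import annotations

from fractions import Fraction

import pytest

from biosavings.cdh_data import PurchaseRecord, load_table1_fixture


def rec(
    region="ON",
    sector="drugstore",
    month="2016-07",
    molecule="infliximab",
    brand="Remicade",
    role="originator",
    form="vial",
    strength="100 mg",
    dollars_cents=0,
    units=0,
) -> PurchaseRecord:
    return PurchaseRecord(
        region=region,
        sector=sector,
        month=month,
        molecule=molecule,
        brand=brand,
        role=role,
        form=form,
        strength=strength,
        dollars_cents=dollars_cents,
        units=units,
    )


@pytest.fixture(scope="session")
def fixture_records():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def paperlike_records():
    from biosavings.synthetic_cdh import generate_paperlike

    return generate_paperlike("table1_national")


# --- independent savings oracle -------------------------------------------
# Direct enumeration over raw records with exact rational arithmetic; no
# pandas, no shared code with the implementation under test.


def _half_up(x: Fraction) -> int:
    x = Fraction(x)
    if x < 0:
        return -_half_up(-x)
    return (x + Fraction(1, 2)).__floor__()


def oracle_savings(records, pairing, per_region=False, cent_rounded=True):
    """Brute-force realized/unrealized savings by direct enumeration.

    Sums dollars and units per (molecule[, region], role) over matched
    presentation keys, forms exact rational unit prices, optionally rounds
    them to cents (half-up), and multiplies deltas by unit totals. Returns
    {molecule: (realized_dollars, unrealized_dollars)} summed over regions
    when per_region is set. Regions without a biosimilar price fall back to
    the pooled delta, mirroring the documented fallback.
    """
    # presentation keys sold by each role, per molecule
    keys = {}
    for r in records:
        keys.setdefault((r.molecule, r.role), set()).add((r.form, r.strength))
    matched = {
        m: keys.get((m, "originator"), set()) & keys.get((m, "biosimilar"), set())
        for m in pairing
    }

    def totals(pred):
        acc = {}
        for r in records:
            if r.molecule in pairing and (r.form, r.strength) in matched[r.molecule] and pred(r):
                d, u = acc.get((r.molecule, r.role), (0, 0))
                acc[(r.molecule, r.role)] = (d + r.dollars_cents, u + r.units)
        return acc

    def delta_cents(acc, molecule):
        od, ou = acc.get((molecule, "originator"), (0, 0))
        bd, bu = acc.get((molecule, "biosimilar"), (0, 0))
        if ou == 0 or bu == 0:
            return None
        op, bp = Fraction(od, ou), Fraction(bd, bu)
        if cent_rounded:
            op, bp = Fraction(_half_up(op)), Fraction(_half_up(bp))
        return op - bp

    national = totals(lambda r: True)
    out = {}
    for molecule in pairing:
        pooled_delta = delta_cents(national, molecule)
        if not per_region:
            if pooled_delta is None:
                out[molecule] = (0, 0)
                continue
            _, ou = national[(molecule, "originator")]
            _, bu = national[(molecule, "biosimilar")]
            out[molecule] = (
                _half_up(pooled_delta * bu / 100),
                _half_up(pooled_delta * ou / 100),
            )
        else:
            realized = unrealized = 0
            for region in sorted({r.region for r in records}):
                acc = totals(lambda r, region=region: r.region == region)
                od, ou = acc.get((molecule, "originator"), (0, 0))
                bd, bu = acc.get((molecule, "biosimilar"), (0, 0))
                if ou == 0 and bu == 0:
                    continue
                d = delta_cents(acc, molecule)
                if d is None:
                    d = pooled_delta
                if d is None:
                    continue
                realized += _half_up(d * bu / 100)
                unrealized += _half_up(d * ou / 100)
            out[molecule] = (realized, unrealized)
    return out
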