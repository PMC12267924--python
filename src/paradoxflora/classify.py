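"""Continuum classification and its summaries.

Every species in the union of the naturalization and native-status tables
is placed on the range-dynamics continuum:

* ``net_loss`` — threatened somewhere in its native range, no known
  naturalized populations;
* ``paradox`` — naturalized somewhere AND threatened somewhere native
  (the conservation paradox);
* ``net_increase`` — naturalized somewhere, nowhere threatened native;
* ``none`` — neither (kept so the four classes partition the input).

Summaries: prevalence of the paradox among naturalized species, the
global-Red-List contrast, per-country shares and family coverage. Reported
percentages are rounded half-up to one decimal; internal values keep full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .threat import IUCNCategory, is_threatened

NET_LOSS, PARADOX, NET_INCREASE, NONE = "net_loss", "paradox", "net_increase", "none"


def round_half_up(value: float, digits: int = 1) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ParadoxClassification:
    accepted_name: str
    is_naturalized_anywhere: bool
    is_threatened_somewhere_native: bool
    is_globally_threatened: bool = False
    continuum_class: str = NONE


@dataclass(frozen=True)
class PrevalenceSummary:
    n_naturalized: int
    n_paradox: int
    pct_paradox: float          # rounded half-up, 1 decimal
    include_nt: bool
    pct_paradox_exact: float = None
    n_ew: int = 0               # only meaningful for the global contrast


def classify_all(naturalizations: pd.DataFrame, native_statuses: pd.DataFrame,
                 include_nt: bool = False,
                 global_statuses: Optional[pd.DataFrame] = None
                 ) -> list[ParadoxClassification]:
    """Classify every species appearing in either table.

    A species recorded as naturalized and native-threatened in the *same*
    country is a data error (the native/naturalized roles are exclusive per
    country) and raises a validation error listing the offenders.
    """
    nat_pairs = set(zip(naturalizations["speciesName"], naturalizations["countryCode"]))
    thr_pairs = {
        (r.speciesName, r.countryCode)
        for r in native_statuses.itertuples()
        if is_threatened(IUCNCategory(r.category), include_nt)
    }
    offenders = sorted(nat_pairs & thr_pairs)
    if offenders:
        raise ValidationError(
            f"{len(offenders)} species are recorded as naturalized and "
            f"native-threatened in the same country", offenders)

    nat_species = set(naturalizations["speciesName"])
    thr_species = {s for s, _ in thr_pairs}
    glob_thr = set()
    if global_statuses is not None:
        glob_thr = {
            r.speciesName for r in global_statuses.itertuples()
            if is_threatened(IUCNCategory(r.category), include_nt)
        }
    species = sorted(nat_species | set(native_statuses["speciesName"]))
    out = []
    for name in species:
        nat = name in nat_species
        thr = name in thr_species
        klass = (PARADOX if (nat and thr) else NET_LOSS if thr
                 else NET_INCREASE if nat else NONE)
        out.append(ParadoxClassification(
            accepted_name=name, is_naturalized_anywhere=nat,
            is_threatened_somewhere_native=thr,
            is_globally_threatened=name in glob_thr, continuum_class=klass))
    return out


def classification_table(classifications) -> pd.DataFrame:
    return pd.DataFrame([{
        "acceptedName": c.accepted_name,
        "isNaturalizedAnywhere": c.is_naturalized_anywhere,
        "isThreatenedSomewhereNative": c.is_threatened_somewhere_native,
        "isGloballyThreatened": c.is_globally_threatened,
        "continuumClass": c.continuum_class,
    } for c in classifications])


def continuum_counts(classifications) -> dict:
    counts = {NET_LOSS: 0, PARADOX: 0, NET_INCREASE: 0, NONE: 0}
    for c in classifications:
        counts[c.continuum_class] += 1
    return counts


def prevalence(classifications, include_nt: bool = False) -> PrevalenceSummary:
    """Share of naturalized species that are threatened somewhere native."""
    if not classifications:
        raise InputError("no classifications supplied")
    n_nat = sum(c.is_naturalized_anywhere for c in classifications)
    if n_nat == 0:
        raise InputError("zero naturalized species: prevalence undefined")
    n_par = sum(c.is_naturalized_anywhere and c.is_threatened_somewhere_native
                for c in classifications)
    exact = 100.0 * n_par / n_nat
    return PrevalenceSummary(n_naturalized=n_nat, n_paradox=n_par,
                             pct_paradox=round_half_up(exact), include_nt=include_nt,
                             pct_paradox_exact=exact)


def global_threat_share(classifications, global_statuses: pd.DataFrame,
                        include_nt: bool = False) -> PrevalenceSummary:
    """Share of naturalized species threatened on the *global* Red List.

    Species without a global assessment count as NE (present in the
    denominator, never threatened). Also reports the count of naturalized
    species listed globally Extinct in the Wild.
    """
    if not classifications:
        raise InputError("no classifications supplied")
    cats = dict(zip(global_statuses["speciesName"], global_statuses["category"]))
    nat = [c.accepted_name for c in classifications if c.is_naturalized_anywhere]
    if not nat:
        raise InputError("zero naturalized species: share undefined")
    thr = [s for s in nat
           if is_threatened(IUCNCategory(cats.get(s, "NE")), include_nt)]
    n_ew = sum(1 for s in nat if cats.get(s, "NE") == "EW")
    exact = 100.0 * len(thr) / len(nat)
    return PrevalenceSummary(n_naturalized=len(nat), n_paradox=len(thr),
                             pct_paradox=round_half_up(exact), include_nt=include_nt,
                             pct_paradox_exact=exact, n_ew=n_ew)


def country_summary(classifications, naturalizations: pd.DataFrame) -> dict:
    """Per receiving country, the share of its naturalized flora classified
    paradox; plus the unweighted mean across countries with a naturalized
    flora and the count of countries whose share exceeds 50%.

    Countries with zero naturalized species are reported with a null share
    and excluded from the mean (0/0 has no meaning for "of the naturalized
    flora").
    """
    par = {c.accepted_name for c in classifications if c.continuum_class == PARADOX}
    rows = []
    for code, grp in naturalizations.groupby("countryCode"):
        species = set(grp["speciesName"])
        n_par = len(species & par)
        pct = 100.0 * n_par / len(species) if species else np.nan
        rows.append({"countryCode": code, "nNaturalized": len(species),
                     "nParadox": n_par, "pctParadox": pct})
    table = pd.DataFrame(rows).sort_values("countryCode").reset_index(drop=True)
    with_flora = table[table["nNaturalized"] > 0]
    mean = float(with_flora["pctParadox"].mean()) if len(with_flora) else np.nan
    over_half = int((with_flora["pctParadox"] > 50.0).sum())
    return {"table": table, "mean_pct": mean,
            "mean_pct_reported": round_half_up(mean) if np.isfinite(mean) else None,
            "n_countries_over_half": over_half}


def family_coverage(classifications, checklist: pd.DataFrame) -> dict:
    """Share of families with naturalized species that also contain a
    paradox species, plus per-family counts."""
    fam = dict(zip(checklist.loc[checklist["status"] == "accepted", "acceptedName"],
                   checklist.loc[checklist["status"] == "accepted", "family"]))
    missing = [c.accepted_name for c in classifications if c.accepted_name not in fam]
    if missing:
        raise InputError(
            f"{len(missing)} classified species missing from the checklist "
            f"(e.g. {missing[:3]})")
    rows = {}
    for c in classifications:
        f = fam[c.accepted_name]
        rec = rows.setdefault(f, {"family": f, "nSpecies": 0, "nNaturalized": 0,
                                  "nParadox": 0})
        rec["nSpecies"] += 1
        rec["nNaturalized"] += int(c.is_naturalized_anywhere)
        rec["nParadox"] += int(c.continuum_class == PARADOX)
    table = (pd.DataFrame(sorted(rows.values(), key=lambda r: r["family"]))
             .assign(hasParadox=lambda d: d["nParadox"] > 0))
    with_nat = table[table["nNaturalized"] > 0]
    if len(with_nat) == 0:
        pct = 0.0
    else:
        pct = 100.0 * int(with_nat["hasParadox"].sum()) / len(with_nat)
    return {"table": table, "pct_families_with_paradox": pct,
            "pct_reported": round_half_up(pct)}
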