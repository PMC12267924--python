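"""Red List category standardization and the threatened predicate.

National Red Lists use heterogeneous category labels (language, legacy
schemes, regional variants). This module maps them onto the IUCN global
categories through data-driven crosswalks and defines what "threatened"
means: EX, EW, CR, EN or VU, optionally widened to include NT. LC, DD and
NE never satisfy the predicate — absence of assessment is not threat.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputError

log = logging.getLogger(__name__)


class IUCNCategory(str, Enum):
    EX = "EX"  # Extinct (incl. Regionally Extinct in national lists)
    EW = "EW"  # Extinct in the Wild
    CR = "CR"  # Critically Endangered
    EN = "EN"  # Endangered
    VU = "VU"  # Vulnerable
    NT = "NT"  # Near Threatened
    LC = "LC"  # Least Concern
    DD = "DD"  # Data Deficient
    NE = "NE"  # Not Evaluated

    def __str__(self) -> str:  # CSV-friendly
        return self.value


#: Severity order used when comparing national and global assessments.
SEVERITY = {c: i for i, c in enumerate(
    [IUCNCategory.NE, IUCNCategory.DD, IUCNCategory.LC, IUCNCategory.NT,
     IUCNCategory.VU, IUCNCategory.EN, IUCNCategory.CR, IUCNCategory.EW,
     IUCNCategory.EX])}

THREATENED = frozenset({IUCNCategory.EX, IUCNCategory.EW, IUCNCategory.CR,
                        IUCNCategory.EN, IUCNCategory.VU})


def is_threatened(category: IUCNCategory, include_nt: bool = False) -> bool:
    """True iff the category counts as threatened.

    EX/EW/CR/EN/VU always do; NT only when ``include_nt``; LC/DD/NE never.
    """
    category = IUCNCategory(category)
    if category in THREATENED:
        return True
    return include_nt and category is IUCNCategory.NT


@dataclass
class CategoryCrosswalk:
    """Mapping from one national scheme's labels to IUCN categories."""

    scheme_id: str
    entries: Mapping[str, IUCNCategory] = field(default_factory=dict)

    def __post_init__(self):
        self.entries = {str(k): IUCNCategory(v) for k, v in self.entries.items()}


def standardize_category(label: str, crosswalk: CategoryCrosswalk) -> IUCNCategory:
    """Look a national label up in the crosswalk.

    Unmapped labels standardize to NE and are logged; an empty label is an
    input error (a blank cell signals a broken upstream join, not an
    unassessed species).
    """
    if label is None or str(label).strip() == "":
        raise InputError("empty national category label")
    label = str(label).strip()
    try:
        return crosswalk.entries[label]
    except KeyError:
        log.warning("scheme %s: unmapped national category %r -> NE",
                    crosswalk.scheme_id, label)
        return IUCNCategory.NE


def load_crosswalk_csv(path, scheme_id: str | None = None) -> dict[str, CategoryCrosswalk]:
    """Read crosswalk rows (schemeId, nationalLabel, iucnCode) into crosswalks.

    Returns a dict keyed by scheme id; pass ``scheme_id`` to restrict to one.
    """
    walks: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["schemeId"]
            if scheme_id is not None and sid != scheme_id:
                continue
            walks.setdefault(sid, {})[row["nationalLabel"]] = IUCNCategory(row["iucnCode"])
    return {sid: CategoryCrosswalk(sid, entries) for sid, entries in walks.items()}


def default_crosswalk() -> CategoryCrosswalk:
    """The bundled default crosswalk: IUCN codes map to themselves, plus
    common national variants (RE -> EX, long-form English and German labels)."""
    path = Path(__file__).parent / "data" / "crosswalk_default.csv"
    return load_crosswalk_csv(path)["default"]


def standardize_table(df, crosswalk: CategoryCrosswalk, column: str = "category"):
    """Standardize a status table's category column in place-safe copy."""
    out = df.copy()
    out[column] = [standardize_category(v, crosswalk).value for v in out[column]]
    return out


def worst_category(categories: Iterable[IUCNCategory]) -> IUCNCategory:
    """Most severe category in an iterable (NE if empty)."""
    cats = [IUCNCategory(c) for c in categories]
    if not cats:
        return IUCNCategory.NE
    return max(cats, key=SEVERITY.__getitem__)
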