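"""Taxonomic name harmonization against a checklist backbone.

Raw names arriving from naturalization tables, Red Lists and occurrence
downloads are resolved to accepted checklist names (exact hits take
precedence over synonym hits), and the analysis-wide exclusion rules —
hybrids and apomictic genera — are applied. Matching is exact by default;
an optional fuzzy stage (normalized edit similarity >= threshold, every
match logged) exists for dirty inputs but is off unless requested, because
silently fuzzy joins corrupt downstream set intersections.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .errors import InputError

log = logging.getLogger(__name__)

HYBRID_MARKERS = ("×",)  # multiplication sign; " x " handled in tokens


@dataclass(frozen=True)
class SpeciesRecord:
    """One accepted taxon; the unit of classification."""

    accepted_name: str
    genus: str
    family: str
    is_hybrid: bool = False
    in_apomictic_genus: bool = False


class NameMapping(NamedTuple):
    raw_name: str
    accepted_name: Optional[str]
    match_kind: str  # exact | synonym | fuzzy | unmatched


_AUTHOR_TOKEN = re.compile(r"[(.&]")


def normalize_name(raw: str) -> str:
    """Canonicalize a raw name: trim, collapse whitespace, strip author
    strings, capitalize the genus only.

    Authors are detected as the first token after the genus that contains
    an uppercase letter, a period or a parenthesis ("Abies alba Mill." ->
    "Abies alba"). Hybrid markers (multiplication sign or a lone "x")
    are preserved.
    """
    tokens = str(raw).strip().split()
    if not tokens:
        return ""
    out = []
    genus = tokens[0]
    if genus in HYBRID_MARKERS or genus.lower() == "x":
        out.append("×")
        tokens = tokens[1:]
        if not tokens:
            return "×"
        genus = tokens[0]
    out.append(genus[:1].upper() + genus[1:].lower())
    for tok in tokens[1:]:
        if tok in HYBRID_MARKERS or tok.lower() == "x":
            out.append("×")
        elif _AUTHOR_TOKEN.search(tok) or (tok[0].isupper() and not tok.isupper()):
            break  # author citation starts here ("Mill.", "(L.)", "Smith")
        else:
            out.append(tok.lower())  # epithet; all-caps treated as case noise
    return " ".join(out)


def looks_hybrid(name: str) -> bool:
    """Hybrid if the name carries a multiplication sign or a lone 'x' token."""
    if any(m in name for m in HYBRID_MARKERS):
        return True
    return any(t.lower() == "x" for t in str(name).split())


def _similarity(a: str, b: str) -> float:
    return difflib.SequenceMatcher(None, a, b).ratio()


def harmonize_names(raw_names: Sequence[str], checklist: pd.DataFrame,
                    fuzzy: bool = False, fuzzy_threshold: float = 0.95) -> list[NameMapping]:
    """Resolve raw names to accepted checklist names.

    Parameters
    ----------
    raw_names : sequence of str
        Names as they appear in an input table; duplicates collapse to one
        mapping, output order follows first appearance.
    checklist : DataFrame
        Columns rawName, acceptedName, status in {accepted, synonym}.
    fuzzy : bool
        Enable the fuzzy fallback stage (normalized edit similarity against
        accepted names, threshold ``fuzzy_threshold``); each fuzzy match is
        logged.
    """
    if checklist is None or len(checklist) == 0:
        raise InputError("checklist is empty")
    if len(raw_names) == 0:
        raise InputError("no raw names supplied")
    accepted_rows = checklist[checklist["status"] == "accepted"]
    if len(accepted_rows) == 0:
        raise InputError("checklist has no accepted rows")

    accepted = {normalize_name(n): n for n in accepted_rows["acceptedName"]}
    synonyms = {
        normalize_name(r.rawName): r.acceptedName
        for r in checklist[checklist["status"] == "synonym"].itertuples()
    }

    seen: dict[str, NameMapping] = {}
    for raw in raw_names:
        if raw in seen:
            continue
        norm = normalize_name(raw)
        if norm in accepted:
            seen[raw] = NameMapping(raw, accepted[norm], "exact")
        elif norm in synonyms:
            seen[raw] = NameMapping(raw, synonyms[norm], "synonym")
        elif fuzzy:
            best = max(accepted, key=lambda cand: _similarity(norm, cand), default=None)
            if best is not None and _similarity(norm, best) >= fuzzy_threshold:
                log.info("fuzzy match: %r -> %r (similarity %.3f)",
                         raw, accepted[best], _similarity(norm, best))
                seen[raw] = NameMapping(raw, accepted[best], "fuzzy")
            else:
                seen[raw] = NameMapping(raw, None, "unmatched")
        else:
            seen[raw] = NameMapping(raw, None, "unmatched")
    return list(seen.values())


def mapping_table(mappings: Iterable[NameMapping]) -> pd.DataFrame:
    return pd.DataFrame(mappings, columns=["rawName", "acceptedName", "matchKind"])


def apply_mapping(df: pd.DataFrame, mappings: Iterable[NameMapping],
                  column: str) -> pd.DataFrame:
    """Rewrite a table's name column to accepted names, dropping rows whose
    name is unmatched (unmatched names never silently propagate)."""
    lut = {m.raw_name: m.accepted_name for m in mappings}
    out = df.copy()
    out[column] = out[column].map(lut)
    dropped = int(out[column].isna().sum())
    if dropped:
        log.warning("dropping %d rows with unmatched names from %s join", dropped, column)
    return out.dropna(subset=[column]).reset_index(drop=True)


def species_from_checklist(checklist: pd.DataFrame,
                           apomictic_genera: set[str] | frozenset[str] = frozenset()
                           ) -> list[SpeciesRecord]:
    """Build SpeciesRecord rows from the accepted checklist rows."""
    apomictic = {g.capitalize() for g in apomictic_genera}
    records = []
    for r in checklist[checklist["status"] == "accepted"].itertuples():
        genus = str(r.genus) if "genus" in checklist.columns else r.acceptedName.split()[0]
        hybrid = bool(getattr(r, "isHybrid", False)) or looks_hybrid(r.acceptedName)
        records.append(SpeciesRecord(
            accepted_name=r.acceptedName, genus=genus, family=str(r.family),
            is_hybrid=hybrid, in_apomictic_genus=genus in apomictic))
    return records


class ExclusionResult(NamedTuple):
    retained: list
    excluded: list


def apply_exclusions(species: Sequence[SpeciesRecord],
                     apomictic_genera: Iterable[str] = ()) -> ExclusionResult:
    """Drop hybrids and members of apomictic genera.

    A species is a hybrid if its flag says so or its name carries a hybrid
    marker. Returns (retained, excluded); the two partition the input.
    """
    apomictic = {g.capitalize() for g in apomictic_genera}
    retained, excluded = [], []
    for sp in species:
        hybrid = sp.is_hybrid or looks_hybrid(sp.accepted_name)
        apo = sp.in_apomictic_genus or sp.genus in apomictic
        (excluded if (hybrid or apo) else retained).append(sp)
    return ExclusionResult(retained, excluded)
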