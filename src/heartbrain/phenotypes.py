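"""ICD-10 phenotype ascertainment.

Phenotypes (the 11 CVD subtypes, Alzheimer's disease, diabetes, ...) are
defined as sets of ICD-10 code atoms.  An atom is either a prefix such as
``I10`` or ``G30.0`` (matching the code itself and any sub-code extension),
or an inclusive range of 3-character categories such as ``I05-I09``.
A participant is flagged for a phenotype iff at least one of their condition
records matches one of its atoms; the definition is lifetime/cross-sectional,
so record dates play no role.

Matching semantics
------------------
Codes are uppercased and dots are stripped before comparison, so the
``I10.0`` and ``I100`` dialects are equivalent.  A prefix atom matches at the
category boundary: ``I10`` matches ``I10``, ``I10.0`` and ``I100`` but never
``I101``-as-category ``I10``'s neighbour ``I11``.  Ranges compare the
3-character category only, and both endpoints must share the same letter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_ATOM_RE = re.compile(r"^[A-Z][0-9]{2}(\.?[A-Z0-9]{1,4})?$")
_CATEGORY_RE = re.compile(r"^[A-Z][0-9]{2}$")


class CodeSpecError(ValueError):
    """Raised for malformed code atoms, reversed or mixed-letter ranges."""


@dataclass(frozen=True)
class CodeRange:
    """Inclusive range of 3-character ICD-10 categories, e.g. I05-I09."""

    low: str
    high: str

    def __post_init__(self) -> None:
        for end in (self.low, self.high):
            if not _CATEGORY_RE.match(end):
                raise CodeSpecError(f"range endpoint {end!r} is not a 3-character category")
        if self.low[0] != self.high[0]:
            raise CodeSpecError(f"mixed-letter range {self.low}-{self.high}")
        if self.low > self.high:
            raise CodeSpecError(f"reversed range {self.low}-{self.high}")

    def contains(self, category: str) -> bool:
        return self.low <= category <= self.high


@dataclass(frozen=True)
class CodeSet:
    """Named set of ICD-10 prefixes and category ranges defining one phenotype."""

    name: str
    prefixes: tuple[str, ...] = ()
    ranges: tuple[CodeRange, ...] = ()

    def __post_init__(self) -> None:
        if not self.prefixes and not self.ranges:
            raise CodeSpecError(f"code set {self.name!r} has no members")
        for p in self.prefixes:
            if not _ATOM_RE.match(p):
                raise CodeSpecError(f"malformed prefix atom {p!r} in set {self.name!r}")


def _normalize(code: str) -> str:
    return code.strip().upper().replace(".", "")


def parse_code_spec(spec: str, name: str | None = None) -> CodeSet:
    """Parse a comma-separated code spec like ``"I05-I09"`` or ``"I10, I11.0"``.

    Both the ASCII hyphen and the en-dash are accepted as range separators.
    Raises :class:`CodeSpecError` naming the offending token on malformed
    atoms, reversed ranges, or mixed-letter ranges.
    """
    prefixes: list[str] = []
    ranges: list[CodeRange] = []
    for raw in spec.split(","):
        token = raw.strip().upper().replace("–", "-").replace("—", "-")
        if not token:
            continue
        if "-" in token:
            parts = [p.strip() for p in token.split("-")]
            if len(parts) != 2 or not all(parts):
                raise CodeSpecError(f"malformed range token {raw.strip()!r}")
            ranges.append(CodeRange(parts[0], parts[1]))
        else:
            if not _ATOM_RE.match(token):
                raise CodeSpecError(f"malformed code atom {raw.strip()!r}")
            prefixes.append(token)
    return CodeSet(name=name or spec.strip(), prefixes=tuple(prefixes), ranges=tuple(ranges))


def match_code(code: str, code_set: CodeSet) -> bool:
    """True iff ``code`` falls in one of the set's ranges or extends one of
    its prefixes at the category boundary.

    Unparseable codes never match (callers may count them via
    :func:`ascertain`'s diagnostics).
    """
    norm = _normalize(code)
    if len(norm) < 3 or not _CATEGORY_RE.match(norm[:3]):
        return False
    category = norm[:3]
    for rng in code_set.ranges:
        if rng.contains(category):
            return True
    for prefix in code_set.prefixes:
        p = prefix.replace(".", "")
        if norm == p or (norm.startswith(p) and len(p) >= 3):
            return True
    return False


@dataclass
class AscertainmentDiagnostics:
    """Counts of records set aside during ascertainment."""

    n_records: int = 0
    n_unparseable: int = 0
    n_unknown_participant: int = 0
    passthrough_columns: list[str] = field(default_factory=list)


def ascertain(
    records: pd.DataFrame,
    code_sets: list[CodeSet],
    roster: pd.Series | list,
    passthrough: pd.DataFrame | None = None,
    diagnostics: AscertainmentDiagnostics | None = None,
) -> pd.DataFrame:
    """Turn long-format condition records into one boolean flag column per
    phenotype, one row per roster participant.

    Parameters
    ----------
    records
        DataFrame with columns ``participant_id`` and ``icd10_code``.
    code_sets
        Phenotype definitions; names must be unique.
    roster
        Participant ids.  Every id appears exactly once in the output;
        participants with no records get all-false flags.  Records whose id
        is not on the roster are excluded and counted.
    passthrough
        Optional pre-computed boolean flags (indexed or keyed by
        ``participant_id``) for phenotypes ascertained outside ICD-10 coding,
        e.g. questionnaire-derived depression.  Columns are carried into the
        output alongside the code-set flags (missing ids filled False).
    """
    names = [s.name for s in code_sets]
    if len(set(names)) != len(names):
        raise ValueError("code set names must be unique")
    roster_idx = pd.Index(pd.Series(roster), name="participant_id")
    if roster_idx.empty:
        raise ValueError("roster is empty")
    if roster_idx.has_duplicates:
        raise ValueError("roster contains duplicate participant ids")
    diag = diagnostics if diagnostics is not None else AscertainmentDiagnostics()
    diag.n_records = len(records)

    recs = records[["participant_id", "icd10_code"]].copy()
    on_roster = recs["participant_id"].isin(roster_idx)
    diag.n_unknown_participant = int((~on_roster).sum())
    if diag.n_unknown_participant:
        logger.warning("excluded %d records with ids not on the roster", diag.n_unknown_participant)
        recs = recs[on_roster]

    codes = recs["icd10_code"].astype(str)
    norm = codes.str.strip().str.upper().str.replace(".", "", regex=False)
    parseable = norm.str.match(r"^[A-Z][0-9]{2}")
    diag.n_unparseable = int((~parseable).sum())
    if diag.n_unparseable:
        logger.warning("ignored %d unparseable ICD-10 codes", diag.n_unparseable)

    # Match each distinct code once, then propagate to records.
    unique_codes = codes[parseable].drop_duplicates()
    out = pd.DataFrame(False, index=roster_idx, columns=names)
    for cs in code_sets:
        matched = unique_codes[unique_codes.map(lambda c: match_code(c, cs))]
        if matched.empty:
            continue
        hit_ids = recs.loc[codes.isin(matched), "participant_id"].unique()
        out.loc[out.index.intersection(hit_ids), cs.name] = True

    if passthrough is not None:
        pt = passthrough.copy()
        if "participant_id" in pt.columns:
            pt = pt.set_index("participant_id")
        pt = pt.reindex(roster_idx).astype("boolean").fillna(False).astype(bool)
        for col in pt.columns:
            out[col] = pt[col]
            diag.passthrough_columns.append(col)
    return out.reset_index()
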