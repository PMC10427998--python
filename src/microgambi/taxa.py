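"""Curated taxa reference list: parsing, validation, and name lookup.

The microgAMBI reference list assigns each curated microbial taxon to an
ecological group: EGI (sensitive or indifferent to pollution/disturbance),
EGIII (tolerant or opportunistic), or "not assigned" when the ecological
function is unknown.  The list is distributed as a UTF-8 tab-separated file
with eight columns:

    A  correlative row number
    B  taxon name (genera are listed without a trailing "sp.")
    C  NCBI accession (provenance only, never resolved)
    D  WoRMS accession (provenance only, never resolved)
    E  ecological-group assignment
    F  DOI / URI evidence links
    G  supporting literature
    H  curator comments

Columns C, D, F, G and H are carried verbatim; only B and E enter any
computation.  Files with only the first five columns are accepted.
"""

from __future__ import annotations

import enum
import io
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

__all__ = [
    "EcologicalGroup",
    "MatchCategory",
    "MatchLevel",
    "TaxonRecord",
    "TaxaReference",
    "ValidationIssue",
    "ParserOptions",
    "MatchOptions",
    "MatchResult",
    "ReferenceSummary",
    "TaxaListError",
    "normalize_name",
    "parse_taxa_list",
    "lookup",
    "summarize_reference",
    "write_taxa_list",
    "write_issue_report",
    "fetch_official_taxa_list",
]

OFFICIAL_TAXALIST_FILENAME = "microgAMBI-taxalist-version 2023-07-05.tsv"


class EcologicalGroup(str, enum.Enum):
    """Pollution-sensitivity category of a curated taxon."""

    EGI = "EGI"
    EGIII = "EGIII"
    NOT_ASSIGNED = "not assigned"


class MatchCategory(str, enum.Enum):
    """Outcome of routing a queried taxon against the reference list.

    ``NOT_IN_LIST`` marks a taxon absent from the list altogether, as opposed
    to ``NOT_ASSIGNED`` (present but of unknown ecological function).
    """

    EGI = "EGI"
    EGIII = "EGIII"
    NOT_ASSIGNED = "not assigned"
    NOT_IN_LIST = "not in list"


_EG_TO_CATEGORY = {
    EcologicalGroup.EGI: MatchCategory.EGI,
    EcologicalGroup.EGIII: MatchCategory.EGIII,
    EcologicalGroup.NOT_ASSIGNED: MatchCategory.NOT_ASSIGNED,
}


class MatchLevel(str, enum.Enum):
    EXACT = "exact"
    GENUS_FALLBACK = "genus_fallback"
    NONE = "none"


class IssueCode(str, enum.Enum):
    DUPLICATE_NAME = "DUPLICATE_NAME"
    CONFLICTING_EG = "CONFLICTING_EG"
    INVALID_EG_CODE = "INVALID_EG_CODE"
    EMPTY_NAME = "EMPTY_NAME"
    BAD_COLUMN_COUNT = "BAD_COLUMN_COUNT"


@dataclass(frozen=True)
class ValidationIssue:
    row_number: int
    severity: str  # "warning" | "error"
    code: IssueCode
    message: str


class TaxaListError(ValueError):
    """Raised in strict mode when the reference list has error-level issues."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        errs = [i for i in issues if i.severity == "error"]
        super().__init__(
            f"taxa list has {len(errs)} error(s); first: "
            f"row {errs[0].row_number}: {errs[0].code.value}: {errs[0].message}"
            if errs
            else "taxa list validation failed"
        )


@dataclass(frozen=True)
class TaxonRecord:
    """One curated reference entry (one row of the taxa list)."""

    row_number: int
    name: str
    eg: EcologicalGroup
    ncbi_accession: Optional[str] = None
    worms_accession: Optional[str] = None
    evidence_links: tuple[str, ...] = ()
    literature: str = ""
    comments: str = ""


@dataclass
class ReferenceSummary:
    total: int
    n_egi: int
    n_egiii: int
    n_not_assigned: int

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "n_egi": self.n_egi,
            "n_egiii": self.n_egiii,
            "n_not_assigned": self.n_not_assigned,
        }


@dataclass
class TaxaReference:
    """Indexed collection of :class:`TaxonRecord` with a normalized-name map.

    ``lookup_map`` keys are case-folded normalized names; each maps to exactly
    one record (the first seen, when duplicates occur).
    """

    records: list[TaxonRecord] = field(default_factory=list)
    lookup_map: dict[str, TaxonRecord] = field(default_factory=dict)
    version_label: str = ""
    issues: list[ValidationIssue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def lookup(self, query_name: str, options: "MatchOptions | None" = None) -> "MatchResult":
        return lookup(self, query_name, options)

    def summarize(self) -> ReferenceSummary:
        return summarize_reference(self)


# -- EG code dialect -------------------------------------------------------

#: Default mapping of the EG tokens seen in list variants onto the enum.
#: Keys are matched case-insensitively after whitespace normalization.
DEFAULT_EG_DIALECT: Mapping[str, EcologicalGroup] = {
    "i": EcologicalGroup.EGI,
    "eg i": EcologicalGroup.EGI,
    "egi": EcologicalGroup.EGI,
    "iii": EcologicalGroup.EGIII,
    "eg iii": EcologicalGroup.EGIII,
    "egiii": EcologicalGroup.EGIII,
    "not assigned": EcologicalGroup.NOT_ASSIGNED,
    "na": EcologicalGroup.NOT_ASSIGNED,
    "": EcologicalGroup.NOT_ASSIGNED,
}


@dataclass
class ParserOptions:
    """Dialect and strictness controls for :func:`parse_taxa_list`.

    ``header``: treat the first row as a header (default).  ``strict``: abort
    with :class:`TaxaListError` when any error-level issue is found.
    ``eg_dialect``: extensible token → group table (keys compared after
    case-folding and whitespace collapsing).
    """

    header: bool = True
    strict: bool = False
    eg_dialect: Mapping[str, EcologicalGroup] = field(
        default_factory=lambda: dict(DEFAULT_EG_DIALECT)
    )
    version_label: str = ""


@dataclass
class MatchOptions:
    """``genus_fallback``: when an exact normalized match fails, retry with
    the first whitespace-delimited token (the genus) of the query."""

    genus_fallback: bool = False


@dataclass
class MatchResult:
    category: MatchCategory
    matched_record: Optional[TaxonRecord]
    match_level: MatchLevel


# -- name normalization ----------------------------------------------------

_WS_RUN = re.compile(r"[\s_]+")
_SP_TOKENS = frozenset({"sp", "sp.", "spp", "spp."})


def normalize_name(raw: str) -> str:
    """Canonicalize a taxon name for matching against the reference list.

    Leading/trailing whitespace is stripped; runs of whitespace and
    underscores collapse to single spaces; trailing "sp.", "sp" or "spp."
    tokens (any case) are removed, because genera are curated without them.
    Case is preserved for display; comparisons case-fold separately (see
    :func:`_key`).  Idempotent; whitespace-only input yields "".

    >>> normalize_name("Vibrio sp.")
    'Vibrio'
    >>> normalize_name("  Pseudomonas_aeruginosa ")
    'Pseudomonas aeruginosa'
    """
    tokens = _WS_RUN.sub(" ", raw).strip().split(" ")
    while tokens and tokens[-1].casefold() in _SP_TOKENS:
        tokens.pop()
    return " ".join(tokens)


def _key(name: str) -> str:
    """Case-folded comparison key of a normalized name."""
    return normalize_name(name).casefold()


# -- parsing ---------------------------------------------------------------

def _as_lines(source: Union[str, Path, IO]) -> Iterable[str]:
    if isinstance(source, (str, Path)) and "\t" not in str(source) and "\n" not in str(source):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
        return
    if isinstance(source, str):
        yield from io.StringIO(source)
        return
    if isinstance(source, bytes):
        yield from io.StringIO(source.decode("utf-8"))
        return
    for line in source:
        yield line.decode("utf-8") if isinstance(line, bytes) else line


def _split_links(cell: str) -> tuple[str, ...]:
    parts = re.split(r"[;,\s]+", cell.strip())
    return tuple(p for p in parts if p)


#: Minimum number of columns a data row needs: A..E (name is B, EG is E).
MIN_COLUMNS = 5
N_COLUMNS = 8


def parse_taxa_list(
    source: Union[str, Path, IO],
    options: ParserOptions | None = None,
) -> TaxaReference:
    """Parse a taxa-reference TSV into a validated :class:`TaxaReference`.

    One :class:`TaxonRecord` per data row.  Structural problems are collected
    as :class:`ValidationIssue` rather than raised, except in strict mode
    where any error-level issue aborts with :class:`TaxaListError`.

    Duplicate handling follows the curation intent of one assignment per
    taxon: a repeated normalized name with the *same* EG is a warning (the
    first record wins); with a *different* EG it is an error, because the
    index would be ambiguous.
    """
    opts = options or ParserOptions()
    records: list[TaxonRecord] = []
    lookup_map: dict[str, TaxonRecord] = {}
    issues: list[ValidationIssue] = []

    lines = _as_lines(source)
    row_idx = 0
    first = True
    for line in lines:
        row_idx += 1
        if first and opts.header:
            first = False
            continue
        first = False
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < MIN_COLUMNS:
            issues.append(
                ValidationIssue(
                    row_idx, "error", IssueCode.BAD_COLUMN_COUNT,
                    f"expected at least {MIN_COLUMNS} tab-separated columns, got {len(fields)}",
                )
            )
            continue
        fields = (fields + [""] * N_COLUMNS)[:N_COLUMNS]
        raw_num, raw_name, ncbi, worms, raw_eg, links, lit, comments = (
            f.strip() for f in fields
        )
        try:
            row_number = int(raw_num)
        except ValueError:
            row_number = row_idx

        name = normalize_name(raw_name)
        if not name:
            issues.append(
                ValidationIssue(row_idx, "error", IssueCode.EMPTY_NAME,
                                "taxon name empty after normalization")
            )
            continue

        eg_token = _WS_RUN.sub(" ", raw_eg).strip().casefold()
        eg = opts.eg_dialect.get(eg_token)
        if eg is None:
            issues.append(
                ValidationIssue(row_idx, "error", IssueCode.INVALID_EG_CODE,
                                f"unrecognized ecological-group code {raw_eg!r}")
            )
            continue

        record = TaxonRecord(
            row_number=row_number,
            name=name,
            eg=eg,
            ncbi_accession=ncbi or None,
            worms_accession=worms or None,
            evidence_links=_split_links(links),
            literature=lit,
            comments=comments,
        )
        key = name.casefold()
        if key in lookup_map:
            prior = lookup_map[key]
            if prior.eg is record.eg:
                issues.append(
                    ValidationIssue(
                        row_idx, "warning", IssueCode.DUPLICATE_NAME,
                        f"duplicate entry for {name!r} (first seen row "
                        f"{prior.row_number}); first record wins",
                    )
                )
            else:
                issues.append(
                    ValidationIssue(
                        row_idx, "error", IssueCode.CONFLICTING_EG,
                        f"{name!r} assigned to {record.eg.value} here but "
                        f"{prior.eg.value} at row {prior.row_number}",
                    )
                )
            continue
        lookup_map[key] = record
        records.append(record)

    if opts.strict and any(i.severity == "error" for i in issues):
        raise TaxaListError(issues)
    return TaxaReference(
        records=records,
        lookup_map=lookup_map,
        version_label=opts.version_label,
        issues=issues,
    )


# -- queries ---------------------------------------------------------------

def lookup(
    ref: TaxaReference,
    query_name: str,
    options: MatchOptions | None = None,
) -> MatchResult:
    """Route a queried taxon name into one of the four categories.

    Exact match on normalized, case-folded names first; with
    ``genus_fallback`` enabled, an unmatched binomial is retried as its first
    token.  ``NOT_IN_LIST`` is a valid outcome, not an error.
    """
    opts = options or MatchOptions()
    key = _key(query_name)
    rec = ref.lookup_map.get(key)
    if rec is not None:
        return MatchResult(_EG_TO_CATEGORY[rec.eg], rec, MatchLevel.EXACT)
    if opts.genus_fallback and " " in key:
        genus = key.split(" ", 1)[0]
        rec = ref.lookup_map.get(genus)
        if rec is not None:
            return MatchResult(_EG_TO_CATEGORY[rec.eg], rec, MatchLevel.GENUS_FALLBACK)
    return MatchResult(MatchCategory.NOT_IN_LIST, None, MatchLevel.NONE)


def summarize_reference(ref: TaxaReference) -> ReferenceSummary:
    """Count records per ecological group (records, not reads)."""
    n_egi = sum(1 for r in ref.records if r.eg is EcologicalGroup.EGI)
    n_egiii = sum(1 for r in ref.records if r.eg is EcologicalGroup.EGIII)
    n_na = sum(1 for r in ref.records if r.eg is EcologicalGroup.NOT_ASSIGNED)
    return ReferenceSummary(len(ref.records), n_egi, n_egiii, n_na)


# -- serialization ---------------------------------------------------------

_EG_OUT = {
    EcologicalGroup.EGI: "I",
    EcologicalGroup.EGIII: "III",
    EcologicalGroup.NOT_ASSIGNED: "not assigned",
}

_HEADER = "\t".join(
    ["n", "taxon", "ncbi_accession", "worms_accession", "EG",
     "evidence_links", "literature", "comments"]
)


def write_taxa_list(ref: TaxaReference, destination: Union[str, Path, IO]) -> None:
    """Serialize a reference back to the eight-column TSV layout."""
    own = isinstance(destination, (str, Path))
    fh = open(destination, "w", encoding="utf-8") if own else destination
    try:
        fh.write(_HEADER + "\n")
        for rec in ref.records:
            fh.write(
                "\t".join(
                    [
                        str(rec.row_number),
                        rec.name,
                        rec.ncbi_accession or "",
                        rec.worms_accession or "",
                        _EG_OUT[rec.eg],
                        ";".join(rec.evidence_links),
                        rec.literature,
                        rec.comments,
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def write_issue_report(issues: Iterable[ValidationIssue], destination: IO) -> None:
    """Write validation issues as TSV (row_number, severity, code, message)."""
    destination.write("row_number\tseverity\tcode\tmessage\n")
    for i in issues:
        destination.write(f"{i.row_number}\t{i.severity}\t{i.code.value}\t{i.message}\n")


OFFICIAL_TAXALIST_URL = (
    "https://ftp.cngb.org/pub/gigadb/pub/10.5524/102001_103000/102460/"
    "microgAMBI-taxalist-version%202023-07-05.tsv"
)


def fetch_official_taxa_list(destination: Union[str, Path], url: str = OFFICIAL_TAXALIST_URL,
                             timeout: float = 60.0) -> Path:
    """Download the official curated taxa list (requires network access).

    Convenience only: every computation accepts any list in the documented
    TSV layout, so offline users can supply their own copy.
    """
    destination = Path(destination)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        destination.write_bytes(resp.read())
    return destination
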