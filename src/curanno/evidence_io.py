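"""Parsers and writers for the tabular evidence the curation rules consume.

Four dialects are handled:

* protein alignment hits — 14-column tab-separated files: the standard
  12 columns of BLAST/DIAMOND tabular output (``outfmt 6``) plus query
  and subject lengths (``qlen``, ``slen``).  Both lengths are required
  because the curation thresholds are coverage fractions on both sides
  of the alignment; files without them are rejected, not approximated.
* per-transcript functional evidence tables (product name, similarity
  provenance, gene-family provenance, optional contaminant flag).
* orthogroup tables in the OrthoFinder ``Orthogroups.tsv`` dialect
  (one column per species, cells are ``", "``-separated member ids).
* single-line BUSCO completeness summaries,
  ``C:95.0%[S:90.0%,D:5.0%],F:2.0%,M:3.0%,n:100``.

Every reader has a matching writer and ``read(write(x)) == x`` on the
domain types; the synthetic-data generator uses the writers, so format
round trips are exercised end to end.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

DB_TAGS = ("microbial_donor", "plant_donor", "recipient", "nr")

HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
).split()


class EvidenceError(ValueError):
    """Raised for malformed evidence tables."""


@dataclass(frozen=True)
class AlignmentHit:
    """One tabular homology hit, tagged with its database partition.

    Subject coordinates are normalized on read so sstart <= send
    (minus-strand hits report them reversed).
    """

    query_id: str
    subject_id: str
    db_tag: str
    pident: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise EvidenceError(
                f"hit {self.query_id!r}: query coordinates "
                f"{self.qstart}..{self.qend} outside 1..{self.qlen}")
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise EvidenceError(
                f"hit {self.query_id!r}: subject coordinates "
                f"{self.sstart}..{self.send} outside 1..{self.slen}")
        if self.evalue < 0:
            raise EvidenceError(f"hit {self.query_id!r}: negative e-value")

    @property
    def query_cov(self) -> float:
        return (self.qend - self.qstart + 1) / self.qlen

    @property
    def subject_cov(self) -> float:
        return (self.send - self.sstart + 1) / self.slen


@dataclass
class FunctionalRecord:
    """Per-transcript functional evidence, EnTAP-style.

    ``similarity_db_tag`` and the ``family_tags`` elements take values
    ``microbial`` / ``non_microbial``.  When ``contaminant_flag`` is set
    it overrides the derivation rule in :mod:`curanno.contamination`.
    """

    transcript_id: str
    product: str | None = None
    has_similarity_hit: bool = False
    similarity_db_tag: str | None = None
    family_tags: frozenset[str] = frozenset()
    contaminant_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.has_similarity_hit and self.similarity_db_tag is None:
            raise EvidenceError(
                f"record {self.transcript_id!r}: similarity hit without a db tag")
        self.family_tags = frozenset(self.family_tags)

    @property
    def has_any_evidence(self) -> bool:
        return bool(self.product) or self.has_similarity_hit or bool(self.family_tags)


@dataclass
class OrthogroupTable:
    """Orthogroup id -> species -> member gene ids."""

    species: list[str]
    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def group_size(self, og_id: str) -> int:
        return sum(len(members) for members in self.groups[og_id].values())

    def all_members(self, og_id: str) -> list[str]:
        return [m for sp in self.species for m in self.groups[og_id].get(sp, [])]

    def n_species_in(self, og_id: str) -> int:
        return sum(1 for sp in self.species if self.groups[og_id].get(sp))


@dataclass(frozen=True)
class BuscoSummary:
    """The five percentages of a BUSCO short-summary line."""

    complete_pct: float
    single_pct: float
    duplicated_pct: float
    fragmented_pct: float
    missing_pct: float
    n_markers: int = 0

    def __post_init__(self) -> None:
        if abs(self.complete_pct - (self.single_pct + self.duplicated_pct)) > 0.1:
            raise EvidenceError("complete% != single% + duplicated%")
        total = self.complete_pct + self.fragmented_pct + self.missing_pct
        if abs(total - 100.0) > 0.2:
            raise EvidenceError(f"C+F+M = {total}, expected 100")


# ---------------------------------------------------------------------------
# alignment hits

def read_hits(stream: Iterable[str] | TextIO, db_tag: str) -> list[AlignmentHit]:
    """Read a 14-column tabular hit file; '#' comment lines are skipped."""
    if db_tag not in DB_TAGS:
        raise EvidenceError(f"unknown db tag {db_tag!r}; expected one of {DB_TAGS}")
    hits = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 14:
            raise EvidenceError(
                f"line {lineno}: expected 14 tab-separated columns "
                f"(outfmt 6 + qlen + slen), got {len(fields)}")
        try:
            sstart, send = int(fields[8]), int(fields[9])
            if send < sstart:
                sstart, send = send, sstart
            hits.append(AlignmentHit(
                query_id=fields[0], subject_id=fields[1], db_tag=db_tag,
                pident=float(fields[2]), aln_length=int(fields[3]),
                mismatches=int(fields[4]), gap_opens=int(fields[5]),
                qstart=int(fields[6]), qend=int(fields[7]),
                sstart=sstart, send=send,
                evalue=float(fields[10]), bitscore=float(fields[11]),
                qlen=int(fields[12]), slen=int(fields[13]),
            ))
        except ValueError as exc:
            if isinstance(exc, EvidenceError):
                raise EvidenceError(f"line {lineno}: {exc}") from exc
            raise EvidenceError(f"line {lineno}: non-numeric field ({exc})") from exc
    return hits


def write_hits(hits: Iterable[AlignmentHit]) -> list[str]:
    lines = []
    for h in hits:
        lines.append("\t".join(str(v) for v in (
            h.query_id, h.subject_id, h.pident, h.aln_length, h.mismatches,
            h.gap_opens, h.qstart, h.qend, h.sstart, h.send,
            h.evalue, h.bitscore, h.qlen, h.slen)))
    return lines


def read_hits_file(path, db_tag: str) -> list[AlignmentHit]:
    with open(path) as fh:
        return read_hits(fh, db_tag)


# ---------------------------------------------------------------------------
# functional records

FUNCTIONAL_COLUMNS = ("transcript_id", "product", "similarity_db_tag",
                      "family_tags", "contaminant_flag")


def read_functional(stream: Iterable[str] | TextIO) -> list[FunctionalRecord]:
    """Read the per-transcript functional-evidence TSV.

    Columns: transcript_id, product, similarity_db_tag, family_tags
    (comma separated), contaminant_flag (true/false/empty).
    """
    records = []
    it = iter(stream)
    header = next(it, None)
    if header is None:
        return records
    cols = tuple(header.rstrip("\n").split("\t"))
    if cols != FUNCTIONAL_COLUMNS:
        raise EvidenceError(f"unexpected functional table header {cols}")
    for lineno, raw in enumerate(it, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise EvidenceError(f"line {lineno}: expected 5 columns, got {len(fields)}")
        tx_id, product, sim_tag, fam, flag = fields
        records.append(FunctionalRecord(
            transcript_id=tx_id,
            product=product or None,
            has_similarity_hit=bool(sim_tag),
            similarity_db_tag=sim_tag or None,
            family_tags=frozenset(t for t in fam.split(",") if t),
            contaminant_flag=None if flag == "" else flag == "true",
        ))
    return records


def write_functional(records: Iterable[FunctionalRecord]) -> list[str]:
    lines = ["\t".join(FUNCTIONAL_COLUMNS)]
    for r in records:
        flag = "" if r.contaminant_flag is None else ("true" if r.contaminant_flag else "false")
        lines.append("\t".join([
            r.transcript_id,
            r.product or "",
            r.similarity_db_tag or "",
            ",".join(sorted(r.family_tags)),
            flag,
        ]))
    return lines


def read_functional_file(path) -> list[FunctionalRecord]:
    with open(path) as fh:
        return read_functional(fh)


# ---------------------------------------------------------------------------
# orthogroups

def read_orthogroups(stream: Iterable[str] | TextIO) -> OrthogroupTable:
    """Read an Orthogroups.tsv-dialect table.

    Cells are ", "-separated member ids (bare "," tolerated).  A member
    id appearing in more than one orthogroup is a hard error.
    """
    it = iter(stream)
    header = next(it, None)
    if header is None:
        raise EvidenceError("empty orthogroup table")
    cols = header.rstrip("\n").split("\t")
    if not cols or cols[0] != "Orthogroup":
        raise EvidenceError("first column must be 'Orthogroup'")
    species = cols[1:]
    table = OrthogroupTable(species=species)
    seen: dict[str, str] = {}
    for lineno, raw in enumerate(it, start=2):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise EvidenceError(
                f"line {lineno}: expected {len(cols)} columns, got {len(fields)}")
        og_id = fields[0]
        if og_id in table.groups:
            raise EvidenceError(f"line {lineno}: duplicate orthogroup id {og_id!r}")
        row: dict[str, list[str]] = {}
        for sp, cell in zip(species, fields[1:]):
            members = [m for m in (cell.split(", ") if ", " in cell else cell.split(","))
                       if m.strip()]
            members = [m.strip() for m in members]
            for m in members:
                if m in seen:
                    raise EvidenceError(
                        f"gene {m!r} appears in both {seen[m]!r} and {og_id!r}")
                seen[m] = og_id
            row[sp] = members
        table.groups[og_id] = row
    return table


def write_orthogroups(table: OrthogroupTable) -> list[str]:
    lines = ["\t".join(["Orthogroup"] + table.species)]
    for og_id in sorted(table.groups):
        row = table.groups[og_id]
        lines.append("\t".join(
            [og_id] + [", ".join(row.get(sp, [])) for sp in table.species]))
    return lines


def read_orthogroups_file(path) -> OrthogroupTable:
    with open(path) as fh:
        return read_orthogroups(fh)


# ---------------------------------------------------------------------------
# BUSCO

_BUSCO_RE = re.compile(
    r"^C:(?P<c>\d+(?:\.\d+)?)%\[S:(?P<s>\d+(?:\.\d+)?)%,D:(?P<d>\d+(?:\.\d+)?)%\],"
    r"F:(?P<f>\d+(?:\.\d+)?)%,M:(?P<m>\d+(?:\.\d+)?)%,n:(?P<n>\d+)$")


def parse_busco_line(text: str) -> BuscoSummary:
    """Parse a one-line BUSCO summary such as
    ``C:95.0%[S:90.0%,D:5.0%],F:2.0%,M:3.0%,n:100``."""
    match = _BUSCO_RE.match(text.strip())
    if match is None:
        raise EvidenceError(f"malformed BUSCO summary line: {text!r}")
    return BuscoSummary(
        complete_pct=float(match["c"]),
        single_pct=float(match["s"]),
        duplicated_pct=float(match["d"]),
        fragmented_pct=float(match["f"]),
        missing_pct=float(match["m"]),
        n_markers=int(match["n"]),
    )


def format_busco_line(summary: BuscoSummary) -> str:
    return (f"C:{summary.complete_pct:.1f}%[S:{summary.single_pct:.1f}%,"
            f"D:{summary.duplicated_pct:.1f}%],F:{summary.fragmented_pct:.1f}%,"
            f"M:{summary.missing_pct:.1f}%,n:{summary.n_markers}")


def _as_stream(lines_or_text) -> Iterable[str]:
    if isinstance(lines_or_text, str):
        return io.StringIO(lines_or_text)
    return lines_or_text
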