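"""Reading and writing topology annotation.

Two formats are supported, both plain text:

* a **minimal UniProt-text-like flat file** (dialect documented below), and
* a **segment table** (TSV) carrying accession, sequence, TMH spans and a
  per-TMH orientation flag.

Flat-file dialect
-----------------
Only the following line types are interpreted; all other line types are
ignored (they are not errors, so genuine UniProt text largely parses)::

    ID   <accession>
    CC   <key>=<value>                      (free meta tags, repeated)
    FT   TRANSMEM   <start>..<end>
    FT   INTRAMEM   <start>..<end>
    FT   TOPO_DOM   <start>..<end>   <label text>
    SQ   SEQUENCE   <n> AA
         <sequence lines, whitespace ignored>
    //

Coordinates on disk are 1-based inclusive (the source-database convention);
in memory everything is 0-based half-open.  Unknown FT kinds produce a
logged warning and are skipped.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO, Union

from Bio.Seq import Seq
from Bio.SeqIO import write as _seqio_write
from Bio.SeqRecord import SeqRecord

from .records import MembraneFeature, ProteinRecord, RecordError, TopologyDomain

logger = logging.getLogger(__name__)

_KNOWN_FT = ("TRANSMEM", "INTRAMEM", "TOPO_DOM")

Source = Union[str, Path, TextIO]


@dataclass
class ParseResult:
    """Parsed records plus the per-record errors that were reported."""

    records: list[ProteinRecord] = field(default_factory=list)
    errors: list[RecordError] = field(default_factory=list)

    def raise_if_errors(self) -> "ParseResult":
        if self.errors:
            raise self.errors[0]
        return self


def _read_source(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    path = Path(source)
    return path.read_text()


# ---------------------------------------------------------------------------
# flat file
# ---------------------------------------------------------------------------

def parse_flatfile(text: str, strict: bool = False) -> ParseResult:
    """Parse flat-file content into protein records.

    Records failing validation are reported in ``ParseResult.errors`` (or
    raised immediately when ``strict``), never silently dropped.
    """
    result = ParseResult()
    blocks: list[list[str]] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "//":
            if current:
                blocks.append(current)
                current = []
            continue
        if line.startswith("ID") and current and any(
            l.startswith("ID") for l in current
        ):
            blocks.append(current)
            current = []
        if line.strip():
            current.append(line)
    if current:
        blocks.append(current)

    for block in blocks:
        try:
            record = _parse_block(block, strict=strict)
        except RecordError as err:
            if strict:
                raise
            result.errors.append(err)
        else:
            result.records.append(record)
    return result


def _parse_block(lines: list[str], strict: bool) -> ProteinRecord:
    accession = "<unknown>"
    meta: dict[str, str] = {}
    features: list[MembraneFeature] = []
    domains: list[TopologyDomain] = []
    seq_parts: list[str] = []
    in_sq = False

    for line in lines:
        tag = line[:2]
        if tag == "ID":
            accession = line[2:].strip().split()[0]
            in_sq = False
        elif tag == "CC":
            in_sq = False
            body = line[2:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
        elif tag == "FT":
            in_sq = False
            kind, span, rest = _split_ft(line, accession)
            if kind not in _KNOWN_FT:
                logger.warning("%s: ignoring unknown feature kind %r", accession, kind)
                continue
            start1, end1 = span
            if start1 > end1 or start1 < 1:
                raise RecordError(
                    accession, f"malformed {kind} coordinates {start1}..{end1}"
                )
            start, end = start1 - 1, end1  # to 0-based half-open
            if kind == "TOPO_DOM":
                domains.append(TopologyDomain(start, end, rest))
            else:
                features.append(MembraneFeature(kind, start, end))
        elif tag == "SQ":
            in_sq = True
        elif in_sq:
            seq_parts.append("".join(line.split()))

    sequence = "".join(seq_parts).upper()
    if not sequence:
        raise RecordError(accession, "record has no sequence block")
    try:
        record = ProteinRecord(accession, sequence, features, domains, meta)
        record.validate(strict=strict)
    except ValueError as err:
        if isinstance(err, RecordError):
            raise
        raise RecordError(accession, str(err)) from err
    return record


def _split_ft(line: str, accession: str) -> tuple[str, tuple[int, int], str]:
    parts = line[2:].strip().split(None, 2)
    if len(parts) < 2:
        raise RecordError(accession, f"malformed FT line: {line.strip()!r}")
    kind = parts[0]
    span_text = parts[1]
    rest = parts[2].strip() if len(parts) > 2 else ""
    sep = ".." if ".." in span_text else None
    try:
        if sep:
            s, e = span_text.split("..")
        else:
            s, e = span_text, rest.split()[0] if rest else ""
            rest = rest.split(None, 1)[1].strip() if rest and " " in rest else ""
        return kind, (int(s), int(e)), rest
    except (ValueError, IndexError) as err:
        raise RecordError(
            accession, f"malformed FT coordinates in line {line.strip()!r}"
        ) from err


def write_flatfile(records: Iterable[ProteinRecord]) -> str:
    """Serialize records to flat-file text; inverse of :func:`parse_flatfile`."""
    out = io.StringIO()
    for rec in records:
        out.write(f"ID   {rec.accession}\n")
        for key in sorted(rec.meta):
            out.write(f"CC   {key}={rec.meta[key]}\n")
        entries: list[tuple[int, str]] = []
        for f in rec.features:
            entries.append((f.start, f"FT   {f.kind}   {f.start + 1}..{f.end}"))
        for d in rec.domains:
            label = f"   {d.label}" if d.label else ""
            entries.append((d.start, f"FT   TOPO_DOM   {d.start + 1}..{d.end}{label}"))
        for _, line in sorted(entries, key=lambda t: (t[0], t[1])):
            out.write(line + "\n")
        out.write(f"SQ   SEQUENCE   {len(rec.sequence)} AA\n")
        seq = rec.sequence
        for i in range(0, len(seq), 60):
            chunk = seq[i : i + 60]
            grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
            out.write(f"     {grouped}\n")
        out.write("//\n")
    return out.getvalue()


def read_flatfile(source: Source, strict: bool = False) -> ParseResult:
    """Parse a flat file from a path or an open text stream."""
    return parse_flatfile(_read_source(source), strict=strict)


def save_flatfile(records: Iterable[ProteinRecord], path: Union[str, Path]) -> None:
    Path(path).write_text(write_flatfile(records))


# ---------------------------------------------------------------------------
# segment table
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["accession", "sequence", "tmh_spans", "orientations"]


def parse_segment_table(text: str, strict: bool = False) -> ParseResult:
    """Parse a TSV segment table into protein records.

    Columns: ``accession``, ``sequence``, ``tmh_spans`` (semicolon-separated
    ``start-end`` pairs, 1-based inclusive) and ``orientations`` (one flag per
    span from ``in_before``/``in_after``/``unknown``).  Orientation flags
    become synthetic flanking topology domains carrying (or omitting) the
    "cytoplasmic" keyword, so downstream orientation resolution behaves the
    same as with database annotation.
    """
    result = ParseResult()
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        return result
    header = lines[0].rstrip("\n").split("\t")
    if header[: len(_TABLE_COLUMNS)] != _TABLE_COLUMNS:
        raise ValueError(
            f"segment table must start with columns {_TABLE_COLUMNS}, got {header}"
        )
    for line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        try:
            result.records.append(_parse_table_row(fields, strict))
        except RecordError as err:
            if strict:
                raise
            result.errors.append(err)
    return result


def _parse_table_row(fields: list[str], strict: bool) -> ProteinRecord:
    if len(fields) < 4:
        raise RecordError(fields[0] if fields else "<unknown>", "short table row")
    accession, sequence, span_text, flag_text = (f.strip() for f in fields[:4])
    sequence = sequence.upper()
    spans: list[tuple[int, int]] = []
    if span_text:
        for item in span_text.split(";"):
            try:
                s, e = item.split("-")
                start1, end1 = int(s), int(e)
            except ValueError as err:
                raise RecordError(accession, f"malformed span {item!r}") from err
            if not (1 <= start1 <= end1 <= len(sequence)):
                raise RecordError(
                    accession,
                    f"span {start1}-{end1} outside sequence of length {len(sequence)}",
                )
            spans.append((start1 - 1, end1))
    flags = [f.strip() for f in flag_text.split(";")] if flag_text else []
    if len(flags) != len(spans):
        raise RecordError(
            accession, f"{len(spans)} spans but {len(flags)} orientation flags"
        )
    for flag in flags:
        if flag not in ("in_before", "in_after", "unknown"):
            raise RecordError(accession, f"unknown orientation flag {flag!r}")

    features = [MembraneFeature("TRANSMEM", s, e) for s, e in spans]
    # Gaps between membrane features (plus the termini) can carry a label.
    bounds = [0] + [x for s, e in spans for x in (s, e)] + [len(sequence)]
    gaps = [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)]
    claims: dict[int, set[str]] = {i: set() for i in range(len(gaps))}
    for i, flag in enumerate(flags):
        if flag == "unknown":
            continue
        cyt_gap = i if flag == "in_before" else i + 1
        other_gap = i + 1 if flag == "in_before" else i
        claims[cyt_gap].add("Cytoplasmic")
        claims[other_gap].add("Extracellular")
    domains: list[TopologyDomain] = []
    for i, (gs, ge) in enumerate(gaps):
        labels = claims[i]
        if len(labels) > 1:
            raise RecordError(
                accession, f"conflicting orientation flags around gap {i}"
            )
        if not labels:
            continue
        label = labels.pop()
        if gs == ge:
            if label == "Cytoplasmic":
                raise RecordError(
                    accession,
                    f"orientation flag requires a cytoplasmic domain in the "
                    f"empty gap at residue {gs + 1}",
                )
            continue
        domains.append(TopologyDomain(gs, ge, label))
    try:
        record = ProteinRecord(accession, sequence, features, domains)
        record.validate(strict=strict)
    except ValueError as err:
        if isinstance(err, RecordError):
            raise
        raise RecordError(accession, str(err)) from err
    return record


def write_segment_table(records: Iterable[ProteinRecord]) -> str:
    """Serialize records to the TSV segment table format.

    The per-TMH orientation flag is derived from the record's topology
    domains with the same nearest-domain keyword rule used for analysis.
    """
    from .extraction import orient_tmh  # local import: io <- extraction is acyclic

    out = ["\t".join(_TABLE_COLUMNS)]
    for rec in records:
        tmhs = rec.transmem_features
        spans = ";".join(f"{f.start + 1}-{f.end}" for f in tmhs)
        flags = []
        for i in range(len(tmhs)):
            orientation = orient_tmh(rec, i)
            flags.append(
                {"keep": "in_before", "reverse": "in_after", "omit": "unknown"}[
                    orientation
                ]
            )
        out.append("\t".join([rec.accession, rec.sequence, spans, ";".join(flags)]))
    return "\n".join(out) + "\n"


def read_segment_table(source: Source, strict: bool = False) -> ParseResult:
    return parse_segment_table(_read_source(source), strict=strict)


# ---------------------------------------------------------------------------
# FASTA export of oriented segments (for inspection)
# ---------------------------------------------------------------------------

def write_segment_fasta(segments, path_or_handle) -> int:
    """Export oriented TMH segments as FASTA (flanks lowercase, core upper).

    Returns the number of sequences written.
    """
    seq_records = []
    for seg in segments:
        seq = seg.inside_flank.lower() + seg.core.upper() + seg.outside_flank.lower()
        seq_records.append(
            SeqRecord(
                Seq(seq),
                id=f"{seg.accession}|tmh{seg.tmh_index}|{seg.regime}",
                description="",
            )
        )
    if hasattr(path_or_handle, "write"):
        return _seqio_write(seq_records, path_or_handle, "fasta")
    with open(path_or_handle, "w") as handle:
        return _seqio_write(seq_records, handle, "fasta")
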