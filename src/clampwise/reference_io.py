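"""Taxonomy-annotated SSU rRNA reference collections.

Reads aligned or unaligned multi-FASTA plus taxonomy (RDP-style
``Lineage=`` headers or a separate two-column TSV, Greengenes ``p__``
prefixes accepted), builds a coordinate map against a numbering reference
(conventionally the E. coli 16S sequence), and slices primer-locus windows.

Coordinates are 1-based and inclusive on both ends throughout, mirroring
the E. coli numbering convention in which primer sites are quoted as e.g.
"46-63".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO

from .errors import InputError, ValidationError
from .seqcore import IUPAC_SETS

__all__ = [
    "TaxonomyRecord",
    "ReferenceSet",
    "LocusWindows",
    "read_reference",
    "write_reference",
    "build_column_map",
    "extract_locus",
]

GAP_CHARS = frozenset("-.")

_RANKS = ("domain", "phylum", "class", "order", "family", "genus")
_GG_PREFIX = {"k": "domain", "d": "domain", "p": "phylum", "c": "class",
              "o": "order", "f": "family", "g": "genus", "s": "species"}


@dataclass(frozen=True)
class TaxonomyRecord:
    """Lineage of one reference sequence, ordered domain -> genus."""

    seq_id: str
    lineage: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValidationError(f"empty lineage for {self.seq_id}")

    @property
    def phylum(self) -> str:
        for rank, name in self.lineage:
            if rank == "phylum":
                return name
        return "unclassified"


@dataclass
class ReferenceSet:
    """A collection of reference sequences with per-record taxonomy.

    ``records`` maps seq_id to an uppercase IUPAC sequence (gapped if
    ``aligned``).  ``column_map`` maps 1-based ungapped positions of the
    numbering reference to 1-based alignment columns.
    """

    records: dict[str, str]
    taxonomy: dict[str, TaxonomyRecord]
    aligned: bool = False
    column_map: dict[int, int] | None = None
    numbering_ref_id: str | None = None
    load_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = set(self.taxonomy) - set(self.records)
        if extra:
            raise ValidationError(f"taxonomy for unknown seq_ids: {sorted(extra)[:5]}")
        if self.aligned:
            lengths = {len(s) for s in self.records.values()}
            if len(lengths) > 1:
                raise ValidationError(
                    f"aligned set has unequal sequence lengths: {sorted(lengths)}"
                )
        if self.column_map is not None:
            cols = list(self.column_map.values())
            if any(b <= a for a, b in zip(cols, cols[1:])):
                raise ValidationError("column_map is not strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def phylum_of(self, seq_id: str) -> str:
        rec = self.taxonomy.get(seq_id)
        return rec.phylum if rec is not None else "unclassified"

    def phyla(self) -> list[str]:
        return sorted({self.phylum_of(sid) for sid in self.records})

    def ungapped(self, seq_id: str) -> str:
        s = self.records[seq_id]
        return "".join(ch for ch in s if ch not in GAP_CHARS)


def _normalize_ref_seq(seq: str, seq_id: str, aligned: bool) -> str:
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out, start=1):
        if ch in GAP_CHARS:
            if not aligned:
                raise InputError(
                    f"gap character in unaligned record {seq_id} at position {i}"
                )
            continue
        if ch not in IUPAC_SETS:
            raise InputError(
                f"invalid character {ch!r} at position {i} of record {seq_id}"
            )
    return out


def _parse_rdp_lineage(description: str) -> tuple[tuple[str, str], ...] | None:
    """RDP dialect: 'Lineage=Root;rootrank;Bacteria;domain;Firmicutes;phylum;...'"""
    key = "Lineage="
    idx = description.find(key)
    if idx < 0:
        return None
    fields = description[idx + len(key):].split()[0].split(";")
    pairs = []
    for name, rank in zip(fields[0::2], fields[1::2]):
        if rank.lower() == "rootrank":
            continue
        pairs.append((rank.lower(), name))
    return tuple(pairs) or None


def _parse_lineage_string(s: str) -> tuple[tuple[str, str], ...]:
    """Semicolon lineage, with or without Greengenes 'p__' prefixes; ranks
    without a prefix are assigned positionally domain -> genus."""
    parts = [p.strip() for p in s.split(";") if p.strip()]
    pairs: list[tuple[str, str]] = []
    for i, part in enumerate(parts):
        if len(part) >= 3 and part[1:3] == "__" and part[0].lower() in _GG_PREFIX:
            rank = _GG_PREFIX[part[0].lower()]
            name = part[3:] or "unclassified"
        else:
            rank = _RANKS[i] if i < len(_RANKS) else f"rank{i}"
            name = part
        pairs.append((rank, name))
    if not pairs:
        raise InputError(f"empty lineage string: {s!r}")
    return tuple(pairs)


def _read_taxonomy_tsv(path: str | Path) -> dict[str, tuple[tuple[str, str], ...]]:
    out: dict[str, tuple[tuple[str, str], ...]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise InputError(f"{path}:{ln}: expected 2 tab-separated columns")
            sid, lineage = parts[0], parts[1]
            if sid in out:
                raise InputError(f"{path}:{ln}: duplicate seq_id {sid!r}")
            out[sid] = _parse_lineage_string(lineage)
    return out


def read_reference(fasta_source: str | Path,
                   taxonomy_source: str | Path | None = None,
                   *,
                   aligned: bool = False,
                   numbering_ref_id: str | None = None) -> ReferenceSet:
    """Read a multi-FASTA (plus optional taxonomy TSV) into a ReferenceSet.

    Taxonomy is taken from the TSV when given, otherwise from RDP-style
    ``Lineage=`` header fields.  Records lacking taxonomy are kept, labeled
    "unclassified", and counted in ``load_report``.
    """
    fasta_source = Path(fasta_source)
    if not fasta_source.exists():
        raise InputError(f"FASTA not found: {fasta_source}")
    if fasta_source.stat().st_size == 0:
        raise InputError(f"empty FASTA file: {fasta_source}")

    records: dict[str, str] = {}
    header_tax: dict[str, tuple[tuple[str, str], ...]] = {}
    try:
        parsed = list(SeqIO.parse(str(fasta_source), "fasta"))
    except ValueError as exc:
        raise InputError(f"malformed FASTA {fasta_source}: {exc}") from exc
    if not parsed:
        raise InputError(f"no FASTA records in {fasta_source}")
    for rec in parsed:
        if rec.id in records:
            raise InputError(f"duplicate seq_id {rec.id!r} in {fasta_source}")
        records[rec.id] = _normalize_ref_seq(str(rec.seq), rec.id, aligned)
        lin = _parse_rdp_lineage(rec.description)
        if lin:
            header_tax[rec.id] = lin

    tsv_tax = _read_taxonomy_tsv(taxonomy_source) if taxonomy_source else {}
    taxonomy: dict[str, TaxonomyRecord] = {}
    missing = []
    for sid in records:
        lin = tsv_tax.get(sid) or header_tax.get(sid)
        if lin is None:
            missing.append(sid)
            lin = (("domain", "unclassified"), ("phylum", "unclassified"))
        taxonomy[sid] = TaxonomyRecord(sid, lin)

    rs = ReferenceSet(
        records=records, taxonomy=taxonomy, aligned=aligned,
        numbering_ref_id=numbering_ref_id,
        load_report={
            "n_records": len(records),
            "n_unclassified": len(missing),
            "unclassified_ids": missing[:20],
        },
    )
    if aligned and numbering_ref_id is not None:
        rs.column_map = build_column_map(rs, numbering_ref_id)
    return rs


def write_reference(rs: ReferenceSet, fasta_path: str | Path,
                    taxonomy_path: str | Path | None = None) -> None:
    """Write FASTA (and optionally a taxonomy TSV) round-trippable by
    :func:`read_reference`."""
    with open(fasta_path, "w") as fh:
        for sid, seq in rs.records.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    if taxonomy_path is not None:
        with open(taxonomy_path, "w") as fh:
            fh.write("# seq_id\tlineage\n")
            for sid in rs.records:
                rec = rs.taxonomy.get(sid)
                if rec is None:
                    continue
                lineage = ";".join(name for _, name in rec.lineage)
                fh.write(f"{sid}\t{lineage}\n")


def build_column_map(rs: ReferenceSet, numbering_ref_id: str) -> dict[int, int]:
    """Map 1-based ungapped positions of the numbering reference to 1-based
    alignment columns."""
    if not rs.aligned:
        raise ValidationError("column map requires an aligned ReferenceSet")
    if numbering_ref_id not in rs.records:
        raise ValidationError(f"numbering reference {numbering_ref_id!r} not in set")
    seq = rs.records[numbering_ref_id]
    cmap: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(seq, start=1):
        if ch not in GAP_CHARS:
            pos += 1
            cmap[pos] = col
    if not cmap:
        raise ValidationError(f"numbering reference {numbering_ref_id!r} is all gaps")
    return cmap


@dataclass
class LocusWindows:
    """Per-sequence locus slices plus the records that do not span the locus."""

    start: int
    end: int
    columns: list[int]                  # alignment columns of each numbering position
    gapped: dict[str, str]              # spanning seq_id -> gapped window slice
    ungapped: dict[str, str]            # spanning seq_id -> ungapped subsequence
    non_spanning: list[str]


def extract_locus(rs: ReferenceSet, start: int, end: int,
                  column_map: dict[int, int] | None = None) -> LocusWindows:
    """Slice the window [start, end] (numbering positions, inclusive) out of
    every record.

    Records whose window begins or ends with an alignment gap do not span
    the locus (typical of partial-length database entries) and are listed
    separately; internal gaps are kept in ``gapped`` and dropped in
    ``ungapped``.
    """
    if start > end:
        raise ValidationError(f"locus start {start} > end {end}")
    cmap = column_map if column_map is not None else rs.column_map
    if rs.aligned:
        if cmap is None:
            raise ValidationError("aligned set needs a column_map (set numbering_ref_id)")
        try:
            columns = [cmap[p] for p in range(start, end + 1)]
        except KeyError as exc:
            raise ValidationError(
                f"locus position {exc.args[0]} outside the column map"
            ) from exc
    else:
        # unaligned records in a common coordinate frame (e.g. synthetic,
        # indel-free collections): positions index the sequences directly
        columns = list(range(start, end + 1))

    gapped: dict[str, str] = {}
    ungapped: dict[str, str] = {}
    non_spanning: list[str] = []
    lo, hi = columns[0], columns[-1]
    for sid, seq in rs.records.items():
        if hi > len(seq):
            non_spanning.append(sid)
            continue
        window = "".join(seq[c - 1] for c in columns)
        if window[0] in GAP_CHARS or window[-1] in GAP_CHARS:
            non_spanning.append(sid)
            continue
        gapped[sid] = window
        ungapped[sid] = "".join(ch for ch in window if ch not in GAP_CHARS)
    return LocusWindows(start=start, end=end, columns=columns,
                        gapped=gapped, ungapped=ungapped,
                        non_spanning=non_spanning)
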