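"""Primer and clamp-oligo placement in numbering-reference coordinates.

Positions follow the E. coli 16S numbering convention: 1-based, inclusive,
with reverse primers quoted 5' end first and hence descending (the
"1510-1494" style).  The numbering reference itself is an input — tests and
the synthetic generator construct stand-ins — so no genome download is
needed.

The clamp-competition check is the placement criterion behind clamping-PCR
panel design: a primer must overlap the clamp oligo's annealing window so
the two compete for the same stretch of template, letting the clamp
suppress organelle templates while the primer wins on bacterial ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .coverage import locate_site
from .errors import ValidationError
from .seqcore import Primer

__all__ = ["PrimerSite", "ClampOligo", "CompetitionReport",
           "map_to_reference", "clamp_competition", "load_clamp_tsv"]


@dataclass(frozen=True)
class PrimerSite:
    """5'/3' terminal coordinates on the numbering reference."""

    five_prime_pos: int
    three_prime_pos: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and self.five_prime_pos >= self.three_prime_pos:
            raise ValidationError("forward site must have 5' position < 3' position")
        if self.strand == "-" and self.five_prime_pos <= self.three_prime_pos:
            raise ValidationError("reverse site must have 5' position > 3' position")

    @property
    def span(self) -> tuple[int, int]:
        """(low, high) inclusive positions, strand-agnostic."""
        lo, hi = sorted((self.five_prime_pos, self.three_prime_pos))
        return lo, hi

    def __len__(self) -> int:
        lo, hi = self.span
        return hi - lo + 1


@dataclass(frozen=True)
class ClampOligo:
    """A clamp oligo (LNA/PNA) given by sequence and/or target window.

    ``tm_c`` is user-supplied metadata (clamp duplex thermodynamics are not
    computed here; LNA-modified stacks need their own parameterization).
    """

    name: str
    sequence: str | None = None
    site: PrimerSite | None = None
    organelle: str = "mitochondrion"  # or "plastid"
    tm_c: float | None = None

    def __post_init__(self) -> None:
        if self.sequence is None and self.site is None:
            raise ValidationError(
                f"clamp {self.name}: provide a sequence or a target site"
            )
        if self.organelle not in ("mitochondrion", "plastid"):
            raise ValidationError(
                f"clamp {self.name}: organelle must be mitochondrion or plastid"
            )


@dataclass(frozen=True)
class CompetitionReport:
    primer_name: str
    clamp_name: str
    overlap_len: int
    min_overlap: int
    competing: bool
    primer_span: tuple[int, int]
    clamp_span: tuple[int, int]


def map_to_reference(primer: Primer, numbering_reference: str,
                     max_mismatch: int = 3) -> PrimerSite | None:
    """Place *primer* on an ungapped numbering reference.

    Reverse primers are searched as their reverse complement on the forward
    strand and reported 5' first (descending).  Returns None when no
    placement stays within ``max_mismatch``; warns when several placements
    tie (the leftmost is reported).
    """
    hit = locate_site(numbering_reference, primer, max_mismatch=max_mismatch)
    if hit is None:
        return None
    # detect ambiguous placement: a second window with the same mismatch count
    rest = numbering_reference[hit.start:]
    second = locate_site(rest, primer, max_mismatch=hit.mismatches)
    if second is not None and second.mismatches == hit.mismatches:
        warnings.warn(
            f"{primer.name}: multiple equal placements; reporting the leftmost "
            f"({hit.start}-{hit.end})", stacklevel=2)
    if primer.is_reverse:
        return PrimerSite(five_prime_pos=hit.end, three_prime_pos=hit.start, strand="-")
    return PrimerSite(five_prime_pos=hit.start, three_prime_pos=hit.end, strand="+")


def clamp_competition(primer_site: PrimerSite, clamp_site: PrimerSite,
                      min_overlap: int | None = None) -> CompetitionReport:
    """Overlap between a primer site and a clamp site, strand-agnostic.

    ``min_overlap`` defaults to primer length - 3, i.e. near-total overlap,
    since clamping panels place primers essentially inside the clamp
    window; pass a smaller value to accept partial competition.
    """
    p_lo, p_hi = primer_site.span
    c_lo, c_hi = clamp_site.span
    overlap = max(0, min(p_hi, c_hi) - max(p_lo, c_lo) + 1)
    if min_overlap is None:
        min_overlap = len(primer_site) - 3
    return CompetitionReport(
        primer_name="", clamp_name="", overlap_len=overlap,
        min_overlap=min_overlap, competing=overlap >= min_overlap,
        primer_span=(p_lo, p_hi), clamp_span=(c_lo, c_hi))


def load_clamp_tsv(path) -> list[ClampOligo]:
    """Load a clamp panel from TSV.

    Columns: ``name``, ``organelle`` and at least one of ``sequence`` or
    the coordinate triple ``pos_5prime``/``pos_3prime``/``strand``; an
    optional ``tm_c`` column carries supplier-reported clamp Tm."""
    import pandas as pd

    from .errors import InputError

    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read clamp TSV {path}: {exc}") from exc
    clamps = []
    for _, row in df.iterrows():
        site = None
        if pd.notna(row.get("pos_5prime")) and pd.notna(row.get("pos_3prime")):
            site = PrimerSite(int(row["pos_5prime"]), int(row["pos_3prime"]),
                              str(row.get("strand", "+")))
        seq = row.get("sequence")
        tm = row.get("tm_c")
        clamps.append(ClampOligo(
            name=str(row["name"]),
            sequence=None if pd.isna(seq) else str(seq),
            site=site,
            organelle=str(row.get("organelle", "mitochondrion")),
            tm_c=None if tm is None or pd.isna(tm) else float(tm)))
    return clamps
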