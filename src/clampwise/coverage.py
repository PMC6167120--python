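"""Primer coverage of a reference collection, overall and per phylum.

Coverage of a primer is the percentage of reference sequences whose
primer-site window the primer matches under a stated mismatch rule.  Three
views are computed:

* whole-site coverage with a mismatch budget (default 0 = perfect match);
* per-base coverage — for each primer position, the percentage of
  sequences in a taxon whose base matches the primer symbol there (the
  grid used to diagnose 3'-end bias per phylum);
* critical-window flags — phyla in which any per-base cell within the last
  3-4 positions of the primer's 3' end falls below a threshold, since a
  single template mismatch there inhibits amplification.

Denominators exclude sequences that do not span the locus (partial-length
database records), which are reported separately.  Reference ambiguity
codes (N etc.) count as a mismatch unless the primer symbol covers every
base the reference could be — database uncertainty is not a free pass.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .reference_io import GAP_CHARS, LocusWindows, ReferenceSet, extract_locus
from .seqcore import IUPAC_SETS, PairingMode, Primer, revcomp

__all__ = [
    "CoverageResult", "PerBaseCoverageTable", "CriticalWindowFlag", "Site",
    "primer_coverage", "locate_site", "per_base_coverage",
    "critical_window_flags", "load_profile_table",
]

ALL_TAXA = "ALL"

_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_MASK = {sym: int(np.bitwise_or.reduce([_BIT[b] for b in bases]))
         for sym, bases in IUPAC_SETS.items()}
_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    """IUPAC string -> uint8 base-set bitmasks (gap/unknown -> 0)."""
    out = np.zeros(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        out[i] = _MASK.get(ch, 0)
    return out


def _site_match(primer_sym: str, target_ch: str,
                mode: PairingMode = PairingMode.OPTIMISTIC) -> bool:
    """Mode-aware per-base match with the conservative ambiguity rule: an
    ambiguous reference base matches only if the primer symbol covers its
    whole base set; alignment gaps never match."""
    if target_ch in GAP_CHARS:
        return False
    p = IUPAC_SETS[primer_sym]
    t = IUPAC_SETS[target_ch]
    if len(t) > 1 or mode is PairingMode.STRICT:
        return t <= p
    return bool(p & t)


@dataclass(frozen=True)
class Site:
    """An ungapped primer placement on a template, 1-based inclusive."""

    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class CoverageResult:
    taxon: str
    n_spanning: int
    n_matched: int
    mismatch_budget: int
    coverage_pct: float | None  # None when no sequence spans the locus

    @property
    def defined(self) -> bool:
        return self.coverage_pct is not None


@dataclass
class PerBaseCoverageTable:
    """Taxon x position grid of per-base match percentages.

    ``positions`` ascend in numbering-reference coordinates and
    ``primer_symbols`` are the primer's symbols on the forward strand at
    those positions; for a reverse primer the 3' terminus therefore sits at
    the *first* position.  ``cells`` is a DataFrame (rows taxa, columns
    positions, float percent).
    """

    positions: list[int]
    primer_symbols: list[str]
    orientation: str
    cells: pd.DataFrame
    n_per_taxon: dict[str, int] = field(default_factory=dict)
    primer_name: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.primer_symbols):
            raise ValidationError("one primer symbol required per position")
        vals = self.cells.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 100):
            raise ValidationError("per-base percentages must lie in [0, 100]")

    def three_prime_window(self, window_len: int) -> list[int]:
        """The numbering positions of the last ``window_len`` bases at the
        primer's 3' end."""
        if window_len > len(self.positions):
            raise ValidationError(
                f"window {window_len} longer than table ({len(self.positions)} positions)"
            )
        if self.orientation == "reverse":
            return self.positions[:window_len]
        return self.positions[-window_len:]


@dataclass(frozen=True)
class CriticalWindowFlag:
    """Flag raised for a taxon when any per-base cell inside the primer's
    3'-end critical window drops below the threshold."""

    taxon: str
    window_positions: tuple[int, ...]
    min_cell_pct: float
    threshold_pct: float
    flagged: bool


# ---------------------------------------------------------------------------
# site location (unaligned path)

def locate_site(sequence: str, primer: Primer, max_mismatch: int = 3) -> Site | None:
    """Best ungapped placement of *primer* on an ungapped template.

    Forward primers are matched on the given strand; reverse primers as
    their reverse complement (the placement is still reported on the
    forward strand).  Ties go to the leftmost start; returns None when even
    the best placement exceeds ``max_mismatch``.
    """
    query = revcomp(primer.sequence) if primer.is_reverse else primer.sequence
    L = len(query)
    if L > len(sequence):
        return None
    seq_mask = _encode(sequence.upper().replace("U", "T"))
    pmask = _encode(query)
    win = np.lib.stride_tricks.sliding_window_view(seq_mask, L)
    ambiguous = _POPCOUNT[win] > 1
    subset_ok = (win & ~pmask & np.uint8(0xF)) == 0
    optimistic_ok = (win & pmask) != 0
    match = np.where(ambiguous, subset_ok & (win != 0), optimistic_ok)
    mismatches = L - match.sum(axis=1)
    best = int(mismatches.argmin())  # argmin takes the leftmost tie
    if int(mismatches[best]) > max_mismatch:
        return None
    return Site(start=best + 1, end=best + L,
                strand="-" if primer.is_reverse else "+",
                mismatches=int(mismatches[best]))


# ---------------------------------------------------------------------------
# coverage

def _forward_symbols(primer: Primer) -> str:
    return revcomp(primer.sequence) if primer.is_reverse else primer.sequence


def _resolve_windows(rs: ReferenceSet, primer: Primer,
                     site: tuple[int, int] | None,
                     locate_max_mismatch: int | None) -> LocusWindows:
    if site is None:
        if rs.aligned:
            raise ValidationError(
                "site unresolvable: aligned sets need site=(start, end) in "
                "numbering coordinates (see positioning.map_to_reference)"
            )
        # unaligned path: place the primer on every record independently
        cap = locate_max_mismatch if locate_max_mismatch is not None else len(primer) // 3
        gapped: dict[str, str] = {}
        non_spanning: list[str] = []
        for sid, seq in rs.records.items():
            hit = locate_site(seq, primer, max_mismatch=cap)
            if hit is None:
                non_spanning.append(sid)
            else:
                gapped[sid] = seq[hit.start - 1:hit.end]
        return LocusWindows(start=0, end=0, columns=[], gapped=gapped,
                            ungapped=dict(gapped), non_spanning=non_spanning)
    start, end = site
    if end - start + 1 != len(primer):
        raise ValidationError(
            f"site span {start}-{end} does not match primer length {len(primer)}"
        )
    return extract_locus(rs, start, end)


def _iter_spanning(rs: ReferenceSet, windows: LocusWindows):
    for sid, window in windows.gapped.items():
        if sid == rs.numbering_ref_id:
            continue
        yield sid, window


def primer_coverage(rs: ReferenceSet, primer: Primer,
                    site: tuple[int, int] | None = None,
                    mismatch_budget: int = 0,
                    mode: PairingMode | str = PairingMode.OPTIMISTIC,
                    locate_max_mismatch: int | None = None
                    ) -> list[CoverageResult]:
    """Per-phylum and overall coverage of *primer* at *site*.

    A sequence is covered when at most ``mismatch_budget`` of its window
    positions fail the per-base match rule.  Taxa in which no sequence
    spans the locus get ``coverage_pct`` None rather than a silent zero.
    """
    if mismatch_budget < 0:
        raise ValidationError("mismatch_budget must be >= 0")
    mode = PairingMode(mode)
    windows = _resolve_windows(rs, primer, site, locate_max_mismatch)
    symbols = _forward_symbols(primer)

    span: dict[str, int] = {}
    hits: dict[str, int] = {}
    for sid, window in _iter_spanning(rs, windows):
        taxon = rs.phylum_of(sid)
        mism = sum(
            not _site_match(psym, tch, mode)
            for psym, tch in zip(symbols, window)
        )
        span[taxon] = span.get(taxon, 0) + 1
        if mism <= mismatch_budget:
            hits[taxon] = hits.get(taxon, 0) + 1

    results = []
    taxa = sorted(span) + [ALL_TAXA]
    total_span = sum(span.values())
    total_hits = sum(hits.values())
    for taxon in taxa:
        n_s = total_span if taxon == ALL_TAXA else span[taxon]
        n_m = total_hits if taxon == ALL_TAXA else hits.get(taxon, 0)
        pct = 100.0 * n_m / n_s if n_s else None
        results.append(CoverageResult(taxon=taxon, n_spanning=n_s, n_matched=n_m,
                                      mismatch_budget=mismatch_budget,
                                      coverage_pct=pct))
    return results


def per_base_coverage(rs: ReferenceSet, primer: Primer,
                      site: tuple[int, int],
                      mode: PairingMode | str = PairingMode.OPTIMISTIC
                      ) -> PerBaseCoverageTable:
    """Per-position match percentages, one row per phylum.

    Phyla with no spanning sequence are omitted (with a warning) rather
    than shown as spurious zeros.
    """
    mode = PairingMode(mode)
    windows = _resolve_windows(rs, primer, site, None)
    symbols = _forward_symbols(primer)
    positions = list(range(site[0], site[1] + 1))

    per_taxon: dict[str, np.ndarray] = {}
    n_per_taxon: dict[str, int] = {}
    for sid, window in _iter_spanning(rs, windows):
        taxon = rs.phylum_of(sid)
        row = per_taxon.setdefault(taxon, np.zeros(len(positions)))
        n_per_taxon[taxon] = n_per_taxon.get(taxon, 0) + 1
        for j, (psym, tch) in enumerate(zip(symbols, window)):
            if _site_match(psym, tch, mode):
                row[j] += 1

    all_taxa = {rs.phylum_of(sid) for sid in rs.records if sid != rs.numbering_ref_id}
    empty = sorted(all_taxa - set(per_taxon))
    if empty:
        warnings.warn(f"taxa with no locus-spanning sequence omitted: {empty}",
                      stacklevel=2)

    cells = pd.DataFrame(
        {tax: 100.0 * per_taxon[tax] / n_per_taxon[tax] for tax in sorted(per_taxon)},
        index=positions,
    ).T
    return PerBaseCoverageTable(positions=positions,
                                primer_symbols=list(symbols),
                                orientation=primer.orientation,
                                cells=cells, n_per_taxon=n_per_taxon,
                                primer_name=primer.name)


def critical_window_flags(table: PerBaseCoverageTable, window_len: int = 4,
                          threshold_pct: float = 79.0
                          ) -> list[CriticalWindowFlag]:
    """Flag taxa with any sub-threshold per-base cell in the 3'-end window.

    ``window_len`` is conventionally 3 or 4 — the span within which a
    single primer-template mismatch inhibits amplification.
    """
    if not 0 <= threshold_pct <= 100:
        raise ValidationError("threshold_pct must be in [0, 100]")
    wpos = table.three_prime_window(window_len)
    flags = []
    for taxon in table.cells.index:
        cells = table.cells.loc[taxon, wpos]
        min_cell = float(cells.min())
        flags.append(CriticalWindowFlag(
            taxon=str(taxon), window_positions=tuple(wpos),
            min_cell_pct=min_cell, threshold_pct=threshold_pct,
            flagged=min_cell < threshold_pct))
    return flags


def load_profile_table(path: str | Path | None = None) -> PerBaseCoverageTable:
    """Load a per-base coverage grid from TSV.

    Format: a ``phylum`` header row listing the numbering positions, a
    ``base`` row with the primer symbol per position, then one row per
    taxon.  With no path, the packaged profile of the 63f-family forward
    primers (positions 60-68, ten phyla) is loaded.
    """
    if path is None:
        path = Path(str(importlib.resources.files("clampwise")
                        .joinpath("data", "forward_3prime_profile.tsv")))
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "base" not in df.index:
        raise ValidationError(f"profile TSV {path} lacks a 'base' row")
    symbols = [str(s) for s in df.loc["base"]]
    cells = df.drop(index="base").astype(float)
    positions = [int(c) for c in cells.columns]
    cells.columns = positions
    return PerBaseCoverageTable(positions=positions, primer_symbols=symbols,
                                orientation="forward", cells=cells)
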