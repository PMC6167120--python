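"""Synthetic taxonomy-annotated SSU rRNA collections with planted truth.

The generator emulates the structure that primer-coverage profiling
measures on real databases: a multi-phylum 16S-like collection in which
every sequence carries the panel's primer sites, and each (phylum,
position) inside a site mismatches the primer symbol with a known planted
probability.  Because the truth is planted, every downstream statistic —
per-base coverage, perfect-match coverage — has an exact expectation to
recover, which is what makes the coverage engine testable without any
database download.

The model is deliberately simple: mismatches are independent across
positions and sequences (per-position coverage, the measured quantity, is
insensitive to correlation structure), substituted bases are uniform over
the bases the primer symbol does not cover, and there are no indels unless
an insertion-column rate is requested.  Phylogenetic realism and chimeras
are out of scope.

Default conditions: the ten-phylum panel of the packaged 3'-end profile,
500 sequences per phylum, per-position mismatch rates derived from that
profile (rate = 1 - pct/100 at positions 60-68), a 2% background
substitution rate outside primer sites, and a ~1,510 nt template carrying
the six bundled primer sites at their published coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coverage import load_profile_table
from .errors import ValidationError
from .reference_io import ReferenceSet, TaxonomyRecord, write_reference
from .seqcore import IUPAC_SETS, Primer, bundled_panel, bundled_panel_metadata, revcomp

__all__ = ["SyntheticSpec", "TruthTable", "default_rates",
           "generate_reference_set", "generate_organelle_decoys",
           "merge_reference_sets", "NUMBERING_REF_ID"]

NUMBERING_REF_ID = "synthetic_numbering_ref"

_BASES = np.array(list("ACGT"))
_IDX = {b: i for i, b in enumerate("ACGT")}

TEMPLATE_LENGTH = 1510


def _panel_site_symbols() -> dict[int, str]:
    """Forward-strand primer symbol at every position covered by the
    bundled panel (the six primer sites, merged; overlaps agree)."""
    meta = bundled_panel_metadata()
    out: dict[int, str] = {}
    for p in bundled_panel():
        row = meta.loc[p.name]
        symbols = revcomp(p.sequence) if p.is_reverse else p.sequence
        lo = int(min(row["pos_5prime"], row["pos_3prime"]))
        for off, sym in enumerate(symbols):
            pos = lo + off
            if pos in out and out[pos] != sym:
                raise ValidationError(
                    f"panel sites disagree at position {pos}: {out[pos]} vs {sym}"
                )
            out[pos] = sym
    return out


def default_rates() -> dict[tuple[str, int], float]:
    """Planted per-(phylum, position) mismatch rates mirroring the packaged
    3'-end per-base profile: rate = 1 - pct/100 at positions 60-68."""
    table = load_profile_table()
    rates: dict[tuple[str, int], float] = {}
    for taxon in table.cells.index:
        for pos in table.positions:
            rates[(str(taxon), pos)] = round(1.0 - float(table.cells.loc[taxon, pos]) / 100.0, 6)
    return rates


def _default_taxa() -> tuple[tuple[str, int], ...]:
    return tuple((str(t), 500) for t in load_profile_table().cells.index)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic collection.  ``seed`` fixes every draw;
    the same spec + seed yields byte-identical output files."""

    taxa: tuple[tuple[str, int], ...] = field(default_factory=_default_taxa)
    rates: dict[tuple[str, int], float] = field(default_factory=default_rates)
    background_rate: float = 0.02
    gap_rate: float = 0.0
    template_length: int = TEMPLATE_LENGTH
    seed: int = 0

    def __post_init__(self) -> None:
        names = [t for t, _ in self.taxa]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate phylum names in spec")
        if any(n < 1 for _, n in self.taxa):
            raise ValidationError("each taxon needs n >= 1 sequences")
        for (tax, pos), r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValidationError(f"rate {r} for ({tax}, {pos}) outside [0, 1]")
        for name, val in (("background_rate", self.background_rate),
                          ("gap_rate", self.gap_rate)):
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} {val} outside [0, 1]")
        if self.template_length < max(_panel_site_symbols()) :
            raise ValidationError(
                f"template_length {self.template_length} too short for the panel sites"
            )


@dataclass
class TruthTable:
    """Planted expectations implied by a SyntheticSpec.

    ``per_base_pct[(phylum, pos)]`` is the expected per-base coverage at a
    primer-site position; expected perfect-match coverage over a window is
    the product of per-position survival probabilities.
    """

    per_base_pct: dict[tuple[str, int], float]
    site_positions: tuple[int, ...]

    def expected_per_base(self, phylum: str, pos: int) -> float:
        return self.per_base_pct[(phylum, pos)]

    def expected_perfect_pct(self, phylum: str, positions: "list[int] | tuple[int, ...]") -> float:
        prod = 1.0
        for pos in positions:
            prod *= self.per_base_pct[(phylum, pos)] / 100.0
        return 100.0 * prod

    def to_json(self, path: str | Path) -> None:
        payload = {
            "site_positions": list(self.site_positions),
            "per_base_pct": {f"{tax}:{pos}": pct
                             for (tax, pos), pct in sorted(self.per_base_pct.items())},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _make_template(rng: np.random.Generator, length: int,
                   sites: dict[int, str]) -> tuple[np.ndarray, str]:
    """Random background template (base indices) plus a concrete numbering
    reference realized from the degenerate site symbols."""
    template = rng.integers(0, 4, size=length)
    ref = template.copy()
    for pos, sym in sorted(sites.items()):
        allowed = np.array([_IDX[b] for b in sorted(IUPAC_SETS[sym])])
        ref[pos - 1] = allowed[rng.integers(0, len(allowed))]
    return template, "".join(_BASES[ref])


def _simulate_taxon(rng: np.random.Generator, template: np.ndarray, n: int,
                    sites: dict[int, str],
                    rates: dict[int, float], background_rate: float) -> np.ndarray:
    """(n, L) base-index matrix for one phylum."""
    L = len(template)
    mat = np.tile(template, (n, 1))
    # background substitutions outside primer sites
    bg = rng.random((n, L)) < background_rate
    site_cols = np.array([p - 1 for p in sites], dtype=int)
    bg[:, site_cols] = False
    shifts = rng.integers(1, 4, size=(n, L))
    mat = np.where(bg, (mat + shifts) % 4, mat)
    # primer-site columns: draw from the symbol set, then plant mismatches
    for pos, sym in sorted(sites.items()):
        allowed = np.array([_IDX[b] for b in sorted(IUPAC_SETS[sym])])
        disallowed = np.array([i for i in range(4) if i not in allowed])
        col = allowed[rng.integers(0, len(allowed), size=n)]
        r = rates.get(pos, 0.0)
        if r > 0:
            if len(disallowed) == 0:
                raise ValidationError(
                    f"cannot plant mismatches at position {pos}: symbol {sym} covers all bases"
                )
            mism = rng.random(n) < r
            col = np.where(mism, disallowed[rng.integers(0, len(disallowed), size=n)], col)
        mat[:, pos - 1] = col
    return mat


def _insertion_columns(rng: np.random.Generator, length: int, gap_rate: float) -> np.ndarray:
    """Columns (0-based, referring to the ungapped frame) after which an
    insertion column is placed in the emitted alignment."""
    if gap_rate <= 0:
        return np.empty(0, dtype=int)
    return np.flatnonzero(rng.random(length) < gap_rate)


def _to_alignment(row: str, ins_after: np.ndarray, fills: "list[str]") -> str:
    if len(ins_after) == 0:
        return row
    parts = []
    prev = 0
    for k, col in enumerate(ins_after):
        parts.append(row[prev:col + 1])
        parts.append(fills[k])
        prev = col + 1
    parts.append(row[prev:])
    return "".join(parts)


def generate_reference_set(spec: SyntheticSpec,
                           out_dir: str | Path | None = None
                           ) -> tuple[ReferenceSet, TruthTable]:
    """Generate the collection (plus its planted TruthTable).

    With ``gap_rate == 0`` the set is emitted unaligned in a common
    coordinate frame (identity alignment); otherwise insertion columns are
    planted and an aligned set with a column map against the included
    numbering reference is returned.  With ``out_dir``, FASTA, taxonomy TSV
    and truth JSON are written there.
    """
    rng = np.random.default_rng(spec.seed)
    sites = _panel_site_symbols()
    template, numbering_ref = _make_template(rng, spec.template_length, sites)

    records: dict[str, str] = {}
    taxonomy: dict[str, TaxonomyRecord] = {}
    per_base: dict[tuple[str, int], float] = {}
    rows: list[tuple[str, str, str]] = []  # (seq_id, phylum, ungapped seq)
    for phylum, n in spec.taxa:
        taxon_rates = {pos: spec.rates.get((phylum, pos), 0.0) for pos in sites}
        mat = _simulate_taxon(rng, template, n, sites, taxon_rates,
                              spec.background_rate)
        for i in range(n):
            sid = f"{phylum}_{i:04d}"
            rows.append((sid, phylum, "".join(_BASES[mat[i]])))
        for pos in sites:
            per_base[(phylum, pos)] = 100.0 * (1.0 - taxon_rates[pos])

    ins_after = _insertion_columns(rng, spec.template_length, spec.gap_rate)
    aligned = len(ins_after) > 0
    if aligned:
        ref_fills = ["-"] * len(ins_after)
        records[NUMBERING_REF_ID] = _to_alignment(numbering_ref, ins_after, ref_fills)
        taxonomy[NUMBERING_REF_ID] = TaxonomyRecord(
            NUMBERING_REF_ID, (("domain", "reference"), ("phylum", "unclassified")))
    else:
        records[NUMBERING_REF_ID] = numbering_ref
        taxonomy[NUMBERING_REF_ID] = TaxonomyRecord(
            NUMBERING_REF_ID, (("domain", "reference"), ("phylum", "unclassified")))
    for sid, phylum, seq in rows:
        if aligned:
            fills = ["".join(_BASES[rng.integers(0, 4, size=1)])
                     if rng.random() < 0.5 else "-" for _ in ins_after]
            records[sid] = _to_alignment(seq, ins_after, fills)
        else:
            records[sid] = seq
        taxonomy[sid] = TaxonomyRecord(
            sid, (("domain", "Bacteria"), ("phylum", phylum)))

    rs = ReferenceSet(records=records, taxonomy=taxonomy, aligned=aligned,
                      numbering_ref_id=NUMBERING_REF_ID)
    if aligned:
        from .reference_io import build_column_map
        rs.column_map = build_column_map(rs, NUMBERING_REF_ID)
    truth = TruthTable(per_base_pct=per_base,
                       site_positions=tuple(sorted(sites)))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_reference(rs, out_dir / "reference.fasta", out_dir / "taxonomy.tsv")
        truth.to_json(out_dir / "truth.json")
    return rs, truth


# ---------------------------------------------------------------------------
# organelle decoys

#: positions carrying organelle-specific clamp-region signatures, flanking
#: the forward and reverse primer sites (plant organelle SSU rRNA genes
#: share the conserved primer sites but differ in the clamp windows)
_SIGNATURE_WINDOWS = {"forward": (30, 42), "reverse": (1471, 1491)}


def generate_organelle_decoys(spec: SyntheticSpec, n_mitochondrion: int = 20,
                              n_plastid: int = 20) -> ReferenceSet:
    """Organelle-like decoy sequences for clamp-competition tests.

    Decoys carry the same (conserved) primer sites as the bacterial
    collection, so bacterial primers anneal to them too — the reason
    clamping is needed at all — but each organelle class carries its own
    fixed signature in the clamp windows flanking the sites.  Signature
    windows and sequences are recorded in ``load_report`` so tests can cut
    clamp oligos that target one class.
    """
    rng = np.random.default_rng(spec.seed + 10_007)
    sites = _panel_site_symbols()
    template, _ = _make_template(rng, spec.template_length, sites)

    signatures: dict[str, dict[str, str]] = {}
    records: dict[str, str] = {}
    taxonomy: dict[str, TaxonomyRecord] = {}
    for organelle, n in (("mitochondrion", n_mitochondrion),
                         ("plastid", n_plastid)):
        sig = {name: "".join(_BASES[rng.integers(0, 4, size=hi - lo + 1)])
               for name, (lo, hi) in _SIGNATURE_WINDOWS.items()}
        signatures[organelle] = {
            name: f"{_SIGNATURE_WINDOWS[name][0]}-{_SIGNATURE_WINDOWS[name][1]}:{s}"
            for name, s in sig.items()
        }
        for i in range(n):
            mat = _simulate_taxon(rng, template, 1, sites, {}, spec.background_rate)[0]
            for name, (lo, hi) in _SIGNATURE_WINDOWS.items():
                mat[lo - 1:hi] = [_IDX[b] for b in sig[name]]
            sid = f"{organelle}_{i:04d}"
            records[sid] = "".join(_BASES[mat])
            taxonomy[sid] = TaxonomyRecord(
                sid, (("domain", "Eukaryota"), ("phylum", organelle)))
    return ReferenceSet(records=records, taxonomy=taxonomy, aligned=False,
                        load_report={"signatures": signatures})


def merge_reference_sets(a: ReferenceSet, b: ReferenceSet) -> ReferenceSet:
    """Union of two unaligned sets sharing a coordinate frame (e.g. the
    bacterial collection plus organelle decoys)."""
    if a.aligned or b.aligned:
        raise ValidationError("merge supports unaligned common-frame sets only")
    overlap = set(a.records) & set(b.records)
    if overlap:
        raise ValidationError(f"duplicate seq_ids in merge: {sorted(overlap)[:5]}")
    return ReferenceSet(records={**a.records, **b.records},
                        taxonomy={**a.taxonomy, **b.taxonomy},
                        aligned=False, numbering_ref_id=a.numbering_ref_id)
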