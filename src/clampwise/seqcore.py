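"""IUPAC degenerate-nucleotide algebra and the :class:`Primer` domain type.

Degenerate primers carry IUPAC ambiguity codes (Y, R, K, W, ...) so that a
single oligo pool matches several sequence variants.  Everything downstream
— coverage, dimer scoring, Tm ranges — reduces to set operations on the
base sets these codes denote, which this module implements.

Two pairing modes are distinguished wherever one degenerate symbol is
compared against another:

``optimistic``
    symbols are compatible if *some* expansion is (set intersection /
    existential pairing).  The conservative choice for dimer risk, and the
    default everywhere.
``strict``
    compatibility must hold for *every* expansion of the target (subset /
    universal pairing).
"""

from __future__ import annotations

import enum
import importlib.resources
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import InputError, ValidationError

__all__ = [
    "IUPAC_SETS",
    "PairingMode",
    "Primer",
    "expand",
    "degeneracy",
    "matches",
    "complementary",
    "revcomp",
    "load_primer_tsv",
    "bundled_panel",
    "bundled_panel_metadata",
]

#: IUPAC nucleotide codes -> the set of unambiguous bases each denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


class PairingMode(str, enum.Enum):
    """Decision rule for degenerate-vs-degenerate symbol comparisons."""

    OPTIMISTIC = "optimistic"
    STRICT = "strict"


def _as_mode(mode: "PairingMode | str") -> PairingMode:
    return PairingMode(mode)


def normalize(seq: str, *, context: str = "sequence") -> str:
    """Uppercase *seq*, map U->T, and validate against the IUPAC alphabet.

    Gap characters are rejected here on purpose: only the alignment-aware
    reference reader deals with gapped sequences.
    """
    if not seq:
        raise ValidationError(f"{context} is empty")
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out, start=1):
        if ch not in IUPAC_SETS:
            raise ValidationError(
                f"invalid IUPAC character {ch!r} at position {i} of {context}"
            )
    return out


@dataclass(frozen=True)
class Primer:
    """A named degenerate oligo, stored 5'->3'.

    ``orientation`` is ``"forward"`` or ``"reverse"``; a reverse primer's
    sequence is its own 5'->3' string (i.e. the reverse complement of the
    template's forward strand at its site).
    """

    name: str
    sequence: str
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("primer name is empty")
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(
                f"orientation must be 'forward' or 'reverse', got {self.orientation!r}"
            )
        object.__setattr__(
            self, "sequence", normalize(self.sequence, context=f"primer {self.name}")
        )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_reverse(self) -> bool:
        return self.orientation == "reverse"


def expand(seq: str) -> list[str]:
    """All unambiguous realizations of an IUPAC string, lexicographically sorted.

    The list has ``degeneracy(seq)`` entries, each the length of *seq*.
    """
    seq = normalize(seq)
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return ["".join(p) for p in itertools.product(*pools)]


def degeneracy(seq: str) -> int:
    """Number of unambiguous realizations, without materializing them."""
    seq = normalize(seq)
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def matches(primer_symbol: str, target_symbol: str,
            mode: PairingMode | str = PairingMode.OPTIMISTIC) -> bool:
    """Does a primer symbol match a target symbol?

    optimistic: the base sets intersect.  strict: every base the target can
    be is covered by the primer symbol (target set is a subset).
    """
    mode = _as_mode(mode)
    p = IUPAC_SETS[normalize(primer_symbol, context="primer symbol")]
    t = IUPAC_SETS[normalize(target_symbol, context="target symbol")]
    if mode is PairingMode.OPTIMISTIC:
        return bool(p & t)
    return t <= p


def complementary(a: str, b: str,
                  mode: PairingMode | str = PairingMode.OPTIMISTIC) -> bool:
    """Can symbols *a* and *b* form a Watson-Crick pair?

    optimistic: some expansion of *a* pairs some expansion of *b*.
    strict: every expansion pair is Watson-Crick.
    """
    mode = _as_mode(mode)
    sa = IUPAC_SETS[normalize(a, context="symbol")]
    sb = IUPAC_SETS[normalize(b, context="symbol")]
    pairs = ((x, y) in _WC for x, y in itertools.product(sa, sb))
    return any(pairs) if mode is PairingMode.OPTIMISTIC else all(pairs)


def revcomp(seq: str) -> str:
    """Reverse complement with degenerate symbols mapped to their complements."""
    seq = normalize(seq)
    return "".join(_COMPLEMENT[ch] for ch in reversed(seq))


# ---------------------------------------------------------------------------
# Panel I/O

def load_primer_tsv(path: str | Path) -> list[Primer]:
    """Load primers from a TSV with columns ``name``, ``sequence`` and an
    optional ``orientation`` column (default forward).  Lines starting with
    '#' are comments; a header row is accepted and detected by name."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read primer TSV {path}: {exc}") from exc
    if "name" not in df.columns or "sequence" not in df.columns:
        # headerless two/three-column file
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        df.columns = ["name", "sequence", "orientation"][: df.shape[1]]
    if "orientation" not in df.columns:
        df["orientation"] = "forward"
    primers = [
        Primer(r["name"], r["sequence"], r["orientation"]) for _, r in df.iterrows()
    ]
    names = [p.name for p in primers]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValidationError(f"duplicate primer names in panel: {sorted(dupes)}")
    return primers


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("clampwise").joinpath("data", name)))


def bundled_panel() -> list[Primer]:
    """The packaged six-primer panel for clamping PCR of bacterial SSU rRNA
    genes: modified 63f, KU63f, KU64f, KU68f (forward) and 1492r, KU1494r
    (reverse)."""
    return load_primer_tsv(_data_path("primer_panel.tsv"))


def bundled_panel_metadata() -> pd.DataFrame:
    """Reported properties of the bundled panel as a DataFrame indexed by
    primer name: published Tm range endpoints (deg C) and E. coli 16S
    coordinates of the annealing site (1-based, 5' then 3' end)."""
    df = pd.read_csv(_data_path("primer_panel.tsv"), sep="\t", comment="#", dtype=str)
    for col in ("tm_min_c", "tm_max_c", "pos_5prime", "pos_3prime"):
        df[col] = pd.to_numeric(df[col])
    return df.set_index("name")
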