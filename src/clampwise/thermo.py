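"""Melting temperatures of degenerate primers.

A degenerate primer is a pool of oligos, so its Tm is a *range* over the
expansions.  Three models are offered:

``wallace``
    Tm = 2(A+T) + 4(G+C); the quick rule of thumb for short oligos.
``gc_content``
    Tm = 81.5 + 0.41 %GC - 675/N (Marmur/Schildkraut-style length-corrected
    GC formula).
``nearest_neighbor`` (default)
    Two-state nearest-neighbor sum with the unified DNA/DNA parameter set
    (SantaLucia 1998) pinned in ``data/nn_params.tsv``, entropy salt
    correction dS += 0.368 (N-1) ln[Na+], and
    Tm = 1000 dH / (dS + R ln(C_T/4)) - 273.15 for non-self-complementary
    duplexes in primer excess.

No published Tm convention is attached to the packaged panel's reported
ranges, so those ranges are carried as metadata; pairwise Tm-difference
analysis takes ranges as inputs and works with any model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import pandas as pd

from .errors import CapacityError, ValidationError
from .seqcore import IUPAC_SETS, Primer, degeneracy, expand, normalize, revcomp

__all__ = ["TmModelConfig", "TmRange", "tm_single", "tm_range",
           "max_pair_tm_difference", "ENUMERATION_CAP"]

#: exhaustive-enumeration limit on primer degeneracy
ENUMERATION_CAP = 4096

_R_GAS = 1.987  # cal / (mol K)

_MODELS = ("wallace", "gc_content", "nearest_neighbor")


@dataclass(frozen=True)
class TmModelConfig:
    """Tm model choice plus the conditions the nearest-neighbor model needs.

    ``na_molar`` is the monovalent cation concentration (mol/L) and
    ``oligo_molar`` the total primer strand concentration C_T (mol/L);
    defaults 50 mM Na+ and 0.5 uM primer are ordinary PCR conditions.
    """

    model: str = "nearest_neighbor"
    na_molar: float = 0.05
    oligo_molar: float = 5e-7

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValidationError(f"unknown Tm model {self.model!r}; pick from {_MODELS}")
        if self.model == "nearest_neighbor":
            if self.na_molar <= 0 or self.oligo_molar <= 0:
                raise ValidationError(
                    "nearest_neighbor model needs positive Na+ and oligo concentrations"
                )


@dataclass(frozen=True)
class TmRange:
    """Min/max Tm (deg C) over the expansions of a degenerate primer."""

    tm_min: float
    tm_max: float
    model: TmModelConfig

    def __post_init__(self) -> None:
        if not (math.isfinite(self.tm_min) and math.isfinite(self.tm_max)):
            raise ValidationError("Tm endpoints must be finite")
        if self.tm_min > self.tm_max:
            raise ValidationError(f"tm_min {self.tm_min} > tm_max {self.tm_max}")


@lru_cache(maxsize=1)
def _nn_table() -> dict[str, tuple[float, float]]:
    import importlib.resources

    path = Path(str(importlib.resources.files("clampwise").joinpath("data", "nn_params.tsv")))
    df = pd.read_csv(path, sep="\t", comment="#")
    return {r["key"]: (float(r["dH"]), float(r["dS"])) for _, r in df.iterrows()}


def _tm_nearest_neighbor(seq: str, config: TmModelConfig) -> float:
    table = _nn_table()
    dh, ds = 0.0, 0.0
    for term in (seq[0], seq[-1]):
        key = "init_AT" if term in "AT" else "init_GC"
        h, s = table[key]
        dh += h
        ds += s
    if seq == revcomp(seq):
        h, s = table["sym"]
        dh += h
        ds += s
        ct_factor = 1.0
    else:
        ct_factor = 4.0
    for i in range(len(seq) - 1):
        d = seq[i:i + 2]
        h, s = table.get(d) or table[revcomp(d)]
        dh += h
        ds += s
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(config.na_molar)
    return 1000.0 * dh / (ds_salt + _R_GAS * math.log(config.oligo_molar / ct_factor)) - 273.15


def tm_single(seq: str, config: TmModelConfig | None = None) -> float:
    """Tm (deg C) of one unambiguous oligo, length >= 2."""
    config = config or TmModelConfig()
    seq = normalize(seq)
    if len(seq) < 2:
        raise ValidationError("Tm needs a sequence of length >= 2")
    if any(len(IUPAC_SETS[ch]) > 1 for ch in seq):
        raise ValidationError(
            "degenerate sequence: use tm_range for the Tm range over expansions"
        )
    gc = sum(seq.count(b) for b in "GC")
    at = len(seq) - gc
    if config.model == "wallace":
        return 2.0 * at + 4.0 * gc
    if config.model == "gc_content":
        return 81.5 + 0.41 * (100.0 * gc / len(seq)) - 675.0 / len(seq)
    return _tm_nearest_neighbor(seq, config)


def _extremal_expansions(seq: str) -> tuple[str, str]:
    """GC-minimizing and GC-maximizing realizations of a degenerate string.

    Valid as Tm extremes only for models monotone in per-position GC
    content (wallace, gc_content)."""
    lo, hi = [], []
    for ch in seq:
        bases = sorted(IUPAC_SETS[ch])
        ats = [b for b in bases if b in "AT"]
        gcs = [b for b in bases if b in "GC"]
        lo.append(ats[0] if ats else gcs[0])
        hi.append(gcs[0] if gcs else ats[0])
    return "".join(lo), "".join(hi)


def tm_range(primer: Primer | str, config: TmModelConfig | None = None) -> TmRange:
    """Tm range over all expansions of a degenerate primer.

    Exhaustive enumeration up to degeneracy 4096; beyond that, GC-extremal
    substitution for the monotone models (wallace, gc_content) and a
    capacity error for nearest_neighbor, whose stack terms are not
    per-position monotone.
    """
    config = config or TmModelConfig()
    seq = primer.sequence if isinstance(primer, Primer) else normalize(primer)
    if degeneracy(seq) <= ENUMERATION_CAP:
        tms = [tm_single(s, config) for s in expand(seq)]
        return TmRange(min(tms), max(tms), config)
    if config.model == "nearest_neighbor":
        raise CapacityError(
            f"degeneracy {degeneracy(seq)} exceeds the enumeration cap "
            f"({ENUMERATION_CAP}) and nearest_neighbor has no extremal shortcut"
        )
    lo, hi = _extremal_expansions(seq)
    return TmRange(tm_single(lo, config), tm_single(hi, config), config)


def max_pair_tm_difference(forward: TmRange, reverse: TmRange) -> float:
    """Worst-case |Tm_f - Tm_r| between two primers' Tm ranges (deg C).

    The maximum over endpoint combinations, floored at 0; symmetric in its
    arguments.  A large value flags a pair whose members cannot share an
    annealing temperature comfortably.
    """
    if forward.model != reverse.model:
        raise ValidationError("Tm ranges computed under different models/configs")
    return max(forward.tm_max - reverse.tm_min, reverse.tm_max - forward.tm_min, 0.0)
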