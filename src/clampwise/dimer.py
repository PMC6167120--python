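"""Mutual 3'-end complementarity between a forward/reverse primer pair.

Primer dimers form when the 3' ends of two primers anneal to each other and
extend; the risk scales with the length of the contiguous complementary run
anchored at the 3' termini.  Two views are computed:

* the *mutual* 3' run — the longest antiparallel register in which both 3'
  terminal bases sit inside one contiguous complementary run (the duplex
  from which *both* primers can extend); and
* a scan of every register in which the reverse primer's 3' terminal base
  pairs somewhere on the forward primer, reporting the run growing 5'-ward
  along the reverse primer and whether the forward 3' terminus lies inside
  it (one-sided extension risk).

Runs are contiguous: a single non-complementary pair terminates a run.
Degenerate symbols pair under optimistic mode by default, since
under-reporting dimer risk is the worse failure.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqcore import PairingMode, Primer, complementary

__all__ = ["PairCell", "ScanRun", "DimerReport",
           "mutual_3prime_run", "scan_reverse_anchored_runs", "dimer_report"]


@dataclass(frozen=True)
class PairCell:
    """One paired position of a run: 1-based 5'->3' indices and symbols."""

    forward_pos: int
    reverse_pos: int
    forward_symbol: str
    reverse_symbol: str


@dataclass(frozen=True)
class ScanRun:
    """A reverse-3'-anchored complementary run at one antiparallel register.

    ``offset`` is the forward-primer position (1-based, 5'->3') paired with
    the reverse primer's 3' terminal base.
    """

    offset: int
    run_length: int
    includes_forward_3prime: bool


@dataclass
class DimerReport:
    forward: str
    reverse: str
    mode: PairingMode
    mutual_run: int
    pair_map: list[PairCell]
    scan_runs: list[ScanRun]


def _seq(p: Primer | str) -> str:
    return p.sequence if isinstance(p, Primer) else Primer("_", p).sequence


def mutual_3prime_run(forward: Primer | str, reverse: Primer | str,
                      mode: PairingMode | str = PairingMode.OPTIMISTIC) -> int:
    """Longest k such that the last k bases of the forward primer pair,
    antiparallel, with the last k bases of the reverse primer.

    k ranges over all registers independently: for each k the forward
    positions L-k+1..L are tested against reverse positions M..M-k+1, so
    both 3' termini lie inside the run.  Returns 0 when no register works.
    """
    f, r = _seq(forward), _seq(reverse)
    mode = PairingMode(mode)
    best = 0
    for k in range(1, min(len(f), len(r)) + 1):
        if all(complementary(f[len(f) - k + i - 1], r[len(r) - i], mode)
               for i in range(1, k + 1)):
            best = k
    return best


def scan_reverse_anchored_runs(forward: Primer | str, reverse: Primer | str,
                               mode: PairingMode | str = PairingMode.OPTIMISTIC
                               ) -> list[ScanRun]:
    """All reverse-3'-anchored complementary runs, one per register.

    For every forward position j at which the reverse 3' terminal base can
    pair, the run extends 5'-ward along the reverse primer (3'-ward along
    the forward).  Sorted by run length descending, then smaller offset.
    """
    f, r = _seq(forward), _seq(reverse)
    mode = PairingMode(mode)
    runs: list[ScanRun] = []
    for j in range(1, len(f) + 1):
        if not complementary(f[j - 1], r[-1], mode):
            continue
        t = 1
        while j + t <= len(f) and t < len(r) and \
                complementary(f[j + t - 1], r[len(r) - 1 - t], mode):
            t += 1
        runs.append(ScanRun(offset=j, run_length=t,
                            includes_forward_3prime=(j + t - 1 == len(f))))
    runs.sort(key=lambda s: (-s.run_length, s.offset))
    return runs


def dimer_report(forward: Primer | str, reverse: Primer | str,
                 mode: PairingMode | str = PairingMode.OPTIMISTIC) -> DimerReport:
    """Full dimer analysis of one pair (use forward == reverse for a
    self-dimer check)."""
    f, r = _seq(forward), _seq(reverse)
    mode = PairingMode(mode)
    k = mutual_3prime_run(f, r, mode)
    pair_map = [
        PairCell(forward_pos=len(f) - k + i,
                 reverse_pos=len(r) - i + 1,
                 forward_symbol=f[len(f) - k + i - 1],
                 reverse_symbol=r[len(r) - i])
        for i in range(1, k + 1)
    ]
    fname = forward.name if isinstance(forward, Primer) else f
    rname = reverse.name if isinstance(reverse, Primer) else r
    return DimerReport(forward=fname, reverse=rname, mode=mode,
                       mutual_run=k, pair_map=pair_map,
                       scan_runs=scan_reverse_anchored_runs(f, r, mode))
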