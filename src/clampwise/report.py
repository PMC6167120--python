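"""Report writers shaped like the standard primer-panel summary tables.

All writers are byte-stable given fixed inputs: rows follow input order or
sorted keys, percentages and temperatures are formatted to one decimal.
"""

from __future__ import annotations

import io
from dataclasses import asdict

import pandas as pd

from . import coverage as _coverage
from . import dimer as _dimer
from . import positioning as _positioning
from . import thermo as _thermo
from .errors import ValidationError
from .reference_io import ReferenceSet
from .seqcore import PairingMode, Primer

__all__ = ["report_primer_panel", "report_dimer_matrix", "render_register"]


def _fmt(x: float | None, nd: int = 1) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def report_primer_panel(panel: list[Primer],
                        reference_set: ReferenceSet | None = None,
                        numbering_ref: str | None = None,
                        tm_config: "_thermo.TmModelConfig | None" = None,
                        sites: dict[str, tuple[int, int]] | None = None,
                        mismatch_budget: int = 0) -> pd.DataFrame:
    """One row per primer: name, sequence, Tm range, coverage (if a
    reference set is given), size as "<N>mer", and numbering-reference
    position as "5'-3'" (if a numbering reference or explicit sites are
    given)."""
    if not panel:
        raise ValidationError("empty primer panel")
    tm_config = tm_config or _thermo.TmModelConfig()
    rows = []
    for p in panel:
        tr = _thermo.tm_range(p, tm_config)
        site = None
        if sites and p.name in sites:
            site = sites[p.name]
        elif numbering_ref is not None:
            ps = _positioning.map_to_reference(p, numbering_ref)
            if ps is not None:
                site = ps.span
        pos_txt = "NA"
        if site is not None:
            lo, hi = site
            pos_txt = f"{hi}-{lo}" if p.is_reverse else f"{lo}-{hi}"
        cov_txt = "NA"
        if reference_set is not None and site is not None:
            res = _coverage.primer_coverage(reference_set, p, site=site,
                                            mismatch_budget=mismatch_budget)
            overall = next(r for r in res if r.taxon == _coverage.ALL_TAXA)
            cov_txt = _fmt(overall.coverage_pct)
        rows.append({
            "primer": p.name,
            "sequence": p.sequence,
            "tm_range_c": f"{_fmt(tr.tm_min)}-{_fmt(tr.tm_max)}",
            "coverage_pct": cov_txt,
            "size": f"{len(p)}mer",
            "position": pos_txt,
        })
    return pd.DataFrame(rows)


def render_register(forward: Primer, reverse: Primer,
                    mode: PairingMode | str = PairingMode.OPTIMISTIC) -> str:
    """Textual antiparallel alignment of a pair at its mutual 3'-end
    register, with the complementary run marked."""
    rep = _dimer.dimer_report(forward, reverse, mode)
    f, r = forward.sequence, reverse.sequence
    k = rep.mutual_run
    f_line = f"{forward.name:>12}  5'-{f}-3'"
    # reverse drawn 3'->5' so paired columns line up; its 3' terminus sits
    # under forward position len(f)-k+1
    indent = len(f"{forward.name:>12}  5'-") + (len(f) - k)
    r_line = " " * indent + f"3'-{r[::-1]}-5'  {reverse.name}"
    marks = " " * (indent + 3) + "|" * k if k else " " * (indent + 3) + "(no mutual 3' run)"
    return "\n".join([f_line, marks, r_line])


def report_dimer_matrix(forward_panel: list[Primer], reverse_panel: list[Primer],
                        mode: PairingMode | str = PairingMode.OPTIMISTIC
                        ) -> tuple[pd.DataFrame, str]:
    """Matrix of mutual 3'-run lengths (rows: forward, cols: reverse) plus
    the per-pair register renderings."""
    if not forward_panel or not reverse_panel:
        raise ValidationError("empty primer panel")
    mat = pd.DataFrame(
        [[_dimer.mutual_3prime_run(f, r, mode) for r in reverse_panel]
         for f in forward_panel],
        index=[f.name for f in forward_panel],
        columns=[r.name for r in reverse_panel],
    )
    buf = io.StringIO()
    for f in forward_panel:
        for r in reverse_panel:
            buf.write(render_register(f, r, mode))
            buf.write("\n\n")
    return mat, buf.getvalue()
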