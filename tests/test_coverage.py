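"""Coverage, per-base profiling, site location, critical-window flags."""

import numpy as np
import pytest

from clampwise.coverage import (ALL_TAXA, CriticalWindowFlag,
                                PerBaseCoverageTable, critical_window_flags,
                                load_profile_table, locate_site,
                                per_base_coverage, primer_coverage)
from clampwise.errors import ValidationError
from clampwise.reference_io import ReferenceSet, TaxonomyRecord
from clampwise.seqcore import Primer, expand, revcomp


def _make_set(seqs: dict[str, str], phyla: dict[str, str] | None = None,
              aligned: bool = False) -> ReferenceSet:
    phyla = phyla or {}
    tax = {sid: TaxonomyRecord(sid, (("domain", "Bacteria"),
                                     ("phylum", phyla.get(sid, "Firmicutes"))))
           for sid in seqs}
    return ReferenceSet(records=dict(seqs), taxonomy=tax, aligned=aligned)


# ---------------------------------------------------------------------------
# whole-site coverage

def test_three_of_four_spanning_sequences_match():
    primer = Primer("p", "ACGT")
    rs = _make_set({"a": "ACGT", "b": "ACGT", "c": "ACGT", "d": "AGGT"})
    res = primer_coverage(rs, primer, site=(1, 4))
    overall = next(r for r in res if r.taxon == ALL_TAXA)
    assert (overall.n_spanning, overall.n_matched) == (4, 3)
    assert overall.coverage_pct == 75.0


def test_all_n_primer_covers_everything():
    primer = Primer("p", "NNNN")
    rs = _make_set({"a": "ACGT", "b": "GGCC", "c": "TTTT"})
    overall = next(r for r in primer_coverage(rs, primer, site=(1, 4))
                   if r.taxon == ALL_TAXA)
    assert overall.coverage_pct == 100.0


def test_reference_n_counts_as_mismatch_unless_primer_covers_it():
    rs = _make_set({"amb": "ANGT"})
    res = primer_coverage(rs, Primer("p", "ACGT"), site=(1, 4))
    assert res[0].n_matched == 0  # N not covered by C
    res = primer_coverage(rs, Primer("p", "ANGT"), site=(1, 4))
    assert res[0].n_matched == 1  # primer N covers any reference base


def test_coverage_monotone_in_mismatch_budget():
    primer = Primer("p", "ACGTACGT")
    rng = np.random.default_rng(5)
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 8)) for i in range(40)}
    rs = _make_set(seqs)
    prev = -1.0
    for budget in range(0, 9):
        res = next(r for r in primer_coverage(rs, primer, site=(1, 8),
                                              mismatch_budget=budget)
                   if r.taxon == ALL_TAXA)
        assert res.coverage_pct >= prev
        prev = res.coverage_pct
    assert prev == 100.0


def test_empty_taxon_is_undefined_not_zero():
    rs = _make_set({"a": "--GT", "b": "ACGT"},
                   phyla={"a": "TM6", "b": "Firmicutes"}, aligned=True)
    rs.column_map = {i: i for i in range(1, 5)}
    res = primer_coverage(rs, Primer("p", "ACGT"), site=(1, 4))
    taxa = {r.taxon: r for r in res}
    assert "TM6" not in taxa  # no spanning sequence: no silent 0% row
    assert taxa["Firmicutes"].coverage_pct == 100.0


def test_budget_zero_consistent_with_per_base_cells():
    """With budget 0, a sequence is covered iff every per-base comparison
    matches; check the aggregate identity on a mixed set."""
    primer = Primer("p", "ACGT")
    rs = _make_set({"a": "ACGT", "b": "ACGA", "c": "TCGT"},
                   phyla={"a": "P1", "b": "P1", "c": "P2"})
    cov = {r.taxon: r for r in primer_coverage(rs, primer, site=(1, 4))}
    table = per_base_coverage(rs, primer, (1, 4))
    # P1: one of two sequences fails only at position 4
    assert list(table.cells.loc["P1"]) == [100.0, 100.0, 100.0, 50.0]
    assert cov["P1"].coverage_pct == 50.0
    # P2: single sequence failing at position 1
    assert cov["P2"].coverage_pct == 0.0
    assert table.cells.loc["P2", 1] == 0.0


def test_planted_mismatch_rate_recovered_within_three_sigma(small_synthetic):
    spec, rs, truth = small_synthetic
    primer = Primer("KU68f", "AYACATGCAAGTCGARCG")
    site = (51, 68)
    cov = {r.taxon: r for r in primer_coverage(rs, primer, site=site)}
    n = dict(spec.taxa)
    for taxon in ("Alphaproteobacteria", "Planctomycetes", "Firmicutes"):
        exp = truth.expected_perfect_pct(taxon, list(range(51, 69))) / 100.0
        sigma = 100.0 * np.sqrt(exp * (1 - exp) / n[taxon])
        assert abs(cov[taxon].coverage_pct - 100.0 * exp) <= max(3 * sigma, 1e-9)


# ---------------------------------------------------------------------------
# site location

def test_locate_planted_primer_exactly():
    rng = np.random.default_rng(1)
    primer = Primer("KU63f", "GCYTWAYACATGCAAGTC")
    background = "".join(rng.choice(list("ACGT"), 200))
    planted = expand(primer.sequence)[0]
    template = background[:45] + planted + background[45 + 18:]
    hit = locate_site(template, primer)
    assert (hit.start, hit.end, hit.strand, hit.mismatches) == (46, 63, "+", 0)


def test_locate_reverse_primer_reports_forward_strand():
    rng = np.random.default_rng(2)
    primer = Primer("KU1494r", "GGYTACCTTGTTACGAC", "reverse")
    background = "".join(rng.choice(list("ACGT"), 120))
    planted = expand(revcomp(primer.sequence))[0]
    template = background[:50] + planted + background[50 + 17:]
    hit = locate_site(template, primer)
    assert (hit.start, hit.end, hit.strand) == (51, 67, "-")


def test_locate_absent_primer_returns_none():
    assert locate_site("A" * 100, Primer("p", "GGGGCCCCGGGG"), max_mismatch=2) is None


def test_locate_tie_breaks_leftmost():
    template = "TTACGTTTACGTTT"
    hit = locate_site(template, Primer("p", "ACGT"), max_mismatch=0)
    assert hit.start == 3


# ---------------------------------------------------------------------------
# per-base tables

def test_expansion_set_gives_all_cells_100():
    primer = Primer("p", "AYRT")
    rs = _make_set({f"e{i}": s for i, s in enumerate(expand(primer.sequence))})
    table = per_base_coverage(rs, primer, (1, 4))
    assert (table.cells.to_numpy() == 100.0).all()


def test_mismatch_planted_at_single_position():
    primer = Primer("p", "ACGTACGT")
    good = "ACGTACGT"
    bad = "ACGTTCGT"  # position 5 only
    rs = _make_set({"g1": good, "g2": good, "b": bad})
    table = per_base_coverage(rs, primer, (1, 8))
    expected = [100.0] * 8
    expected[4] = pytest.approx(200.0 / 3)
    assert list(table.cells.loc["Firmicutes"]) == expected


def test_empty_taxon_row_omitted_with_warning():
    rs = _make_set({"a": "--GT", "b": "ACGT"},
                   phyla={"a": "TM6", "b": "Firmicutes"}, aligned=True)
    rs.column_map = {i: i for i in range(1, 5)}
    with pytest.warns(UserWarning, match="TM6"):
        table = per_base_coverage(rs, Primer("p", "ACGT"), (1, 4))
    assert list(table.cells.index) == ["Firmicutes"]


def test_reverse_primer_three_prime_window_is_low_coordinate_end():
    table = PerBaseCoverageTable(
        positions=[1494, 1495, 1496, 1497], primer_symbols=list("GTCG"),
        orientation="reverse",
        cells=__import__("pandas").DataFrame(
            [[50.0, 90.0, 90.0, 90.0]], index=["P"], columns=[1494, 1495, 1496, 1497]))
    assert table.three_prime_window(3) == [1494, 1495, 1496]


# ---------------------------------------------------------------------------
# critical-window flags

def test_bundled_profile_window4_threshold79_unflagged_set():
    """On the packaged ten-phylum 3'-end grid, the phyla with every cell at
    positions 65-68 at/above 79% are exactly the five known tolerant ones."""
    table = load_profile_table()
    flags = critical_window_flags(table, window_len=4, threshold_pct=79.0)
    unflagged = {f.taxon for f in flags if not f.flagged}
    assert unflagged == {"Proteobacteria", "Firmicutes", "Actinobacteria",
                         "TM7", "Verrucomicrobia"}
    assert all(f.window_positions == (65, 66, 67, 68) for f in flags)
    assert all(f.flagged == (f.min_cell_pct < 79.0) for f in flags)


def test_threshold_extremes():
    table = load_profile_table()
    assert not any(f.flagged for f in critical_window_flags(table, 4, 0.0))
    flags100 = critical_window_flags(table, 4, 100.0)
    assert all(f.flagged for f in flags100)  # every phylum has a cell < 100


def test_window_longer_than_table_rejected():
    table = load_profile_table()
    with pytest.raises(ValidationError):
        critical_window_flags(table, window_len=10)
    with pytest.raises(ValidationError):
        critical_window_flags(table, 4, threshold_pct=150)
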