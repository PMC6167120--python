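"""Synthetic collection generator: determinism and truth recovery."""

import numpy as np
import pytest

from clampwise.coverage import per_base_coverage, primer_coverage
from clampwise.errors import ValidationError
from clampwise.synthetic import (NUMBERING_REF_ID, SyntheticSpec, TruthTable,
                                 default_rates, generate_organelle_decoys,
                                 generate_reference_set, merge_reference_sets)


def test_same_seed_gives_byte_identical_files(tmp_path):
    spec = SyntheticSpec(taxa=(("Firmicutes", 30), ("TM7", 30)), seed=99)
    generate_reference_set(spec, out_dir=tmp_path / "a")
    generate_reference_set(spec, out_dir=tmp_path / "b")
    for name in ("reference.fasta", "taxonomy.tsv", "truth.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
               (tmp_path / "b" / name).read_bytes()


def test_different_seed_changes_output(tmp_path):
    base = SyntheticSpec(taxa=(("Firmicutes", 10),), seed=1)
    other = SyntheticSpec(taxa=(("Firmicutes", 10),), seed=2)
    a, _ = generate_reference_set(base)
    b, _ = generate_reference_set(other)
    assert a.records != b.records


def test_zero_rates_give_perfect_coverage(panel):
    spec = SyntheticSpec(taxa=(("Firmicutes", 40),), rates={},
                         background_rate=0.0, seed=5)
    rs, truth = generate_reference_set(spec)
    for p in panel.values():
        from clampwise.seqcore import bundled_panel_metadata
        row = bundled_panel_metadata().loc[p.name]
        lo = int(min(row["pos_5prime"], row["pos_3prime"]))
        hi = int(max(row["pos_5prime"], row["pos_3prime"]))
        res = primer_coverage(rs, p, site=(lo, hi))
        assert all(r.coverage_pct == 100.0 for r in res)
    assert truth.expected_per_base("Firmicutes", 63) == 100.0


def test_rate_one_zeroes_the_position():
    spec = SyntheticSpec(taxa=(("Firmicutes", 25),),
                         rates={("Firmicutes", 65): 1.0},
                         background_rate=0.0, seed=6)
    rs, truth = generate_reference_set(spec)
    from clampwise.seqcore import Primer
    primer = Primer("KU68f", "AYACATGCAAGTCGARCG")
    table = per_base_coverage(rs, primer, (51, 68))
    assert table.cells.loc["Firmicutes", 65] == 0.0
    assert (table.cells.loc["Firmicutes"].drop(65) == 100.0).all()
    overall = primer_coverage(rs, primer, site=(51, 68))[0]
    assert overall.coverage_pct == 0.0
    assert truth.expected_perfect_pct("Firmicutes", range(51, 69)) == 0.0


def test_per_base_truth_recovery_within_three_sigma(small_synthetic):
    """Observed per-base coverage at every planted position stays within 3
    binomial standard deviations of its expectation (n=300/phylum)."""
    spec, rs, truth = small_synthetic
    from clampwise.seqcore import Primer
    primer = Primer("KU68f", "AYACATGCAAGTCGARCG")
    table = per_base_coverage(rs, primer, (51, 68))
    n = dict(spec.taxa)
    for taxon in table.cells.index:
        for pos in table.positions:
            exp = truth.expected_per_base(taxon, pos) / 100.0
            sigma = 100.0 * np.sqrt(exp * (1 - exp) / n[taxon])
            obs = float(table.cells.loc[taxon, pos])
            assert abs(obs - 100.0 * exp) <= max(3.0 * sigma, 1e-9), (taxon, pos)


def test_spec_validation():
    with pytest.raises(ValidationError):
        SyntheticSpec(taxa=(("A", 5), ("A", 5)))
    with pytest.raises(ValidationError):
        SyntheticSpec(taxa=(("A", 0),))
    with pytest.raises(ValidationError):
        SyntheticSpec(rates={("A", 63): 1.5})
    with pytest.raises(ValidationError):
        SyntheticSpec(background_rate=-0.1)
    with pytest.raises(ValidationError):
        SyntheticSpec(template_length=100)


def test_default_conditions_mirror_bundled_profile():
    spec = SyntheticSpec()
    assert len(spec.taxa) == 10
    assert all(n == 500 for _, n in spec.taxa)
    rates = default_rates()
    assert rates[("TM6", 60)] == pytest.approx(1 - 0.583)
    assert rates[("Proteobacteria", 68)] == pytest.approx(1 - 0.947)


def test_truth_table_consistency():
    truth = TruthTable(per_base_pct={("P", 60): 90.0, ("P", 61): 80.0},
                       site_positions=(60, 61))
    assert truth.expected_perfect_pct("P", [60, 61]) == pytest.approx(72.0)


def test_decoys_share_primer_sites_but_separate_by_taxon(panel):
    spec = SyntheticSpec(taxa=(("Firmicutes", 30),), rates={},
                         background_rate=0.0, seed=8)
    bacteria, _ = generate_reference_set(spec)
    decoys = generate_organelle_decoys(spec, n_mitochondrion=10, n_plastid=10)
    # decoys drop the numbering reference; merge into one mixed set
    del bacteria.records[NUMBERING_REF_ID]
    del bacteria.taxonomy[NUMBERING_REF_ID]
    bacteria.numbering_ref_id = None
    mixed = merge_reference_sets(bacteria, decoys)
    res = {r.taxon: r for r in primer_coverage(mixed, panel["KU63f"], site=(46, 63))}
    # the conserved primer site is present in organelles too: the clamp, not
    # the primer, is what discriminates
    for taxon in ("Firmicutes", "mitochondrion", "plastid"):
        assert res[taxon].coverage_pct == 100.0
    assert res["mitochondrion"].n_spanning == 10


def test_zero_decoys_requested():
    spec = SyntheticSpec(taxa=(("Firmicutes", 1),), seed=8)
    empty = generate_organelle_decoys(spec, n_mitochondrion=0, n_plastid=0)
    assert len(empty) == 0


def test_organelle_signatures_differ_between_classes():
    spec = SyntheticSpec(taxa=(("Firmicutes", 1),), seed=8)
    decoys = generate_organelle_decoys(spec, n_mitochondrion=3, n_plastid=3)
    sig = decoys.load_report["signatures"]
    assert sig["mitochondrion"]["forward"] != sig["plastid"]["forward"]
    # every decoy of a class carries its class signature verbatim
    for sid, seq in decoys.records.items():
        organelle = decoys.phylum_of(sid)
        window, s = sig[organelle]["forward"].split(":")
        lo, hi = (int(x) for x in window.split("-"))
        assert seq[lo - 1:hi] == s
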