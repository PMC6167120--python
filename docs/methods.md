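# Methods

This note documents the models and numerical conventions behind
`clampwise`, the choices made where the design was genuinely open, and what
the synthetic-data tests do and do not demonstrate about real reference
collections.

## Degenerate-symbol semantics

Every IUPAC code denotes a set of bases; a degenerate primer is a uniform
pool over the per-position products. Two comparison semantics exist
whenever an ambiguous symbol meets another symbol:

* **optimistic** — the comparison succeeds if *some* pair of expansions
  succeeds (non-empty set intersection for matching; existential
  Watson–Crick pairing for complementarity);
* **strict** — it must succeed for *every* expansion of the target
  (subset for matching; universal pairing for complementarity).

Optimistic is the default everywhere. For dimer risk it is the
conservative choice (a degenerate position that *can* pair is a risk some
fraction of the pool realizes); for coverage it reflects that a degenerate
primer pool contains the matching oligo. One asymmetric exception: an
**ambiguous base in the reference** (N and friends) counts as a mismatch
unless the primer symbol covers its whole base set. Database uncertainty
is not evidence of a match, so coverage is not inflated by poorly
determined reference positions.

`U` is normalized to `T` on input (SSU rRNA collections mix gene and
transcript conventions) and lowercase to uppercase. Gap characters are
rejected everywhere except in aligned reference collections, which are the
responsibility of `reference_io`.

## Coordinates

All positions are 1-based and inclusive on both ends, in the numbering of
a designated reference sequence (conventionally E. coli 16S — "position
46–63" style). Reverse primers are quoted 5' coordinate first, hence
descending ("1510–1494"), and are reverse-complemented onto the forward
strand before any locus comparison. The numbering reference is an input,
never embedded: tests and the generator construct synthetic references
carrying the panel sites at their published coordinates.

## Coverage

A sequence **spans** a locus when its aligned window neither begins nor
ends with a gap; non-spanning records (typically partial-length database
entries) are excluded from numerator *and* denominator and reported
separately, so truncated deposits cannot deflate coverage. Whole-site
coverage counts a spanning sequence as covered when at most
`mismatch_budget` window positions fail the per-base rule; the default
budget is 0 (perfect-match coverage, the usual coverage-tool semantics),
exposed as a parameter. Per-base coverage is the percentage of spanning
sequences in a taxon matching the primer symbol at one position. A taxon
with no spanning sequence gets an *undefined* (None) coverage, never a
silent 0%, and is dropped from per-base tables with a warning.

Coverage with budget 0 and the per-base table are mutually consistent by
construction: a sequence is perfectly covered iff it contributes a match
in every column. The critical-window rule flags a taxon when any per-base
cell among the last `w ∈ {3, 4}` 3'-end positions falls below a threshold
— the span in which a single primer–template mismatch inhibits
amplification even at permissive annealing temperatures. For a reverse
primer profiled on the forward strand the 3' window is the *low*-coordinate
end of the table.

For unaligned single-record searches, `locate_site` scans every ungapped
offset (both orientations handled via reverse complement), scoring
mismatches under the rules above, ties broken leftmost; placements worse
than `max_mismatch` (default 3) are rejected.

## Dimer model

Dimer risk is scored as the longest *contiguous* complementary run in an
antiparallel register that contains both 3' termini (`mutual_3prime_run`):
for each candidate length k the last k bases of the forward primer are
tested against the last k of the reverse, and a single non-complementary
pair terminates the run. Contiguity is the right model here: removing a
reverse primer's terminal dinucleotide shifts the register and genuinely
shortens the run, which is exactly the designed effect in the bundled
panel (5 → 3/4 → 1 across the redesigns). Non-contiguous complementary
positions are not accumulated.

The register scan (`scan_reverse_anchored_runs`) reports, for every
position where the reverse primer's 3' terminal base can pair on the
forward primer, the run extending 5'-ward along the reverse primer and
whether the forward 3' terminus lies inside it. A long run that *excludes*
the forward terminus is a one-sided structure from which only the reverse
primer could extend — a qualitatively smaller risk than mutual extension,
and the property that distinguishes the 3'-shifted forward primer in the
bundled panel. Self-dimers are the same operations with both arguments
equal. Thermodynamic ΔG scoring and hairpins are out of scope.

## Melting temperatures

Three models, selected by `TmModelConfig`:

| model | formula | use |
|---|---|---|
| `wallace` | 2(A+T) + 4(G+C) | quick short-oligo rule |
| `gc_content` | 81.5 + 0.41·%GC − 675/N | length-corrected GC rule |
| `nearest_neighbor` (default) | two-state NN sum, unified DNA/DNA parameters | defensible absolute values |

The nearest-neighbor parameters (SantaLucia 1998 unified set: ten stacks,
terminal A·T/G·C initiation, symmetry term) are pinned in
`src/clampwise/data/nn_params.tsv`; the entropy salt correction is
ΔS += 0.368(N−1)·ln[Na⁺] and Tm = 1000·ΔH / (ΔS + R·ln(C_T/x)) − 273.15
with x = 4 for non-self-complementary duplexes (x = 1 plus the symmetry
term for self-complementary ones). Defaults: 50 mM Na⁺, C_T = 0.5 µM.
Tm values are reported to 0.1 °C; range endpoints are never rounded before
differencing.

A degenerate primer's `TmRange` is the min/max over its expansions,
enumerated exhaustively up to degeneracy 4096. Beyond the cap, Wallace and
GC-content Tm are monotone in per-position GC content, so the range is
obtained by GC-extremal substitution (proved equal to enumeration by a
seeded oracle test); nearest-neighbor stack terms are not per-position
monotone and raise a capacity error instead of guessing.

The worst-case pair difference is
`max(Tm_max^F − Tm_min^R, Tm_max^R − Tm_min^F, 0)` — the largest |ΔTm|
over endpoint combinations, symmetric in its arguments.

**Known limitation.** The bundled panel ships with its reported Tm ranges
as metadata, and no tested model reproduces them exactly (Wallace gives
50–54 °C for KU63f against a reported 54–60 °C; the reporting convention
for those values is not stated anywhere we can verify). The toolkit
therefore treats reported ranges as *inputs* to pair-difference analysis
and never reverse-engineers a formula to fit them. Clamp (LNA) duplex
thermodynamics are likewise not computed — LNA-modified stacks need their
own parameter set — so clamp Tm is user-supplied metadata.

## Clamp competition

Competition is interval arithmetic on numbering coordinates: the overlap
of two inclusive position ranges, strand-agnostic, with a primer declared
"competing" when the overlap reaches `min_overlap`. The default
`min_overlap = primer length − 3` encodes near-total containment, the
geometry in which a primer annealing site sits essentially inside the
clamp window; the exact geometry a given design requires is configurable
because no sharper universal criterion exists.

## Synthetic collections

The generator emulates the *structure coverage profiling measures*, not
16S evolution: a seeded ~1,510-nt uniform-random template carrying the six
bundled primer sites at their published coordinates (site positions hold
the degenerate primer symbol; each simulated sequence draws a concrete
base from the symbol's set), per-(phylum, position) mismatch rates that
replace the drawn base with a uniform choice among the bases the primer
does *not* cover, and an independent background substitution rate (default
2%) everywhere outside primer sites. With an insertion-column rate > 0 an
aligned set is emitted (numbering reference gapped at insertion columns)
to exercise column-map logic; otherwise sequences share the template's
coordinate frame directly. Organelle decoys share the conserved primer
sites — the very reason clamping is needed — but carry class-specific
signature sequence in clamp-flanking windows (positions 30–42 and
1471–1491).

Default conditions: the ten phyla of the packaged per-base grid, 500
sequences per phylum, and per-position rates derived from that grid
(rate = 1 − pct/100 at positions 60–68), so the default collection
reproduces the mismatch structure the grid reports. Everything is driven
by one `numpy` generator seeded from the spec, with a fixed draw order, so
a spec + seed pair yields byte-identical FASTA.

Because mismatches are planted independently per position, the truth table
is exact: expected per-base coverage is 100(1 − r) and expected
perfect-match coverage is 100·Π(1 − r) over the site. Tests and the
acceptance script check recovery within 3 binomial standard deviations per
cell. **What this does and does not show:** it validates the counting
machinery (denominators, spanning rules, degenerate matching, taxon
partitioning) end to end, but synthetic sequences have no covariation
between positions, no phylogenetic structure, no chimeras and no
length-truncation pattern beyond the planted gaps — so coverage figures on
real database snapshots (which additionally depend on the snapshot's
sequence selection) are not reproduced here, only the computations that
produce them. Note also that a maximum over many per-cell z-scores is an
extreme-order statistic: on 180 cells a worst |z| slightly above 3 occurs
in roughly a third of seeds, which is why the acceptance script reports
the measured maximum rather than clipping it.

## Problem sizes

Test-suite and acceptance runs use the generator at 300–500 sequences per
phylum (1,510 nt each), sizes at which binomial noise on a per-base cell
is ~1–2 percentage points and the full pipeline runs in seconds; the
oracle sweeps use 1,000 random primer pairs (dimer) and 200 random
degenerate primers (Tm extremal-substitution equivalence).
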