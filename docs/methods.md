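# Methods

## Model of a restriction digest

A restriction enzyme is modelled as an IUPAC recognition pattern plus a
single top-strand cut offset (e.g. HinfI = `G^ANTC`, offset 1). Digestion
of a chromosome is deterministic and complete: every occurrence of the
recognition site is cut (no partial digestion, no star activity, no
methylation-state dependence — methylation sensitivity is carried as
catalog metadata only). Chromosomes are independent molecules: fragments
never span record boundaries.

Site scanning reports every match start on the forward strand, overlaps
included; degenerate pattern positions expand to their IUPAC base sets.
For non-palindromic patterns the reverse-complement pattern is scanned too
and positions are merged — a no-op for the (palindromic) built-in catalog,
but correct for arbitrary user enzymes. Two asymmetries matter:

* **Genome ambiguity codes match nothing**, including pattern `N`.
  Assembly gaps (N runs) must not generate phantom cut sites or fragments;
  windowed profiles over gap-rich regions consequently show the
  characteristic count drops.
* **Reverse-orientation cuts** of a non-palindromic site starting at `p`
  fall at `p + site_length − cut_offset`: the enzyme sits on the opposite
  strand, so its bottom-strand cleavage is what crosses the reported
  (top) strand.

Cut coordinates from all participating enzymes are merged and
deduplicated; a coordinate claimed by two enzymes keeps both labels, and a
fragment end carries the full label set (either enzyme's adapter could
ligate there). Fragments are the half-open intervals between consecutive
cuts, 0-based, so interval arithmetic and BED export are exact.

## Selection rules and IgC

GBS library selection is modelled as (i) an inclusive length window,
default 100–600 bp — deliberately wider than the 200–400 bp of current
protocols, for comparative screening headroom — and (ii) for double
digests the **different-ends rule**: a fragment is sequenceable only if
two *distinct* enzymes can be assigned to its two ends. A chromosome end
never qualifies, so terminal fragments are excluded from pair-mode
selection automatically. A fragment whose end carries a shared label set
(`{A}` / `{A,B}`) qualifies, since assignment A–B is possible; excluding it
would silently discard real library molecules. A self-pair (E, E)
therefore selects nothing and has IgC 0 by construction.

The coverage statistic is `IgC = 100 · selected_length / genome_length`,
in percent. The denominator defaults to the reported assembly length
(every letter, N included); `acgt_only` is available for gap-heavy
assemblies. Values are kept at full precision internally; tabular output
rounds half-up to one decimal only at the presentation layer.

### Open conventions

Two conventions the published tables do not state are exposed as flags
rather than guessed:

* `boundary_mode` — fragment boundaries at the physical cut coordinate
  (`cut_offset`, default) or at the recognition-site start (`site_start`);
  the difference is a few bp per fragment.
* `terminal_policy` — whether chromosome-terminal segments count as
  fragments (`include`, default, which makes fragment lengths sum exactly
  to the record length) or not (`exclude`); the effect is at most two
  fragments per record.

`igc_gbs.reproduce.convention_sweep` digests under all four combinations
so a published genome-scale count can be matched exactly and the
generating convention identified; any residual is reported alongside the
assembly used.

## Windowed profiles

Fragment density along a chromosome is reported per fixed-width window
(default 100 kb). Windows are tumbling (step = width) so counts are
disjoint and sum to the fragment total; a `step` parameter enables
overlapping sliding windows. A fragment belongs to the window containing
its start coordinate — unambiguous and order-independent; versus counting
overlaps, the difference is at most one fragment per window for ≤600-bp
fragments in 100-kb windows. The short final window is kept, preserving
the count total. Each window also reports the mean cut coordinate within
it (NaN when the window holds no cuts).

## Batch ranking

`build_matrix` digests an (enzyme or pair) × genome grid; each cell is an
independent digest, so cells equal single runs and the grid is
deterministic. A genome that fails to load marks its column missing (NaN)
without aborting the grid, and missing cells are excluded from summaries
rather than imputed. Row summaries use the sample standard deviation
(ddof = 1), which reproduces the printed SD columns of the bundled
published tables; the convention is recorded in the matrix metadata.
Ratios to a reference row are computed from full-precision values —
re-deriving printed per-species ratios from printed (rounded) coverages
can differ in the second decimal, which is why the bundled empirical table
carries the printed ratios themselves.

## Synthetic genomes and the oracle

The fixture generator draws i.i.d. bases at a requested GC fraction, then
overwrites planted motifs and N-gap runs at declared coordinates. The
background is guaranteed free of a declared set of recognition motifs in
either orientation, enforced by redrawing offending windows at generation
time (not post-hoc masking), so that *every* site in the result is
planted. Each record gets its own PRNG stream spawned deterministically
from the spec seed: identical seeds give byte-identical FASTA, and
appending records never reshuffles earlier ones.

Because all sites are planted, the exact digest outcome follows from
direct arithmetic on the planted coordinates. `expected_digest` performs
that arithmetic without touching the scanning/digestion modules and
refuses to run unless the motif-freedom guarantee covers every enzyme
under test; it is the oracle the engine is tested against, alongside a
second, position-by-position IUPAC comparison oracle implemented
independently inside the test suite.

What the generator does *not* emulate: repeat structure, isochores / GC
heterogeneity along a chromosome, methylation landscapes, and sequencing
artefacts. Passing oracle tests therefore demonstrates the correctness of
the digestion arithmetic, not the realism of coverage values for any real
genome; realistic values come from running the same code on a real
assembly (see the convention-sweep harness).

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely at desk scale —
toy sequences of 12–25 bp, random sequences up to ~20 kb, and synthetic
genomes of 10–15 kb with 20–40 planted sites — chosen so the full battery
completes in seconds while still exercising every code path (gaps,
multi-record genomes, both boundary modes, both terminal policies, both
strand orientations). Genome-scale runs use the identical code path; a
~120-Mb plant assembly digests in minutes on one CPU.

Degenerate-input behaviour: an empty sequence or a site-free record is a
valid digest (one terminal-terminal fragment, or none under `exclude`);
cuts at coordinate 0 or L would create zero-length fragments and are
suppressed; `min_len > max_len` and cut coordinates beyond the record are
errors, not clamps. IgC of an empty genome is an error (zero denominator).

## Bundled published tables

Three small TSVs ship with the package: the 22-species IgC matrix of the
21 top-ranked pairs plus the PstI+MspI reference, the 60-enzyme
single-digest screen over four plant genomes, and the empirical coverage
(EgC) ratios of three pairs in 12 plant species. They are *inputs* to the
summary/ranking machinery (row means, SDs, plant-group means, reference
ratios are recomputed from them in tests and in the acceptance script);
the digestion engine never reads them.

## Known limitations

* Isoschizomer naming and the full published 60-enzyme / 70-pair lists are
  not built in; the catalog covers the enzymes named in the bundled tables'
  reproductions and is user-extensible via TSV.
* Adapter chemistry, buffer compatibility, read depth and sequencing cost
  are out of scope: the package ranks combinations by coverage only.
* Empirical coverage (from sequenced reads) is not computed; its printed
  values appear only as aggregation inputs.
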