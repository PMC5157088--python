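# Methods

## Coordinate model

All intervals are half-open `[start, end)` with 0-based starts, identical to
the first three BED columns. Region strings (`chrom:start-end`) use the same
convention. This choice is forced by the merge semantics the package
implements: `chr1:101-200` and `chr1:200-210` collapse (they touch at a
boundary base count of zero), while `chr1:10-100`/`chr1:101-200` and
`chr1:210-211` gaps of one base do not. A 1-based closed reading would make
at least one of those behaviours inconsistent. Zero-width intervals are
rejected at construction: membership of an empty interval is undefined in
this algebra, and no operation can produce one.

The single deliberate exception is the VCF query surface: `query_vcf` takes
tabix-convention windows, 1-based and inclusive at both ends, because that
is the convention of the indexing tools those queries are drawn from. The
CLI names the argument `--tabix-region` so the two conventions cannot be
confused.

## Chromosome orderings

Two total orders are provided. *Lexicographic* is byte-wise comparison of
the full name. *Natural* strips an optional case-insensitive `chr` prefix,
splits the remainder into alternating numeric/alphabetic runs, compares
numeric runs as integers and alphabetic runs case-insensitively, with
numeric runs ordering before alphabetic ones at the same position — so
`chr1 … chr22 < chrM < chrX < chrY`, matching GNU version sort. Ties after
this tokenised comparison (names differing only in case or prefix spelling)
fall back to the raw string, which keeps both relations antisymmetric and
therefore makes sorting deterministic and permutation-invariant; this is
verified by property test over random name multisets.

Names are never silently normalized: `1` and `chr1` are distinct
chromosomes everywhere. The `check_chr` validation flag reports missing
`chr` prefixes instead of renaming, because silent renaming corrupts joins.

## Overlap vs. merge defaults

Two defaults differ by design, mirroring the behaviour of the classic BED
engines:

* overlap (join, membership, intersect, subtract) requires at least one
  shared base — bookended intervals never overlap;
* merge at `distance=0` with `bookend=True` (the default) collapses
  bookended intervals.

`merge_regions(distance=d, bookend=b)` collapses a run when the next
interval starts at most `running_end + d` (strictly before, when `bookend`
is off). The bookend flag therefore governs boundary equality uniformly at
every distance, the simplest extension of the distance rule.

## Operations

All operations are sweep-line over per-chromosome lists sorted by
`(start, end)`; complexity is `O(n log n)` in the input size, with binary
search (`O(log n)` per probe) for point/interval lookups. Tie-breaking in
sorts is `(chromosome, start, end)` ascending and stable thereafter.

**Ordering resolution.** Operations that emit sorted sets resolve their
output ordering as: explicit argument → ordering recorded on the input set →
natural. The bundled example sets record a lexicographic sort because the
canonical outputs list chromosomes lexicographically (`chr1, chr10, chr2,
chr20`); fresh unsorted input defaults to natural order.

**Join** (`join_left`) merges both inputs internally, then emits one row per
overlapping right partner for each left interval, in left order then right
start, or a single sentinel row (`.`, −1, −1) when none overlaps. Sentinel
fields appear jointly, enforced at construction. Inputs are merged first
because unmerged inputs would make the later partition-cell signatures
ambiguous; the membership vector of `in_region` is defined on the caller's
interval order and is consistent with the join's sentinel structure.

**Multi-set partition** (`multijoin`) collects, per chromosome, every
endpoint of every (merged) input as a breakpoint; consecutive breakpoints
bound a candidate cell, emitted iff at least one set covers it, annotated
with the covering count, comma-joined labels and 0/1 membership vector.
With merged inputs, adjacent emitted cells always differ in signature, so no
coalescing step exists. Cells tile the union exactly; this is checked
against a per-base oracle.

**Subtract** has two first-class modes. `whole` (default) keeps each merged
left interval intact iff it shares no base with the right set — the
behaviour of the canonical worked example. `partial` returns the base-level
difference as maximal intervals. The two satisfy a conservation law used as
a standing property test: `width(partial difference) + shared width = total
width`.

**Intersect** returns the base-level intersection as maximal clipped
sub-regions. (An alternative reading — returning the right set's full
intervals — is already available as the non-sentinel rows of `join_left`,
so the clipped form is the one implemented.)

**Flank** emits `[s−u, s)` and `[e, e+d)` per interval, clipped at 0 and at
the chromosome length when a genome table is supplied; flanks that clip to
zero width are dropped, and flanks are returned separately from their
sources, unmerged, so the operation stays auditable and invertible.

## Venn summaries

Two feature modes, both yielding mutually exclusive categories summing to
the union (2–5 sets, bounds enforced):

* **bp** — partition cells from `multijoin`, cell widths summed per
  membership signature;
* **interval** — the union is merged into maximal atomic intervals; an
  atomic interval belongs to set S iff S covers at least `fraction` of its
  width (default `1e-9`, i.e. any positive overlap); atomic intervals are
  counted per signature.

The `fraction` threshold is meaningful only for interval counting and is
ignored in bp mode, where per-base accounting already defines membership
exactly. Rendering is delegated to downstream plotting tools; the summary
serializes as a `signature<TAB>amount` table or JSON.

## VCF handling

The reader models the eight fixed VCF columns only (no FORMAT/sample
columns), maps `.` to missing, preserves header lines verbatim and carries
INFO opaquely. Region extraction is a pure linear text scan — the reference
semantics any index must reproduce — returning records in file order,
deduplicated across overlapping query windows (deduplication is a package
decision, documented here because engines differ). bgzf virtual offsets and
`.tbi`/`.csi` indexes are out of scope.

## Example data

`example_regions()` rebuilds the worked example used throughout the
documentation and tests: an 8-interval unsorted set whose merge gives set A
(304 bp over four chromosomes), and sets B and C reconstructed by inverting
the canonical 24-cell partition truth table — each cell signature pins which
sets cover it, so B and C are uniquely determined; the reconstruction is
itself executed as a test. The synthetic VCF contains the six OR4F5 coding
mutations of the worked example plus fixed decoy records placed outside the
queried window and inside a second window, so query tests are exact with no
randomness. `random_regions` draws uniform positions and widths from a
seeded generator, clipped to chromosome ends, and is fully reproducible per
seed.

The synthetic data are idealized: single-ended intervals with no strand,
no nested annotation columns, uniformly random placement, and a VCF with
only the fixed eight columns. Passing tests therefore demonstrate the
correctness of the interval algebra and parsers, not robustness to the full
diversity of production BED/VCF dialects (browser extensions, structural
variant notation, multi-sample genotypes).

## Verification strategy

Every operation is checked two independent ways: exact reproduction of the
canonical worked-example outputs, and differential testing against
brute-force base-enumeration oracles (intervals expanded to literal base
sets, operations recomputed set-theoretically) on seeded random instances
with coordinates below 10⁴ — 500 instances in the acceptance suite, sized
so the whole test run stays inside a couple of minutes on one CPU. A hidden
`parity-check` CLI subcommand additionally compares merge/intersect/subtract
against an installed BEDTools binary on BED inputs, used as an external
differential oracle in one test.

## Known limitations

* No strand-aware operations, closest-feature/window queries or coverage
  histograms.
* BED trailing columns are opaque payload: sorting preserves them,
  operations that rebuild intervals (merge, subtract, intersect) drop them.
* Natural ordering of exotic contig names (e.g. `HLA-DRB1*15:01:01`) is a
  convention (tokenised version sort), not a community standard; such names
  also collide with the region-string separator characters and must travel
  through BED, not region strings.
* The VCF layer is a minimal data-row model, not a full VCF 4.x validator.
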