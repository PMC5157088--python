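# regionkit

Native genomic-interval algebra for Python: sorting, merging, joining,
multi-set partitioning, subtraction, intersection, membership testing,
flanking, tabix-style VCF region queries, BED conversion and overlap
(Venn-style) summarization — implemented directly, with no external engine
binaries.

## Who it is for

Anyone who manipulates genomic ranges in analysis pipelines — annotating
intervals against gene models, merging replicate peak sets, quantifying
overlap between experiments — and wants the semantics of the classic
command-line BED engines available as a plain Python library and a small
CLI, with results in ordinary Python data structures.

## The model

The universal currency is the half-open interval **[start, end)** on a named
chromosome, 0-based — exactly the BED convention. Region strings
(`"chr1:10-100"`) share the same convention, so text and tabular forms
interconvert with no coordinate shift. Two conventions, mirroring the
classic engines' defaults, run through the algebra:

* **Overlap** requires ≥ 1 shared base: *bookended* intervals
  (`prev.end == next.start`) never overlap.
* **Merging** at distance 0 *does* collapse bookended intervals by default.

Chromosomes sort either **naturally** (version sort: `chr2 < chr10`, with
`chrM/X/Y` after the numbered chromosomes) or **lexicographically**
(`chr10 < chr2`); both are total orders.

The multi-set partition (`multijoin`) cuts the union of *n* labeled sets at
every interval endpoint and annotates each atomic cell with the membership
truth vector of the sets covering it; Venn summaries aggregate those cells
per signature, by base pairs or by atomic-interval counts.

VCF region queries follow the tabix convention — `chrom:start-end` with
**1-based inclusive** bounds — deliberately distinct from native region
strings; the CLI flag is named `--tabix-region` to keep the boundary
explicit.

## Worked example

```python
import regionkit as rk

bundle = rk.example_regions()          # built-in example data
raw = bundle.raw_example               # 8 unsorted regions

print(rk.sort_regions(raw).to_strings())
# ['chr1:10-100', 'chr1:101-200', 'chr1:200-210', 'chr1:211-212',
#  'chr2:10-50', 'chr2:40-60', 'chr10:50-100', 'chr20:1-5']

print(rk.sort_and_merge(raw).to_strings())
# ['chr1:10-100', 'chr1:101-210', 'chr1:211-212',
#  'chr2:10-60', 'chr10:50-100', 'chr20:1-5']
```

Note `chr1:101-200` and `chr1:200-210` merged (they touch), while the 1-bp
gaps on either side did not. Joining the merged set A against set B gives
one row per overlapping partner, with `.`/`-1` sentinels when none overlaps:

```python
for row in rk.join_left(bundle.set_a, bundle.set_b):
    print(row.left, row.right_chrom, row.right_start, row.right_end)
# chr1:10-100 . -1 -1
# chr1:101-210 chr1 111 250
# chr1:211-212 chr1 111 250
# chr10:50-100 . -1 -1
# chr2:10-60 chr2 40 60
# chr20:1-5 . -1 -1

print(rk.in_region(bundle.set_a, bundle.set_b))
# [False, True, True, False, True, False]

stats = rk.coverage_stats(bundle.set_a, bundle.set_b)
print(stats.total_bp, stats.shared_bp)
# 304 120
```

Set A covers 304 bp, of which 120 bp are shared with B; the bp-mode Venn
summary splits the 420 bp union into 184 bp exclusive to A, 116 bp
exclusive to B and the 120 bp intersection.

The same operations are available from the shell:

```sh
regionkit example-data demo/
regionkit snm demo/raw.regions
regionkit multijoin demo/a.regions demo/b.regions demo/c.regions
regionkit query-vcf demo/cosmic_example.vcf --tabix-region 1:1000-100000 --table
```

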