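# Methods

## Model and procedure

cytocomp treats a soft-masked assembly as a two-channel signal along
each chromosome: base composition (GC vs AT) and repeat annotation
(lowercase vs uppercase). Both are summarized over a consecutive,
non-overlapping tiling of fixed window size *w*; each base belongs to
exactly one window, so window statistics aggregate exactly (the GC% of
a 3*w* window is the counted-base-weighted mean of its three *w*
windows, and window counts sum to the whole-chromosome count).

Percentages are defined over **counted bases** only — A/C/G/T of either
case. N runs, IUPAC ambiguity codes and gap characters are carried
through the parser verbatim but excluded from every numerator and
denominator. Three consequences:

- a window inside an assembly gap has no denominator and is emitted
  with missing values (`NA` in CSV), preserving the positional tiling —
  downstream plots and correlations simply skip these windows;
- `gc_pct_masked` / `gc_pct_unmasked` are likewise missing whenever the
  corresponding fraction is empty in that window;
- whenever both fractions are non-empty, the overall GC% is exactly the
  counted-base-weighted mean of the two fraction GC% values.

The trailing window of a chromosome whose length is not a multiple of
*w* is emitted and computed over its actual residues, so a chromosome
always yields ⌈length/*w*⌉ windows. Internal arithmetic is 0-based
half-open; emitted `start_bp` is 1-based.

## Statistics

Per assembly, windows of all chromosomes are pooled (one result per
species, matching how such correlations are reported) and Pearson's *r*
between window GC% and rep% is computed over pairwise-complete pairs,
with the two-sided p-value from the *t* transformation on *n* − 2
degrees of freedom. Pairs are put into a canonical sort order before
summation so the result is bit-identical regardless of chromosome
pooling order. p-values are displayed with a floor of 1e-16; the exact
computed value is retained in the machine-readable output. Degenerate
inputs are explicit errors, not NaNs: fewer than 3 pairs raises an
insufficient-data error, and a constant measure (e.g. rep% ≡ 0 in an
unmasked genome) raises an undefined-correlation error.

The compensation summary contrasts mean `gc_pct_unmasked` with mean
`gc_pct_masked` and correlates the two across windows where both exist.
A negative fraction correlation quantifies repeat-driven GC
homogenization: windows whose unique DNA is GC-poor carry GC-rich
repeats, flattening the overall profile (the fish-like regime); the
mammal-like regime shows the opposite contrast, with GC-rich unique
peaks over GC-poorer repeats.

## Parameters

| parameter | default | meaning |
|---|---|---|
| window size *w* | 1000 bp | tiling resolution; 1 kbp resolves individual repeat blocks in teleost-sized genomes; 3 kbp (polyploid fish, mammals) and 10 kbp (very large genomes) are documented presets |
| record filter | off | minimum record length (bp) and id regex, to exclude unplaced scaffolds |
| repeat color scale | (0%, red 255,0,0) → (50%, orange 255,165,0) → (100%, green 0,170,0) | anchor percentages/colors are fixed constants so rendering is exactly testable; user-overridable |
| GC color scale | (≤30%, green 0,170,0) → (≥60%, red 255,0,0), linear between, clamped outside | the 30–60% span covers the GC range of typical fish chromosome windows |
| max plot width | 10 000 px | the longest chromosome of an assembly spans this width; all panels share the resulting bp-per-pixel scale so panel widths are proportional to chromosome length |

CSV dialect: comma separator, `.` decimal point, Unix line endings,
`#`-prefixed metadata lines (record id, length, window size, assembly,
tool version) before the header. Percentages are written with 3
decimals — lossless for *w* ≤ 10 000 since window percentages quantize
in steps of 100/*w*. Missing values are the literal `NA`, never 0 and
never an empty field, so gaps remain distinguishable from true-zero
windows. Writes are temp-then-rename, so a failed run never leaves a
truncated table.

## Synthetic assemblies

The generator builds chromosomes from exact-length segments, each with
a per-base GC probability, a mask flag, or an N-run flag. Base identity
within the GC and AT classes is uniform (G:C = A:T = 50:50). Because
segment boundaries sit at exact bp offsets on the 1-kb grid, the
mask state of every 1-kb window is deterministic and the expected GC%
of every window is available in closed form — window means over *n*
counted bases recover a segment's GC probability *p* to within the
binomial error sqrt(*p*(1−*p*)/*n*).

Five preset architectures emulate repeat layouts observed along real
vertebrate chromosomes: telomeric repeat blocks on acrocentric
chromosomes, interstitial repeat blocks, dispersed intermingled
repeats, a repeat-poor compact genome (masked fraction 5%), and a
mammal-like pattern of GC-rich unique peaks (GC probability 0.6) over a
homogeneous AT-rich background. Fish-like presets give repeats a GC
probability (0.45) at or above the unique background (0.41); the
mammal-like preset inverts that. Default preset chromosomes are
1.5–3 Mbp — large enough that every window-level expectation is tested
at hundreds-to-thousands of windows per chromosome, while keeping the
default suite fast; a `scale` factor grows them to real chromosome
sizes (the profiler itself is exercised up to 55.41 Mbp in the tests).

For correlation recovery, a separate constructor draws per-window
(GC probability, repeat fraction) from a bivariate normal with a chosen
correlation ρ (clipped to valid ranges) and masks the first
`round(rep·w)` bases of each window. The realised window GC% carries
binomial noise (SD ≈ 1.6% at *w* = 1000), which attenuates the observed
*r* by a few percent relative to ρ; recovery is asserted within ±0.03
at 10 000 windows.

What the synthetic data do **not** emulate: real repeat sequence
content (no transposon consensus models — only case structure matters
to this tool), strand asymmetry, masking errors, assembly
mis-joins, and the long-range autocorrelation of real isochore
landscapes. Passing the recovery tests therefore demonstrates that the
measurement machinery is exact and unbiased under known ground truth,
not that any particular biological claim holds in real genomes.

## Numerical and design choices

- **Counting** is one vectorised pass per chromosome (ASCII lookup
  table → 9 classes → one `bincount` over window×class codes); a
  55.41-Mbp chromosome profiles in a few seconds. The test suite pins
  this against a deliberately naive per-character oracle, exactly —
  both compute `100·num/den` in the same IEEE order, so float equality
  is meaningful.
- **Trailing windows** are emitted rather than dropped or merged:
  dropping loses data, merging breaks the ⌈length/*w*⌉ contract.
- **Record identity** is the first whitespace-delimited header token,
  matching both Ensembl and NCBI FASTA dialects; line wrapping is
  ignored on read and fixed at 60 columns on write.
- **Panel order** is by data-row count, descending, with lexicographic
  record-id tie-break — deterministic for any input set.
- **Color mapping** is piecewise-linear per RGB channel between
  anchors, clamped outside the anchor span; exact anchor hits return
  the anchor color. The plotted point list is written as a TSV sidecar
  and is byte-reproducible; the PNG raster is smoke-tested only.
- **Sign conventions**: rep% uses lowercase counts only; uppercasing a
  sequence zeroes rep% everywhere and provably leaves GC% untouched
  (case carries no compositional information).
- **Fetching** rejects hard-masked (`rm`) remote variants outright,
  since N-masking destroys the lowercase signal the tool profiles, and
  is idempotent (an existing decompressed file short-circuits the
  download). Remote layouts are template data, not code.

## Known limitations

- Per-repeat-class GC% (DNA transposons vs retroelements) is not
  computable from soft-masked FASTA, which carries no class labels.
- Correlation analysis is within-assembly only; no phylogenetically
  corrected cross-species statistics.
- rep% inherits whatever quality the upstream repeat masking had; the
  tool measures the annotation, it does not validate it.
- No centromere or ideogram glyphs: centromere positions are generally
  not annotated in the target assemblies.
- Streaming FASTA only; no random-access (faidx/2bit) path. Chromosome
  sequences are held in memory one at a time.
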