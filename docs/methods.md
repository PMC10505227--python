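# Methods

## Break geometry

A cut site is the 8-bp recognition motif (default `GCGATCGC`) plus the 2-nt
cut-center interval at motif offsets [3, 5) — the AT dinucleotide left as
3′ overhangs when the enzyme cleaves `GCGAT/CGC`. All half-open, 0-based.
For configurable motifs the center defaults to the middle 2 nt; externally
supplied site lists (e.g. Cas9 target panels) carry an explicit center via
BED thickStart/thickEnd. Ambiguity codes are unsupported and `N` in the
reference never matches: recognition is exact.

`site_window(site, flank)` is `[center_start − flank, center_end + flank)`
(length `2·flank + 2`), clipped to the contig. Metaprofiles instead use the
window `[mid − flank, mid + flank)` of length exactly `2·flank`, centered
on the midpoint between the two center bases, so the profile has
`2·flank/bin_size` bins and the two center bases sit in the two bins
adjacent to offset 0. At `bin_size = 1` those two bins contain only the
cut-center bases, which is what makes the central coverage dip of
non-spanning read populations directly observable; at coarser bins the
central bin mixes center and abutting-covered bases by construction.

## Span classification

Relative to a site's center `[cs, ce)`, a read `[s, e)` is

- **spanning** if it overlaps the center by ≥ 1 bp (`s < ce and e > cs`);
- **not spanning** if it does not overlap and its gap — `cs − e` left of
  the center, `s − ce` right of it — is ≤ `max_dist` (default 5 nt;
  abutting reads have gap 0);
- **excluded** otherwise (including reads on another contig).

The classification is total: every read gets exactly one label. `max_dist`
is measured from the 2-nt center, not the full motif. The per-site ratio
`n_span / (n_span + n_nospan)` is undefined (site dropped) when no read
qualifies; `min_reads` (default 1) controls the drop threshold. Each
alignment record is counted once; mates are never merged.

With the field-default `max_dist = 5`, the qualifying denominator keeps
only non-spanning reads within 5 nt, so the ratio estimates the spanning
share *among near-break reads* — deliberately sensitive to persistent
breaks, and an overestimate of the generator's global spanning fraction
`f_span`. Recovery of `f_span` itself is exact when the qualifying window
covers the generator's whole placement support (`max_dist = W_r` with
background off), which is how the recovery checks are run.

## Bootstrap KS comparison

Two ratio vectors are compared via fixed-edge histograms on [0, 1]
(`n_bins = 20` by default; the right edge of the last bin is inclusive),
normalized to sum 1 and cumulated; the statistic is the maximum absolute
CDF difference. The null is built by merging the two vectors and drawing
`B = 1000` random partitions without replacement into the two original
group sizes; `p` is the plain fraction of partition statistics ≥ the
observed one (a `(k+1)/(B+1)` variant is available). The merged vector is
sorted and the smaller group drawn first, so `p` is exactly invariant to
swapping the inputs. All `B` partitions are drawn identically and i.i.d.
Partitioning into the original sizes reduces to equal halves when the
vectors have equal length (the top-50-sites setting) and keeps the null
exchangeable otherwise. The bin count is a free choice; the test suite
checks that conclusions on clearly separated distributions are stable over
`n_bins ∈ {10, 20, 50}`. A continuous (unbinned) two-sample KS is provided
only as a cross-check, not as the primary statistic.

## Coverage, enrichment and widths

Coverage bins hold read-bases overlapping the bin divided by `bin_size`
(default 10 bp), so `total_signal × bin_size` equals total read-bases
exactly before normalization. Depth normalization rescales each track to a
common total and is idempotent. The treatment/control comparison scores
each bin `−log₁₀ P(X ≥ t)` for `X ~ Poisson(max(c, λ₀))`, with the
treatment value rounded to the nearest integer for the discrete upper tail
(`P(X ≥ 0) = 1`, so empty bins score 0); `λ₀` defaults to the genome-wide
mean control value, which keeps scores finite where the control is empty.
Control choice is configuration: no-antibody libraries for released-
fragment experiments, input libraries for chromatin (pellet) experiments.

Site enrichment is the signal sum (bin value × bp, partial bins pro-rated)
over the ±1-kb window; ranking is by enrichment descending with ties
broken by (contig order, start). An externally computed ranking can be
supplied in place of the internal one wherever a ranking is consumed.

Peak width is summarized as the one-sided 90%-signal-mass radius of the
metaprofile, computed independently on each side of the cut: the smallest
distance d such that bins within [0, d] hold ≥ 90% of that side's signal.
This is the package's own definition of "average width"; field reports of
peak extent rarely state a computable definition, so these widths are
comparable within the package but not an exact external target.

## Synthetic data model

Per site i with mean-normalized log-normal efficiency `e_i` (σ_log = 1 by
default — a long-tailed efficiency ranking), the read count is
`Poisson(reads_per_site_mean · e_i · occupancy_scale)`. Each break-derived
read spans the center with probability `f_span` (placement uniform over
all start positions that overlap the center); otherwise it lies entirely
on one fair-coin side with its inner edge at distance `Uniform[0, W_r]`
(released, default W_r = 200 bp) or `|Normal(0, W_s)|` (spreading, default
W_s = 400 bp) from the center boundary, never overlapping the center.
Fragment lengths are normal (mean 80 bp, sd 25, truncated ≥ 20 bp): in the
released regime end-bound, nuclease-released products are short and
protected, and this length together with W_r keeps ~90% of signal within
~230 bp of the cut, matching the short-range released geometry; in the
spreading regime the inner-edge scale dominates and the same fragment
model yields half-widths of ~700 bp at W_s = 400. Spanning reads model
factors still bound at repaired or re-ligated sites; the mixture is purely
a read-placement model, not a cut–religate kinetic process, because the
downstream analyses only see read geometry. Spreading is likewise a
phenomenological stand-in for inward sliding/re-binding of the end-bound
complex, for which no quantitative model is available.

Background is break-independent: uniform noise at `background_rate`
reads/kb plus `n_promoters` promoter-like loci (reads' midpoints normal
with sd 200 bp), placed ≥ 2 kb from every cut center so truth labels stay
clean. The genome generator plants motifs at ≥ `min_site_spacing` (default
4 kb, required > 2·(halfwidth + mean fragment) so neighboring sites'
reads cannot mix) and locally re-draws background bases until a motif scan
returns exactly the planted set. Identical config + seed gives
byte-identical outputs; all randomness flows through
`numpy.random.default_rng` seeded from the config seed (pipeline stages
derive per-stage seeds < 2³¹ from one master seed).

What the generator does **not** emulate: sequencing error and quality,
PCR duplicates (input is assumed deduplicated), mate pairs, chromatin
state covariates, mappability structure, and the true genomic density of
recognition sites. Passing tests therefore demonstrate correctness of the
analysis under the stated placement model, not performance on real
libraries.

## Quantification rules

`%DNA = 2^(Ct(input) − Ct(test)) × 100` assumes exactly 2-fold
amplification per cycle (no efficiency correction). No-antibody recovery
is subtracted; negative corrected values are flagged, never clamped. Ct
values outside 5–40 warn but compute.

The proteomics filter imputes missing abundances as half the minimum
observed value in the same replicate/channel column (the imputation factor
is a parameter; "low-value imputation" admits several conventions and
half-minimum is a common floor), removes proteins with < 2 unique peptides
in any replicate or without +Ab detection in every replicate, and retains
proteins with +Ab/−Ab ≥ 5 in **every** replicate by default — the stricter
of the two natural readings; a mean-ratio mode is provided. An imputation
floor of 0 in a −Ab channel is an error, since ratios against it are
undefined.

## Numerical and scale choices

- Track bins 10 bp; metaprofile bins 10 bp (1 bp where the 2-nt dip is
  measured); flank 1 kb; top-300 sites for profiles/matrices and top-50
  for span vectors as conventional defaults.
- Poisson tail uses `logsf` for finite scores in extreme bins.
- Clustering ties are broken by factor column order; Euclidean distances
  between rank vectors are invariant to reversing the rank direction, so
  ascending ranks are used and the choice does not affect merges.
- Pearson ρ is computed on raw enrichment (matching scatter-panel
  practice); clustering uses rankings. Constant vectors are an error, not
  NaN.
- Test and acceptance problem sizes (100–200 sites, 50–200 reads/site,
  ≤ 2-Mb genomes, B = 1000, 100–200 replicates) are chosen so the full
  suite completes in minutes on one CPU while leaving Monte-Carlo error
  well inside the asserted tolerances.

## Known limitations

- The span statistic assumes deduplicated single-interval reads; paired
  ends double-count fragments that cover a site twice.
- `read_bedgraph` infers the bin size as the GCD of record boundaries when
  not given; pathological single-record tracks fall back to 1-bp bins.
- The empirical p-value without the +1 correction can be 0 and is slightly
  anti-conservative at small B; use `plus_one=True` for a strictly
  positive, conservative estimate.
- Curated genome-wide site lists (e.g. the published hg19 AsiSI
  annotation) are not reproduced; they require an external genome and may
  be a curated subset of a naive scan.
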