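# Methods

## Coordinates and conventions

All internal coordinates are 0-based half-open. BED/BEDPE/bedGraph pass
through unchanged; GTF (1-based inclusive) and per-cytosine reports (1-based
positions) are converted at the I/O boundary. The TSS of a − strand gene is
`end − 1`, the last base of its half-open interval; the TTS is symmetric.
The mitochondrial contig is identified by an explicit configured name, never
by a size heuristic, because both the ChIP normalization and the
nonconversion estimate hinge on the nuclear/mitochondrial partition.

## ChIP enrichment over background

Fragment counts are taken in non-overlapping windows (default 1000 bp)
tiling each contig from 0; the trailing partial window is kept, counted
as-is, and flagged `partial` so downstream consumers can exclude it. The
default counting rule (`overlap`) counts a fragment in every window it
intersects by ≥ 1 bp, matching the semantics of the interval-coverage tools
used for this analysis in practice; `start_in_window` is provided when exact
conservation (window counts summing to the fragment count) matters.

Normalization divides every window count by the **median** count over
mitochondrial windows. The median of an even number of windows is the
midpoint of the two central values — this matters because the denominator
defines the unit of enrichment. A zero mitochondrial median or an absent
mitochondrial window is a hard error: enrichment over background is
undefined there and silently patching the denominator would corrupt every
downstream value. The normalization is scale-invariant (multiplying all
counts by c > 0 changes nothing) and maps the mitochondrial median itself
to 1.0.

## Gene-anchored metaplots

For each gene the signal over [anchor − flank, anchor + flank) is extracted
in gene orientation (− strand genes mirrored so positive offsets point into
the gene body at the TSS), averaged within fixed-width bins (default 10 bp,
bin offsets are left edges), and then averaged across genes with **equal
weight per gene**. Genes whose window crosses a contig edge contribute only
their defined bases (undefined bases are NaN-excluded) rather than being
dropped — on compact test genomes, dropping would bias the profile.
Expression quintiles are formed by sorting on RPKM descending with ties
broken by gene id; group sizes differ by at most one, remainders going to
the most-expressed groups, so quintile profiles recombine exactly (weighted
by group size) into the all-genes profile. ChIP signal is scaled to
genome-wide mean 1 per library before aggregation so replicate libraries of
different depth overlay; the raw-depth path is available by skipping
`BasewiseSignal.scaled_to_unit_mean()`.

Heatmaps are the same per-gene rows ordered by RPKM descending; their column
means equal the ungrouped metaplot by construction, which the tests assert.

## MNase nucleosome-edge profiles

Duplicates are removed on (contig, start, end) — strand excluded, since a
fragment's two reads share outer coordinates. Insert size is `end − start`;
the reported SD uses the n−1 denominator. Edge profiles aggregate
strand-aware 5′-end depth: peaks mark gene-oriented nucleosome left edges.
By default (`match_gene`) + strand genes use genome plus-strand 5′ ends and
− strand genes use genome minus-strand 5′ ends, mirrored by the metaplot
flip, so the peak semantics are identical for genes of either orientation.
The literal `plus_only` mode (plus-strand ends for all genes) is kept as an
option because the original aggregation tooling for this analysis is
ambiguous on the point; for − strand genes its peaks mark right edges.

## Bisulfite methylome

The caller's null is bisulfite nonconversion: at a truly unmethylated
cytosine, m ~ Binomial(n, r). r is estimated as (Σm)/(Σn) pooled over all
mitochondrial sites — pooling weights each read equally and is the maximum
likelihood estimate of a single shared error rate (typical values ~0.5%).
Each site with n ≥ `min_coverage` (default 3) receives the one-sided tail
p = P(X ≥ m); Benjamini–Hochberg runs over exactly the tested sites
(insufficient-coverage sites never enter the family); a site is methylated
when q ≤ alpha (default 0.05 — the correction method is standard here but
the threshold is a package choice, exposed in `MethylomeConfig`). Sites are
tested per strand and never collapsed across strands, because methylation in
this system is not restricted to a symmetric sequence context.

Weighted methylation level of a region is 100·(Σm)/(Σn) over qualifying
sites; a region with no qualifying site returns NaN, never a silent 0.
Domain metaplots pool counts across all domains per bin (20 × 50 bp flank
bins each side, 20 equal-length body bins of 5% each) and report the
weighted level of the pooled counts — note this is coverage-weighted, unlike
the equal-gene-weight convention of the gene metaplots; the two conventions
follow their respective field usages and are deliberately not unified.
Domain flanks overlapping an adjacent domain are still counted in the flank
of the anchoring domain (simplest reproducible rule).

### DMR detection

The DMR procedure is fully specified here because published descriptions of
this analysis typically defer to citations: sliding windows (1000 bp, step
100 bp) pool counts per sample over sites covered ≥ min_coverage in both
samples; windows with ≥ `dmr_min_sites` (default 5) such sites get a
two-sided Fisher exact test on (Σm_a, Σn_a−Σm_a; Σm_b, Σn_b−Σm_b); BH runs
over tested windows; windows significant at `dmr_alpha` **and** with an
absolute weighted-level difference ≥ `dmr_min_diff` (default 20 points)
merge across gaps ≤ `dmr_merge_gap_bp` (500) into intervals labelled by
direction. The effect-size gate means a genome-wide 10-point shift reports
zero DMRs — by design, such a shift is a level/count phenotype, not a
regional one. Windows with exactly equal sample proportions are assigned
p = 1 without calling the exact test; this is conservative and such windows
can never pass the effect gate.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, at
toy scale. Defaults (all in `SimConfig`, all overridable):

| parameter | default | rationale |
|---|---|---|
| nuclear genome | 2 × 500 kb | ~1 Mb keeps every analysis < seconds while leaving ≥ 500 windows per contig |
| mitochondrial contig | 20 kb | ~10k cytosine sites → nonconversion estimated from ~2×10⁵ reads |
| genes | 200 × 1.5 kb, strands random, non-overlapping | median fungal gene scale; 40 genes per quintile |
| RPKM | log-normal(μ=1.5, σ=2), 20% exactly 0 | heavy right tail plus a silent fraction, so the lowest quintile is dominated by unexpressed genes |
| domains | 10 × 5 kb, disjoint from genes, nuclear only | heterochromatic islands; the mitochondrial contig is fully unmethylated by construction |
| methylation | domains 45%, background 0%, nonconversion 0.5% | typical heterochromatin-domain frequency and bisulfite error scale |
| bisulfite coverage | Poisson, mean 20× | routine WGBS depth |
| ChIP | 3× nuclear enrichment; promoter boost 2× over 500 bp upstream of the TSS, scaled by expression quintile; fragments 200 ± 30 bp | global chromatin binding plus a graded promoter preference |
| MNase | spacing 200 bp, NFR 150 bp, jitter SD 20 bp, fragments 140 ± 23 bp | mononucleosome regime with phased arrays behind an NFR |
| library sizes | 500k fragments each | matches the ~0.5–0.8 fragments/bp depth of real libraries, scaled to the toy genome |

Implementation notes. Every simulator is a pure function of (inputs, seed),
with an independent seed stream per assay so regenerating one library never
perturbs another. The promoter boost multiplier is
1 + (boost − 1)·(G + 1 − q)/G for expression group q of G: the full boost
for the most-expressed group, decaying linearly to baseline (never below
baseline) for silent genes — boosting by expression *rank* rather than raw
RPKM avoids heavy-tail artifacts. Observed bisulfite counts are
m ~ Binomial(n, f + (1−f)·r): nonconversion applies to the unmethylated
fraction of molecules, so a fully methylated site is unaffected by r and
an unmethylated one errors at exactly r. Fragment lengths are normal with a
hard floor at 50 bp (clipping, not rejection — cheap and free of loop
pathology; the floor is > 3 SD from every default mean so the moment
distortion is negligible). Placement jitter is truncated toward zero when
discretised to base coordinates, so the modal 5′-end base sits exactly on
the phased edge. MNase sampling excludes NFR zones from both phased and
background placements, making the NFR trough a property of the locus, not
only of the arrays.

### What the generator does not emulate

No read-level sequence simulation (no sequencing errors, mapping bias, or
GC bias), no PCR-duplicate structure beyond exact-coordinate duplicates, no
CpG/CHG/CHH context structure, no copy-number variation, and uniform random
genome sequence (no repeats). Passing tests therefore demonstrate that the
*quantification machinery* recovers planted signal under the stated noise
model — they do not validate alignment, bias correction, or behaviour on
repetitive DNA, all of which are upstream of this package's inputs.

## Numerical choices and degenerate inputs

* BH q-values: step-up with `q(k) = min_{j≥k} p(j)·T/j` capped at 1;
  verified against an independent reference implementation on random
  p-vectors (lengths 1–1000) to float precision.
* Quintile ties broken by gene id ascending, making groupings reproducible
  under equal RPKM (including all-zero expression).
* All-NaN metaplot bins stay NaN; aggregation uses NaN-aware means.
* Readers reject invariant violations (m > n, duplicate sites, start ≥ end,
  unknown contigs) with the offending line number; they never repair.
* Empty fragment sets, zero-domain simulations, and empty DMR results are
  valid outputs, not errors; undefined statistics (weighted level of an
  uncovered region, SD of < 2 fragments, zero mitochondrial median) raise
  or return NaN explicitly.

## Verification scale

The test suite and `scripts/acceptance.py` run the full stack on the ~1 Mb
default genome: 20-replicate null-control calling (~10⁷ tested sites
total), planted-frequency recovery at 45%/55%, planted 10 kb DMR recovery
at 30%/90%, 3× enrichment recovery, noise-free and jittered nucleosome-edge
recovery, and insert-size moments at n = 50,000. The methylated-site-count
ordering between the 45% and 55% strains is asserted on counts summed over
10 replicate library pairs: the expected per-pair difference (~+50 sites) is
comparable to the per-library fluctuation of near-threshold and
false-positive calls (driven largely by the ±3% sampling error of the
per-library nonconversion estimate), so a single pair is an unreliable
read-out of a real expected-value ordering; replicate-summing is the
standard remedy and mirrors how replicate libraries are compared in
practice.

## Known limitations

* The DMR window test uses pooled counts, so within-window heterogeneity is
  averaged out; boundary placement is resolved only to the window step.
* `weighted_level` and the domain metaplot are linear in counts and carry no
  uncertainty estimate; callers needing intervals should bootstrap over
  sites.
* The SAM/BAM adapter trusts the aligner's proper-pair template lengths and
  does not reconstruct fragments from secondary/supplementary alignments.
* Metaplot extraction is dense per-contig; genomes far beyond ~10⁸ bp would
  want a windowed or chunked signal representation.
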