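# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `tuatlas`, and states what the synthetic-data
suites do and do not demonstrate.

## Coordinate and strand conventions

Internal coordinates are 1-based inclusive (GenBank convention); BED and
bedGraph files are converted at the I/O boundary. "Downstream" of position
*p* always means *p*+1 on the plus strand and *p*−1 on the minus strand.
Replicons are handled as linear sequences: window means are truncated at
replicon ends with the denominator equal to the number of in-range
positions. Ambiguity codes other than N are rejected; N positions carry no
calls.

## TSS calling: negative-binomial exceedance test

Per condition, candidate positions pass two prefilters: (a) a nonzero
count in at least one library of the condition (treated or untreated), and
(b) a replicate-averaged RppH-treated count at or above the 95th
percentile (linear interpolation) of the averaged counts over the
positions surviving (a), pooled across replicons. The treated libraries
carry the TSS signal, so (b) defaults to treated-only averages; a
`prefilter_source="all"` switch is exposed.

Counts at position *i* in library *j* are modelled as
NB(μ = s_j·q, var = μ + α·μ²). Size factors s_j use a median-of-ratios
estimator with a positive-count geometric-mean reference (the "poscounts"
flavour): per-position 5′-end matrices are extremely sparse, and the
classic estimator restricted to all-positive rows would be computed almost
entirely on the signal rows themselves, folding the treatment effect into
the normalization. For the same reason both the size factors and the
pooled dispersion are estimated on the full zero-filter survivor set, not
on the percentile-selected candidates. The dispersion α is a single pooled
method-of-moments estimate over rows with group mean ≥ 1 (below that the
moment estimator carries no information), negative estimates clipped to
zero, floored at 1e−8.

Two designs are computed per candidate:

* **unpaired** — a Wald test on log group rates q̂ = ΣK/Σs with
  delta-method variances under the NB model; rates are floored at half a
  count so that an all-zero group yields a finite, conservative statistic;
* **paired** — replicate as a blocking factor: a one-sample *t* test
  (df = n−1) on per-replicate normalized log ratios
  log((K_t+0.5)/s_t) − log((K_u+0.5)/s_u), with the empirical standard
  error floored by the NB delta-method standard error. Without that floor,
  degenerate replicate agreement (e.g. treated counts (1,1,1) against
  untreated (0,0,0)) produces a zero empirical variance and a spurious
  p ≈ 0; the floor is what keeps the paired design calibrated on null
  data.

P values are BH-adjusted per design across all tested positions of the
condition (all replicons jointly); a position is a TSS when either design
gives FDR < 0.05 and the fold change is positive. This is an exceedance
test in the spirit of a count-model differential test with a one-sided
alternative; bit-exact replication of any external engine's shrinkage
estimators is a non-goal — the acceptance standard is planted-signal
recovery and false-call control, both verified by simulation.

Adjacent called positions are resolved into one primary TSS (highest
replicate-averaged treated coverage; ties to the strand-aware
upstream-most position — the same tie rule is used everywhere in the
package) plus secondary TSSs. Condition catalogs are merged after
dropping secondaries, counting detecting conditions per site. For promoter
modelling the merged catalog is thinned so no two same-strand sites lie
within 15 bp (keep the most-conditions site, ties upstream); promoter
counting coalesces sites within 10 bp greedily by descending normalized
read count, which is deterministic and idempotent.

Validation against independent reference sites compares nearest-TSS
distances (or region counts) between the real catalog and a control
catalog rotated a quarter turn around the replicon, with a two-sided
Wilcoxon signed-rank test on the paired values.

## TTS calling: Poisson test with a dynamic λ

Candidates are positions with a count strictly greater than the 95th
percentile of the library's nonzero counts (both strands, all replicons
pooled). The null rate for each candidate is the *largest* of: the
strand-specific genome-wide mean (denominator includes zeros), the
replicon-strand mean, and the means of 13/51/251/501/1001-bp windows
centred on the position. Window means include the tested position's own
count — "centred on the tested position" with no stated exclusion, and
including it enlarges λ, which is the conservative direction; both choices
are config-exposed. The one-sided tail probability is
P(X ≥ x) = 1 − F(x−1) under Poisson(λ); BH is applied across the
library's tested positions, and a position must recur at the exact same
coordinate in ≥ 2 biological replicates (no ±1 fuzziness, which would
inflate counts) to become a preliminary 3′ terminus of the condition.

## Processing sites vs termination sites

5′-monophosphoryl sites are called from the RppH-*untreated* TSS-seq
tracks with the identical Poisson/BH/≥2-replicate machinery, then every
called TSS position — primary and secondary both, with a flag to restrict
to primaries — is removed. A preliminary 3′ terminus at *p* with a 5′P
site exactly 1 nt downstream (same strand) is a processing site; a
terminus overlapping a same-strand tRNA is a processing site; a terminus
with a 5′P at its own position or 1 nt upstream violates the expected
cleavage geometry and is removed with reason `upstream_5p_conflict`
rather than silently dropped; everything else is a TTS. Processing
positions are pooled across conditions and purged from every condition's
TTS list (`pooled_processing`), which makes pooling monotone: adding a
condition can only shrink TTS lists.

## TU annotation

A TSS is assigned to the nearest same-strand downstream start codon
within 650 bp (distance to the first base of the annotated start codon;
0 allowed). Assignment takes precedence over categorization: a TSS inside
gene A but ≤ 650 bp upstream of gene B pairs with B and keeps the
`intragenic_upstream_gene` flag. Leaders ≤ 5 nt define leaderless
transcripts. Unassigned TSSs are intragenic (inside a same-strand gene),
antisense (inside an opposite-strand gene) or intergenic. If two genes
share a start coordinate the longer gene wins, then lexicographic gene id.

A promoter is *regulated* when some condition's activity (size-factor
normalized replicate-mean treated count) exceeds the chromosomal mean
promoter activity for that condition and is ≥ 10× its activity under some
other condition; zero activities take a pseudocount of 0.5. Constant
promoter candidates are genes with −0.45 < log2FC < 0.45 (exclusive) and
adjusted p > 0.05 in *each* of the three growth-phase pairwise
comparisons of a supplied differential-expression table, intersected with
TSS–gene pairs whose TSS is intergenic or leaderless and detected under
all three growth-phase conditions. The published follow-up curation of
such candidates was manual; `predominance_filter` offers an automated
approximation (leader ≤ 200 nt, TSS share of gene activity ≥ 0.5) and is
labelled as such.

## Promoter model: malign, gap surprisal, multiscan

Windows are 61 nt in transcript orientation ending at the TSS — wide
enough for a −35 at the maximal discriminator (3–12 nt) plus spacer
(12–22 nt) with margin; all three ranges are configurable. Information
quantities are in bits; frequencies carry a 0.25-per-base pseudocount; the
small-sample correction is e(n) = 3/(2·ln2·n), the large-n approximation
for 4 symbols (its error is far below the tolerances used anywhere).

*malign* seeds a profile by drawing 5 windows (seeded RNG) and
enumerating every offset combination, keeping the alignment with maximal
R = Σ_l (2 − H_l − e(n)); aligns every window greedily against the
growing profile; removes the seed contribution; and runs refinement
passes in which each window is re-placed at its best offset, the move
kept only if total information does not decrease — so passes are
monotone, R ≤ 12 bits, and termination is guaranteed (tolerance 0.01
bits/pass, ≤ 100 passes). The whole procedure is restarted 5 times and
the highest-information result kept: single runs occasionally converge to
mixed-register local optima, which score measurably lower.

Two properties of this optimizer are worth stating plainly:

* **Register canonicalization.** When only part of the hexamer is
  informative (the "TAnnnn" case), every common shift of all placements
  that keeps the informative columns inside the hexamer has essentially
  the same information, and the register the iteration lands in is
  arbitrary — no information criterion can distinguish them. Among global
  shifts within 20% (≥ 0.3 bits) of the maximal R, the implementation
  chooses the one packing information into the leftmost columns, the
  conventional register of the σ hexamers (TATAAT and TTGACA lead with
  their informative bases). This pins the discriminator and spacer
  length distributions to the conventional frame.
* **Null bias.** Maximizing information over ~10–20 candidate offsets per
  window inflates apparent information on pure noise: at n = 200 uniform
  random windows the aligned "motif" carries ≈ 3.4 bits. This selection
  bias is inherent to the procedure, not a defect; the test suite pins
  the meaningful property (noise stays far below a planted motif's
  ≈ 12 bits) rather than pretending the null is unbiased.

The preliminary −35 profile is built from the offsets implied by an
assumed 17-nt spacer, then optimized with malign over each window's
spacer-compatible offsets. *multiscan* then iterates: place each −35 at
the offset maximizing Ri(−35) − GS(spacer), re-derive the −35 matrix and
the gap-surprisal table GS(d) = log2(n_mode/n_d) (0.5 pseudocount for
unobserved in-range spacings, zero at the mode) from current placements,
until placements are stable. Windows with total score
Ri(−10) + Ri(−35) − GS ≤ 0 do not conform to the model and are dropped
after convergence; the model is rebuilt from survivors. Ties in offset
scores always go to the smallest offset, and a single integer seed makes
the whole model build bit-reproducible.

## Terminator analysis

Forward matches place a TTS at positions 1–12 of a predicted terminator's
3′ flank (hairpin end + k in transcript orientation); rescue matches
place an opposite-strand TTS at the mirror window on the 5′ side and
report the terminator id with an "r" suffix. A TTS may match several
terminators (all reported); headline counts de-duplicate by TTS.
Orientation uses the nearest annotated gene on each genomic side
(convergent → ←, divergent ← →, otherwise in-line), except sites more
than 50 bp after a same-strand start codon inside a gene, which are
internal; sites beyond a replicon's outermost gene default to in-line.

Hairpin ΔG is a nearest-neighbor approximation: Turner-89-style RNA stack
energies (Watson–Crick plus G·U wobble, versioned constants in one table)
summed along the stem, plus a hairpin-loop initiation term by loop length
(Jacobson–Stockmayer extrapolation beyond 9 nt). Stem and loop come from
the predictor when available, else from maximal pairing inward from the
hairpin ends. These values approximate exact-folding energies; only
ordinal comparisons (longer GC stem more stable; AU stems weaker) are
promised or tested.

## Synthetic data: what it emulates and what it does not

Counts are NB(mean m, dispersion α; variance m + α·m²) with per-replicate
size factors; planted events *add* to the background. Defaults: dispersion
0.1 (typical RNA-seq scale), background 0.2 end events per position per
library for both treated and untreated (background 5′-monophosphoryl ends
ligate in both preparations), planted TSS means 200 (treated) vs 2
(untreated) emulating the sharp treated excess at true TSSs, planted 3′
pileups of mean 100 at terminator U tracts (offset 7, the canonical
release position) and at processing-site 3′ partners. The default
scenario is a 100-kb genome with 60 genes, 40 TSSs (planted 0–300 nt
upstream of start codons, a few leaderless, each with planted
TTGACA/TATAAT motifs at spacer 17/discriminator 6), 25 TTSs of which 10
at planted GC-stem terminators, 10 processing pairs, and 3 replicates per
library kind. Promoter recovery uses 500 windows per seed with identity
1.0 at the planted informative positions and 0.25 elsewhere, spacer
distribution {15: 5%, 16: 20%, 17: 45%, 18: 20%, 19: 10%} and
discriminator {5: 25%, 6: 50%, 7: 25%}.

What passing these suites shows: the callers are calibrated under their
own noise model, recover strong planted signals at realistic depths, and
the deterministic rules (classification, assignment, refinement,
coalescing, terminator mapping) are exact. What it does not show:
robustness to features of real libraries that are not simulated —
sequence-dependent ligation bias, rRNA depletion artifacts, positional
correlation of background reads along transcripts, replicate outliers, or
mapping ambiguity. Real-data totals additionally depend on the exact
upstream read processing and the original differential-expression engine,
and are therefore out of scope for the simulation suites.

## Problem sizes used by the test and acceptance runs

Null calibration uses 100 seeds per caller (10-kb NB tracks for the TSS
test, 100-kb Poisson tracks for the TTS test); recovery uses 20 seeds of
the default scenario; promoter recovery uses 20 seeds × 500 windows (the
acceptance script uses 10/50/5 seeds for the same blocks). These sizes
give Monte-Carlo standard errors well below the asserted margins while
keeping a full run in a few minutes on one CPU.

## Known limitations

* The NB Wald/t tests are asymptotic; with 2 replicates per arm the
  paired design is conservative rather than powerful (the unpaired design
  carries most detection power at n = 3).
* Circular replicons are treated as linear (no wraparound windows); a
  wraparound flag exists on the data model but callers truncate.
* The ΔG table is approximate by design; do not compare its absolute
  values against exact-folding servers.
* malign explores offsets greedily from a heuristic seed; with ≤ 5
  restarts it reaches ≥ 95% of the exhaustive optimum on small instances
  (verified), but global optimality is not guaranteed.
* The constant-promoter curation step is an approximation of a manual
  judgement and is flagged as such in its docstring.
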