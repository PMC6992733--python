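# Methods

`pccelv` reimplements, as a tested pipeline, a peptide-level analysis of
proteolytic processing of the polycystin complex — polycystin-1 (PC1),
polycystin-2 (PC2) and fibrocystin — in urinary exosome-like vesicles
(ELVs), based on gel-slice (GeLC-MS/MS) peptide intensity data from a
two-cohort comparison (13 individuals with *PKD1* mutations vs 18 with
normal kidneys).  This note documents the model, the conventions, the
synthetic-data generator, and the numerically load-bearing design
choices.

## Coordinate and cleavage conventions

All residue coordinates are 1-based and inclusive.  A cleavage site is
identified by the position `p` of the **last residue of the N-terminal
product**: the cut hydrolyses the bond between `p` and `p+1`, so the
products are `[1..p]` and `[p+1..L]` and concatenating them restores the
chain.  The GPS/GAIN autoproteolysis of PC1 (`HL|T`, threonine starting
the C-terminal fragment at 3049) is therefore "cleavage at 3048".  Some
published peptide coordinate listings are internally inconsistent by one
residue (an 11-mer listed as spanning 12 positions); this package fixes
`stop = start + len − 1` everywhere and does not reproduce the
inconsistency.

## Gel-slice scheme

The default scheme is the ten-window lane sectioning A (270–500 kDa)
through J (10–15 kDa).  The published legend prints window B as
"140 kDa–27 kDa"; since the windows must tile 10–500 kDa this is treated
as a typo for 140–270 kDa, and the raw legend text is preserved in the
scheme's `comment` field.  Windows are half-open on the light side and a
boundary mass belongs to the heavier window — gels cannot resolve
boundary masses, so the convention is arbitrary but fixed and
documented.

## Mass arithmetic

Peptide masses are residue-mass sums plus water (monoisotopic
18.010565 Da), using the standard monoisotopic and average residue
tables; the proton mass is 1.007276 Da.  Monoisotopic masses drive m/z
(`(M + z·1.007276)/z`, full precision internally, two decimals for
display); average masses drive gel-scale kDa arithmetic, since SDS-PAGE
measures the isotope-averaged ensemble.  Cysteine carbamidomethylation
is available as a flag but off by default (no fixed modifications are
assumed; the key diagnostic peptide `TAFGASLFVPPSHVR` contains neither
Cys nor Met, so the choice does not affect the headline m/z values).
Glycan-corrected fragment masses add the annotated carbohydrate mass of
every sequon inside the fragment that survives the chosen treatment:
Endo H removes only high-mannose ("endoH_sensitive") chains, PNGase F
removes all N-linked chains.

Trypsin cleaves C-terminal to K/R except before proline.  Semi-tryptic
products at an annotated biological cleavage site run from the site to
the neighbouring tryptic boundaries; when the site happens to fall on a
tryptic boundary the products are flagged fully tryptic.  The default
detectability window is 700–4000 Da monoisotopic with up to two missed
cleavages for digestion utilities (the generator uses fully tryptic,
0-missed peptides); both are configurable, and fragment-level peptide
counts are always reported under the window actually used rather than
asserted.

## Differential analysis

Per (protein, peptide, slice) key, intensities are log2-transformed and
compared between cohorts with Welch's t-test (unequal variances; the
cohorts are 13 vs 18, so the pooled-variance assumption is not
attractive; Student's test is available by flag).  Zero intensities are
censoring (not-detected) and are excluded rather than imputed.  P-values
are deliberately uncorrected — the peptide map is exploratory and the
emulated analysis selected peptides at uncorrected p < 0.01 — and a
Benjamini–Hochberg q-value column is available but off by default.  The
effect sign convention is fixed: `log2_ratio = mean(log2 PKD1) −
mean(log2 normal)`, negative = decreased in the mutant cohort.

## Region intensity ratios and tail depletion

The stoichiometry statistic follows the pooled computation of the
emulated analysis: for each peptide in a region, intensities are summed
across the region's slices within each sample, averaged across samples,
and the per-peptide values are then averaged across peptides; the ratio
of two region means estimates the relative molar abundance of the
proteoform populations the regions map onto.  The order (sum across
slices per sample, average across samples, then across peptides) was
ambiguous in the source description and is fixed and documented here.
All samples are pooled by default (cohort subsets are selectable): a
protein-wide cohort fold-change cancels in the ratio.  Regions select by
slice set and start/stop predicates, e.g. "slice A AND stop < 3048" vs
"slices B–J AND stop > 3048".  `tail_depletion` is the same statistic
with the tail defined by `start ≥ tail_start` over all slices, returning
0 when no tail peptide is detected.

## Cleavage-site localization

For each candidate boundary `b` (by default the observed peptide stop
positions — the only breakpoints peptide data can resolve), the slice
distributions of peptides entirely N-terminal (`stop ≤ b`) and entirely
C-terminal (`start > b`) are compared with the Jensen–Shannon divergence
(base 2, bounded in [0, 1], symmetric, well-defined for categorical
slice labels); spanning peptides are excluded from both sides.  Each
peptide contributes its **intensity-normalized** slice profile:
intensity decides *where* a peptide sits (how its ion current splits
across slices), while peptides are equipotent within a region.  This
normalization matters: if region distributions are weighted by raw ion
current while the support weight counts peptides, moving a peptide with
intensity share ε across the boundary costs only ~ε·(−log2 ε)/2 in
divergence but gains 1/n in support, so the score maximum provably
drifts past low-responding peptides into the cleaved region (empirically
the planted site was recovered in only ~70/100 cohorts under raw
weighting, vs 100/100 with normalized profiles).

The score is `JSD × min(n_N, n_C)`, peaking where the split is both
clean and well supported; local maxima above a threshold (default 1.0)
with at least 3 peptides per side are emitted, ranked by score.  Calls
carry the interval from the candidate boundary to the residue before the
first C-terminal-side peptide — the data cannot localize the cut more
finely — and are flagged `exact` when the flanking peptides abut.
Equal-score plateaus merge into a single interval call.

## Band algebra and glycan milestones

`contiguity_check` verifies user-declared sum/difference constraints on
observed band masses (e.g. 52 + 29 = 81 kDa implies the two fragments
are contiguous pieces of the 81 kDa form; 81 − 70 = 11 kDa is the
C-terminal trim) within a default tolerance of 2 kDa, the error scale
implied by whole-kDa band reporting.  `localize_by_glycan_milestones`
enumerates sequon subsets whose treatment-removable glycan mass matches
an observed deglycosylation shift; with the annotated 2 + 5 + 5 kDa
chains, a 2 kDa Endo H shift isolates the first sequon and a 10 kDa
PNGase F shift the mature pair, bounding the TOP-loop cut between
sequons one and two.  Glycan counts are small, so exhaustive enumeration
is exact.

## Synthetic cohort generator

The generator produces long-format (protein, peptide, slice, sample)
ion-current tables with the structure the pipeline assumes:

* **Proteins** are deterministic pseudo-random sequences with planted
  K/R spacing (gaps 7–16 aa, mean tryptic peptide ~11.5 aa, mostly
  inside the 700–4000 Da window), planted sequons, and planted cleavage
  sites; the filler alphabet follows natural residue frequencies but
  excludes K/R (tryptic sites are planted), P (would silently suppress
  planted sites) and N (sequons are planted).  Sequence seeds are fixed
  per preset, so peptide maps are frozen and only abundances and noise
  vary with the dataset seed.  An optional FASTA loader accepts real
  sequences when the user supplies them.
* **Proteoform populations** (cleavage-set, molar-fraction pairs)
  determine fragment membership; each peptide appears in the gel slice
  assigned to each containing fragment's glycosylated average mass by
  the shared scheme, so generated placements agree with
  `assign_expected_slice` by construction.  Peptides spanning a
  population's cut never report on that population.
* **Regional multipliers** plant relative molar abundances along the
  chain (ectodomain excess, post-cleavage deficits, residual tails).
* **Base ion currents** are log-uniform over two decades per peptide,
  mimicking the dynamic range of peptide response factors, and are
  arithmetic-mean-normalized within each multiplier region over the
  observable peptides.  Without this normalization the planted regional
  ratios would not be recoverable at the stated tolerances: the
  peptide-sampling error of a region-mean ratio with a 2-decade response
  spread is ~13–18 % relative at the simulated peptide counts, and the
  noise-free limit would not reproduce the planted multiplier exactly.
  With it, response spread is a within-region property and planted
  ratios are exact in the noise-free limit.
* **Cohort structure**: 13 mutant vs 18 normal samples; a per-protein
  fold-change multiplies the mutant samples.  Observations carry
  multiplicative log-normal noise (default sd 0.4 in log2 units, a
  realistic label-free peptide CV) and are thinned by a per-(peptide,
  sample) detection probability (default 0.8), emulating run-to-run
  missingness.
* Output is deterministic given the seed, byte-identical across reruns.

### Presets

`pc1_fig1`: PC1-like 4302-aa protein, GPS cut at 3048, ectodomain excess
1.4, cohort fold 0.5.  `pc1_fig2`: adds a 60 % population with the
TM-IV/V hairpin (3475), TOP-loop (3760) and C-tail trim (4202) cuts, so
C-terminal peptides spread over multiple slices.  `fibrocystin_ppc`:
4074-aa protein, PPC cut at 3616 and tail release at the TM (3859);
ectodomain at 1.0, residual tail at exactly 5.1 % of the slice-A mean,
and the post-PPC multiplier calibrated analytically from the frozen
peptide counts so that the pooled "slices B–J, stop > 3616" statistic —
which, as in the emulated analysis, includes the single detectable tail
peptide — equals 58 %.  The synthetic tail is built so exactly one tail
peptide falls in the mass window (dense K/R spacing plus one planted
11-mer), mirroring the single quantifiable C-tail peptide in the real
data.  `pc2_tail`: 968-aa protein, C-tail cut at 806 (the C-fragment is
the last 17.8 kDa), cleaved fraction 11.5 % so that the tail peptides'
slice I–J : A–D intensity ratio is 13 %.  `cemip2_null`: 1383-aa
uncleaved control, cohort fold 2.0 (increased).  Cohort fold-changes
are direction-of-effect settings: 0.5 for PC1/PC2 (clearly decreased),
0.67 for fibrocystin (the previously reported mutant/normal ratio), 2.0
for the hyaluronidase control (reported as doubled).

### What the generator does not model

No spectrum- or chromatogram-level effects (PSM scoring, retention time,
match-between-runs artifacts), no intensity-dependent censoring, no
shared-peptide ambiguity between proteins, no protease non-specificity
beyond the annotated biological sites, and no inter-sample
normalization drift.  Passing recovery tests therefore show that the
statistics invert the generator's abundance model faithfully at
realistic noise and missingness — not that they are robust to every
artifact of real LC-MS data.

## Problem sizes and numerical choices

Simulated cohorts use the full planted proteins (≈370 detectable
peptides for the PC1-like protein, ≈330 for fibrocystin, ≈9 000–12 000
table rows per cohort), and localization recovery is assessed over 100
seeded cohorts per preset; the numbered analysis scripts use 25 for the
narrative run.  Ratios are reported at full precision; m/z displays at
two decimals; band algebra tolerance 2 kDa; glycan-milestone tolerance
0.5 kDa; change-point minimum support 3 peptides per side and minimum
score 1.0.  Degenerate inputs are values, not crashes: empty regions
return flagged undefined ratios, absent tails return 0, proteins with
fewer than 10 peptides produce no cleavage calls (with a warning), and
sites at tryptic boundaries yield fully tryptic "semi-tryptic" products.

## Known limitations

Cleavage calls are intervals bounded by observed peptides; a site in a
long peptide-free stretch is localized only to that stretch.  The
region-ratio statistic assumes equal response factors within a region
only in expectation; with few peptides (the PC2 tail has ~14) the
recovery tolerance is correspondingly wider.  Western-blot band
fractions ("about 40 %/60 %") are image-derived quantities outside the
peptide data model and are represented only as population fractions in
`pc1_fig2`, not estimated.  Real cohort effect sizes for PC1/PC2 are
direction-of-effect choices, not measurements.
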