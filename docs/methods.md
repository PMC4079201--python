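# Methods

This note documents the models, defaults and numerical choices behind
`satscan`, and what the synthetic-data tests do and do not demonstrate
about real genomes.

## Relative-frequency profiling

For a k-mer *w* at a valid position of a focal chromosome, the statistic is
`(k_focal(w)·L_bg)/(k_bg(w)·L_focal)`; counts include overlapping
occurrences. Defaults and their rationale:

- **k = 13** (configurable). Long enough that a 13-mer is
  chromosome-diagnostic at *Drosophila* genome scale (4¹³ ≈ 6.7×10⁷
  exceeds genome size), and prime, so profiles are not dominated by di-
  and trinucleotide simple repeats whose periods divide composite k.
- **Strand handling**: by default a k-mer and its reverse complement share
  one canonical key (`strand_mode="both"`), because satellite arrays occur
  in both orientations; single-strand counting is available and the mode is
  recorded on every table and profile. Note that in canonical mode a k-mer
  whose reverse complement also occurs on the same chromosome accumulates
  both occurrences under one key.
- **N handling**: windows containing any non-ACGT character are skipped
  entirely — they enter neither numerator nor denominator — so assembly
  gaps cannot create artifactual ratios.
- **Zero-background k-mers** get a denominator count of 1 and a
  `background_absent` flag rather than being dropped: they are the most
  focal-specific signal, and dropping them would delete exactly the
  positions that make a satellite cluster visible. A consequence worth
  knowing: on data where most k-mers are unique, the profile's *median*
  sits near `L_bg/L_focal`, not near 1; the near-1 baseline of a real A/A
  comparison emerges only when most k-mers are genuinely shared.
- Counting streams one chromosome at a time into a sorted code/count
  table; profiles are materialized per chromosome only.

## Cluster calling

Clusters are maximal runs of profile positions with ratio strictly greater
than the threshold (default 20; ties at the threshold are excluded). Runs
whose consecutive above-threshold positions lie within `merge_gap` bp
(default 200) are merged — this also bridges N gaps inside arrays — and
merged runs spanning less than `min_len` bp (default 500) are discarded as
single-k-mer spikes. A cluster covers `[first_position, last_position + k)`
so the final k-mer's extent is included. The merge and minimum-length
defaults are this package's decisions: they admit kilobase-scale satellite
clusters while suppressing isolated spikes, and both are configurable.

## Monomer characterization

The tandem period of a cluster sequence is estimated from seed
autocorrelation: score(p) is the fraction of positions whose 8-mer recurs
exactly p bases downstream. A true tandem unit scores high at its period
and all multiples; the elected period is the smallest candidate scoring at
least 90% of the best, which resolves dimer/trimer sub-multiples. Inputs
whose best score falls below 0.2 are reported non-periodic; random
sequence scores near 4⁻⁸, so 0.2 is a conservative noise floor — but note
that arrays whose copies are pairwise ~20% divergent (10% per copy from
the consensus) sit near that floor, which bounds the detectable
divergence.

The consensus is a per-column majority vote over period-length frames
anchored at the sequence start (ties break lexicographically). Because the
anchor is arbitrary with respect to array phase, the consensus is defined
up to circular rotation; family grouping and mapping are rotation-aware, so
nothing downstream depends on the phase.

Families are formed by single-linkage clustering on pairwise identity
above 0.7 (a package decision; random 300-bp pairs score ≈0.53 and
essentially never exceed 0.62). Identity is computed with edlib in infix
mode against the doubled partner sequence, in both orientations, which
handles circular rotation exactly. Each family's representative is its
longest member.

## Homology search

The genome-wide mapper is an ungapped seed-and-extend nucleotide search:
exact 11-bp seeds on both strands, extension with match +1 / mismatch −2
under an X-drop of 12, per-diagonal deduplication, and highest-score
selection among overlapping same-strand extensions. Significance is the
Karlin–Altschul expectation `E = K·m·n·exp(−λS)` with λ solved numerically
from the scoring distribution at uniform composition (λ ≈ 1.34 for +1/−2)
and K = 0.621, the standard constant for this score pair; n counts both
strands. Default reporting threshold E < 10⁻⁴. Gapped alignment is out of
scope: divergent copies are found through the short seed and the mismatch
tolerance of extension, which empirically recovers ≥95% of copies at 10%
divergence. Hit counts from any re-implemented search are
method-analogous, not identical, to other BLAST-family tools.

## Coverage and loci

Coverage is computed on the union of hit intervals per chromosome (no
double counting). The focal/background ratio follows the per-comparison
averaging rule: pooled focal percent divided by each background
chromosome's percent, averaged over background chromosomes; uncovered
background chromosomes are skipped and flagged rather than dividing by
zero. Hits whose consecutive members (sorted by start, strand ignored) are
separated by at most 1 kb form a locus; the sweep with a running span end
equals the transitive closure of the pairwise 1-kb relation.

## Concerted-evolution test

Copies are globally aligned to the family consensus (match +1, mismatch
−1, gap −2) and projected onto consensus columns; insertions relative to
the consensus are dropped, so all copies share one coordinate system — a
star alignment standing in for a full MSA, chosen because it is
deterministic and dependency-free while providing exactly what the
distance computation needs. Copies outside [0.5, 2]× the consensus length
are filtered with a logged reason. Pairwise distance is the Hamming
fraction over columns where both copies carry a base (gap columns excluded
pairwise, not listwise, maximizing compared sites per pair).

The test is a one-sided Wilcoxon rank-sum (within < between, the
directional hypothesis): exact enumeration when both classes have ≤20
untied values, otherwise the tie-corrected normal approximation. The two
agree within 0.01 once both groups have ≥5 members; below that the
discrete error of the approximation alone can reach ~0.02, so very small
families should rely on the exact path.

## Recombination-density model

Chromosomes are tiled with non-overlapping 250-kb windows (the last window
per chromosome may be shorter and is flagged). A hit is *counted* in the
window containing its start but its bp are *clipped* across windows, so
counts are never double-assigned while coverage conserves bp; window rate
is the length-weighted mean of overlapping map windows. The exponential
model `E[response] = exp(a + b·rate)` is fitted as a Poisson GLM with log
link — chosen because it handles zero-count windows naturally and matches
the exponential mean form; the coverage response uses covered bp with
window length as exposure, making `exp(a)` a per-bp rate. A log(y+1)
least-squares mode exists for sensitivity comparison. Degenerate inputs
(all-zero response, constant rates, <3 rated windows) raise explicit
errors. Median rates are computed over windows, one unweighted value per
window. The predicted focal/background coverage ratio is
`exp(b·(c·median_focal − median_background))` with c = 4/3 by default (the
X effective population size correction); the intercept cancels. Evaluating
this with slope 1.98 and medians 3.32/2.78 gives ≈26.1.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, with full
ground truth:

- **Background**: i.i.d. bases at composition (A,C,G,T) =
  (0.29, 0.21, 0.21, 0.29), the AT-rich balance typical of *Drosophila*.
- **Scale**: defaults are a 1-Mb focal chromosome and two 750-kb
  background chromosomes — the package's chosen problem size, preserving
  the multi-window, multi-chromosome structure of chromosome-scale data
  at desk scale.
- **Satellite**: a random 359-bp monomer (or a user-supplied one), planted
  as 12 focal and 1-per-background-chromosome tandem-array loci of 16–40
  copies (5.7–14.4 kb, within the 1–20-kb scale of real clusters). Locus
  positions are drawn with intensity ∝ exp(a + b·rate) per window
  (defaults a = −4.56, b = 2.14), with ≥2-kb clearance between loci so the
  1-kb locus rule keeps planted loci distinct.
- **Evolution**: each locus descends from a founder carrying 0.08/site
  divergence from the monomer; each copy then mutates at 0.05/site and
  every site reverts to the founder state with probability h = 0.9
  (homogenization). h = 1 makes same-locus copies identical; h = 0 gives
  independent copy divergence, and with founder divergence also zero the
  within/between distinction vanishes entirely — the null of the
  concerted-evolution test. This is a phenomenological model of concerted
  evolution: it controls the within<between signature directly rather
  than simulating unequal crossing-over or gene-conversion tracts.
  The founder divergence default matters for detection: locus-private
  k-mers (those spanning founder mutations) are what push profile ratios
  past the threshold, and at 0.08/site they occur every ~12 bp, densely
  enough that above-threshold runs never break across the 200-bp merge
  gap. The copy-number floor matters too: a locus-private 13-mer in an
  n-copy array has ratio ≈ n·L_bg/L_focal, so at the default length ratio
  of 1.5 an array needs ≥14 copies to clear the >20 threshold — the 16-copy
  minimum keeps planted arrays detectable by design.
- **Recombination landscape**: piecewise-constant per 250-kb window, rates
  Gamma(shape 4) with scale 0.83 (focal, mean ≈3.3 cM/Mb) and 0.70
  (background, mean ≈2.8 cM/Mb), matching the scale of the observed
  median rates. Constancy at the analysis window size makes the
  exponential density model exactly well-specified for fit-recovery tests.
- Seeded runs are bit-reproducible.

What passing on this generator does **not** show about real data: no
transposable elements or segmental duplications (the search's specificity
against interspersed repeats is untested), no indel evolution within
copies (substitution-only divergence flatters the period estimator),
no heterochromatic assembly collapse, and a recombination landscape with
no fine-scale structure below 250 kb.

`truth_eval` scores pipeline outputs against the planted truth (interval
matching at Jaccard ≥ 0.5; recall/precision, period error, locus accuracy,
coverage error, fit-coefficient error), with all metrics defined and
flagged on empty inputs.

## Known limitations

- The search is ungapped; heavily indel-diverged satellite copies would be
  fragmented into multiple hits or missed.
- The period estimator assumes substitution-dominated divergence; arrays
  with frequent length variants between copies blur the autocorrelation
  peak beyond ±2 bp.
- Karlin–Altschul K is a tabulated constant for +1/−2, not recomputed for
  arbitrary scoring or composition.
- The coverage-ratio averaging follows the per-comparison rule and is
  sensitive to near-zero background percents; chromosomes with zero
  coverage are excluded and flagged rather than imputed.
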