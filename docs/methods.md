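# Methods

## Barcode and host extraction

A read is scanned for the construct end sequence (the "anchor", default the
15-bp Tn5 mosaic end `GTGTATAAGAGACAG`) allowing substitutions only, up to
`max_anchor_mismatches` (default 2), at the leftmost satisfying offset; the
forward orientation is tried first, then the reverse complement, first
success wins. Indels are not tolerated: anchor-region sequencing errors are
dominated by substitutions, and a Hamming scan is deterministic and cheap.
The barcode is the `barcode_length` bases (default 17) ending
`spacer_length` bases before the anchor; in mapping mode the host flank is
everything downstream of the anchor. Barcodes containing N are discarded
before tallying because an ambiguous base has no well-defined edit distance
to its neighbours. Absence of a barcode is an outcome, not an error, and is
reported in run statistics.

The construct grammar `B<len>[N<spacer>]<end-sequence>` (e.g.
`B17N13GTGTATAAGAGACAG`) describes arbitrary designs; the tool is agnostic
to the transposon system (Tn5, mariner, Tn7) since mapping never assumes a
target-site motif.

## Library mapping

Host flanks of ≥ 20 nt are aligned to the reference. The default engine is
`blastn` (tabular output, word size 11, dust off); only hits sharing a
query's maximal bitscore survive. An exact-substring engine is also built
in: every perfect occurrence of the flank (either strand) scores equally,
which reproduces the tie semantics of best-bitscore filtering on error-free
data with no external binary.

**Junction coordinate.** The insertion site is the 1-based reference
position of the first host base next to the construct. For plus-strand
placements this is the alignment's leftmost reference coordinate
(extrapolated through any query-start clipping, `sstart − (qstart−1)`); for
minus-strand placements it is the rightmost coordinate
(`sstart + (qstart−1)`).

**Location resolution.** Per barcode, read support is accumulated per site;
sites within ±5 bp (same replicon and strand) collapse onto the
most-supported position — random-primed junction reads start exactly at the
junction, so jitter only arises from alignment clipping, and the tolerance
is configurable. Reads whose flank has several tied best-score placements
(repeats) count only in the denominator of the primary fraction. A barcode
is kept iff ≥ 75% of its reads support the primary site (boundary
inclusive); otherwise it is removed as multimapped — deliberately
conservative for repeat-region insertions.

**Barcode merging.** Among kept barcodes at the same collapsed position,
any barcode within Levenshtein distance strictly below 2 of a more abundant
one is merged into it (reads added). Processing in descending abundance
with a lexicographic tie-break makes the result order-independent and
read-conserving; the same greedy clustering (checked against a brute-force
all-pairs dynamic-programming oracle in the tests) is used when merging
counted barcodes without a library map.

**Annotation.** GFF3 features of the requested type (default `gene`) are
matched by overlap, else nearest by signed bp gap (negative when the
insertion lies 5′ of the feature start in genome coordinates). For
overlapping insertions the percentile is
`100·(site − start + 1)/length` on plus-strand features and
`100·(end − site + 1)/length` on minus-strand features, i.e. percent of the
gene length from its own 5′ end. Run statistics include genes hit within
the [5, 95] percentile core, the usual criterion for a disruptive insertion.

## Counting and lineage frequencies

Counting tallies extracted barcodes per sample. With a library map, a
counted barcode is absorbed into a mapped barcode only when exactly one
mapped barcode lies within the edit-distance bound — the mapped barcode
wins regardless of abundance, and ambiguity (several candidates) leaves the
counts untouched so reads are never misassigned between real strains.
Unmapped barcodes are retained (flagged un-annotated): lineage-tracking
experiments have no map at all. Sample tables outer-join into a count
matrix (missing = 0), and per-sample relative frequencies (columns sum
to 1) support plotting lineage trajectories across passages.

## Selection analysis

`BarcodeScreenModel.fit()` runs four steps on a two-condition design
(multi-condition experiments are analysed pairwise):

1. **Normalisation.** Median-of-ratios size factors: reference_i is the
   geometric mean of barcode i across samples (rows with any zero are
   excluded from the reference); s_j is the median of count_ij/reference_i.
   Factors are rescaled to geometric mean 1, which makes normalisation
   idempotent and is invisible to fold changes and tests. With spiked-in
   controls, both steps are restricted to the control barcodes — the right
   choice when a bottleneck has distorted the bulk of the library.
2. **Mean–variance modelling.** Per barcode, mean μ_i and variance v_i of
   normalised counts across control-condition replicates; over barcodes
   with v_i > μ_i > 0, OLS of log(v_i − μ_i) on log μ_i yields
   σ²(μ) = μ + e^b·μ^k. Fewer than 10 usable barcodes (or a single
   replicate) triggers the Poisson fallback σ² = μ. Conditioning on
   v_i > μ_i biases e^b upward for data that are truly Poisson; with
   genuinely overdispersed data and a few tens of replicates the parameters
   are recovered within a few percent (the acceptance script measures this
   at 5000 barcodes).
3. **Barcode ranking.** μ̂ = mean normalised control count, T = mean
   normalised treatment count; X ∼ NB(mean μ̂, variance σ²(μ̂)) (Poisson
   when σ² ≤ μ̂). One-sided tails use integer boundaries,
   p_neg = P(X ≤ ⌊T⌋) and p_pos = P(X ≥ ⌈T⌉), which preserves
   p_neg + p_pos ≥ 1 for non-integer T. LFC = log₂((T+1)/(μ̂+1)) with
   pseudocount 1. Percentile ranks u = rank/N (ascending p, average ties).
4. **Gene ranking (α-RRA).** For a gene with member ranks
   u₍₁₎ ≤ … ≤ u₍m₎, ρ = min over the "good" order statistics (direction
   p < α, default 0.05) of P(Beta(k, m−k+1) ≤ u₍k₎); genes with no good
   member get ρ = 1. The null distribution of ρ per gene size is built by
   randomly reassigning barcode ranks to genes; p = (1 + #{ρ_perm ≤
   ρ_obs})/(1 + n_perm), BH-adjusted per direction. Gene LFC is the median
   of member LFCs. Hits are conventionally FDR < 0.05 with |LFC| > 0.6.

**Permutation count.** The smallest attainable permutation p-value is
1/(n_perm + 1), so the permutation count must grow with the number of genes
for BH-adjusted discoveries to be resolvable: with G genes and D true hits,
FDR resolution at level q needs n_perm ≳ G/(qD). The default is therefore
adaptive, 100 permutation rounds per gene (minimum 1000); an explicit
`n_perm` overrides it.

**Null p-value distribution.** α-RRA's skipping rule puts an atom at
p = 1: under a global null with m = 3 barcodes per gene and α = 0.05,
about (1 − 0.05)³ ≈ 86% of genes have no good member and receive ρ = 1,
p = 1 exactly. The null p distribution is therefore a mixture of a roughly
uniform low-p component and that atom — valid and conservative
(P(p ≤ t) ≤ t for all t, and the fraction below 0.05 is on target) but not
uniform in the Kolmogorov–Smirnov sense. This is a structural property of
the aggregation rule, not an implementation artefact.

**Control QC.** Per sample, OLS of log₁₀(count + 1) on
log₁₀(concentration) over the wild-type control barcodes, on raw counts —
QC gates samples *before* they influence size factors. A sample is retained
iff r² > 0.8; with fewer than 4 wild-type controls (or a single
concentration) QC is skipped with a warning and all samples retained. If
every sample of one condition fails, the analysis aborts.

## Synthetic data

The simulator provides ground truth for every stage and emulates: a random
genome with non-overlapping genes on both strands (optional duplicated
repeat segments for multimap tests); uniform insertion sites with unique
barcodes (pairwise distance ≥ 3, with optional deliberate distance-1
collision pairs); junction reads with substitution errors at a set rate and
random orientation; and two-condition screens whose baseline lineage
abundances are Dirichlet-uniform, with treatment abundances scaled by
2^(gene LFC + per-barcode jitter, sd 0.2 in log₂) and counts drawn
gamma-Poisson with variance μ + φμ². An optional multinomial bottleneck
thins each sample's population before sequencing, emulating host-imposed
colonisation bottlenecks.

Default screen conditions: 1000 genes × 3 barcodes, 3 vs 3 replicates at
10⁶ reads per sample, dispersion φ = 0.1, 20 genes spiked at LFC = −2.
Control spike-ins default to a 4-point two-fold dilution series
(1, 0.5, 0.25, 0.125; 3 wild-type barcodes per level, 5% of sample mass):
a two-fold series keeps every control quantifiable even through a
bottleneck — a 1000× series leaves the lowest level at single-digit counts,
making the control size-factor estimate itself the dominant noise source —
while still spanning enough range for the QC regression. The mapping-scale
default (a few thousand insertions on a 0.2–5 Mb genome) mirrors a small
Tn5 library at a few hundred insertions per Mb.

What the simulator does **not** emulate: quality-score-dependent error
profiles, indels, PCR chimeras and jackpotting, index hopping, GC and
position biases, or insertion-site preference. Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model, not
robustness to every artefact of real libraries.

## Numerical choices and degenerate inputs

- Edit distances via `edlib`; the test suite carries an independent
  dynamic-programming oracle.
- Leftmost anchor match wins; merging order is descending abundance with
  lexicographic tie-break; primary-site ties break deterministically —
  identical seeds give byte-identical output CSVs.
- Empty FASTQ → empty tables and zeroed statistics, not errors. Zero-sum
  frequency columns, duplicate sample ids, and a matrix with no
  all-positive barcode raise informative errors (the last suggests control
  normalisation).
- p-values are clipped to [1e-300, 1]; a treatment mean of 0 against a
  positive control mean gives the exact lower-tail mass.

## Known limitations

- Two-condition comparisons only; no paired designs, time-course joint
  models, or batch covariates.
- The mean–variance fit uses control-condition replicates only and is
  biased for near-Poisson data (see above); the Poisson fallback bounds the
  damage.
- Gene assignment takes the first annotation attribute; barcodes without a
  gene are tested but excluded from gene ranking.
- Essentiality calling from insertion density, UMI handling, and
  enrichment against external pathway databases are out of scope.
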