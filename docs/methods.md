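# Methods

## The assay being modeled

synstarr analyzes barcoded reporter (STARR-seq/MPRA-style) experiments that
measure the transcriptional activity of a 10-bp abscisic-acid-responsive
element (ABRE) embedded in a fixed 50-bp promoter fragment of the
Arabidopsis *ABI1* gene (`TCTCCTTCCCATTTTCTTCG|TCTACGTGTC|GACCATCCACCGGTTTTTGT`,
window at 0-based offsets [20, 30)). Two degenerate libraries are modeled:
*ACGT-core* randomizes the four central core positions (window offsets 3–6;
4^4 = 256 variants) and *ACGT-flank* randomizes the three positions on each
side of the core (offsets 0–2 and 7–9; 4^6 = 4096 variants). The four
physically synthesized flank pools are treated as one 4^6 space because the
partition into pools carries no information relevant to analysis. A
non-degenerate *35S-control* design holds a constitutive enhancer fragment;
since only its length and identity as a fixed 50-mer matter here, the
shipped enhancer sequence — like the 35S minimal-promoter segment and the
reporter-ORF prefix of the construct — is a clearly labelled synthetic
stand-in and is configurable.

Each construct couples its variant to a 12-bp barcode matching
`VNNVNNVNNVNN` (V ∈ {A,C,G} at offsets 0, 3, 6, 9; 3^4·4^8 = 5,308,416
possible strings) placed in the transcribed reporter, so RNA reads identify
variants through the barcode→variant dictionary built from plasmid
association sequencing.

## Simulator

The generator draws, per variant v:

* baseline log2 activity `a_v ~ Normal(activity_mean, activity_sd²)`
  (defaults 0 and 1);
* a condition effect `δ_v ∈ {+effect, −effect, 0}` with probabilities
  `frac_enhancing`, `frac_blunting`, remainder (defaults 0.05/0.05,
  `effect_log2fc = 1`, i.e. a twofold change under treatment — a small
  responsive minority, as observed in such screens);
* `1 + Poisson(mean − 1)` barcodes (mean 11, matching the ~10.8–11
  barcodes/variant of the motivating experiments), drawn uniformly without
  replacement from the VNN space; with probability `collision_rate`
  (default 0.004, the birthday-collision rate expected when ~40k barcodes
  are sampled from 5.3M) a slot instead reuses a barcode already owned by
  another variant;
* a plasmid abundance weight `w_b ~ LogNormal(0, 0.5)`. The real abundance
  distribution across barcodes is unknown; log-normal is an assumption,
  flagged as such.

Counts are negative binomial with variance `μ + αμ²` (`nb_dispersion`
default α = 0.05 at barcode level; α = 0 gives Poisson). DNA counts follow
the weights scaled to `dna_depth`; RNA counts scale `w_b · 2^(a_v + δ_v·1[ABA])`
to `rna_depth` per sample (defaults 2 × 10⁶ reads/sample, 3 replicates per
condition). Replicates share the truth but draw independent counts; there
are no replicate-level batch effects (the config dataclass is the extension
point). FASTQ emission writes overlapping association read pairs (100 nt
each over the 171-nt construct) and 50-nt RNA reads with the barcode between
fixed anchors, applies independent per-base substitution errors
(`base_error_rate`, default 0.001), and uses constant high quality strings —
qualities only matter in merge consensus. All randomness flows from one seed
through named child generators, so identical configs give byte-identical
FASTQ output.

What the simulator does **not** emulate: PCR jackpotting, indels, adapter
read-through, quality-score structure, batch effects, or position-dependent
error rates. Passing recovery tests therefore show the analysis is correct
under its own statistical assumptions, not that those assumptions hold for
any given real library.

## Association

Read pairs are merged fastq-join-style: reverse-complement read 2, take the
longest overlap ≥ 6 nt with ≤ 8% mismatches, resolve disagreements toward
the higher-quality base (read 1 on ties). Extraction is strictly exact-match:
the 20-nt context upstream of the window locates the construct and every
fixed base (remaining promoter context, minimal promoter + synJ + ATG
spacer, reporter prefix) must match; the window's fixed positions must match
the design; the barcode must satisfy the VNN pattern. Rejections are tallied
by reason (anchor / window / barcode) to keep the accounting auditable.

The dictionary is built with three filters, in this order: (1) drop
(barcode, variant) pairs with fewer than 10 reads; (2) drop barcodes still
observed with ≥ 2 variants — a map keyed by barcode cannot hold two variants
and discarding is the conservative choice; (3) drop variants with fewer than
5 surviving barcodes. The read filter is applied per (barcode, variant) pair,
the unit the filter names. One consequence, found by property testing:
raising the pair-read threshold is not strictly monotone, because removing
the weaker member of a collision can release that barcode back into the map.
The filter order is kept as specified; the property holds unconditionally
for the variant-level filter and on collision-free data for the read filter.

## Quantification

Counts are normalized to counts per million within each sample. The strength
of variant v in RNA sample s is

    strength_vs = log2( (Σ_b RNA_cpm[b,s] + 1) / (Σ_b DNA_cpm[b] + 1) )

summing over v's mapped barcodes. Barcode counts are summed before the
ratio (depth-efficient and standard for MPRA); a median-of-barcode-ratios
alternative is available via `aggregate="median"`. The +1 pseudocount (on
the cpm scale, configurable) keeps strengths finite and vanishes as counts
grow. The input-DNA denominator is the association sequencing itself — the
only DNA data the workflow produces — and is shared by all RNA samples.
A variant is *detected* if at least one mapped barcode survives the ≥ 5-read
RNA filter in at least one sample; undetected variants are excluded from
ranking. Class is `high` iff mean control strength is strictly > 0 (exactly
0 is `low`). CPM totals are computed on the filtered matrix, i.e. on the
counts the matrix actually contains.

## Responsiveness testing

Variant-level counts (barcodes summed) are normalized by median-of-ratios
size factors rescaled to geometric mean 1, with a total-count fallback when
no variant is nonzero in every sample. Dispersion is estimated per variant
by the method of moments, `α = (s² − m̄)/m̄²` on normalized counts within
each condition, averaged across conditions and floored at 10⁻⁸. For each
variant a two-group NB model (`y_sj ~ NB(s_j q_c, α)`, size factors as
offsets) is fit by maximum likelihood — closed form in the Poisson limit,
otherwise a bracketed root of the strictly decreasing score function. The
log2 fold change is `log2(q_ABA/q_ctrl)`; its standard error comes from the
observed Fisher information `I_c = Σ_j μ_j(1+αy_j)/(1+αμ_j)²` of each group.

The Wald statistic is referred to a Student t distribution with
`n_samples − 2` degrees of freedom. With a plug-in dispersion estimated
from 3 + 3 replicates, the statistic behaves like a t variable with ~4 df,
and a normal reference roughly doubles the nominal type-I rate (measured
0.11–0.13 at nominal 0.05 in null simulations); the t reference restores
calibration (measured 0.04–0.05). This replaces the information-sharing
that DESeq2 achieves through dispersion shrinkage. Other DESeq2 features —
shrinkage priors, outlier replacement, independent filtering — are
deliberately omitted, so on real data the calls approximate rather than
duplicate that tool. A condition whose counts are all zero has its mean
floored at 0.5 normalized counts and the variant is flagged. Classification
uses raw p < 0.05 with fold change > 1.2 (enhancing) or < 1/1.2 (blunting);
a Benjamini–Hochberg column is emitted for transparency but not used for
classing.

## Sequence preference

Consensus matrices are per-position empirical base frequencies over a
subset (default: the `high` activity class), with IUPAC codes at arg-max
ties. The probability-logo statistic tests, per degenerate position and
base, whether variants carrying the base are more (or less) active than all
others using one-sided Wilcoxon rank-sum tests; the displayed height is
`−log10(min one-sided p)` signed positive when "greater" wins, with p
floored at 10⁻³⁰⁰. Rank-sum was chosen over a t statistic (available via
`statistic="t"`) because strength distributions are heavy-tailed; the
rank basis also makes every statistic invariant under monotone transforms
of the activities. P-values are exact by enumeration of group assignments
(ties handled via midranks) while `C(n, n₁) ≤ 20 000`, otherwise
tie-corrected normal approximation with continuity correction. A cell is
flagged significant when its smaller one-sided p < 0.01; because two
directions are tested, the expected null rate of flagged cells is ~2%,
while each one-sided p is individually uniform (the calibration check
measures the one-sided rate). Motif group comparisons partition variants by
their upstream or downstream flanking triplet (e.g. GGG/GTG downstream of
the core) and report group sizes, medians and a two-sided rank-sum p versus
the "other" group; an empty group is an error naming the motif.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on simulated data at
the sizes their checks require: 100 variants × 8 barcodes for the lossless
FASTQ round trip, 500–1000 variants × ~10 barcodes at 2 × 10⁶ reads/sample
for recovery, calibration and power, 200 variants for preference
statistics, and 100-permutation calibration runs. All are seeded; pipeline
runs with the same config and seed produce byte-identical TSV artifacts.

## Known limitations

* Exact-match extraction discards any read with an error in fixed sequence;
  at appreciable error rates the yield drops accordingly (no fuzzy barcode
  collapse — by design, matching the exact-match workflow).
* Dispersion estimation with 3 replicates per condition is noisy per
  variant; calibration relies on the t reference, not on precise α.
* The single DNA pool serves as denominator for all RNA samples; per-sample
  DNA sequencing is not modeled.
* Logo rendering is out of scope; outputs are plain matrices a plotting
  layer can consume.
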