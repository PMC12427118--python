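# Methods

## Structural model

The accessibility calculation treats both molecular complexes as rigid.
For each contiguous placement of the enzyme-bound DNA segment along the
nucleosomal DNA, the deoxyribose-backbone atoms of both strands are
paired across structures by (base-pair offset, strand, atom name) —
atoms missing on either side are dropped pairwise — and the
RMSD-minimizing proper rotation + translation is found by the Kabsch/SVD
construction with reflection correction. The transform is applied to
*all* atoms of the probe complex; clash scoring then counts the fraction
of enzyme atoms (protein class of the probe) having at least one
histone atom (protein class of the nucleosome, DNA excluded) closer
than the sum of van der Waals radii. Counting *atoms with ≥1 overlap*
rather than overlapping *pairs* keeps the score a percentage in [0,100]
and matches the "fraction of enzyme atoms" reading of the statistic.

Choices that matter:

* **Backbone atom set** — C1′, C2′, C3′, C4′, O4′, C5′, O3′, O5′, P
  (P absent on 5′-terminal residues). The sugar ring plus phosphate
  linkage is robust to sparsely resolved bases and keeps the per-residue
  atom count high enough for a stable fit; configurable.
* **Base pairing** — residue i of strand 1 pairs with residue N+1−i of
  strand 2 by chain residue ordering. This is the duplex numbering
  convention, not hydrogen-bond detection; nicked or unusual duplexes
  need a pre-cleaned chain pair.
* **Alternate locations** — highest occupancy wins, ties broken by
  altloc letter, for determinism.
* **Hydrogens** — excluded from selection and clash scoring by default:
  crystal structures usually lack them, and mixing hydrogen-bearing and
  hydrogen-free structures would bias the normalization. Flag to include.
* **Radii** — Bondi-style set with a 1.7 Å fallback, overridable by a
  two-column table. Absolute clash percentages depend on this choice
  (and on the atom inventory of the structures), so only the *shape* of
  the profile — in particular its periodicity — is comparable across
  radius sets.
* **Neighbor search** — a KD-tree restricts candidate pairs using the
  query atom's radius plus the maximum target radius, then applies the
  exact criterion per pair on squared distances; the result is
  contractually bit-identical to the all-pairs check (property-tested),
  the tree is purely a speed optimization.

The periodicity estimator mean-centers the clash series and returns the
integer lag in 5..20 maximizing the autocorrelation; a constant profile
has no defined period and raises.

## Idealized structures

The synthetic nucleosome places two antiparallel pseudo-backbone strands
on a left-handed superhelix (defaults: radius 41.9 Å, pitch 25.9 Å,
1.65 turns over 147 bp — canonical nucleosome dimensions) with a local
twist of 10.2 bp per turn, around a pseudo-histone core of 3000
protein-class atoms uniform in a 32 Å sphere. The probe is a straight
duplex with the same backbone construction plus a 500-atom enzyme blob
(12 Å sphere) centered 28 Å off the helix axis on the azimuth bisecting
the strand backbones at the alignment segment's midpoint — i.e. on the
groove face, so that after superimposition the blob points toward or
away from the core depending on the local twist phase. Backbone atoms
carry small fixed per-name offsets in the local frame so fits are
non-degenerate. Both builders are deterministic per seed (numpy PCG64).

These builders reproduce the *geometry* that drives the analysis (the
rotational register of wrapped DNA), not the chemistry: absolute clash
values are synthetic, and a real enzyme–DNA complex will differ in atom
inventory and shape. What carries over to real structures is the
pipeline and the periodicity of the profile, not its amplitude.

## NDR calling

Methylated/unmethylated GCH counts in 200-bp windows every 20 bp are
tested against the genome-wide background (all coverage-filtered GCH
sites counted once, windows not excluded) in a 2×2 χ² test, df = 1,
without Yates correction — the counts are far from the small-sample
regime where the correction matters. A window is significant when
p < 10⁻⁵ *and* its GpC level exceeds the background level (depletion in
the accessibility signal must not create an LNDR); significant windows
that overlap or touch are merged, the merged call carrying the minimum
member p-value. Windows with fewer than 5 observations are skipped and
QC-counted. HNDRs are the per-chromosome complement, so LNDR ∪ HNDR
partitions each chromosome exactly (property-tested).

Coverage filtering keeps sites with more than 3 reads (strict), the
Methods-section reading of the upstream filter; the threshold is a
parameter everywhere it is used.

A windowed caller has an intrinsic boundary resolution: any 200-bp
window overlapping an accessible span by more than the minimally
detectable overlap becomes significant and contributes its *entire*
extent to the merged call. A 300-bp feature is therefore dilated by
up to roughly a window width per side, and because the χ² statistic's
sampling standard deviation is √(2+4λ) regardless of read depth, the
significance transition in overlap fraction is irreducibly soft — no
choice of coverage or contrast makes boundary-level Jaccard against a
300-bp truth approach 1 while keeping detection power. The synthetic
defaults favor power (recall/precision ≥ 0.9); measured boundary
Jaccard on planted spans is ~0.6, and the boundary histograms show the
same up-to-one-window smear around the planted edges.

## Regions and orientation

Four anchors per gene — TSS, first-intron start, first-intron end,
second-intron start, all transcription-oriented — each carry a
−2000..+1000 bp window (3001 bp), mirrored for minus-strand genes so
that −2000 is always transcriptionally upstream. Genes without a second
(or any) intron emit fewer anchors. Aggregated methylation curves and
NDR boundary histograms use the same oriented relative coordinates;
positions with no sites are reported missing, not zero.

## Match statistic and registers

The match-score follows the printed conditional exactly, including
boundary semantics: level equal to m_thres counts as unmethylated,
clash equal to c_thres as tolerated. Windows must fit entirely inside
the NDR∩region intersection so every CpG has a defined clash value, and
must contain at least one CpG. Cohen's d uses sample standard
deviations and the averaged-variance pooling; the Wilcoxon rank-sum
test is exact for tiny groups and uses midranks with the normal
approximation otherwise. No multiple-testing correction is applied —
raw p-values are reported alongside the effect size, which is the
quantity of interest. Effect-size bins use |d| at 0.2/0.5/0.8 with
inclusive lower bounds; the sign is reported separately via d itself
(a large negative separation is not "negligible").

Relating genomic position to profile phase requires a *register*:

* `register="genomic"` (default): phase = position mod P. This is the
  register in which the synthetic generator tiles accessibility, so it
  is the register under which planted coupling is recoverable, and the
  one the end-to-end tests and effect tables use.
* `register="window"`: each window is scored under its own assumed
  nucleosome origin (offset k → profile position k+1). For data whose
  true register is unknown this scores every possible placement — but
  averaged over uniformly placed windows the expected score equals the
  independence expectation exactly (a pattern's mean agreement with its
  own circular shifts is p·q + (1−p)(1−q)), so on translation-invariant
  synthetic data the effect size collapses to ~0. The suite keeps this
  as an explicit negative control; choosing it as the default would
  make coupling unrecoverable by construction.

The randomized null permutes (level, count) tuples among CpG positions
within a scope — by default region-class × NDR-kind strata — leaving
positions and coverage untouched, so the level multiset is preserved
exactly; replicates and scope are configurable and every permutation is
seeded.

## Synthetic data: what it emulates and what it does not

The generator plants the features the analysis is designed to detect:
elevated GCH methylation (65 % vs 20 % background) in −200..+100 bp
spans around expressed TSSs, sinusoidal GCH phasing (period 190 bp,
amplitude 10 %) downstream, CpG states outside planted spans following
the tiled accessibility indicator (clash ≤ 5 %) with probability
`coupling` (fair coin otherwise, and always a fair coin inside planted
spans — no nucleosome, no constraint), methylated CpGs at level 85 %
and unmethylated at exactly 0 so the m_thres = 0 call is well defined,
reads as Binomial(Poisson(10) coverage, level). Site densities are
0.05/bp (GpC) and 0.11/bp (CpG, island-like so 136-bp windows carry
~15 CpGs, populating the 10–20-CpG stratum). Contrast and coverage were
fixed by a power analysis of the χ² caller (per-window noncentrality
≫ the 10⁻⁵ cutoff) before any end-to-end run.

Not emulated: real sequence (contexts are assigned, not derived),
strand-specific methylation, copy-number or mappability artifacts,
distance-dependent nucleosome positioning beyond the single planted
span and sinusoid, and any absolute correspondence between synthetic
clash percentages and a real enzyme's footprint. Passing tests
therefore demonstrate that the pipeline recovers what it is designed to
recover under its own model; they do not validate the biological effect
sizes attainable on experimental data.

## Problem sizes and determinism

The default synthetic genome uses 16 three-exon genes (~230 kb), where
the full pipeline runs in seconds; the uncoupled negative-control run
uses 96 genes with 2-bp window steps because overlapping windows are
strongly correlated and the Monte-Carlo noise floor of d scales with
the number of *independent* window stretches. All randomness flows
through seeded numpy Generators; reruns are byte-identical, and
hypothesis-based property tests run derandomized.

## Known limitations

Rigid-body superimposition ignores induced fit: a near-zero clash
fraction is necessary, not sufficient, for productive binding, and
moderate clashes might be relieved by conformational adjustment
(relaxation by energy minimization or dynamics is out of scope).
mmCIF, multi-model NMR input and hydrogen placement are unsupported.
The caller's boundary dilation (above) bounds boundary-level agreement
with narrow features. The genomic register assumes a translation-fixed
nucleosome phase, which is the synthetic generator's convention; real
chromatin has locally varying registers, for which the window register
exists but carries no shift-averaged signal.
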