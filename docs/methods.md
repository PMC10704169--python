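# Methods

## Lipid model

Every lipid is an elemental composition assembled by condensation
bookkeeping: a diether core is glycerol plus two isoprenoid alcohols
(C20 phytanyl or C25 sesterterpanyl) minus one H2O per ether bond, and
each head-group or glycosyl attachment removes one further H2O. This
reproduces archaeol as C43H88O3 (652.6733 Da). Head groups are stored as
their free molecules together with the number of cores they bridge (1
for diethers, 2 for cardiolipin-type lipids) and the number of
condensation junctions (2 for BPG, 3 for the phosphate-bridged
glyco-cardiolipins). Sulfation adds SO3 (79.95682 Da) without water
loss; each hexose adds C6H10O5 (162.05282 Da).

Unsaturation is modelled purely compositionally (−H2 per double bond,
0–8 per core); double-bond positions are not represented because CID
spectra do not localize them. Where a rule needs per-chain unsaturation
(the sodium-adduct chain-loss rule), the total is split
ceil/floor between the two chains — an explicit convention, not a
structural claim. Menaquinone MK_n:m is menadione with an n-isoprene
chain carrying m double bonds; bacterioruberin is the C50 tetrol
C50H76O4 with up to three anhydro variants. Di-extended archaeol
(two C25 chains) is enumerable but disabled in the default
configuration, since it has not been observed in halobacterial
cultures.

Monoisotopic masses come from an IUPAC table restricted to
C/H/N/O/P/S/Na. Two charge-carrier conventions are supported: `proton`
(1.007276 Da, physically exact to the neglected electron binding) and
`hydrogen_atom` (1.007825 Da, the vendor-style convention that neglects
the electron); the leucine enkephalin lock mass 556.2771 is reproduced
under the latter.

## In-silico spectra

MS² spectra are predicted from a class-level rule table
(`data/fragment_rules.tsv`): neutral losses (head group ± H2O, hexose,
SO3, intact chains as alkenes ± H2O, water), diagnostic ions (protonated
head groups, the PI head ion at m/z 261.038, the menaquinone ion at
187.0754) and the sodium-adduct rule (sequential intact losses of the
two unsaturated chains; [M+Na]+ spectra are generated only for
unsaturated species and kept out of the default annotation library
because sodiated ether lipids fragment poorly and would invite false
annotation). The shipped rules are reconstructions of generic
ether-lipid CID behaviour, not measured spectra, and the table is meant
to be replaced for instrument-specific work. The rule vocabulary is
deliberately rich enough that predicted spectra have realistic peak
counts; with fewer than six fragments per spectrum the networking gate
(≥ 6 shared peaks) could never fire.

## Annotation score

Candidates within 0.01 Da of the precursor are scored as the unweighted
mean of four components in [0, 1], reported on a 0–100 scale: MS¹
similarity exp(−½(Δm/σ)²) with σ = half the MS¹ tolerance; forward dot
product on square-root intensities with greedy nearest-m/z peak pairing
at 0.05 Da (each peak used once); reverse dot product normalized over
matched query signal; and the matched fraction of library fragments.
The acceptance threshold is 70%. The exact formula of the upstream
alignment software is unpublished at this granularity; this one is
defined so that a self-match scores 100 regardless of peak order and
unrelated spectra fall well below threshold. Identifications whose
class requires a diagnostic ion (PI → 261.038) are accepted but flagged
*tentative* when that ion is absent. A curation blacklist stands in for
expert review of false positives, which cannot be automated faithfully.

## Filters

Blank filtering keeps a feature iff max(sample) ≥ 10 × max(blank), with
a ratio of exactly 10 kept ("lower than 10-fold" removed) and
blank-absent features always kept; aggregation is max over blanks and
max over samples (conservative). RT correction fits a piecewise-linear
map through located internal-standard anchors (constant shift with one
anchor); anchors deviating more than 0.8 min are excluded and reported.
Coverage percentages are computed against the MS²-bearing feature
count, rounded to two decimals.

## Core-chain accounting

Intact polar lipids are collapsed onto their diether cores; cardiolipins
contribute both cores at full weight because chain accounting is
per-core (the upstream convention is unstated; this choice keeps the
conservation identity exact). Abundance weighting uses semi-quantified
abundances rather than raw feature counts. MK and bacterioruberin are
excluded (no glycerol-diether core). Unsaturated cores are split into
low (< 4) and poly (≥ 4) unsaturation; the two percentages partition
the unsaturated pool and sum to 100 whenever it is non-empty. The
chain↔molecule conversion *f*mol = 2·*f*chain is exact on rationals and
guarded by the no-diExt-AR precondition (*f*chain ≤ 50%).

## Molecular networking

Spectrum cleaning removes fragments within 17 Da of the precursor and
keeps a peak iff it ranks in the top 6 intensities among peaks within
±25 Da of itself (a sliding window, the GNPS convention; fixed bins are
configurable). The modified cosine allows a fragment pair to match
directly (|Δm/z| ≤ 0.05) or shifted by the signed precursor mass
difference; the optimal one-to-one assignment over eligible pairs is
found exactly via linear-sum assignment on square-root intensity
products, and the score is normalized so it is symmetric and bounded by
1. Edges require cosine strictly above 0.7 **and** ≥ 6 matched peaks.
Boundary semantics throughout: m/z exactly 500 is kept, components of
exactly 4 nodes are kept. No per-node edge cap is applied. Components
are labelled by their most frequent annotated class, else by a taxon
contributing > 50% of node occurrences ("<taxon>-dominant unknown"),
else "unknown"; unannotated nodes in annotated components are counted
as analogs, those in all-unknown components as candidate new
structures. Note that same-core lipids of different classes genuinely
share fragments (head losses expose identical core ions; chain losses
match via the precursor shift), so mixed-class components are expected,
not an artifact.

## Chemotaxonomy and phylogeny

For clustering, abundances are log10-transformed and z-scored within
each sample column; for ordination they are sum-normalized per sample
and log10-transformed. Zeros are replaced by half the smallest positive
value in the matrix; a constant column under scaling falls back to
sd = 1 with a warning. Replicates are averaged (arithmetic mean) before
strain-level clustering. The distance metric is Euclidean on the scaled
values (heatmap-package default; configurable). "Ward" uses scipy's
variance-minimizing Ward criterion on Euclidean observations; the
distinction from the alternative Ward variant does not change any merge
on data of this study's scale (verified on the default synthetic set).
PCA is an SVD of column-centered data. PLS-DA uses NIPALS with one-hot
class encoding, per-feature autoscaling and two components by default;
VIP_j = sqrt(p · Σ_a w²_ja SSY_a / Σ_a SSY_a), which guarantees
mean(VIP²) = 1.

p-distances use pairwise deletion of gap/ambiguous sites. Neighbor
joining follows Saitou–Nei with the standard Q-matrix and branch-length
formulas; negative branch lengths are clamped to zero. Bootstrapping
resamples alignment columns with replacement (default 1,000 replicates;
the column resampling is the only stochastic element, so support values
are invariant to taxon input order at a fixed seed). Concordance between
a lipidome dendrogram and the reference is reported as the adjusted Rand
index between the k-cluster cut and reference labels (ARI = 0 at k = 1
by convention) plus the unrooted Robinson–Foulds distance.

## Synthetic study design

The generator emits the design the analysis expects: seven strains from
three orders, grown in triplicate, with two extraction blanks. Class
presence follows the strain-by-class tier table (major / trace /
absent); per-strain unsaturation percentages, poly-unsaturation
fractions and C25-chain fractions are the study's printed values
(e.g. 20.72% unsaturated cores for *Hf. mediterranei*, 13.44–26.16% C25
chains across the *Natrialbales*). Tier semantics are a free choice,
documented here: a major class sits at a class-specific base level
(detector counts, chosen so that even trace species at base/50 clear
the 3,000-count detection floor — the table emulates a *detected*
feature export), trace = major/50.

Noise model: per-scan m/z jitter is Gaussian with σ = 0.005 Da; the
consensus m/z of an aligned feature averages one observation per
carrying sample and therefore jitters with σ/√n. Replicate variation
factors into a shared per-replicate biomass/extraction factor
(log-normal, σ = 0.3) times per-species measurement noise (CV 10%), so
within-strain composition — the quantity every downstream statistic
uses — is realistically stable while absolute intensities vary.
Ammonium-adduct formation is decided per head-group class (adduct
formation is head chemistry), with [M+NH4]+ at half the [M+H]+
response. Each strain also emits homolog-shifted unknown analogs of its
library species (+k·CH2, fragments above half the precursor shifted
with it), each order emits a five-member novel homolog family with a
shared synthetic fragmentation pattern, and blanks carry contaminants
whose sample carry-over stays below the 10× rule. An internal standard
(C19-PC, [M+H]+ 818.6633) is spiked into every non-blank sample. The
toy 16S alignment mutates a random ancestral sequence along the order
topology (10% substitutions root→order, 2% order→strain), which makes
within-order similarity strictly exceed between-order similarity.

What the generator does **not** emulate: chromatographic peak shapes,
isotopologue envelopes, in-source fragmentation, co-elution and
real spectral backgrounds. Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline's logic under the
stated statistical structure, not performance on raw instrument data.

## Problem sizes and numerical choices

The default synthetic study produces ~175 aligned features (~780
library spectra), sizes chosen so a full simulate→report run completes
in seconds while exercising every stage; all statistics above are
computed at these sizes. Duplicate predicted fragments within 1e-4 Da
merge keeping the larger intensity; MSP export prints m/z to 4 decimals
and intensities to 1 decimal, which makes export→import→export
byte-stable. Scoring ties are broken by smaller MS¹ error, then
lexicographic species name; scipy's deterministic ordering breaks
clustering ties. Seeds propagate through `numpy.random.default_rng`
from a single integer.

## Known limitations

* Fragment intensities in the rule table are nominal, not fitted to
  measured spectra; scores are therefore comparable within this library
  but not calibrated against external libraries.
* The Gly-AHH head group is modelled as hexosyl-aminohexanehexaol
  (C12H25NO11 free form); its exact reported structure differs by a
  condensation convention and only shifts all species of those two
  classes by a constant.
* Cardiolipins are enumerated with two identical cores; mixed-core
  cardiolipins are not generated (unresolvable at MS¹ from the
  symmetric species in most cases).
* PLS-DA VIP is computed for two components on autoscaled data; with
  more components than informative latent directions the NIPALS
  deflation stops early.
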