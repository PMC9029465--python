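# Methods

This note records the models, conventions and numerical choices behind
hbskit, and what the synthetic-data generators do and do not emulate.

## Coordinate system

Genomic positions are 1-based inclusive internally; 0-based half-open
coordinates appear only in BED output. The TSS-relative axis is zero-free:
the TSS base is +1 and the base immediately upstream is −1. This "unit-based"
convention was chosen because it is the unique one under which a window
described as −6765..+4234 around a minus-strand TSS at absolute 27230845
has absolute bounds 27237610..27226612 (27230845 − 27226612 + 1 = 4234;
27230845 − 27237610 = −6765) and length 10,999. `abs_to_rel`/`rel_to_abs`
are exact inverses and are property-tested as a bijection on random loci of
both strands.

Window extraction always returns the sequence in gene-sense orientation
(reverse complement of the plus-strand slice for minus-strand genes), with
index maps local→relative→absolute. Soft-masked (lowercase) input is
uppercased and scanned; no masking rule is applied. `N` never matches any
motif or anchor position, not even another `N`.

## TSS mapping

The TSS is defined by the genomic base matching the transcript's first
nucleotide, so the mapper places only the mRNA's 5′-terminal anchor
(default 30 bases; tunable) on both strands with a Hamming-distance
tolerance (default 0). A 30-base anchor makes spurious placements in a
~10 kb locus vanishingly unlikely while tolerating short 5′ reads; spliced
alignment of the full transcript is deliberately out of scope since introns
cannot move the 5′ end. Multiple placements raise an error listing all of
them rather than picking one — a single-TSS annotation presumes uniqueness —
and zero placements are likewise an error.

## HBS scanning and classification

The detector is the core+flank rule: exact occurrences of A⁰CGTG (optionally
the degenerate RCGTG), each annotated with the bases at −2 and +5 relative
to A⁰ in match orientation. `HIGH` confidence requires G⁻² and/or C⁺⁵ — an
inclusive OR. Flanks falling outside the scanned sequence are `UNKNOWN`,
count as absent, and set a low-context warning flag. The position of a site
is defined as its A⁰ base; published site positions do not state which core
base they index, so this is this package's convention.

The default scan covers the gene-sense strand only; `scan_antisense=True`
adds complementary-strand hits, reported at the sense base pairing A⁰.
Weight-matrix scoring of the wider site is not implemented: the core+flank
rule is the documented detector, and matrix scores would add a model the
flank rule does not need.

BED6 export spans the five core bases; on a genomic minus-strand match the
core extends toward decreasing absolute coordinates from A⁰. Scores encode
confidence (1000 HIGH / 500 CORE_ONLY). GFF3 is 1-based inclusive; CSV
round-trips every candidate field.

## qPCR quantification

Amplification efficiency defaults to 2 (one doubling per cycle), consistent
with primer efficiencies near 100%; it is exposed as a parameter. Fold
enrichment is `E^(Ct_IgG − Ct_sample)`; ΔΔCt fold change is
`E^−[(ΔCt_sample) − (ΔCt_calibrator)]`. Input-percent normalization is
deliberately not applied — the implemented quantity is enrichment over the
IgG control only.

Replicate Cts are averaged *before* exponentiation for the point estimate
(the standard ΔΔCt practice; it makes the calibrator's own fold change
exactly 1), while per-replicate fold values — replicates paired by index —
feed the SEM (= sd/√n, undefined rather than 0 at n = 1). Missing roles
(IgG, housekeeping, calibrator) produce structured errors naming the
condition and role. Downstream inferential statistics (normality tests,
ANOVA, post-hoc comparisons) are out of scope; the per-condition CSV output
is shaped for any stats package.

## Structure and trajectory metrics

A contact is an atom pair, one atom from each selection (default moieties:
protein vs DNA, assigned from residue names — standard amino-acid codes and
common force-field variants → PROTEIN; DA/DC/DG/DT/DN → DNA; else OTHER),
with Euclidean distance ≤ cutoff (default 0.6 nm). The comparison is
inclusive at the boundary so results are bit-reproducible; for real-valued
coordinates the boundary set has measure zero. Counting uses two k-d trees
(`scipy.spatial.cKDTree.count_neighbors`) and is tested to equal the O(n²)
enumeration exactly across sparse and dense random packings. Residue-level
maps aggregate the same pairs, so their totals always equal the pair count.
Hydrogens are not excluded: all atoms in the selections count.

RMSD optionally applies least-squares rigid superposition
(Kabsch, SVD with reflection correction) before the displacement RMS;
rigid-motion invariance holds to < 1e-9 nm. RMSF is the per-atom RMS
displacement over a trailing window, against either the window-mean
structure (default — the standard fluctuation definition) or the window's
first frame (provided because fluctuation is sometimes described relative
to a starting structure; the two differ by √2 for a symmetric oscillator,
and both modes are exposed rather than asserting one). No superposition is
applied inside RMSF; frames are assumed pre-aligned, which the synthetic
generator guarantees. There is no periodic-boundary handling anywhere:
coordinates are treated as whole molecules in open space.

PDB reading is implemented over the fixed-column ATOM/MODEL records so the
package can enforce its error contract precisely: unparseable coordinate
fields are reported with their line number, and models with diverging atom
counts are reported by model number. A file without MODEL records is one
frame. Coordinates convert Å→nm on read (×0.1) and back on write (×10);
round-tripping is exact to the PDB's 0.001 Å precision.

## Synthetic data

The generators define the test conditions; their defaults are fixed and are
not tuning knobs.

**Locus.** Background bases are drawn i.i.d. (uniform by default; an
optional composition parameter exists because genomic core density is
GC-sensitive, but the truth table never depends on it). Planted sites write
an 8-base footprint `[−2][−1]ACGTG[+5]` in gene-sense orientation at the
requested TSS-relative offsets; the −2/+5 bases are forced to (or away
from) G/C according to the requested flank class, and the −1 base is drawn
from {A,G,T} because a C there would create a reverse-strand core
overlapping the plant. Accidental occurrences of ACGTG *and* of its reverse
complement CACGT outside planted spans are destroyed by single-base
substitution (iterated to a fixpoint), so scans — sense-only or antisense —
recover exactly the planted truth. Plants must be ≥ 8 bp apart with
footprints inside the window. Destruction-by-substitution was chosen over
rejection sampling to keep generation O(length) with an exact truth table.
The default layout plants six sites on a minus-strand locus spanning the
default −6765..+4234 window: #1 at −2186 (G⁻² and C⁺⁵), #2 at −1200, #3 at
+350, #4 at +1500 (both flanks), #5 at +2600 (C⁺⁵ only), #6 at +3900 —
i.e. two upstream sites and a high-probability set {#1, #4, #5}. Only the
−2186 offset is an externally fixed position; the remaining offsets are
representative choices made once.

**Transcript.** Exons run gene-sense from the TSS with configurable intron
gaps (100 bp default), so the mRNA's 5′ base is exactly the TSS base and
anchor mapping must recover the planted locus.

**Ct tables.** Per replicate, the reference (IgG or housekeeping) Ct is
drawn Normal(base_ct = 25, sd); the paired sample Ct is the reference draw
minus log₂(true fold) plus independent Normal(0, sd) noise (plus a fixed
5-cycle target-vs-housekeeping gap in the expression design). Defaults — six
replicates, 0.2-cycle noise, a 35-fold enrichment under extended hypoxia
against a ~5.8-fold normoxic control — mirror the study conditions the
package targets. At sd 0 the summaries reproduce the true folds exactly; at
sd 0.2, n = 6, the mean recovered log₂ fold is unbiased to < 0.05 over 500
seeds (tested).

**Trajectories.** Protein atom *k* and DNA atom *k* form a designated pair
placed 0.45 nm apart when scheduled "in contact" and 1.5 nm apart otherwise;
distinct pairs sit 3 nm apart, and all other atoms ≥ 18 nm from DNA, so the
0.6 nm contact count of each frame equals the schedule exactly and survives
PDB coordinate rounding (margins 0.15 nm on either side of the cutoff). The
schedule maximum is therefore limited to min(n_protein, n_dna) — one DNA
partner per protein atom. Designated fluctuating atoms (disjoint from
contact pairs) oscillate ±amplitude along z on alternating frames, far from
all DNA, so mean-reference RMSF over any even trailing window equals the
amplitude exactly, and first-frame-reference RMSF equals amplitude·√2.

**What the generators do not emulate**: real base composition, CpG islands
and repeat structure; spliced-alignment artefacts or 5′-end heterogeneity;
qPCR efficiency drift, pipetting covariance or amplification curves; MD
physics (solvent, thermal motion, correlated dynamics). Tests passing on
synthetic data therefore demonstrate correctness of the computational
pipeline — coordinates, detection, arithmetic, counting — not biological
performance of the detector on real chromatin.

## Problem sizes in the test suite

The suite runs entirely on generated data: full-size (10,999 bp) loci where
window geometry matters, 1,000-bp loci for the 200-locus exact-recovery
sweep, 500-seed Monte-Carlo for qPCR recovery, 100 random 80-atom
configurations for the contact oracle, and ≤ 10-frame trajectories. These
sizes keep the complete suite under ten seconds while leaving every
contract exercised at full fidelity.

## Known limitations

* The scanner enumerates exact cores only; it does not score wider binding
  preferences or integrate chromatin state, conservation or ChIP-seq peaks.
* Enrichment assumes a shared efficiency for ChIP and IgG reactions and no
  input-percent normalization.
* Contact counting and RMSD/RMSF assume whole molecules in open space; no
  periodic-image handling.
* The TSS mapper requires the 5′ anchor to lie in a single exon (true by
  construction for the generator; real 5′ UTRs with micro-exons would need
  a spliced aligner).
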