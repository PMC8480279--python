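# Methods

`fmscreen` reimplements, as a tested desk-scale pipeline, the analysis
behind a multiplexed functional-metagenomic screen: an arrayed cosmid
library (~30 kbp stool-metagenome inserts in an *E. coli* host) is assayed
against reporter cell lines, hits are called by in-plate Z-scores and
validated in quadruplicate, active clones are dereplicated into effector
regions by insert overlap, effector genes are localized by transposon
mutagenesis, and effector-protein prevalence is measured across patient
protein catalogs. Every input is produced by the synthetic-data generator,
so the statistical machinery can be validated end to end without any
external data.

## Screening model

Each 384-well plate carries `n_controls_per_plate = 42` empty-vector
control wells (default positions: columns 1, 12 and 23, rows A–N;
configurable, since plate maps vary between labs). Readouts are
assay-specific:

- **NF-κB**: fraction of live GFP-expressing cells among live cells;
- **LC3**: mean GFP-LC3 puncta per live cell;
- **SoNar** (redox): the excitation ratio F420/F485 from plate-reader
  channel pairs. A zero F485 denominator is a QC failure, not a readout.

Wells are normalized per plate and replicate:

    Z = (readout − mean_control) / sd_control

with the control mean and *sample* SD (n−1 denominator; the convention is
not dictated by the protocol, so the unbiased estimator was chosen)
computed from that plate's usable control wells only. A plate with fewer
than two usable controls is rejected. A clone is a primary hit when
Z > 3 (strictly), the well passed QC, and its dead-cell fraction (PI+
cells over Hoechst+ nuclei) is at or below the toxicity gate. The gate
defaults to 0.5 — the underlying protocol states only that toxic wells
were excluded, not a cutoff — and gated wells are reported with a
`gated_toxic` flag rather than dropped. NF-κB and LC3 use the upper tail;
the ratiometric redox readout deviates in either direction, so it defaults
to two-sided. Validation re-assays each primary hit in quadruplicate and
requires Z > 3 in at least 3 of 4 replicate wells.

Printed percentages are rounded half away from zero (one decimal for hit
rates, nearest integer for prevalence), which reproduces every headline
rate exactly from its integer counts.

The null calibration property follows from this design: with control
statistics estimated from 42 wells, the Z > 3 upper-tail rate on pure-null
plates is slightly above the ideal Gaussian 0.135% (a Student-t-like
inflation, empirically ~0.25%), and the test asserts the [0.05%, 0.5%]
band on 10^5 simulated null wells.

## Image quantification

Quantification is deliberately segmentation-free: nuclei are local maxima
of the Gaussian-smoothed DAPI channel (minimum separation 6 px, relative
threshold 0.3 of the dynamic range over the median background, with an
absolute dynamic-range floor so empty images yield nothing), and each cell
is a fixed-radius disk (10 px) around its nucleus. Death is called from
mean PI intensity in the disk; GFP positivity from mean FITC intensity of
live cells; puncta as FITC local maxima (3×3 footprint) rising more than a
fixed margin above the cell's diffuse level (disk median). All thresholds
are configuration values calibrated against the synthetic renderer — no
numerical equivalence with any vendor analysis module is claimed.

The renderer places cells on a jittered grid (no overlap by construction),
stamps Gaussian nuclear/PI spots (σ = 2 px), a uniform cytoplasmic disk
for GFP, and one σ = 1.2 px punctum per simulated granule at precomputed
in-cell offsets that keep puncta ≥ 3.2 px apart (capacity 17 per cell; a
Poisson draw above that raises an error rather than silently merging).
Additive Gaussian noise (σ = 0.02 against unit-amplitude nuclei) gives an
SNR at which detection is essentially perfect, which is what makes the
round-trip oracle (image summaries vs ground-truth-table summaries within
0.02 death fraction / 5% relative readout) a meaningful test of the
quantification logic rather than of noise. Real microscope images bring
overlapping cells, uneven illumination, and focus drift that the renderer
deliberately omits; passing these tests validates the bookkeeping, not
robustness to such artifacts.

## Overlap dereplication

Overlap between two inserts is estimated by unique-k-mer chaining
(k = 31, 2-bit packed): k-mers occurring exactly once in each sequence are
matched in both orientations of the second insert, the longest chain of
matches strictly increasing in both coordinates is found
(patience-sorting LIS), and overlap = chain span + (k−1). For error-free
sequence this equals the exact shared-substring length (verified against a
quadratic-DP longest-common-substring oracle); the uniqueness filter
prevents repeat-seeded spurious chains. Pairs sharing no canonical k-mer
are skipped by a sorted-array intersection prefilter.

Edges require overlap strictly greater than 5,000 bp. Regions are the
connected components of the edge graph (union-find), so chains of pairwise
overlaps merge even when the end clones do not directly overlap —
transitive closure is the natural reading of reference-mapping-based
grouping, and it is what makes a tiled group of eight clones one region.
Isolated clones become singleton regions.

## Transposon mapping

ORFs are called by a simple maximal ATG→stop scan on both strands
(bacterial translation table, minimum 150 nt, ATG-only starts by default
with GTG/TTG available as options) — gene-finding accuracy is not the
point here; the caller only needs to support insertion attribution, and it
agrees with a six-frame brute-force oracle on random sequence. Insertions
are located by exact match of the first 30 bases of the flanking read (and
of its reverse complement) against the insert; multiple matches are
reported as ambiguous, never silently assigned. Mutants are inactive when
a strict majority of replicate Z-scores (against empty-vector controls)
fall at or below 3; an even split breaks toward active. Each mapped
inactivating insertion is attributed to the ORF containing it (ties
between overlapping ORFs go to the longest) or to intergenic space; the
nomination is unambiguous when exactly one ORF carries all inactivating
insertions.

## Prevalence

Queries are aligned to every catalog protein by Smith-Waterman local
alignment (BLOSUM62, affine gaps costing 11 + 1·length, the common BLAST
parameterization), via `Bio.Align.PairwiseAligner`. A match requires
identity strictly above 90% — identical columns over all alignment columns
including gaps — and query coverage strictly above 70% (coverage is
measured on the query; the choice is configurable). A 5-mer sharing
prefilter skips hopeless candidates. Per-patient presence/absence feeds
per-query counts and the fraction of patients carrying any match. The
protein-vs-protein formulation replaces a translated nucleotide search:
for already-translated effector queries and protein catalogs the two are
equivalent, and no frame search is needed.

## The planted fixture

`fmscreen.pipeline.make_paper_fixture` generates the dataset whose
*structure* carries the screen's headline tallies: 38,000 clones; 499, 339
and 182 planted primary actives for the three assays; 86, 5 and 1 of them
reproducing in ≥3 of 4 validation replicates; an 82-clone NF-κB library
planted as 37 singletons plus 10 overlap groups of sizes
8,7,6,5,4,4,3,3,3,2 (overlaps 8 kbp, comfortably above the 5 kbp
threshold); a 5-clone LC3 library forming 3 regions; three transposon
panels with one designated effector gene each; and 286 patient catalogs,
163 of which carry a homolog of one of 11 query proteins at 2% mutation
(the rest: decoys only, or a 20% diverged homolog that must fail the
identity threshold).

Because these tallies are planted structure, they must not depend on the
noise seed. Fixture clone wells are therefore drawn anchored to their own
plate's realized control statistics — null wells strictly inside |Z| < 2.5,
actives offset by +8 control SDs — so the downstream Z-scoring recovers
the planted hit set exactly, for every seed. This anchoring is a property
of the fixture only; the general simulator (`synthetic.simulate_screen`)
draws unconditioned Gaussian noise and is the basis of the null-calibration
and power tests. The fixture's job is arithmetic fidelity, not realism:
attrition between primary and validation screens, plate drift, and
real-community sequence composition are all outside what it emulates.

## Generator defaults

| parameter | default | rationale |
| --- | --- | --- |
| plate format | 16×24, 42 controls | arrayed-library layout |
| insert length | Normal(30 kbp, 2 kbp), min 15 kbp | cosmid insert size |
| active effect | 8 control SDs | strong validated hits sit far above Z=3 |
| reproducibility | 0.9 | per-replicate chance an active stays active |
| toxic fraction / death | 0.01 / 0.8 | sparse, clearly toxic wells |
| baseline death | Normal(0.05, 0.015) | healthy-well PI background |
| flanking reads | 200 bp, error-free | Sanger reads are long and accurate |
| decoy proteins | Normal(300, 50) aa | typical bacterial protein length |

Problem sizes in the test-suite were chosen for desk-scale runs: 10^5
wells for null calibration, 500 planted actives for power, 50 transposon
panels, 8–12 clone libraries for the DP oracle comparisons, and 50-patient
catalogs for the threshold-separation check.

## Known limitations

- The overlap estimator is exact only for error-free sequence; indels or
  chimeric inserts would fragment chains (real data would want a banded
  aligner behind the same interface).
- ORF calling is intentionally naive; operon structure, RBS context and
  alternative starts are ignored.
- The image pipeline has no segmentation and assumes non-overlapping
  cells; it does not model vendor formats, flat-field or focus artifacts.
- Cosmid instability (false transposon knockouts) is reported in the
  literature for this vector family but has no computational correction
  here; resolving it requires subcloning evidence outside this package's
  scope.
- One published tally is internally inconsistent upstream (86 validated
  NF-κB clones vs 82 analyzed); the dereplication fixture follows the
  82-clone analysis set.
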