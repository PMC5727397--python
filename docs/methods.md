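# Methods

## Model

The experiment this package analyses couples Cas9/NHEJ mutagenesis of a
candidate regulatory locus with paired amplicon sequencing of genomic
DNA and cDNA. The quantity of interest for a deletion allele *i* is its
fold effect on steady-state transcript abundance, estimated as the
UDP-normalized score

UNS_i = (cDNA_i / gDNA_i) / (cDNA_WT / gDNA_WT).

The gDNA ratio controls for allele frequency in the cell pool; the
wild-type ratio controls for library-size and amplification differences
between the two libraries, so the UNS is invariant to rescaling either
library's total depth. The consensus activity of a miRNA response
element is the gDNA-depth-weighted mean UNS over alleles that delete at
least one base of its extended seed (site positions 1–8):

MRE-score = Σᵢ wᵢ·UNSᵢ, wᵢ = gDNA_countᵢ / Σⱼ gDNA_countⱼ.

Assumptions: PCR/sequencing sample alleles proportionally within each
library; deletion alleles do not alter amplification efficiency; the
wild-type pool is abundant enough that its ratio is a stable baseline
(hence the wild-type depth filter); and a deletion's effect acts through
removed *cis* elements, so alleles sharing a footprint share an effect.

## Pipeline stages and numerical choices

**Coordinates.** SAM's 1-based starts are converted at the parse
boundary; everything internal is 0-based half-open. Reverse-strand reads
need no special handling because SAM stores SEQ in reference
orientation. `=`/`X` CIGAR operations are folded into `M`; mismatches
are recovered by direct base comparison against the reference.

**ROI calling.** Per-nucleotide deletion percentages are smoothed with a
normalized box kernel (default width 5, odd, edge windows renormalized)
and segmented where the smoothed signal exceeds `min_signal` (default
0.5 %); segment boundaries are then extended outward while the signal
keeps rising into/falling out of the segment (nearest sign change of the
discrete first derivative), so a segment spans the full support of its
peak. The ROI is the union of the widest gDNA and cDNA segments, ties
broken by larger area then leftmost. The defaults suppress
single-position error spikes while preserving ~19-nt deletion peaks;
both are tunable, and a manual ROI override is recorded with
`source=manual`.

**Read filters.** Within the ROI, reads are discarded if truncated
(alignment does not span the ROI, including clips landing inside it), if
they carry an insertion whose junction is strictly inside the ROI, or if
mismatches exceed 10 % of aligned (non-deleted) ROI positions — the
denominator choice is documented because only the numerator threshold is
canonical. Count thresholds are exclusive: wild-type counts < 100
exclude the amplicon, UDP counts < 10 drop the UDP; counts equal to the
threshold are kept.

**Degenerate cases.** A UDP with gDNA but no cDNA reads scores UNS = 0
(complete transcript loss); a UDP with no gDNA reads, or a wild-type
record with a zero count, cannot be scored and is routed to the
exclusions table with a reason — every input UDP appears exactly once in
{scored, excluded}. UDP output order is (first deleted position,
deletion length, code), making reruns byte-identical.

**Group boundaries.** MRE-score groups are low < 2, medium [2, 4]
(closed — scores exactly 2 or 4 are medium, a tie rule the source
partition leaves open), high > 4.

**De-novo sites.** A deletion can juxtapose flanking bases into an
ectopic seed match; any 7-mer from the supplied seed list present in the
mutant ROI sequence but absent from the wild-type ROI sequence excludes
the UDP. The scan is positionless string search over the full mutant ROI
by design; boundary-spanning sites outside the ROI are not considered.

**Cooperativity.** The additive (no-interaction) expectation for a
combinatorial CEP is the product of its source CEPs' mean UNS values,
since UNS is a fold change. The primary test compares observed
combinatorial UNS values with the pairwise product set {aᵢ·bⱼ} of
source values (two-sided Mann-Whitney; "cooperative" requires
significance plus an observed median above the product median), with a
one-sample Wilcoxon against the scalar prediction as a secondary check.
Because each source value appears in many products, the product set is
internally dependent and the test runs slightly hot: measured type-I
error is ≈ 6.5 % at nominal α = 0.05 under the additive null, within
the ≤ 7 % design bound. Unweighted source means are used (each CEP's
"average UNS"); depth-weighted means are a reasonable alternative the
data did not force.

**Contextual features.** Local AU content uses 5-nt windows sliding by
1 nt over the sequence around the seed; windows overlapping the seed are
skipped; each window's A/U fraction is weighted by 1/d with d the
distance from the window centre to the nearest seed boundary, floored at
1 nt (1/d diverges at 0; with centred 5-nt windows the geometric minimum
is 3, but the floor also guards non-default window sizes). AU is
reported as a fraction in [0, 1]. Accessibility z-scores shuffle the
entire input sequence (default 10 000 times, seeded) and standardize the
target profile per position; positions with zero baseline SD are
reported missing; the aggregate is the mean z over the 25 nt immediately
upstream of the extended seed. The folding backend is an injected
callable; the shipped AU-window backend is a toy stand-in with the right
interface and qualitative shape (AU-rich ⇒ accessible), not a
thermodynamic model — tests exercise the z-score machinery, not folding
physics. Pairing free energy, conservation and Pol-II occupancy are
consumed as precomputed per-MRE columns.

## What the simulator emulates — and what it does not

`simdata` generates: deletions anchored at Cas9 cut sites extending away
from the PAM; lengths geometric with minimum 1 nt, parameterized so the
median is 19 nt (success probability 1 − 0.5^(1/(m−0.5))); Dirichlet
(α = 1) allele frequencies carrying `editing_rate` (default 0.5) total
mass, wild type keeping the rest; multinomial gDNA counts and
effect-reweighted multinomial cDNA counts, so every allele's expected
UNS equals its effect E by construction; uniform substitution errors
(default 2 × 10⁻³/base); optional per-UDP effect heterogeneity
(`effect_sigma`: mean-preserving lognormal scatter around the class
effect, default 0 — real repertoires show a continuous UNS spread, e.g.
partial seed overlaps, that a single shared E cannot represent); and an
optional cooperativity factor c multiplying multi-MRE allele effects
(c^(k−1) for k seed hits). Identical configs give byte-identical SAM.

Not emulated: quality-score structure, PCR duplicates and chimeras,
insertion alleles (beyond testing the discard rule), microhomology bias
in deletion junctions, paired-end mate structure, and alignment errors —
reads are emitted with their true CIGARs, so passing round-trip tests
demonstrates the pipeline's bookkeeping, not robustness to aligner
artefacts. Each SAM record is treated as an independent read throughout
(how mates were merged upstream is outside this package's scope).

A separate lightweight generator (`simulate_cooperativity_dataset`)
draws per-UDP UNS values directly as lognormal noise (σ = 0.25) around
class effects; under c = 1 a combinatorial draw is distributed exactly
like a product of one source-A and one source-B draw, making it the
correct additive null for calibrating the cooperativity test at scale
(1000 repetitions in seconds, which full SAM-level simulation would not
allow).

## Problem sizes used by the test suite

Parameter-recovery runs use one amplicon at 10⁵ reads per library with
30 alleles (E = 5 recovered within ±15 %, E = 1 within ±10 %).
Replicate-concordance runs use depth 10⁴ with 8 alleles and
`effect_sigma` = 0.5 — about 600 reads per allele, a realistic per-UDP
coverage, under a heterogeneous truth; sparser repertoires at the same
total depth push more alleles toward the count filter where UNS noise
dominates and R² degrades regardless of pipeline correctness.
Cooperativity calibration uses 30 source and 30 combinatorial values per
run, 100 runs for power at c = 2 and 1000 for type-I at c = 1.

## Known limitations

- The minimal single-deletion aligner exists for desk-scale worked
  examples; production alignment (BWA or similar) is upstream and its
  output is consumed, never reproduced.
- MRE-score estimates transcript-abundance effects only; translational
  repression is invisible to a gDNA/cDNA readout.
- Stabilizing loci (score < 1) are reported but flagged for exclusion
  from downstream feature analysis, mirroring how such targets are
  treated in practice.
- The ROI segmentation can merge two nearby cut-site peaks into one
  region; for densely multiplexed designs the full-amplicon ROI override
  is the intended mode.
- Accession-scale benchmark numbers require the deposited dataset (SRA
  PRJNA393090) and are exercised only when those inputs are provided
  locally.
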