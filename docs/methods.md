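# Methods

## The species tree and time scale

All simulation and rate work uses a fixed eight-taxon ultrametric
chronogram for the classical Opiliones topology
`(Cyphophthalmi,((Eupnoi,Dyspnoi),Laniatores))` with node ages, in units of
100 Myr: root 5.01, Phalangida 4.88, Palpatores 3.60, Eupnoi 0.97,
Dyspnoi 2.94, Troguloidea 1.44, Laniatores 2.37. Exemplar genera name the
leaves (Siro; Leiobunum, Protolophus; Hesperonemastoma, Ortholasma,
Trogulus; Sitalcina, Sclerobunus). A per-family distant-outgroup ortholog
(the ancestral sequence evolved along a 2.0-unit stem) lets matrices be
rooted on a distant reference taxon; on an unrooted eight-taxon tree the
Phalangida clade is otherwise a trivial bipartition and its support would
be unmeasurable.

## The substitution model

Coding sequences evolve site-independently under the 4-state symmetric
(Jukes–Cantor-type) model: on a branch of duration t at rate λ each site
substitutes with probability ¾(1 − e^(−4/3·λt)), uniformly to the three
alternative bases. Closed forms
(E[p] = ¾(1 − e^(−8/3·λt)) for two taxa at divergence t) make every
downstream statistic testable. Exchangeabilities and rate heterogeneity
models of production inference engines are intentionally absent: the
screens and statistics under test depend on rate magnitude, not on
exchangeability structure. Two constraints keep sequences coding-like:
the first (ATG) and last (stop) codons are held invariant — purifying
selection on translation boundaries — and any substitution creating an
internal stop codon is resampled. The resampling suppresses realized
divergence in stop-adjacent codons by a few percent relative to the
unconstrained closed form; the generator test asserts agreement within
0.01 absolute rather than pretending the constraint is free.

## Generator defaults (the study conditions)

- 300 single-copy + 30 paralogous gene families, 20 contaminants.
- CDS length uniform 150–400 codons.
- Per-gene rates lognormal (meanlog −3.6, sdlog 0.6 per 100 Myr), chosen so
  a default batch spans realized average pairwise divergences of roughly
  0.05–0.45 — a FAST/MED/SLOW spread. No empirical per-gene divergence
  range is prescribed anywhere, so this spread is a stand-in, not a
  reproduction of any dataset.
- UTR flanks uniform 20–90 nt of random sequence.
- Fragmentation probability 0.2 per (gene, taxon): the CDS is split into
  2–3 pieces with 30–90 nt overlaps, each piece at least 150 nt before
  overlap extension (assemblers do not emit ultrashort contigs; typical
  de novo transcriptome assemblies keep transcripts above 100 bp).
- Redundant alternative transcripts (same CDS, fresh UTRs) with
  probability 0.1; paralogous families carry an extra copy in a random
  taxon subset, evolved 0.15 expected substitutions/site beyond the
  ortholog; contaminants are random-composition sequences of 200–1000 nt.
- The reference protein set is the translated ancestral CDS per family
  plus 25 random decoy proteins, standing in for an annotated outgroup
  peptide database.

What the generator does **not** emulate: indel evolution (alignment is
still exercised through UTRs, fragmentation, and trimming), read-level
sequencing error, expression variation, chimeric misassemblies, and
codon-usage or compositional bias. Passing tests therefore demonstrate
the pipeline's logic and numerics, not robustness to alignment-hard real
data.

## Translated search

The search is a deterministic stand-in for tblastn at desk scale: exact
amino-acid 4-mer seeds against all six frames; every seeded
(protein, frame) pair is screened by the best ungapped segment score along
its seed diagonals (Kadane on the BLOSUM62 diagonal profile, threshold 40
raw — single seeds are admitted because short divergent fragments that
legitimately score ≥ 40 bits often carry only one exact 4-mer; production
BLAST reaches these through neighborhood words, which we do not
implement); survivors are aligned with an affine-gap local aligner
(BLOSUM62; a gap of length k costs 11 + k). Raw scores map to bits with
the gapped-BLOSUM62 Karlin–Altschul constants λ = 0.267, K = 0.041, and
E-value cutoffs of external searches translate to bit cutoffs through the
search-space size, which keeps filtering independent of database size.
The default floor is 40 bits. An exact affine Smith–Waterman with a fixed
tie-break (diagonal, then up, then left) serves as the test oracle; the
production path uses Biopython's C pairwise aligner under the same scoring
scheme, so optimal scores agree between routes by construction.

## Screens and their boundary semantics

Rule order in the strict screen: presence in all 8 taxa → region length →
paralogy → reading-frame excess → gap fraction; completeness is a ranking
preference at the 300-gene cap (complete-both-ends first, then longer
region, then gene id — the tie-break at the cap is genuinely open and
this ranking is our stand-in). Boundaries are strict: the sub-300-bp
region rule discards 299 nt and keeps 300; the 5%-gap rule discards a gap
fraction of 0.051 and keeps 0.050; the EST screen's 200-bp overlap floor
discards 199. Paralogy — defined in such screens only qualitatively, as
multiple divergent transcripts from one taxon over one region — is
quantified here as coding-overlap identity below 0.98 over at
least 100 nt, computed by edit distance over the reference-projected
overlap; transcripts identical over the overlap are redundant alternative
transcripts, and one is chosen uniformly under the run seed.
A conspicuously extended reading frame is quantified as a stop-to-stop ORF
exceeding 1.5× the reference protein length. All three quantifications are
config-exposed. Every decision lands in a TSV audit log — the reproducible
equivalent of hand-auditing matrices in a spreadsheet.

## Super-transcripts and alignment

Fragment placement is an exact seeded ungapped-diagonal placement on the
reference protein (fragments are colinear with the reference; a gapped
local aligner occasionally introduced a spurious gap and misplaced an
overlap by one codon, which the diagonal method cannot do). Overlapping
fragments must agree exactly over the overlap or the merge fails;
reference-implied gaps between adjacent fragments are filled with `?`
(missing), never `-` (gap) — how such inter-fragment gaps should be
represented in matrices is genuinely open, and `?` is the conservative
choice. Gene alignment is reference-anchored rather than progressive:
each row's conceptual translation is globally aligned to the reference
peptide (BLOSUM62, gap open:extend 12:3, free end gaps) and rows are
merged on reference coordinates, with insertion columns padded to the
maximum per position. Every candidate reaches this stage only by matching
the reference, so the anchor always exists; the construction is
deterministic and back-threads onto nucleotides so every gap is a whole
codon. For indel-free synthetic data it coincides with a progressive MSA.
Trimming cuts columns before the majority-consensus ATG column and after
the first consensus stop column; genes without a start column are flagged
partial; rows missing data inside the window are padded with `?`.

## Rates and informativeness

Per-gene rate is summarized as the unweighted mean p-distance over row
pairs with pairwise deletion. Binning sorts descending and splits into
contiguous equal bins (remainder to the slowest; ties by gene id).
Per-site rates are per-column ML on the chronogram under the n-state
symmetric model (n = 4 nucleotide, n = 20 amino acid), by pruning
likelihood, bounded to [0, 20/root-age]; invariant columns are exactly 0;
optimization is a 64-point grid plus 60 vectorized golden-section
iterations per column, which matches a 2000-point dense-grid oracle to
1e-3. The 2:1 transition:transversion variant of the emulated site-rate
step is noted as a config extension point, not implemented. The
informativeness of a site is ρ(t; λ) = 16 λ² t e^(−4λt) (the closed-form
peak t* = 1/(4λ) anchors the tests); net PI sums sites, per-site PI
divides by alignment length, and profiles are integrated by trapezoid on a
T/1000 grid (errors are second order; the grid is our choice).
Columns whose rate is unavailable are excluded from sums but counted in
the per-site normalization. Net profiles of real multi-rate genes peak
early because high-rate sites contribute peaks ∝ λ; this is a property of
the measure, not an estimator defect.

## Tree inference

JC correction d = −¾ ln(1 − 4p/3) with saturation (p ≥ 0.75) flagged and
clamped to a configured ceiling (default 5.0). Neighbor joining breaks
Q-matrix ties by the lexicographically smallest cluster pair and clamps
negative branch lengths to zero, moving the deficit to the sister edge so
path lengths are preserved. Bootstrap resampling draws multinomial column
weights (codon-triple mode preserves codon phase but plain column
resampling is the default, matching standard practice); support is the
percentage of replicates containing each full-data split. Distances per
replicate are computed from precomputed per-pair difference/comparability
indicator vectors by one matrix–vector product, so 500 replicates on a
250 kb matrix take seconds.

## Problem sizes

Tests and the acceptance script run the full default conditions: the
recovery study uses the complete 330-family batch end-to-end; topology
recovery uses truth-derived supermatrices (the family coding sequences are
colinear by construction, so no search is needed to build a known-answer
matrix) across 10 seeds at 500 replicates; binning fidelity uses 5 seeds
of 300 genes; estimator/oracle agreement uses 50 columns and 50 randomized
search pairs.

## Known limitations

- No indel evolution in the generator, hence no stress on the aligner's
  gap placement beyond constructed unit cases.
- The seeded search has no composition-based statistics or low-complexity
  masking; decoy/contaminant rejection relies on seed + ungapped + bit
  thresholds alone.
- The bit-score/E-value mapping assumes the gapped-BLOSUM62 constants for
  all gap settings.
- Per-site rate ML on 8 taxa is noisy; profiles built from estimated rates
  have heavy right-tail sites dominating early peaks (see above).
- The NJ + bootstrap stage is a topology-recovery stand-in, not a
  replacement for ML/Bayesian inference; matrices and partition files are
  exported for external engines.
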