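# Methods

This note documents the models, conventions and design choices behind
`pepgood`, in the spirit of a methods appendix: what each component
assumes, which knobs matter, and what the synthetic benchmarks do and do
not establish.

## Peptide representation and monomer chemistry

Peptides are carried as records with a one-letter sequence (standard
peptides), a SMILES string (modified peptides), or both. Sequences are
rendered to SMILES by condensing per-residue fragments (each fragment runs
backbone N → Cα → carbonyl C, so string concatenation forms the amide
bonds); termini are a free amine and free acid. The 20 canonical
fragments reproduce the reference linear-peptide SMILES produced by
RDKit's own residue builder, including Ile/Thr side-chain
stereochemistry — this equivalence is pinned by tests.

The reverse mapping ("computationally breaking the peptide bonds")
locates backbone units with the SMARTS pattern `[NX3][CX4][CX3](=[OX1])`,
links units whose carbonyl carbon bonds the next unit's nitrogen, and
takes the longest such chain as the backbone. Side-chain amides (Asn,
Gln, acylated side chains) do not match the unit pattern and are never
broken. Each released monomer is capped to its free amino acid
(N-side cut → H, C-side cut → OH) and identified by canonical-SMILES
lookup:

* canonical monomer → its own letter (a stereo-free monomer SMILES is
  accepted for achiral inputs);
* non-canonical monomer → `X` (mode `x`) or its natural-analog letter
  from the monomer table (mode `analog`, falling back to `X`).

The shipped table (`data/monomer_analogs.csv`) holds the 20 canonical
monomers and 14 common modifications (N-methylations, D-configurations,
side-chain acylation, backbone analogs). It is a compact, editable
stand-in for a full monomer library; entries are keyed on canonical
SMILES, so users may append rows freely. Deterministic tie-breaks:
equal-length backbone chains prefer the smaller carbonyl atom index, and
cyclic backbones are opened at the amide whose carbonyl has the smallest
canonical index.

## Fingerprints

ECFP follows the standard diameter naming (ECFP-16 = radius 8), hashed
to 2048 bits by default; counted fingerprints carry per-bit
multiplicities and are compared with generalized (min/max) Jaccard.
Hash collisions from folding are accepted, as is standard.

The MinHashed atom-pair fingerprint builds, for every heavy-atom pair and
every radius r ≤ diameter/2, the shingle `A|d|B` where A, B are the
canonical chirality-aware SMILES of the two atoms' circular environments
(lexicographically ordered, so the pair is orientation-free) and d the
topological distance. Signatures are the component-wise minima of
universal-hash permutations `(a·x + b) mod p` with p the smallest prime
above 2³², seeded by a fixed package constant so signatures are identical
across runs and machines. Signature agreement is an unbiased estimator
of shingle-set Jaccard with standard error ≈ √(J(1−J)/n_perm); at the
default n_perm = 2048 the mean absolute error measured against exact
shingle Jaccard on random peptide pairs is ~0.006. The exact variant
constants of published MinHash atom-pair schemes are not reproduced;
tests pin this package's scheme against its own exact-Jaccard oracle.

## Alignment similarities

Global similarity is Needleman–Wunsch under BLOSUM62 with affine gaps
(open 10, extend 0.5 — the EMBOSS needle defaults, since only the
implementation family is conventionally fixed), normalized as identical
columns over the full alignment length including gaps. Local similarity
emulates a prefiltered Smith–Waterman: pairs sharing no k-mer (k = 3 by
default, the shortest peptide-meaningful word) score 0 without aligning;
the emulation does not reproduce MMseqs2 internals and says so in its
function-spec metadata. Among co-optimal alignments the aligner's first
is used, which is deterministic.

## Partitioning

The edge rule is similarity ≥ threshold, so the guarantee is strict:
every train–test pair sits strictly below the threshold. Components are
assigned to test in ascending size (ties: smallest member id) until the
test fraction reaches 20%; the largest remaining component is always
reserved for train. Smallest-first maximizes the chance of landing in
the 18.5–20% validity window; descending assignment is available via the
components being exposed for custom policies. The default threshold grid
is 0 to 1 in steps of 0.05, balancing resolution against the quadratic
cost of the sweep; both the grid and the 18.5% floor are configurable.

Dynamic range is reported in two forms, reflecting two conventions in
use: the headline value is the spread max − min of valid thresholds in
percentage points; the count of valid partitions is returned alongside.

Embedding-based similarity accepts a precomputed id → vector table and
converts Euclidean distance to similarity as `1/(1+d)`; computing
embeddings from pretrained language or graph models is outside this
package's scope by design.

## GOOD curves and metrics

Classification is scored with the Matthews correlation coefficient
(zero-denominator convention: 0), regression with SPCC, implemented as
Spearman's rank correlation of predictions against labels (Pearson is
available behind the scoring helper for users who prefer it; the rank
form matches the monotonicity statistic used elsewhere in the package).
Monotonicity is computed per seed as Spearman's ρ between threshold and
metric, and summarized across seeds as mean ± sd; five seeds (0–4) are
the default. Constant metric vectors have undefined correlation and are
reported as 0 with a warning. The default screening model is an SVM on
ECFP-16 features — a cheap, conventional baseline whose curve shape is
representative — and any estimator honouring the train/predict contract
can be substituted.

## Selection rule

δ and ε are interpreted on the 0–1 scale of dynamic range / 100, so
δ₀ = 0.2 means "within 20 percentage points of the best". The Step-2
maximum is computed over the survivors of the monotonicity filter (a
flag restores the global maximum); Step-4 ties break by larger dynamic
range, then name. The implementation is tested for exact agreement with
an exhaustive enumeration of the δ schedule on random candidate tables.

## Comparison statistics and significant ranks

Kruskal–Wallis (tie-corrected, χ² p-value) gates the interpolation
analysis; pairwise one-tailed Wilcoxon signed-rank tests (exact
permutation p for ≤ 25 non-zero differences, tie-corrected normal
approximation beyond) compare representations, at a Bonferroni-corrected
threshold with m = the number of pairwise comparisons actually performed
(12 comparisons → 0.05/12 ≈ 0.004). Extrapolation tables use one-way
ANOVA with Tukey HSD, uncorrected further since Tukey already adjusts for
multiplicity. Rank assignment walks the representations in descending
mean order and compares each to the first member of the current rank —
not its immediate predecessor — opening a new rank on a significant
difference; the procedure is invariant to input order, and pairing is by
experiment unit (dataset × threshold × seed, or dataset × run).

## Negative sampling

Molecular weights are RDKit average weights with implicit hydrogens.
Matching uses 10 quantile bins on the positives' weight distribution —
distribution-free and robust at the dataset sizes involved; bins the pool
cannot fill are topped up with the nearest-weight unused records and the
fallback count is reported. Pool records sharing a sequence or SMILES
with a positive are excluded to prevent leakage. The match guarantee is
conditional on a *well-covered* pool (drawn from the same weight
population as the positives): with 100 positives against a 300-record
same-population pool, the positive/negative KS statistic stays ≤ 0.1 for
100 of 100 sampling seeds. A pool with systematically different weights
can only be matched up to its own support.

## Synthetic benchmarks

The generator emulates small peptide bioactivity datasets: 8 cluster
motifs, per-position mutation rate 0.15, lengths 8–25, n = 300 by
default. The latent score is hydrophobic fraction + a cluster effect
(N(0, 0.5)) + N(0, 0.2) noise; classification thresholds at the median.
These defaults were chosen once to yield a non-trivial dynamic range and
learnable signal at n = 200–500 and are not tuned per experiment.
Modified records substitute 1–2 monomers from the modified library before
SMILES assembly; substitutions are label-neutral, emulating modified
analogs that retain activity. Paired standard/modified benchmarks split
one generated population in half and modify one half record by record, so
both halves share motifs and label rule and differ only chemically.

What passing tests on this data do show: the pipeline's bookkeeping is
sound (no leakage, correct validity accounting), the statistics match
independent oracles, and the framework's central assumption — performance
rising with the similarity threshold — is recovered when the data are
constructed to satisfy it. The assumption is a property of the
generating rule, not of every draw: ECFP monotonicity is typically
0.5–0.9 at n = 300 and positive on average across generator seeds
(asserted by a one-sided test), but an occasional draw can invert the
curve when its held-out clusters happen to sit far from the decision
boundary. What they do not show: anything about
real assay noise, activity-cliff behaviour, class imbalance, or the
relative merits of learned embeddings, none of which the generator
models.

## Experiment protocols and HPO

Interpolation runs the full factorial representation × model × valid
threshold × seed; extrapolation runs 25 subsample-and-retrain rounds at
80% of the standard set, evaluating every round on the complete modified
set. The degenerate control (modified = standard) is compared against an
independently coded random-subsample baseline that evaluates on the
complete dataset under the same convention — a held-out-only baseline
would be structurally lower because the protocol's test set contains the
training records in the degenerate case.

HPO is a seeded serial random search (default budget 20 draws) over
standard SVM and gradient-boosting spaces, scored by 5-fold
cross-validated metric (stratified for classification), with early
stopping after a patience of non-improving draws; deterministic given the
seed. The search strategy is pluggable, so a Bayesian optimizer can be
dropped in where budget allows. With fewer than 5 examples per fold the
search falls back to default hyperparameters with a warning.

The acceptance script's problem sizes (n = 300 main benchmark, n = 150
paired sets, 100 sampling seeds, 100 MinHash pairs, 512 permutations for
the MinHash similarity matrix) are the package's desk-scale defaults,
chosen so a full from-scratch run completes in minutes on one CPU.

## Known limitations

* Backbone detection assumes α-amino-acid units; β-amino acids or
  peptoid-like backbones other than the shipped templates are not
  recognized as backbone monomers.
* The local-alignment emulation is not MMseqs2 (no profile k-mers or
  ungapped prescore); at peptide lengths this matters little, but scores
  are not interchangeable with MMseqs2 output.
* CCPart with smallest-first assignment can overshoot the 20% test
  target when component sizes are coarse; the validity flag, not the
  target, is the contract.
* The count-fingerprint similarity is generalized Jaccard; other count
  similarities (cosine, Dice) are not provided.
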