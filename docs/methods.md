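# Methods

## Problem and model

An EC class is a reaction label, not a sequence family. `ecaudit` treats
the question "is this record plausibly a member of its EC class?" as
evidence-proximity: a record is suspect when it is far, in sequence and in
domain architecture, from every member with experimental evidence. Three
per-record signals are computed:

1. **Maximum identity to the characterised set.** Optimal global alignment
   (Needleman–Wunsch semantics with affine gaps) of the query against the
   top prefilter candidates; identity is `100 · identical non-gap columns /
   all alignment columns`. The denominator deliberately includes gap
   columns: it is the conservative convention, it is applied uniformly, so
   the 25% threshold keeps one meaning across the package. Terminal gaps
   are penalised like internal ones. A record below the threshold
   *strictly* (< 25%) is flagged; identity exactly 25.0 is not below it.
2. **Canonical architecture.** Architectures are compared as multisets of
   domain labels (order disregarded, copy number respected — a duplicated
   domain is a different architecture). The canonical set is whatever
   architectures the characterised members exhibit. Records whose
   architecture is unknown are scored non-canonical but excluded from the
   headline fraction's denominator by default, since missing domain calls
   on partial genes would inflate the estimate; a flag includes them.
3. **Conserved residues** (optional). Catalytic/substrate-binding positions
   are specified as 1-based indices in an ungapped reference; the query is
   globally aligned to the reference and each position checked in the
   aligned column. A position aligned to a gap counts as not conserved
   rather than an error.

## Alignment-free prefilter

All-vs-characterised alignment is avoided with count-based k-tuple
profiles (word size 3; windows containing `X` are skipped) compared by a
set-based Normalised Google Distance, `f(·)` = distinct word counts,
`f(p,q)` = shared distinct words, `N` = corpus-wide distinct words
supplied by the caller. The value is clamped to [0, 1]; no shared words
gives 1 (this produces the identity-0 "no homolog" convention downstream),
identical word sets give 0. The prefilter is validated by rank agreement:
Spearman rho between NGD and alignment dissimilarity on a 50-sequence
identity ladder is ≈ 0.86. NGD saturates at 1 for deeply diverged pairs,
so `top_n` (default 1, mirroring the highest-k-tuple-similarity pairing)
can be raised when the characterised set is large and diverse;
`top_n = |characterised|` provably equals the exhaustive maximum and is
what the oracle tests assert.

## Clustering

Two routes, both deterministic:

- **MCL** on a similarity graph. When no BLAST tabular file is supplied,
  the graph is built from all-vs-all alignment identities, keeping only
  edges ≥ 30% identity — an all-vs-all BLAST likewise reports no
  significant hit for unrelated pairs, and this sparsity is what lets MCL
  resolve families. The pinned policy: self-loops at each node's maximum
  incident weight (1 for isolated nodes), column-stochastic normalisation,
  expansion (matrix square) alternating with inflation (elementwise power
  1.4, renormalise), entries < 1e-5 pruned, convergence at max change
  < 1e-8 or 100 iterations (warning on non-convergence). Clusters are read
  from attractor rows, overlapping supports merged; representatives are
  the highest-degree members (ties to the lexicographically smallest id).
- **Greedy identity clustering** (CD-HIT-style), default threshold 90%:
  records sorted longest-first (ties by id); each joins the first cluster
  whose representative aligns at ≥ threshold, else founds its own.
  Candidates sharing no word of size 5 are skipped without aligning. True
  alignment identity is used instead of a short-word heuristic identity —
  correctness over speed at desk scale. Characterised members absorbed
  into clusters are restored to the analysis set afterwards, so the
  evidence set is never thinned.

## Representative selection

Per-column Shannon entropy over the 20 amino acids plus the gap symbol
(gaps are informative of cluster substructure) defines the cluster MSA's
total information. A subset of rows explains, at column j, the probability
mass of the symbols it exhibits; the objective is the entropy-weighted
mean coverage. This operationalisation was an open design choice: it is
monotone, submodular, equals 1 on the full set, and reduces to intuitive
cases (an invariant alignment is fully explained by any single sequence).
Greedy selection adds the row with the largest marginal gain (ties to the
lowest row index) until 85% is explained. The first pick is exhaustively
optimal; beyond it greedy carries the usual (1 − 1/e) guarantee only — a
known limitation, the best single sequence can appear in no optimal pair,
so small optimality gaps at fixed panel sizes are possible. Internal MSAs
are built by center-star alignment around the longest sequence (merged
with once-a-gap-always-a-gap); externally supplied aligned FASTA is
accepted as-is and is preferable for deeply divergent clusters.

## Screening and kinetics

- Control subtraction: signal minus the mean no-substrate control;
  negatives retained (clipping would bias replicate statistics).
- `LOD = mean(blanks) + 4 · SD` with the sample (n−1) standard deviation —
  three replicates, unbiased estimator.
- Hit rule: soluble in ≥ 2 expressions AND strictly above the LOD in ≥ 2
  assay replicates; the LOD is the boundary of non-detection, so equality
  is not activity.
- Rates from absorbance slopes via Beer–Lambert using the DCPIP
  extinction coefficient 20.7 mM⁻¹cm⁻¹ (600 nm), path length 1 cm by
  default.
- Michaelis–Menten fits are unweighted nonlinear least squares
  (Levenberg–Marquardt, tolerances 1e-12) initialised at
  `V_max⁰ = max v`, `K_M⁰ = S` nearest the half-maximal velocity, with
  Jacobian-based standard errors; a fitted `K_M` outside `(0, 100·max S)`
  raises a poorly-constrained warning (typical when only saturating
  concentrations were measured). `k_cat = V_max/[E]`,
  efficiency `= k_cat/K_M`. On noiseless data the generator's parameters
  are recovered to < 1e-6 relative error; at 5% multiplicative noise and
  8 concentrations the median `K_M` error over 100 seeds is ≈ 7%.

## Synthetic data: what it emulates and what it does not

The generator plants the structure the audit assumes: one canonical
family whose first members are characterised and share a canonical
architecture, plus unrelated families with pairwise-distinct architectures
whose roots are rejection-sampled to < 30% mutual alignment identity.
Defaults: 60 canonical (5 characterised) + 20 + 20 outliers, root length
350 (inside the 200–580 length filter), within-family identity drawn from
0.70–0.95, per-site indel rate 0.01, superkingdoms drawn 90% Bacteria /
7% Eukaryota / 3% Archaea (the class's observed skew). Mutation is exact:
`⌈(1 − target)·L⌉` positions substituted without replacement, so ungapped
identity is controlled analytically before indels; single-residue indels
follow. Roots use uniform residue frequencies by default; a
BLOSUM-background option gives unrelated-pair identities in the realistic
~15–20% twilight zone. Ground truth (family index, misannotated flag,
superkingdom, architecture) is emitted alongside.

Not emulated: tree-structured evolution (members are independent mutants
of a root, so within-family topology is star-like), domain-level events
(architectures are assigned, not evolved), alignment ambiguity from
low-complexity regions, and annotation noise in the characterised labels
themselves. Passing ground-truth-recovery tests therefore shows the
pipeline arithmetic is right under the planted model, not that real
databases have any particular misannotation rate.

## Numerical and policy choices

- Deduplication keeps the first-seen record; the characterised flag ORs
  across a duplicate group (evidence attaches to the sequence, not the
  accession). Idempotent.
- Filter removal reasons are counted with precedence too_short > too_long
  > ambiguous; kept + removed partitions the input.
- Identity histograms use bins [i, i+1) for i = 0..99 plus a closed [100]
  bin, so exact self-matches are visible apart.
- Prefilter ties are broken by lexicographic subject id; co-optimal
  alignments by the aligner's deterministic traceback.
- All randomness flows from explicit seeds / `numpy` Generators; reruns
  of the pipeline are byte-identical.
- Problem sizes in the test and acceptance runs (100-record reference
  class, 24-record clustering class, 200 oracle pairs, 50 selection
  fixtures, 100 kinetics seeds) are desk-scale choices that keep the whole
  suite under a minute while leaving every planted effect far larger than
  its estimation noise.

## Known limitations

- Greedy selection beyond the first pick is near-optimal, not optimal
  (see above).
- The NGD prefilter with `top_n = 1` can miss the true closest
  characterised sequence when NGD saturates; raise `top_n` for diverse
  evidence sets.
- Center-star MSAs degrade on clusters mixing very divergent members;
  supply an external alignment there.
- The greedy clustering is quadratic in the number of founders; it is
  meant for thousands, not millions, of records.
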