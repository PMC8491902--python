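# ecaudit

Annotation-quality audit for enzyme (EC) classes.

Enzyme Commission numbers group enzymes by the reaction they catalyse, yet
most database entries receive their EC number by automated similarity
transfer, and errors propagate as databases grow. `ecaudit` implements a
desk-scale audit of one EC class at a time: given the class's protein
sequences, the subset with experimental evidence ("characterised"), and
per-sequence domain architectures, it quantifies how far each record sits
from the experimental evidence and flags likely misannotations.

The audit combines:

- **Closest-characterised identity.** For each record, the percent identity
  to the nearest characterised class member,
  `identity = 100 · matches / alignment columns`, from an optimal global
  alignment (BLOSUM62, affine gaps −10/−0.5). An alignment-free prefilter —
  count-based k-tuples (word size 3) compared with a set-based Normalised
  Google Distance `d(p,q) = (max(log f(p), log f(q)) − log f(p,q)) /
  (log N − min(log f(p), log f(q)))` — ranks candidates so only the best
  are aligned. Records below 25% identity (strictly) sit in the twilight
  zone where function transfer is unreliable.
- **Domain-architecture comparison.** Two records share an architecture iff
  their domain-label multisets match, order disregarded. Architectures seen
  among characterised members are "canonical"; the fraction of records with
  known but non-canonical architectures is the headline misannotation
  estimate.
- **Clustering.** Markov clustering (inflation 1.4) of an all-vs-all
  similarity graph resolves the class into families; a greedy 90%-identity
  clustering (word-size-5 prescreen, longest-first) collapses sequencing
  redundancy for database-scale runs, with absorbed characterised members
  restored afterwards.
- **Representative selection.** Per cluster, the Shannon entropy
  `H_j = −Σ_a p_ja log₂ p_ja` of each alignment column (gap included)
  defines the cluster's information; sequences are greedily selected until
  85% of the entropy-weighted symbol mass is explained — a compact,
  information-dense panel for experimental testing.
- **Screen and kinetics processing.** Control subtraction, limit of
  detection `LOD = mean(blanks) + 4·SD`, the 2-of-3 soluble AND 2-of-3
  active hit rule, absorbance-to-rate conversion through the DCPIP
  extinction coefficient (20.7 mM⁻¹cm⁻¹ at 600 nm), Michaelis–Menten
  fitting of `v = V_max·S/(K_M+S)`, and `k_cat/K_M`.
- **Synthetic data.** A generator of EC-class-like datasets with known
  ground truth — one canonical characterised family plus divergent
  "misannotated" families with distinct architectures — so every stage is
  testable without database downloads.

## Worked example

Generate a synthetic class (60-member canonical family with 5
characterised members, plus 40 records in two unrelated families) and
audit it:

```sh
ecaudit simulate --outdir demo --seed 42
ecaudit audit demo/class.fasta \
    --domains demo/domains.tsv \
    --characterised demo/characterised.txt \
    --outdir demo/out
```

prints

```
records=100 fraction_below_threshold=0.400 fraction_non_canonical=0.400 clusters=3
```

Reading: of 100 records, 40% fall below 25% identity to every
characterised member and the same 40% carry a non-canonical architecture —
exactly the planted misannotated fraction — and MCL resolves the class
into its 3 families. `demo/out/` holds `report.json`, `per_record.tsv`
(per-record identity, closest characterised id and flags), `clusters.tsv`,
`selection.tsv` (per-cluster representative panels with explained-information
steps) and `histograms.tsv` (per-superkingdom identity histograms, bin
size 1).

Kinetics from a substrate/velocity table:

```sh
ecaudit kinetics velocities.tsv --enzyme-conc 6.6e-7
```

prints, for data generated at K_M = 4.0·10⁻⁴ M,

```
K_M=4.000e-04 M  k_cat=5.180 /s  k_cat/K_M=1.295e+04 /M/s
```

As a library: `ecaudit.classify(records, characterised_ids)` returns the
per-record flags and class summary; `ecaudit.run_audit(PipelineConfig(...))`
runs the full pipeline.

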