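# Methods

This note documents the models, defaults and design choices behind
`toxtriage`, and what the synthetic-data generators do and do not
emulate.

## Registry and curation

Substances are keyed strictly by CAS-RN. The checksum (weighted digit
sum mod 10) is enforced at registration by default, with a lenient
flag, because every downstream join is CAS-based and a mistyped key
silently orphans annotations. Synonyms merge case-insensitively with
whitespace normalization; two different SMILES under one CAS raise a
conflict carrying both structures rather than overwriting. Substances
without structures are retained and routed to non-QSAR methods; they
are counted, never dropped.

Structure categorization applies a deterministic rule ladder after an
RDKit parse/sanitize attempt (failures are statuses, not exceptions):

1. sanitize failure → the no-sanitizable subcategory chosen by rules
   2–4 on the raw parse;
2. any carbon–metal bond → organometallic (metal = every element
   except H, C, N, O, P, S, Se, halogens, noble gases, B, Si);
3. multiple fragments → salt; organic salt if any fragment has a
   carbon bonded to H or another carbon, else inorganic salt;
4. single fragment: carbon-bearing → organic; a lone metal atom/ion →
   inorganic metal; else inorganic;
5. an organic with ≥ 2 amide backbone repeats
   (`[NX3][CX4][CX3](=O)`) → peptide.

Modelable categories are organic, organic salt (desalted to the
largest carbon-bearing fragment — the conventional choice, since the
counter-ion carries no QSAR signal at this fingerprint resolution) and
peptide. Classification is canonical-form-based and therefore
invariant to SMILES atom ordering. Under rule 4 a single carbon-bearing
fragment is organic regardless of C–H bonding, so CO₂-like species are
filed as organic; the C–H/C–C test applies only to salt fragments.

## Annotation integration

One label per (substance, endpoint) from {YES, NO, Pending,
NoInformation}, resolved by source tier:

1. a positive assertion from CLP, REACH or SVHC → YES;
2. else a positive from a registration dossier or other secondary
   ECHA source → Pending (still in a classification process; this tier
   yields Pending regardless of polarity);
3. else any reference-database assertion → its polarity (YES/NO);
4. else any Pharos assertion → its polarity;
5. else NoInformation.

Within tiers 3–4 positive beats negative — the conservative rule: a
substance that any source flags as hazardous is treated as such. Two
consequences worth stating explicitly: a *negative-only* core-ECHA
annotation set falls through to NoInformation (core regulatory sources
assert hazards, not their absence), and adding a positive core-ECHA
annotation can only move a label toward YES (monotone conservatism).
Integration depends only on the annotation multiset, so it is
order-invariant and idempotent.

The hazard-code → endpoint table is configuration, not code: the
shipped default maps CLP H340/H341 (mutagenicity), H350/H351
(carcinogenicity) and H360/H361/H362 (reproductive toxicity) to the
combined CMR label, Annex XIII flags to PBT/vPvB, endocrine-assessment
entries to ED, and passes bare endpoint tags through. Unknown codes
map to nothing rather than erroring, so new source vocabularies
degrade gracefully.

## Training sets and imbalance

Only YES (1) and NO (0) substances train models; NoInformation
substances form the prediction set. For CMR, Pending defaults to
positive — if a substance *could* be CMR it is treated as CMR. Two
imbalance regimes:

* negatives dominate → **simple oversampling**: each minority record
  duplicated exactly once (the minority class doubles). No synthetic
  interpolation: fingerprint space is binary and sparse, and SMOTE-style
  interpolants are not valid molecules.
* positives dominate → **balanced-subset ensemble**: positives are
  shuffled (seeded) and chunked into subsets of size n_neg, each subset
  holding *all* negatives; short chunks are topped up by resampling
  positives used elsewhere. Every subset is exactly balanced and every
  positive appears in at least one subset. The default subset count is
  ⌈n_pos/n_neg⌉ with a floor of three.

Duplicate canonical structures across CAS are kept (one record per
CAS) and flagged in the dataset note.

## Conformal QSAR

Mondrian (class-conditional) inductive conformal prediction over a
random forest:

* features: 2048-bit hashed topological-path fingerprints (RDKit);
  the same representation serves read-across, so one structure
  encoding covers the pipeline;
* split: 70/30 proper-train/calibration, stratified, seeded;
* nonconformity: 1 − forest probability of the class;
* p-value: rank counting with ties counted as ≥ and +1 smoothing,
  per class;
* prediction set at level *s*: classes with p > 1 − s (strict
  inequality; no worked example sits on the boundary, so the choice is
  recorded here);
* forest defaults: 500 trees, √d features per split, unlimited depth,
  fixed seed. Hyperparameter tuning was deliberately skipped — on
  these fingerprint datasets it buys little, and fixed settings keep
  models comparable across endpoints.

Ensembles majority-vote the members' prediction sets: each member
adds +1 to every class in its set (a both-classes member increments
both counts, an empty one neither); strict majority decides, equality
is uncertain. Reported ensemble p-values are member means — used only
for significance/confidence reporting, never for the class call.

Numerical notes. The p-value tie comparison uses a 1e-12 slack so
that calibration scores survive CSV serialization round-trips with
ties intact. The rank-counting p-value is discrete and
tie-conservative, hence *super-uniform*: its CDF sits at or below the
diagonal. Tests therefore check the validity direction (empirical
exclusion ≤ nominal within Monte-Carlo tolerance) rather than
two-sided uniformity, which this estimator does not and should not
satisfy exactly. Conformal validity is *marginal*: conditioned on one
calibration draw the realized exclusion rate fluctuates with both
calibration and query sample sizes, so per-seed measurements scatter
around the nominal level; definite-prediction accuracy ≥ level is an
empirical regularity here, not a theorem, and also varies by seed.

Metrics: conformal coverage is the definite fraction; sensitivity,
specificity, MCC and conformal accuracy are computed over definite
predictions only and reported as undefined when nothing is definite.

## Read-across

Maximum Tanimoto similarity of each query against the positively
annotated set; strictly above 0.8 ⇒ positive inference. Strict
comparison follows the "higher than the cutoff" reading; ties at the
cutoff are not inferred. Nearest-neighbour ties break by CAS
lexicographic order for reproducibility. Two all-zero fingerprints
score 0.0 by convention (with a warning). Only positive inference is
made; a miss is "none", never NO.

## Accounting and validation selection

Predicted labels merge under a separate provenance and only into
previously NoInformation pairs; integrated labels are immutable.
Reports store integer counts as the source of truth and derive every
percentage on demand; the high-confidence stratum is inclusive
(confidence ≥ 80%), while the read-across cutoff is strict — the
asymmetry mirrors the two conventions' phrasings. For CMR the
YES + Pending stratum is also emitted combined, since summaries of
positive-leaning substances conventionally merge the two.

Validation candidates are ranked by significance first, confidence
second (significance derives from the smaller p-value and dominates
reliability), CAS as the final tie-break; the top *n* and bottom *n*
per predicted class are selected (deduplicated when a class is small).
Experimental outcomes combine by OR for CMR (any positive assay
decides) and AND for PBT (all of persistent, bioaccumulative, toxic
required); a missing outcome yields "incomplete" whenever it could
still change the verdict, and incomplete comparisons are reported as
unconfirmed, not as disagreements.

## Synthetic data

The fixture generators emulate the *statistical* structure of a real
industrial-chemical inventory, not its chemistry:

* registries draw SMILES from a curated template library spanning all
  ten curation categories (default mix ~82% modelable), with
  checksum-correct CAS identifiers and a 5% structureless fraction;
* annotations are sparse (default 84% of pairs unannotated), multi-
  source, and conflicting at a configurable rate; per-endpoint
  prevalences mirror the regimes the pipeline must handle — CMR-like
  (positives ≫ negatives → ensemble partitioning), PBT/vPvB-like (rare
  positives → oversampling), ED-like (almost no negatives →
  read-across). Negative assertions are drawn only from the
  reference-database/Pharos tiers, so at zero conflict rate integration
  recovers the generator's ground truth exactly wherever annotated;
* binary structure datasets encode the class signal as ring
  chlorination (2–4 Cl on a substituted benzene vs none), flipped with
  a configured label-noise probability — an exchangeable setting with
  controlled Bayes error, suitable for checking conformal validity by
  simulation.

Passing tests on these fixtures demonstrates the pipeline's logic and
the conformal guarantees under exchangeability; it does not
demonstrate predictive accuracy on real inventories, whose chemical
diversity, annotation biases and inter-source correlation structure
the templates do not model. Problem sizes in the test suite and the
acceptance script (hundreds of substances, 500-query conformal
checks) were chosen as the smallest at which the binomial tolerances
are meaningful.

## Known limitations

* No tautomer/charge standardization beyond desalting; no
  stereochemistry normalization; mixtures (UVCB) are out of scope.
* The curation ladder is intentionally coarse: a single-fragment
  carbon-bearing species is "organic" even when conventional chemistry
  would not call it that.
* Integration cannot produce NO from core-ECHA sources alone (see
  above); inventories whose negatives live only in regulatory sources
  will under-count NO labels.
* Read-across similarity values depend on the fingerprint dialect;
  other dialects shift similarities and therefore cutoff decisions.
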