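# toxtriage

Confidence-aware *in silico* safety-liability triage for industrial
chemical inventories.

Large inventories of industrial chemicals (textiles, leather, dyes,
polymer intermediates) are mostly uncharacterized: for a typical
registry, the vast majority of (substance, endpoint) hazard annotations
are simply missing. `toxtriage` implements a desk-scale pipeline that

1. **curates** a substance registry keyed by CAS-RN (checksum-validated),
   classifying every structure into ten categories (organic, organic
   salt, peptide, organometallic, inorganic, inorganic salt, inorganic
   metal, and their no-sanitizable variants) and keeping the modelable
   subset;
2. **integrates** multi-source hazard annotations (CLP, REACH, SVHC,
   registration dossiers, a reference database, Pharos) into one label
   per substance and endpoint — **CMR**, **ED**, **PBT**, **vPvB** —
   drawn from {YES, NO, Pending, NoInformation}, with a conservative,
   regulatory-source-first precedence;
3. **fills gaps** in two ways:
   - *conformal QSAR*: Mondrian inductive conformal random forests over
     2048-bit topological-path fingerprints, with class-imbalance
     correction (simple oversampling, or balanced-subset ensembles with
     majority voting when positives dominate);
   - *read-across*: Tanimoto-similarity analogue inference against
     positively annotated structures (cutoff 0.8), for endpoints too
     imbalanced to model;
4. **accounts** for the before/after label changes, stratified by
   prediction confidence, and **selects prospective-validation
   candidates** from the most and least reliable predictions.

## The statistics at the core

For a query *x* and class *c* ∈ {0, 1}, the nonconformity score is
α<sub>c</sub>(x) = 1 − P̂(c | x) under a random forest fitted on a
proper training split. With Mondrian (class-conditional) calibration
scores α<sup>(1)</sup>…α<sup>(n_c)</sup>,

    p_c = ( #{ α^(i) ≥ α_c(x) } + 1 ) / ( n_c + 1 )

At significance level *s*, class *c* enters the prediction set iff
p<sub>c</sub> > 1 − s; a singleton set is a definite call, both-or-
neither is *uncertain*. This guarantees the true class is excluded
from at most a fraction 1 − s of prediction sets, per class, up to
finite-sample fluctuation. Per-prediction reliability is summarized as

    significance = 1 − min(p0, p1)        confidence (%) = 100 · max(p0, p1)

Read-across uses the Tanimoto index T(A, B) = |A∩B| / |A∪B| over
fingerprint bitsets; a query strictly above 0.8 similarity to a
positive analogue inherits a positive inference (never a negative one —
absence of a close positive analogue is not evidence of safety).

## Worked example

```python
from toxtriage import significance_confidence, assign_label

# a published validation-candidate row: p0 = 0.750, p1 = 0.003
sig, conf = significance_confidence(0.750, 0.003)
print(f"label={assign_label(0.750, 0.003, 0.8)}  "
      f"significance={sig:.3f}  confidence={conf:.1f}%")
```

prints

```
label=negative  significance=0.997  confidence=75.0%
```

i.e. at level 0.8 only class 0 survives (p0 = 0.750 > 0.2, p1 = 0.003 ≤
0.2): a definite negative whose smaller p-value leaves 0.003 of doubt
(significance 0.997) and whose larger p-value backs the call with 75%
confidence. A full synthetic-inventory round trip:

```python
from toxtriage import Registry, integrate_all
from toxtriage.registry import load_annotations
from toxtriage.curation import curate_registry
from toxtriage.datasets import extract_training_set, oversample
from toxtriage.conformal import MondrianConformalForest, featurize_many
from toxtriage.accounting import predict_uninformed, account
from toxtriage.fixtures import (FixtureConfig, generate_registry,
                                generate_source_annotations)

cfg = FixtureConfig(n_substances=400, annotation_sparsity=0.55, seed=7,
                    endpoint_prevalence={"CMR": 0.35, "ED": 0.9,
                                         "PBT": 0.3, "vPvB": 0.3})
substances, _ = generate_registry(cfg)
annotations, _ = generate_source_annotations(substances, cfg)
registry = Registry.from_frame(substances)
labels = integrate_all(registry, load_annotations(annotations)).labels
curation = curate_registry(registry)

dataset, _ = extract_training_set(labels, curation, "PBT")
model = MondrianConformalForest(random_state=7).fit(
    featurize_many(oversample(dataset).records["smiles"]),
    oversample(dataset).records["y"])
predictions, failures = predict_uninformed(labels, curation, model,
                                           "PBT", level=0.8)
report = account(labels, predictions)
print(f"uninformed before: {report.before['NoInformation']}, "
      f"filled: {report.n_new} ({report.filled_pct:.2f}%), "
      f"high-confidence: {report.n_highconf_new} "
      f"({report.filled_highconf_pct:.2f}%)")
```

prints

```
uninformed before: 212, filled: 98 (46.23%), high-confidence: 53 (25.00%)
```

— of 212 substances with no PBT information, 98 received a definite
conformal prediction at level 0.8, 53 of them with confidence ≥ 80%.

The same workflow is scriptable from the shell via the `toxtriage`
command (`fixtures`, `curate`, `integrate`, `dataset`, `train`,
`predict`, `rax`, `account`, `select-validation`, `compare`); each
subcommand is a thin wrapper over the functions above.

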