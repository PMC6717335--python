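# acutetox

Consensus (Q)SAR modeling of rat acute oral toxicity (LD50).

The median lethal dose (LD50, mg/kg body weight) drives the regulatory
hazard banding of chemicals. This package implements a complete in-silico
modeling stack for five regulatory endpoints derived from it:

* **LD50 point estimate** — continuous, modeled as log10 of the dose in
  mmol/kg (`log10(LD50 / MW)`);
* **vT** ("very toxic") — binary, positive iff LD50 < 50 mg/kg;
* **nT** ("non-toxic") — binary, positive iff LD50 > 2000 mg/kg;
* **EPA** — the 4-category hazard scheme (I ≤ 50 < II ≤ 500 < III ≤ 5000 < IV);
* **GHS** — the 5-category scheme (I ≤ 5 < II ≤ 50 < III ≤ 300 < IV ≤ 2000 < V).

Around these endpoints it provides, for computational toxicologists and
cheminformaticians:

* **Dataset preparation** — duplicate aggregation after desalting,
  PCA-based structural-outlier flags, and a K-means cluster-stratified
  80/20 internal split over fingerprints + activity (`acutetox.datasets`,
  `acutetox.preprocess`).
* **Similarity machinery** — binary fingerprints (substructure-key,
  Daylight-style path), three structural-key blocks (35 constitutional /
  11 heteroatom / 154 functional-group counts), and the integrated
  similarity index
  `SI = S(FP)^0.4 · S(CD)^0.35 · S(HE)^0.1 · S(FG)^0.15`
  combining a Maxwell–Pilliner fingerprint similarity with three
  Bray–Curtis key similarities (`acutetox.similarity`).
* **Read-across with abstention** — a similarity-thresholded kNN
  (`IstKnnRegressor`) that refuses to predict when no neighbor is similar
  enough, a single neighbor is not similar enough, or the neighbors'
  experimental values disagree too much; with LOO cross-validation and a
  five-parameter grid search (`acutetox.readacross`).
* **Structural-alert mining** — exhaustive fragment enumeration by
  recursive acyclic-bond breakage, likelihood-ratio validation
  (`LR = (tp/n_target)/(fp/n_other)`), greedy ruleset reduction, and
  rule-based classification whose applicability domain is fragment
  presence (`acutetox.alerts`).
* **Tree ensembles** — balanced random forests (per-tree balanced
  bootstrap for imbalanced classes) and plain forests with per-tree
  confidence, a hyperparameter-tuned forest pathway with response-outlier
  flagging, an on-the-fly local-model engine over 20–50 structural
  neighbors, and a forest "error model" predicting per-compound absolute
  error (`acutetox.forests`, `acutetox.localmodels`).
* **Four applicability domains** — Manhattan-distance percentile,
  forest-confidence, predicted-error percentile, and real-vs-dummy
  (mirror-matrix) classification, plus outlier-similarity screening and a
  Pareto-based coverage/performance tuner (`acutetox.domain`).
* **PF/CS consensus** — regression consensus by averaging in-AD member
  predictions with a *prediction fraction* PF, classification consensus by
  majority vote with a *consensus score* CS = agreeing − disagreeing votes
  (ties abstain), reliability thresholds, PF-stratified error reports,
  Cooper statistics, balanced accuracy and the generalized (multiclass)
  Matthews correlation coefficient, with Pareto-front model selection
  (`acutetox.consensus`, `acutetox.metrics`).
* **Synthetic data** — deterministic generators for descriptor matrices,
  clustered fingerprint populations, planted-toxicophore SMILES sets and
  multi-model prediction ledgers, with full ground-truth records
  (`acutetox.synth`).

## Worked example

```python
from acutetox.datasets import ChemicalRecord, derive_endpoints
from acutetox.readacross import IstKnnParams, istknn_predict_from_sims
from acutetox.consensus import integrate_classification, integrate_regression

records = [
    ChemicalRecord("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", ld50_mg_per_kg=192.0),
    ChemicalRecord("aspirin", "CC(=O)Oc1ccccc1C(=O)O", ld50_mg_per_kg=200.0),
    ChemicalRecord("parathion", "CCOP(=S)(OCC)Oc1ccc([N+](=O)[O-])cc1", ld50_mg_per_kg=2.0),
]
print(derive_endpoints(records)[["id", "mw", "log_mmol", "vt", "nt", "epa", "ghs"]]
      .round(3).to_string(index=False))

res = istknn_predict_from_sims(
    sims=[0.91, 0.84, 0.62], values=[-0.52, -0.11, 1.40],
    params=IstKnnParams(k=3, t_sim1=0.75, t_sim2=0.85, enhancement=2, t_minmax=1.5),
    ids=["n1", "n2", "n3"],
)
print(f"read-across: prediction={res.prediction:.4f} reason={res.reason} "
      f"neighbors={[nid for nid, _, _ in res.neighbors]}")

cls = integrate_classification(["positive", "positive", "negative", "positive"],
                               in_ad=[True, True, True, False])
print(f"classification consensus: label={cls.value} CS={cls.cs}")
reg = integrate_regression([-0.42, -0.30, -0.61, 0.95], in_ad=[True, True, True, False])
print(f"regression consensus: value={reg.value:.4f} PF={reg.pf}")
```

prints

```
       id      mw  log_mmol       vt       nt epa ghs
 caffeine 194.194    -0.005 negative negative  II III
  aspirin 180.159     0.045 negative negative  II III
parathion 291.265    -2.163 positive negative   I   I
read-across: prediction=-0.3314 reason=OK neighbors=['n1', 'n2']
classification consensus: label=positive CS=1
regression consensus: value=-0.4433 PF=0.75
```

Parathion's 2 mg/kg puts it in the most toxic band of both category
schemes and in the vT positive class. The read-across call retains the two
neighbors above the similarity threshold 0.75 and returns their
SI²-weighted mean (the third neighbor, SI 0.62, is excluded); had the
retained values spanned ≥ 1.5 log units it would have abstained. The
classification consensus sees three in-AD votes (2 positive, 1 negative):
label positive with consensus score 2 − 1 = 1. The regression consensus
averages the three in-AD values and reports a prediction fraction of 3/4.

A `acutetox` command-line tool mirrors the library: `prepare`, `split`,
`train-istknn`, `mine-alerts`, `predict-alerts`, `integrate`, `evaluate`,
`simulate`.

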