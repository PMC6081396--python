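# lcmds

Predicting drug–drug interactions (DDIs) for **new drugs** — drugs with no
recorded interaction yet — from a drug–drug similarity matrix, using
per-drug **local classification models (LCM)** and a supervised
**Dempster–Shafer evidence fusion** of three member classifiers (LCM-DS).

The package is aimed at computational drug-safety work: given a curated
DDI network over *m* known drugs (a symmetric binary matrix **A**) and
pairwise similarities **S** in [0, 1] (e.g. Jaccard/Tanimoto similarity of
fingerprint or side-effect profiles), it ranks the known drugs a newly
introduced drug *x* is most likely to interact with.

## The model

For each known drug *d<sub>j</sub>*, the drugs interacting with
*d<sub>j</sub>* are labeled positive and the rest negative, and a small
classifier is trained on **S** restricted to the other drugs.  Three
members are implemented, each emitting a decision profile
**y** = [p₊, p₋] with p₊ + p₋ = 1 for the query drug:

- **MLKNN** — a Bayesian posterior over the number of positively labeled
  drugs among the K = 5 most similar neighbors, with smoothed prior
  Pr[y=1] = (1+c)/(M+2);
- **RLS** — regularized least squares on the similarity kernel,
  f(x) = **s**ₓ (**S** + αI)⁻¹ **y**, α = 0.5;
- **SVM** — a C-SVC (C = 1) on the precomputed similarity kernel with
  Platt-calibrated probabilities.

LCM-DS fuses the three profiles.  Per classifier *n* and class *k* it
forms the likelihood

&nbsp;&nbsp;s<sub>k</sub><sup>n</sup> = y(k)·exp(−‖R<sub>k</sub><sup>n</sup> − y‖₂) / Σ<sub>i</sub> y(i)·exp(−‖R<sub>i</sub><sup>n</sup> − y‖₂),

where R<sub>k</sub><sup>n</sup> is the class-k mean training profile
(reference profile).  Treated as simple support functions and combined
under Dempster's rule, this yields the per-classifier evidence
e<sub>k</sub> = s<sub>k</sub>(1−s<sub>j</sub>)/(1−s<sub>k</sub>s<sub>j</sub>),
which is multiplied across classifiers with reference-quality weights
w<sub>k</sub>(n) and normalized over classes.  Classical fusion baselines
(average / product / max / min and decision templates) and the
naive-similarity (NS) and label-propagation (LP) baselines are included,
along with hold-out cross-validation with AUPR, LOOCV degree-bias
analysis, and a factor-ablation harness.

## Worked example

```python
import numpy as np
from lcmds import (SyntheticConfig, generate_synthetic_ddi,
                   HoldoutPlan, holdout_cv_many)

data = generate_synthetic_ddi(SyntheticConfig(seed=11))   # 60 drugs, 4 clusters
plan = HoldoutPlan(ratio=0.25, repetitions=10)
reports = holdout_cv_many(data.interactions, data.similarity, plan,
                          ["svm", "ds", "ns"])
for method, rep in reports.items():
    print(f"{method:4s}  mean AUPR = {rep.mean:.4f}  (sd {rep.std:.4f})")
```

prints

```
svm   mean AUPR = 0.7478  (sd 0.0369)
ds    mean AUPR = 0.7492  (sd 0.0340)
ns    mean AUPR = 0.6410  (sd 0.0463)
```

Each repetition withholds 25% of the drugs with all their interactions,
scores every withheld drug against every training drug, and pools those
pairs into one precision–recall curve.  The planted pair prevalence here
is ≈ 0.33, so all three methods recover substantial signal; the local
classifiers beat the similarity-sum baseline, and the DS fusion matches
or edges out its best member.

The same runs are available from the shell:

```bash
lcmds simulate --seed 11 --out data/
lcmds evaluate-holdout --interactions data/interactions.tsv \
      --similarity data/similarity.tsv --method ds --repetitions 10 \
      --seed 1 --out run/
lcmds evaluate-loocv --synthetic --method ns --out loocv/
```

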