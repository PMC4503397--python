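# nabind

Sequence-based prediction of DNA- and RNA-binding residues in proteins.

Proteins recognise nucleic acids through a small set of interface residues.
When no experimental structure of the complex is available, those residues
must be predicted from sequence alone. `nabind` implements a hybrid
predictor that combines two complementary sources of evidence:

* **A feature-based classifier.** Every residue is described by a sliding
  window (the residue plus five flanking positions on each side) over seven
  descriptor families: the logistic-normalised PSSM row
  f(x) = 1/(1+e^−x); three conservation scores computed from the profile's
  weighted observed percentages — Shannon entropy SE = −Σ p log p, relative
  entropy RE = Σ p log(p/q), and the Jensen–Shannon divergence
  JSD = λ Σ p log(p/c) + (1−λ) Σ q log(q/c) with c = λp + (1−λ)q and
  λ = 0.5; predicted structural descriptors (secondary structure,
  normalised accessibility, dihedrals/180, disorder); five physicochemical
  scales; interface propensity (min–max normalised frequency ratio);
  sequential-position indicators; and chain-global length/composition.
  An RBF-kernel SVM (C = 10, γ = 0.1) with sigmoid-calibrated probability
  output produces the per-residue **Fscore**.
* **A template predictor.** The query is searched against a library of
  labeled chains with a profile-alignment engine that reports a similarity
  probability ("HHscore", 0–100). The top-ranked template transfers its
  annotations: a query residue gets **Tscore** 1 iff it aligns to a binding
  template residue, 0 otherwise.

The final score is the similarity-gated piecewise combination

    Cscore = α·Fscore + (1−α)·Tscore   if HHscore ≥ cutoff
    Cscore = Fscore                    otherwise

with α = 0.6 and cutoff = 85 by default; residues with Cscore ≥ 0.5 are
called binding.

The package also provides the dataset-construction protocol (binding =
any heavy atom within 4.5 Å of a nucleic-acid atom; X-ray chains better
than 3 Å, ≥40 residues, ≥5 binding residues, ≤30% pairwise identity),
chain-level cross-validation, residue- and chain-based evaluation
(recall/precision/F1/ACC/MCC/AUC), paired predictor comparison with a
Shapiro–Wilk-gated t/Wilcoxon test, the non-binder RPP diagnostic with a
Kolmogorov–Smirnov comparison, and a seeded synthetic-data generator so
the whole pipeline runs without external binaries or downloads.

## Worked example

Generate a synthetic study in which the feature evidence marks one half of
each chain's binding residues and exact-copy templates annotate the other
half, then cross-validate the three predictors:

```python
from nabind import FixtureConfig, generate_dataset
from nabind.workflows import run_hybrid_experiment

ds = generate_dataset(FixtureConfig(seed=5, n_chains=50, complementary=True))
exp = run_hybrid_experiment(ds, seed=5)
for name, m in [("feature (F)", exp.feature_metrics),
                ("template (T)", exp.template_metrics),
                ("hybrid (C)", exp.hybrid_metrics)]:
    print(f"{name:<13s} MCC={m.mcc:.3f}  F1={m.f1:.3f}  recall={m.recall:.3f}  "
          f"precision={m.precision:.3f}  AUC={m.auc:.3f}")
```

```
feature (F)   MCC=0.369  F1=0.449  recall=0.581  precision=0.365  AUC=0.760
template (T)  MCC=0.659  F1=0.635  recall=0.466  precision=1.000  AUC=0.733
hybrid (C)    MCC=0.763  F1=0.783  recall=0.707  precision=0.878  AUC=0.982
```

Each component sees only half of the truth — the template arm transfers
its half with perfect precision but capped recall, the feature arm finds
its half with more noise — while the fused predictor recovers both halves
and beats either component on every ranking metric.

The same pipeline is available from the shell:

```sh
nabind make-fixtures --seed 7 --n-chains 20 --out demo/
nabind train --dataset demo/dataset.tsv --pssm-dir demo/pssm \
    --struct-dir demo/struct --regime balanced --out demo/model.bin
nabind predict --model demo/model.bin --dataset demo/library.tsv \
    --query demo/dataset.tsv --pssm-dir demo/pssm --struct-dir demo/struct \
    --out demo/preds.tsv
nabind evaluate --preds demo/preds.tsv --dataset demo/dataset.tsv \
    --level residue --out demo/report.json
```

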