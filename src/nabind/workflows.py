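"""End-to-end experiment orchestration: cross-validated feature scoring,
template search, hybrid combination, and reporting.

These helpers wire the modules together the way the study protocol does:
chain-level cross-validation folds, interface propensity and classifier fit
on training folds only, template transfer from a library, piecewise score
fusion, then residue- and chain-based evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_builder import LabeledChain, make_cv_folds
from .evaluation import (MetricSet, residue_based_evaluation,
                         residue_metrics, chain_based_evaluation)
from .feature_predictor import (SvmConfig, TrainingRegime, build_training_set,
                                predict_fscores, train)
from .features import (FeatureConfig, assemble_vectors, interface_propensity,
                       layout_fingerprint)
from .fixtures import FixtureConfig, SyntheticDataset, generate_dataset
from .hybrid import HybridConfig, PredictionResult, binarize, combine
from .io_formats import SequenceProfile, write_predictions
from .template_predictor import (TemplateLibrary, ToyEngineConfig,
                                 ToyProfileSearchEngine, select_top_template,
                                 transfer_annotations)


def featurize_chains(chains: list[LabeledChain],
                     profiles: dict[str, SequenceProfile],
                     struct_tables: dict,
                     propensity,
                     cfg: FeatureConfig | None = None) -> dict[str, np.ndarray]:
    cfg = cfg or FeatureConfig()
    return {
        c.id: assemble_vectors(c.sequence, profiles[c.id],
                               struct_tables[c.id], propensity, cfg)
        for c in chains
    }


def cross_validated_fscores(ds: SyntheticDataset, k: int = 5, seed: int = 0,
                            regime: TrainingRegime | None = None,
                            svm_cfg: SvmConfig | None = None,
                            feature_cfg: FeatureConfig | None = None
                            ) -> dict[str, np.ndarray]:
    """Out-of-fold feature-predictor scores for every chain.

    Interface propensity and the classifier are fit on the training folds
    only; the test fold is scored with the training-fold propensity table.
    """
    regime = regime or TrainingRegime()
    svm_cfg = svm_cfg or SvmConfig()
    feature_cfg = feature_cfg or FeatureConfig()
    folds = make_cv_folds(ds.chains, k=k, seed=seed)
    by_id = {c.id: c for c in ds.chains}
    fp = layout_fingerprint(feature_cfg)
    out: dict[str, np.ndarray] = {}
    for fold in range(k):
        train_ids, test_ids = folds.split(fold)
        train_chains = [by_id[i] for i in train_ids]
        test_chains = [by_id[i] for i in test_ids]
        prop = interface_propensity(train_chains)
        feats_train = featurize_chains(train_chains, ds.profiles,
                                       ds.struct_tables, prop, feature_cfg)
        feats_test = featurize_chains(test_chains, ds.profiles,
                                      ds.struct_tables, prop, feature_cfg)
        X, y = build_training_set(train_chains, feats_train, regime)
        model = train(X, y, svm_cfg, regime, fingerprint=fp)
        for c in test_chains:
            out[c.id] = predict_fscores(model, feats_test[c.id], fingerprint=fp)
    return out


def template_scores(ds: SyntheticDataset,
                    library: TemplateLibrary | None = None,
                    engine_cfg: ToyEngineConfig | None = None
                    ) -> dict[str, tuple[np.ndarray, float | None]]:
    """Per-chain template transfer: (tscores, hhscore of the top template)."""
    library = library if library is not None else ds.library
    profiles = ds.library_profiles if library is ds.library else {
        tid: e.profile for tid, e in library.entries.items()
        if e.profile is not None
    }
    engine = ToyProfileSearchEngine(profiles, engine_cfg or ToyEngineConfig())
    out = {}
    for chain in ds.chains:
        hits = engine.search(ds.profiles[chain.id], library)
        top = select_top_template(hits)
        tscores, has = transfer_annotations(len(chain.sequence), top, library)
        out[chain.id] = (tscores, top.hhscore if has else None)
    return out


@dataclass
class HybridExperiment:
    """Pooled residue-level outcome of one cross-validated hybrid run."""

    feature_results: list[PredictionResult]
    template_results: list[PredictionResult]
    hybrid_results: list[PredictionResult]
    feature_metrics: MetricSet
    template_metrics: MetricSet
    hybrid_metrics: MetricSet


def run_hybrid_experiment(ds: SyntheticDataset, seed: int = 0, k: int = 5,
                          regime: TrainingRegime | None = None,
                          svm_cfg: SvmConfig | None = None,
                          hybrid_cfg: HybridConfig | None = None,
                          engine_cfg: ToyEngineConfig | None = None
                          ) -> HybridExperiment:
    """Cross-validate the feature arm, run the template arm, fuse, evaluate.

    The template library is the dataset's own fixture library (annotation
    sources are separate template entries, never the query chain itself).
    Component predictors are evaluated through the same calling convention
    as the hybrid (threshold 0.5 on their own scores).
    """
    hybrid_cfg = hybrid_cfg or HybridConfig()
    regime = regime or TrainingRegime(mode="balanced", seed=seed)
    fscores = cross_validated_fscores(ds, k=k, seed=seed, regime=regime,
                                      svm_cfg=svm_cfg)
    tscores = template_scores(ds, engine_cfg=engine_cfg)

    f_res, t_res, h_res = [], [], []
    for chain in ds.chains:
        f = fscores[chain.id]
        t, hh = tscores[chain.id]
        f_res.append(PredictionResult(
            chain_id=chain.id, residues=chain.sequence, fscores=f,
            tscores=None, hhscore_used=None, cscores=f,
            calls=binarize(f, hybrid_cfg.call_threshold)))
        t_res.append(PredictionResult(
            chain_id=chain.id, residues=chain.sequence, fscores=f,
            tscores=t if hh is not None else None,
            hhscore_used=hh, cscores=t,
            calls=binarize(t, hybrid_cfg.call_threshold)))
        h_res.append(combine(chain.id, chain.sequence, f,
                             t if hh is not None else None, hh, hybrid_cfg))

    labels = ds.labels()
    return HybridExperiment(
        feature_results=f_res, template_results=t_res, hybrid_results=h_res,
        feature_metrics=residue_based_evaluation(f_res, labels).metrics,
        template_metrics=residue_based_evaluation(t_res, labels).metrics,
        hybrid_metrics=residue_based_evaluation(h_res, labels).metrics,
    )


def holdout_feature_auc(ds: SyntheticDataset, seed: int = 0,
                        train_fraction: float = 0.5,
                        regime: TrainingRegime | None = None,
                        svm_cfg: SvmConfig | None = None,
                        shuffle_labels: bool = False) -> float:
    """Held-out AUC of the feature predictor on a chain-level split.

    With ``shuffle_labels`` the training labels are permuted within the
    training set (a permutation null: the held-out AUC should sit near 0.5).
    """
    rng = np.random.default_rng(seed)
    regime = regime or TrainingRegime(mode="balanced", seed=seed)
    order = rng.permutation(len(ds.chains))
    n_train = max(1, int(len(ds.chains) * train_fraction))
    train_chains = [ds.chains[i] for i in order[:n_train]]
    test_chains = [ds.chains[i] for i in order[n_train:]]

    if shuffle_labels:
        shuffled = []
        for c in train_chains:
            labels = c.labels.copy()
            rng.shuffle(labels)
            if not labels.any() or labels.all():
                labels = c.labels.copy()
            shuffled.append(LabeledChain(c.id, c.sequence, labels,
                                         c.na_type, c.source))
        train_chains = shuffled

    prop = interface_propensity(train_chains)
    feats_train = featurize_chains(train_chains, ds.profiles, ds.struct_tables, prop)
    feats_test = featurize_chains(test_chains, ds.profiles, ds.struct_tables, prop)
    X, y = build_training_set(train_chains, feats_train, regime)
    model = train(X, y, svm_cfg or SvmConfig(), regime)
    scores = np.concatenate([predict_fscores(model, feats_test[c.id])
                             for c in test_chains])
    truth = np.concatenate([c.labels for c in test_chains])
    from .evaluation import auc
    return auc(scores, truth)


def score_external_chains(train_ds: SyntheticDataset,
                          query_ds: SyntheticDataset, seed: int = 0,
                          regime: TrainingRegime | None = None,
                          svm_cfg: SvmConfig | None = None,
                          hybrid_cfg: HybridConfig | None = None
                          ) -> list[PredictionResult]:
    """Score one dataset's chains with a pipeline trained on another.

    Mirrors the independent-test protocol: propensity, classifier and
    template library all come from the training dataset; queries contribute
    nothing to training.
    """
    regime = regime or TrainingRegime(mode="balanced", seed=seed)
    hybrid_cfg = hybrid_cfg or HybridConfig()
    prop = interface_propensity(train_ds.chains)
    feats_train = featurize_chains(train_ds.chains, train_ds.profiles,
                                   train_ds.struct_tables, prop)
    feats_query = featurize_chains(query_ds.chains, query_ds.profiles,
                                   query_ds.struct_tables, prop)
    X, y = build_training_set(train_ds.chains, feats_train, regime)
    model = train(X, y, svm_cfg or SvmConfig(), regime)
    engine = ToyProfileSearchEngine(train_ds.library_profiles)
    results = []
    for chain in query_ds.chains:
        f = predict_fscores(model, feats_query[chain.id])
        hits = engine.search(query_ds.profiles[chain.id], train_ds.library)
        top = select_top_template(hits)
        t, has = transfer_annotations(len(chain.sequence), top,
                                      train_ds.library)
        results.append(combine(chain.id, chain.sequence, f,
                               t if has else None,
                               top.hhscore if has else None, hybrid_cfg))
    return results


def run_full_pipeline(seed: int, out_dir: str | Path,
                      fixture_cfg: FixtureConfig | None = None,
                      k: int = 5) -> dict:
    """Fixtures -> features -> train -> predict -> evaluate, written to disk.

    Produces ``predictions.tsv`` and ``report.json``; fully determined by
    the seed (used for generation, folds, and every stochastic component).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = fixture_cfg or FixtureConfig(seed=seed, n_chains=12,
                                       length_range=(50, 70))
    ds = generate_dataset(cfg)
    exp = run_hybrid_experiment(ds, seed=seed, k=min(k, len(ds.chains)))
    write_predictions(exp.hybrid_results, out_dir / "predictions.tsv")
    labels = ds.labels()
    report = {
        "seed": seed,
        "n_chains": len(ds.chains),
        "residue_level": {
            "feature": exp.feature_metrics.as_dict(),
            "template": exp.template_metrics.as_dict(),
            "hybrid": exp.hybrid_metrics.as_dict(),
        },
        "chain_level": chain_based_evaluation(exp.hybrid_results, labels).as_dict(),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
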