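"""Benchmark studies on synthetic antigen sets.

Two entry points:

* :func:`recovery_study` - the parameter-recovery benchmark: generate
  independent synthetic antigen sets (one per seed), run the full patch
  pipeline, train the three classifiers and measure held-out F1 and
  whether the planted flexibility feature (``F_patch_max``) is
  recovered among the top MDI features.

* :func:`full_study` - one seed end to end, additionally exercising
  redundancy reduction, the KNN baseline and eplet-level scoring of
  unconfirmed eplets against the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import Label, cluster_sequences, make_splits, reduce_redundancy
from .descriptors import FEATURE_NAMES
from .learner import (
    ALGORITHMS,
    TrainedModel,
    evaluate,
    knn_baseline,
    mdi_importance,
    predict_many,
    train_final,
)
from .pipeline import (
    AntigenResult,
    PipelineParams,
    features_matrix,
    label_antigen,
    process_antigen,
)
from .scoring import report_to_frame, score_report
from .synthetic import SynthConfig, SyntheticBundle, generate_antigen_set

#: representative hyperparameters of the shipped model family: a pruned
#: CART tree (no leaf below 3 samples), 500 extra trees, 1000 boosted trees
DEFAULT_PARAMS = {
    "DT": {"min_samples_leaf": 3},
    "ET": {"n_estimators": 500},
    "GT": {"n_estimators": 1000},
}


@dataclass
class LabeledBundle:
    bundle: SyntheticBundle
    results: dict[str, AntigenResult]
    labeled: list  # LabeledPatch, all labels
    X: np.ndarray
    y: np.ndarray


def build_labeled_dataset(
    bundle: SyntheticBundle, params: PipelineParams | None = None
) -> LabeledBundle:
    """Run the patch pipeline and label every patch of a synthetic bundle."""
    params = params or PipelineParams()
    conserved_by_locus = {
        locus: _conserved(bundle, locus)
        for locus in sorted(set(bundle.antigen_locus.values()))
    }
    results: dict[str, AntigenResult] = {}
    labeled = []
    for ens in bundle.ensembles:
        res = process_antigen(ens, params)
        results[ens.antigen_id] = res
        conserved = conserved_by_locus[bundle.antigen_locus[ens.antigen_id]]
        labeled.extend(label_antigen(res, bundle.registry, conserved))
    X, y = features_matrix(labeled)
    return LabeledBundle(bundle, results, labeled, X, y)


def _conserved(bundle: SyntheticBundle, locus: int) -> set[tuple[str, int]]:
    from .dataset import conserved_positions

    return conserved_positions(bundle.locus_alleles(locus))


def recovery_study(
    seeds=range(10),
    cfg: SynthConfig | None = None,
    test_fraction: float = 0.10,
    algorithms=ALGORITHMS,
) -> dict:
    """Planted-signal recovery across seeds.

    For each seed a fresh antigen set is generated and processed; the
    labeled patches are split 90/10 (stratified), each algorithm is
    trained on the training part and scored on the held-out part, and a
    model trained on all labeled patches provides MDI importances.  The
    returned dictionary reports per-algorithm mean/per-seed F1 and, for
    the decision tree, in how many seeds the planted ``F_patch_max``
    feature ranks in the MDI top 3.
    """
    cfg = cfg or SynthConfig()
    f1s: dict[str, list[float]] = {a: [] for a in algorithms}
    top3_hits = {a: 0 for a in algorithms}
    fmax_idx = FEATURE_NAMES.index("F_patch_max")
    n_samples = []
    for seed in seeds:
        seed = int(seed)
        lb = build_labeled_dataset(generate_antigen_set(replace(cfg, seed=seed)))
        n_samples.append(len(lb.y))
        plan = make_splits(lb.y, n_splits=1, test_fraction=test_fraction,
                           seeds=[seed])
        train_idx, test_idx = plan.pairs[0]
        for algo in algorithms:
            model = train_final(lb.X[train_idx], lb.y[train_idx], algo,
                                DEFAULT_PARAMS[algo], seed=seed)
            f1s[algo].append(evaluate(model, lb.X[test_idx], lb.y[test_idx])["f1"])
            full = train_final(lb.X, lb.y, algo, DEFAULT_PARAMS[algo], seed=seed)
            imp, _ = mdi_importance(full)
            if fmax_idx in np.argsort(imp)[::-1][:3]:
                top3_hits[algo] += 1
    n_seeds = len(list(seeds))
    return {
        "seeds": [int(s) for s in seeds],
        "n_samples_mean": float(np.mean(n_samples)),
        "f1": {a: float(np.mean(v)) for a, v in f1s.items()},
        "f1_per_seed": {a: [float(x) for x in v] for a, v in f1s.items()},
        "fmax_top3_hits": top3_hits,
        "n_seeds": n_seeds,
    }


def full_study(seed: int = 0, cfg: SynthConfig | None = None) -> dict:
    """One end-to-end run: counts, NRd reduction, models, KNN, eplet scores."""
    cfg = replace(cfg or SynthConfig(), seed=int(seed))
    lb = build_labeled_dataset(generate_antigen_set(cfg))
    labels = [lp.label for lp in lb.labeled]
    counts = {
        "patches_total": len(lb.labeled),
        "epitope": sum(1 for l in labels if l is Label.EPITOPE),
        "nonepitope": sum(1 for l in labels if l is Label.NONEPITOPE),
        "ineligible": sum(1 for l in labels if l is Label.INELIGIBLE),
    }

    clusters = cluster_sequences(lb.bundle.polymorphic_chain_sequences())
    nrd = reduce_redundancy(clusters, lb.labeled)
    nrd_counts = {
        "clusters": clusters.n_clusters,
        "nrd_epitope": sum(1 for lp in nrd if lp.label is Label.EPITOPE),
        "nrd_nonepitope": sum(1 for lp in nrd if lp.label is Label.NONEPITOPE),
    }

    plan = make_splits(lb.y, n_splits=10, test_fraction=0.10,
                       seeds=[int(seed) + k for k in range(10)])
    models: dict[str, TrainedModel] = {}
    test_f1 = {}
    for algo in ALGORITHMS:
        per_split = []
        for train_idx, test_idx in plan.pairs:
            m = train_final(lb.X[train_idx], lb.y[train_idx], algo,
                            DEFAULT_PARAMS[algo], seed=int(seed))
            per_split.append(evaluate(m, lb.X[test_idx], lb.y[test_idx])["f1"])
        test_f1[algo] = float(np.mean(per_split))
        models[algo] = train_final(lb.X, lb.y, algo, DEFAULT_PARAMS[algo],
                                   seed=int(seed))

    knn = knn_baseline(lb.X, lb.y, plan, k=3)
    eplet_report, eplet_accuracy = score_unconfirmed(lb, models)

    return {
        "counts": counts,
        "nrd": nrd_counts,
        "test_f1": test_f1,
        "knn_cv_f1": knn.train_f1,
        "knn_test_f1": knn.test_f1,
        "eplet_report": eplet_report,
        "eplet_confirmation_accuracy": eplet_accuracy,
    }


def score_unconfirmed(lb: LabeledBundle, models: dict[str, TrainedModel]):
    """Score unconfirmed eplets with each model and compare to ground truth.

    Returns the report table and the per-model fraction of unconfirmed
    eplets whose confirmation call matches the generator's planted
    truth (accessible eplets only).
    """
    from .trajectory import ResidueId

    unconfirmed = [ep for ep in lb.bundle.eplets if not ep.verified]
    patch_scores: dict[str, dict] = {m: {} for m in models}
    for ep in unconfirmed:
        for aid in ep.carriers:
            res = lb.results[aid]
            for pos, aa in ep.residues:
                # carrier sequences hold the eplet residue at this position
                rid = ResidueId(aid, ep.chain, pos, aa)
                dv = res.descriptors.get(rid)
                if dv is None:
                    continue  # residue not solvent-accessible on this antigen
                for mname, model in models.items():
                    score = float(predict_many(model, dv.as_array()[None, :])[0])
                    (patch_scores[mname]
                     .setdefault(ep.name, {})
                     .setdefault(aid, {}))[(ep.chain, pos)] = score

    records = [lb.bundle.registry.record(ep.name) for ep in unconfirmed]
    frames = {}
    accuracy = {}
    truth = {ep.name: ep.true_epitope for ep in unconfirmed}
    results_by_model = {}
    for mname in models:
        results, excluded = score_report(records, {mname: patch_scores[mname]})
        results_by_model[mname] = (results, excluded)
        hits = sum(
            1 for r in results if r.confirmed[mname] == truth[r.eplet.name]
        )
        accuracy[mname] = hits / len(results) if results else float("nan")
    # combined table over models
    all_scores = {m: patch_scores[m] for m in models}
    results, excluded = score_report(records, all_scores)
    frame = report_to_frame(results, excluded)
    return frame, accuracy
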