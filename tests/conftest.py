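"""Shared fixtures: the desk-scale synthetic cohort and MIL experiment.

The cohort (40 samples per class, 1024×1024 slides, texture-separated
classes) and the three-split training experiment are session-scoped because
they are by far the most expensive artifacts; several tests interrogate the
same trained model.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from hypomil.mil import HypoxiaMILClassifier
from hypomil.preprocess import add_tissue_fractions, filter_tiles, tile_slide
from hypomil.stratify import BuffaScorer, stratify_cohort
from hypomil.synthetic import (SynthConfig, generate_expression,
                               generate_slides)

COHORT_SEED = 11
DEMO_SCHEDULE = dict(lr=0.01, epochs=15, bag_size=20)


@pytest.fixture(scope="session")
def demo_cohort():
    """Two-class synthetic cohort: filtered tiles, weak labels, splits."""
    cfg = SynthConfig(seed=COHORT_SEED, n_samples_per_class=40)
    slides = generate_slides(cfg)
    expr, truth = generate_expression(cfg)
    scores = BuffaScorer(cfg.signature_genes).fit_transform(expr)
    tiles_by, true_class = {}, {}
    for rec in slides:
        kept = filter_tiles(add_tissue_fractions(
            tile_slide(rec, cfg.tile_size_px)))
        tiles_by[rec.sample_id] = np.stack([t.pixels for t in kept])
        true_class[rec.sample_id] = rec.true_class
    del slides
    y = {s: int(scores.loc[s, "binary_label"] == "hypoxic") for s in tiles_by}
    splits = stratify_cohort(scores, n_splits=3, seed=COHORT_SEED)
    return {"cfg": cfg, "tiles_by": tiles_by, "scores": scores,
            "true_class": true_class, "y": y, "splits": splits}


@pytest.fixture(scope="session")
def mil_experiment(demo_cohort):
    """Three-split training run plus a shuffled-label null on split 0."""
    tiles_by = demo_cohort["tiles_by"]
    y = demo_cohort["y"]
    aurocs, models = [], []
    for k, sp in enumerate(demo_cohort["splits"]):
        model = HypoxiaMILClassifier(random_state=COHORT_SEED * 100 + k,
                                     **DEMO_SCHEDULE)
        model.fit([tiles_by[s] for s in sp["train"]],
                  [y[s] for s in sp["train"]])
        probs = [model.predict_sample(tiles_by[s]) for s in sp["test"]]
        aurocs.append(roc_auc_score([y[s] for s in sp["test"]], probs))
        models.append(model)

    # permutation null, one run per split: cohort labels are permuted as a
    # whole, the model trains on the permuted training labels, and its
    # predictions are scored against the permuted *test* labels — labels
    # that are pure noise with respect to anything learnable, so the AUROC
    # concentrates at chance.  (Scoring against the true labels instead is
    # degenerate here: the null model's decision axis always retains a
    # residual texture component with arbitrary sign, and texture orders
    # the classes perfectly, sending that AUROC toward 0 or 1.)
    rng = np.random.default_rng(99)
    all_ids = sorted(tiles_by)
    null_aurocs = []
    for k, sp in enumerate(demo_cohort["splits"]):
        permuted = dict(zip(all_ids,
                            rng.permutation([y[s] for s in all_ids])))
        null_model = HypoxiaMILClassifier(random_state=4242 + k,
                                          **DEMO_SCHEDULE)
        null_model.fit([tiles_by[s] for s in sp["train"]],
                       [permuted[s] for s in sp["train"]])
        probs = [null_model.predict_sample(tiles_by[s]) for s in sp["test"]]
        null_aurocs.append(
            roc_auc_score([permuted[s] for s in sp["test"]], probs))

    # an attention-pooled model on split 0 for tile-level analyses: its
    # bag feature is a convex combination of tile features, so single-tile
    # (bag-of-one) scoring matches the training feature distribution much
    # better than under max pooling; it gets a longer schedule because
    # per-tile calls need sharper features than bag-level ranking
    att_model = HypoxiaMILClassifier(pooling="attention", random_state=9900,
                                     **{**DEMO_SCHEDULE, "epochs": 30})
    sp0 = demo_cohort["splits"][0]
    att_model.fit([tiles_by[s] for s in sp0["train"]],
                  [y[s] for s in sp0["train"]])

    return {"aurocs": aurocs, "null_aurocs": null_aurocs,
            "auroc_shuffled": float(np.mean(null_aurocs)),
            "model": models[0], "att_model": att_model,
            "cohort": demo_cohort}
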