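"""Random-forest diagnostic classifier over candidate-locus betas.

The training protocol mirrors a repeated random-holdout model selection:

A. draw 80% of cases and 80% of controls (within-class) as a training set,
   holding the remainder out as a test set;
B. fit a random forest on the training betas;
C. score the held-out samples;
D. record the held-out AUC (and sensitivity/specificity at the call
   threshold);
E. repeat for ``n_iterations`` random splits and fix the single model with
   the highest held-out AUC (earliest iteration wins ties).

The fixed model is then applied unchanged to all later cohorts.  A second
stage (:func:`reduce_signature`) shrinks the locus set to a fixed-size
signature by mean variable importance across iterations and re-runs the
protocol on the reduced matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .evaluation import (
    PerformanceReport,
    as_binary_truth,
    auc_rank,
    evaluate_scores,
)
from .io import BetaMatrix, CANCER_GROUPS, SampleSheet

MODEL_FORMAT_VERSION = 1

#: samples with more than this fraction of signature loci missing are
#: flagged unclassifiable instead of being called
MAX_MISSING_FRACTION = 0.2


class TrainingError(RuntimeError):
    """The training cohort cannot support the protocol."""


@dataclass
class TrainedClassifier:
    """A fixed forest over a locus signature, plus training provenance.

    ``train_medians`` are per-locus medians of the training matrix, used to
    impute sporadically missing betas at prediction time.  ``provenance``
    records the protocol parameters, seed, every per-iteration held-out AUC
    and the index of the selected iteration.
    """

    signature_loci: list[str]
    model: RandomForestClassifier
    train_medians: pd.Series
    threshold: float = 0.5
    provenance: dict = field(default_factory=dict)


@dataclass
class ClassificationResult:
    """Per-sample cancer probability and binary call.

    ``call`` is ``cancer_present`` / ``cancer_absent``; samples with too
    many missing signature loci carry ``unclassifiable`` and a NaN
    probability.
    """

    table: pd.DataFrame  # index sample_id; columns probability, call

    @property
    def probabilities(self) -> pd.Series:
        return self.table["probability"]

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]

    def classified(self) -> pd.DataFrame:
        return self.table[self.table["call"] != "unclassifiable"]


def _labels_from_sheet(betas: BetaMatrix, sheet: SampleSheet):
    samples = [s for s in betas.sample_ids if s in sheet.table.index]
    if not samples:
        raise TrainingError("no overlap between beta matrix and sample sheet")
    y = sheet.table.loc[samples, "group"].isin(CANCER_GROUPS).to_numpy()
    return samples, y


def _impute_medians(x: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    medians = x.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])[:5]
        raise TrainingError(f"loci with no observed betas: {bad}")
    return x.fillna(medians), medians


def train_protocol(
    betas: BetaMatrix,
    sheet: SampleSheet,
    loci=None,
    n_iterations: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
    n_estimators: int = 500,
    max_features="sqrt",
    threshold: float = 0.5,
) -> TrainedClassifier:
    """Repeated stratified-holdout forest training with AUC model selection.

    ``loci`` restricts the matrix to a candidate set (default: all loci).
    Only samples present in ``sheet`` are used; cancers are the positive
    class, all other groups negative.  Deterministic for a given seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    locus_ids = list(loci) if loci is not None else betas.locus_ids
    sub = betas.subset_loci(locus_ids)
    samples, y = _labels_from_sheet(sub, sheet)
    x = sub.values[samples].T  # samples x loci
    if y.all() or not y.any():
        raise TrainingError("training requires both classes")
    x, medians = _impute_medians(x)

    rng = np.random.default_rng(seed)
    iter_seeds = rng.integers(0, 2**31 - 1, size=n_iterations)
    pos_idx = np.nonzero(y)[0]
    neg_idx = np.nonzero(~y)[0]
    if len(pos_idx) < 2 or len(neg_idx) < 2:
        raise TrainingError("need >= 2 samples per class for an 80/20 split")

    aucs, sens, specs, importances, models, splits = [], [], [], [], [], []
    x_arr = x.to_numpy()
    for i in range(n_iterations):
        it_rng = np.random.default_rng(iter_seeds[i])
        train_idx, test_idx = _stratified_split(
            pos_idx, neg_idx, train_fraction, it_rng
        )
        model = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features=max_features,
            random_state=int(iter_seeds[i]),
            n_jobs=1,
        )
        model.fit(x_arr[train_idx], y[train_idx])
        pos_col = list(model.classes_).index(True)
        probs = model.predict_proba(x_arr[test_idx])[:, pos_col]
        y_test = y[test_idx]
        aucs.append(auc_rank(probs, y_test))
        calls = probs >= threshold
        rep = evaluate_scores(probs, calls, y_test)
        sens.append(rep.sensitivity)
        specs.append(rep.specificity)
        importances.append(model.feature_importances_)
        models.append(model)
        splits.append((train_idx, test_idx))

    best = int(np.argmax(aucs))  # argmax keeps the earliest tie
    mean_importances = pd.Series(
        np.mean(importances, axis=0), index=locus_ids, name="mean_importance"
    )
    provenance = {
        "n_iterations": n_iterations,
        "train_fraction": train_fraction,
        "seed": int(seed),
        "n_estimators": n_estimators,
        "max_features": max_features,
        "aucs": [float(a) for a in aucs],
        "holdout_sensitivities": sens,
        "holdout_specificities": specs,
        "selected_iteration": best,
        "mean_importances": mean_importances,
        "training_samples": [samples[j] for j in splits[best][0]],
        "test_samples": [samples[j] for j in splits[best][1]],
        "n_cases": int(y.sum()),
        "n_controls": int((~y).sum()),
        "stage": "full",
    }
    return TrainedClassifier(
        signature_loci=locus_ids,
        model=models[best],
        train_medians=medians,
        threshold=threshold,
        provenance=provenance,
    )


def _stratified_split(pos_idx, neg_idx, train_fraction, rng, max_retries: int = 10):
    """80/20-style split drawn within each class; the test set always holds
    at least one sample of each class."""
    for _ in range(max_retries):
        parts_train, parts_test = [], []
        for idx in (pos_idx, neg_idx):
            perm = rng.permutation(idx)
            n_train = min(int(np.floor(train_fraction * len(idx))), len(idx) - 1)
            n_train = max(n_train, 1)
            parts_train.append(perm[:n_train])
            parts_test.append(perm[n_train:])
        test = np.concatenate(parts_test)
        if len(parts_test[0]) > 0 and len(parts_test[1]) > 0:
            return np.sort(np.concatenate(parts_train)), np.sort(test)
    raise TrainingError("could not draw a two-class test split")


def reduce_signature(
    classifier: TrainedClassifier,
    betas: BetaMatrix,
    sheet: SampleSheet,
    target_size: int = 150,
    seed: int | None = None,
    **train_kwargs,
) -> TrainedClassifier:
    """Shrink the locus set to a fixed-size signature and retrain.

    Loci are ranked by mean forest variable importance across the parent's
    training iterations (mean impurity decrease); the top ``target_size``
    are kept and the full protocol is re-run on the reduced matrix.  The
    reduction mechanism is an implementation assumption and is recorded as
    such in provenance.
    """
    if target_size < 2:
        raise ValueError("target_size must be >= 2")
    importances: pd.Series = classifier.provenance["mean_importances"]
    if target_size > len(importances):
        raise ValueError("target_size exceeds the number of candidate loci")
    order = importances.sort_values(ascending=False, kind="stable")
    top = list(order.index[:target_size])
    if seed is None:
        seed = classifier.provenance.get("seed", 0) + 1
    kwargs = {
        "n_iterations": classifier.provenance["n_iterations"],
        "train_fraction": classifier.provenance["train_fraction"],
        "n_estimators": classifier.provenance["n_estimators"],
        "max_features": classifier.provenance["max_features"],
        "threshold": classifier.threshold,
    }
    kwargs.update(train_kwargs)
    reduced = train_protocol(betas, sheet, loci=top, seed=seed, **kwargs)
    reduced.provenance["stage"] = "reduced"
    reduced.provenance["reduction"] = {
        "method": "mean variable importance ranking (assumed, not prescribed)",
        "target_size": target_size,
        "parent_seed": classifier.provenance.get("seed"),
        "parent_aucs": classifier.provenance.get("aucs"),
    }
    return reduced


def predict(classifier: TrainedClassifier, betas) -> ClassificationResult:
    """Score samples with the fixed model.

    ``betas`` may be a :class:`BetaMatrix`, a loci x samples DataFrame, or a
    per-locus Series for a single sample (e.g. from a sequencing call set).
    Missing signature loci are imputed with the training-cohort median when
    at most 20% are missing; beyond that the sample is flagged
    ``unclassifiable``.
    """
    if isinstance(betas, BetaMatrix):
        frame = betas.values
    elif isinstance(betas, pd.Series):
        frame = betas.to_frame(name=betas.name or "sample")
    else:
        frame = pd.DataFrame(betas)
    x = frame.reindex(classifier.signature_loci)
    missing_frac = x.isna().mean(axis=0)
    pos_col = list(classifier.model.classes_).index(True)

    rows = {}
    ok = missing_frac.index[missing_frac <= MAX_MISSING_FRACTION]
    if len(ok):
        filled = x[ok].apply(lambda col: col.fillna(classifier.train_medians))
        probs = classifier.model.predict_proba(filled.T.to_numpy())[:, pos_col]
        for s, p in zip(ok, probs):
            call = "cancer_present" if p >= classifier.threshold else "cancer_absent"
            rows[s] = (float(p), call)
    for s in missing_frac.index[missing_frac > MAX_MISSING_FRACTION]:
        rows[s] = (np.nan, "unclassifiable")
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["probability", "call"])
    return ClassificationResult(table.loc[list(frame.columns)])


def evaluate(result: ClassificationResult, truth) -> PerformanceReport:
    """Score a classification against reference-standard labels.

    Every called sample must have a truth label; unclassifiable samples are
    excluded from the confusion counts and reported separately.
    """
    truth = as_binary_truth(truth)
    missing = set(result.table.index) - set(truth.index)
    if missing:
        raise ValueError(f"samples without truth labels: {sorted(missing)[:5]}")
    classified = result.classified()
    n_unclassifiable = len(result.table) - len(classified)
    t = truth.loc[classified.index].to_numpy()
    calls = (classified["call"] == "cancer_present").to_numpy()
    return evaluate_scores(
        classified["probability"].to_numpy(), calls, t,
        n_unclassifiable=n_unclassifiable,
    )


def save_classifier(classifier: TrainedClassifier, path) -> None:
    """Serialize a classifier as a versioned container."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "signature_loci": classifier.signature_loci,
            "model": classifier.model,
            "train_medians": classifier.train_medians,
            "threshold": classifier.threshold,
            "provenance": classifier.provenance,
        },
        path,
    )


def load_classifier(path) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported classifier container version")
    return TrainedClassifier(
        signature_loci=payload["signature_loci"],
        model=payload["model"],
        train_medians=payload["train_medians"],
        threshold=payload["threshold"],
        provenance=payload["provenance"],
    )
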