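"""Small marker panels (1/3/5/10 loci) benchmarked against the full signature.

A small panel calls a sample positive when *any* member locus exceeds its
per-locus cut-off; cut-offs are derived only from normal-urothelium
training samples (a quantile, by default the maximum, plus an optional
margin).  A logistic regression over the member betas supplies a continuous
score for ROC analysis.  Panels are selected greedily over AUC-ranked
markers, maximising union-call sensitivity subject to a training
false-positive-rate ceiling (default < 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .classifier import TrainedClassifier, evaluate as evaluate_classifier, predict
from .evaluation import (
    auc_rank,
    confusion_metrics,
    evaluate_scores,
)
from .io import BetaMatrix, CANCER_GROUPS, SampleSheet


@dataclass(frozen=True)
class CutoffRule:
    """Per-locus positivity threshold: quantile of normal-urothelium betas
    plus a fixed margin; a locus call is positive iff beta > threshold."""

    quantile: float = 1.0
    margin: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.quantile <= 1.0:
            raise ValueError("quantile must be in (0, 1]")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


def derive_cutoffs(
    betas: BetaMatrix, sheet: SampleSheet, rule: CutoffRule | None = None
) -> pd.Series:
    """Per-locus thresholds from normal-urothelium training samples only."""
    rule = rule or CutoffRule()
    normals = [s for s in sheet.samples_in("normal_urothelium") if s in betas.sample_ids]
    if not normals:
        raise ValueError("no normal-urothelium samples to derive cut-offs from")
    sub = betas.values[normals]
    thresholds = sub.quantile(rule.quantile, axis=1) + rule.margin
    return thresholds.clip(0.0, 1.0).rename("threshold")


def _case_control(betas: BetaMatrix, sheet: SampleSheet):
    samples = [s for s in betas.sample_ids if s in sheet.table.index]
    y = sheet.table.loc[samples, "group"].isin(CANCER_GROUPS).to_numpy()
    return samples, y


def marker_calls(betas: BetaMatrix, cutoffs: pd.Series) -> pd.DataFrame:
    """Boolean loci x samples positivity matrix (beta strictly above cut-off).

    Missing betas never call positive.
    """
    thr = cutoffs.reindex(betas.values.index)
    return betas.values.gt(thr, axis=0).fillna(False)


def rank_single_markers(
    betas: BetaMatrix, sheet: SampleSheet, cutoffs: pd.Series
) -> pd.DataFrame:
    """Rank individual loci as one-marker tests.

    AUC uses the raw beta as score; sensitivity/specificity/NPV/PPV come
    from the cut-off call.  Returns a DataFrame sorted by AUC (descending).
    """
    samples, y = _case_control(betas, sheet)
    sub = betas.values[samples]
    calls = marker_calls(betas.subset_samples(samples), cutoffs)
    rows = []
    for lid in sub.index:
        scores = sub.loc[lid].to_numpy(dtype=float)
        mask = ~np.isnan(scores)
        auc = auc_rank(scores[mask], y[mask]) if mask.any() else None
        rep = confusion_metrics(calls.loc[lid].to_numpy(), y)
        rows.append(
            {
                "locus_id": lid,
                "auc": auc,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "npv": rep.npv,
                "ppv": rep.ppv,
            }
        )
    ranked = pd.DataFrame(rows).set_index("locus_id")
    return ranked.sort_values("auc", ascending=False, kind="stable")


@dataclass
class OligoPanel:
    """A small locus set plus its union cut-off rule and logistic scorer."""

    loci: list[str]
    cutoffs: pd.Series  # thresholds for member loci
    model: LogisticRegression | None
    member_medians: pd.Series
    training_fpr: float
    training_sensitivity: float
    constraint_met: bool

    @property
    def size(self) -> int:
        return len(self.loci)

    def union_calls(self, betas: BetaMatrix) -> pd.Series:
        calls = marker_calls(betas.subset_loci(self.loci), self.cutoffs)
        return calls.any(axis=0)

    def scores(self, betas: BetaMatrix) -> pd.Series:
        x = (
            betas.values.reindex(self.loci)
            .apply(lambda col: col.fillna(self.member_medians))
            .T.to_numpy()
        )
        if self.model is None:
            return pd.Series(x.mean(axis=1), index=betas.sample_ids)
        pos = list(self.model.classes_).index(True)
        return pd.Series(
            self.model.predict_proba(x)[:, pos], index=betas.sample_ids
        )


def _fit_logistic(betas: BetaMatrix, loci, y) -> tuple[LogisticRegression | None, pd.Series]:
    x = betas.values.reindex(loci)
    medians = x.median(axis=1, skipna=True).fillna(0.0)
    x = x.apply(lambda col: col.fillna(medians)).T.to_numpy()
    if len(set(y)) < 2:
        return None, medians
    model = LogisticRegression(max_iter=1000)
    model.fit(x, y)
    return model, medians


def select_top_panels(
    betas: BetaMatrix,
    sheet: SampleSheet,
    cutoffs: pd.Series,
    sizes=(3, 5, 10),
    fpr_max: float = 0.10,
    ranked: pd.DataFrame | None = None,
) -> dict[int, OligoPanel]:
    """Greedy forward selection of the best-performing marker combinations.

    Candidates are considered in AUC-rank order; at each step the marker
    giving the largest union-call sensitivity gain while keeping training
    FPR strictly below ``fpr_max`` is added (ties broken by rank).  When no
    candidate satisfies the ceiling, the lowest-FPR extension is taken and
    the panel is flagged ``constraint_met=False``.  A logistic regression
    over member betas is fitted for probabilistic scoring.
    """
    if ranked is None:
        ranked = rank_single_markers(betas, sheet, cutoffs)
    samples, y = _case_control(betas, sheet)
    sub = betas.subset_samples(samples)
    calls = marker_calls(sub, cutoffs)  # loci x samples boolean
    candidates = list(ranked.index)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())

    panels: dict[int, OligoPanel] = {}
    for size in sorted(sizes):
        members: list[str] = []
        union = np.zeros(len(samples), dtype=bool)
        while len(members) < size:
            best_choice, best_sens, best_fpr = None, -1.0, None
            fallback_choice, fallback_fpr, fallback_sens = None, np.inf, -1.0
            for lid in candidates:
                if lid in members:
                    continue
                u = union | calls.loc[lid].to_numpy()
                sens = (u & y).sum() / n_pos if n_pos else 0.0
                fpr = (u & ~y).sum() / n_neg if n_neg else 0.0
                if fpr < fpr_max and sens > best_sens:
                    best_choice, best_sens, best_fpr = lid, sens, fpr
                if (fpr, -sens) < (fallback_fpr, -fallback_sens):
                    fallback_choice, fallback_fpr, fallback_sens = lid, fpr, sens
            if best_choice is None:
                best_choice = fallback_choice
            members.append(best_choice)
            union |= calls.loc[best_choice].to_numpy()
        fpr = (union & ~y).sum() / n_neg if n_neg else 0.0
        sens = (union & y).sum() / n_pos if n_pos else 0.0
        model, medians = _fit_logistic(sub, members, y)
        panels[size] = OligoPanel(
            loci=members,
            cutoffs=cutoffs.reindex(members),
            model=model,
            member_medians=medians,
            training_fpr=float(fpr),
            training_sensitivity=float(sens),
            constraint_met=bool(fpr < fpr_max),
        )
    return panels


def compare_panels(
    full: TrainedClassifier | None,
    panels: dict[int, OligoPanel] | list[OligoPanel],
    test_betas: BetaMatrix,
    truth,
    single_markers: pd.DataFrame | None = None,
    test_sheet_cutoffs: pd.Series | None = None,
) -> pd.DataFrame:
    """Side-by-side test performance of the full model, small panels and
    (optionally) single markers: Specificity, Sensitivity, NPV, PPV, AUC.

    All models must have been trained without the test data.  Single
    markers are given by a ranked table (from :func:`rank_single_markers`)
    plus per-locus ``test_sheet_cutoffs`` derived on training normals.
    """
    from .evaluation import as_binary_truth

    truth = as_binary_truth(truth)
    rows = []

    def _row(label, report):
        rows.append(
            {
                "model": label,
                "Specificity": report.specificity,
                "Sensitivity": report.sensitivity,
                "NPV": report.npv,
                "PPV": report.ppv,
                "AUC": report.auc,
            }
        )

    if full is not None:
        result = predict(full, test_betas)
        _row("full_panel", evaluate_classifier(result, truth))

    panel_list = list(panels.values()) if isinstance(panels, dict) else list(panels)
    for panel in sorted(panel_list, key=lambda p: -p.size):
        t = truth.reindex(test_betas.sample_ids).to_numpy()
        calls = panel.union_calls(test_betas).to_numpy()
        scores = panel.scores(test_betas).to_numpy()
        _row(f"top_{panel.size}", evaluate_scores(scores, calls, t))

    if single_markers is not None and test_sheet_cutoffs is not None:
        t = truth.reindex(test_betas.sample_ids).to_numpy()
        calls_all = marker_calls(test_betas, test_sheet_cutoffs)
        for lid in single_markers.index:
            scores = test_betas.values.loc[lid].to_numpy(dtype=float)
            mask = ~np.isnan(scores)
            rep = confusion_metrics(calls_all.loc[lid].to_numpy(), t)
            rep.auc = auc_rank(scores[mask], t[mask])
            _row(f"marker_{lid}", rep)

    return pd.DataFrame(rows).set_index("model")
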