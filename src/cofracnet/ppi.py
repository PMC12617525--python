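"""PPI prediction: labeled pairs from a reference catalog, three classifiers
plus their ensemble with fivefold cross-validation, auROC-based score
thresholding, and compartment-plausibility filtering.

Positives are within-complex pairs of the reference catalog restricted to
detected proteins; negatives are sampled cross-complex pairs that are
intra-complex nowhere. Each labeled pair's reported score comes from the CV
fold in which it was held out (no leakage); unlabeled pairs are scored by
models refit on all labeled pairs. The ensemble score is the unweighted mean
of the three model probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FORBIDDEN_PAIRS, ComplexCatalog, ScoredNetwork, canonical_pair
from .similarity import PairFeatureTable

SINGLE_MODELS = ("rf", "glm", "svm")
MODELS = SINGLE_MODELS + ("ensemble",)


@dataclass
class TrainingSet:
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    provenance: dict[tuple[str, str], list[str]]
    negative_ratio: float

    def labels(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.positives + self.negatives,
                                        names=["protein_a", "protein_b"])
        return pd.Series([1] * len(self.positives) + [0] * len(self.negatives),
                         index=idx, name="label")


@dataclass
class ModelCv:
    fold_aurocs: list[float]
    pooled_auroc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    roc_cutoffs: np.ndarray


@dataclass
class CvReport:
    per_model: dict[str, ModelCv]
    k_folds: int
    fold_of_pair: dict[tuple[str, str], int]
    threshold: float | None = None
    threshold_rule: str | None = None

    def as_dict(self) -> dict:
        return {
            "k_folds": self.k_folds,
            "threshold": self.threshold,
            "threshold_rule": self.threshold_rule,
            "models": {
                name: {
                    "fold_aurocs": [round(a, 6) for a in cv.fold_aurocs],
                    "pooled_auroc": round(cv.pooled_auroc, 6),
                }
                for name, cv in self.per_model.items()
            },
        }


def build_training(reference: ComplexCatalog, detected: Iterable[str],
                   negative_ratio: float = 1.0, seed: int = 0) -> TrainingSet:
    """Derive labeled pairs from a reference complex catalog.

    Positives: all unordered intra-complex pairs with both proteins detected.
    Negatives: uniform sample (without replacement, seeded) of detected
    cross-complex pairs that are intra-complex in no reference complex, at
    ``negative_ratio`` negatives per positive.
    """
    detected = set(detected)
    ref_detected = sorted(reference.members() & detected)
    provenance: dict[tuple[str, str], list[str]] = {}
    for cid in sorted(reference.complexes):
        members = sorted(reference.complexes[cid] & detected)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                provenance.setdefault((a, b), []).append(cid)
    positives = sorted(provenance)
    if not positives:
        raise ValueError("reference does not overlap detected proteins")

    intra = set(positives)
    eligible = [
        (a, b)
        for i, a in enumerate(ref_detected)
        for b in ref_detected[i + 1:]
        if (a, b) not in intra
    ]
    n_neg = min(int(round(negative_ratio * len(positives))), len(eligible))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_neg, replace=False)
    negatives = sorted(eligible[i] for i in idx)
    return TrainingSet(positives, negatives, provenance, negative_ratio)


def _make_model(name: str, seed: int):
    if name == "rf":
        return RandomForestClassifier(n_estimators=500, random_state=seed,
                                      n_jobs=1)
    if name == "glm":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000))
    if name == "svm":
        # radial-basis margin classifier with Platt probability calibration
        return make_pipeline(
            StandardScaler(),
            CalibratedClassifierCV(SVC(kernel="rbf", random_state=seed),
                                   ensemble=False))
    raise ValueError(f"unknown model {name!r}; valid: {SINGLE_MODELS}")


def train_and_score(features: PairFeatureTable, training: TrainingSet,
                    models: Sequence[str] = MODELS, k_folds: int = 5,
                    seed: int = 0) -> tuple[pd.DataFrame, CvReport]:
    """Cross-validated training and scoring of all pairs.

    Returns a pair x model score table (columns = requested models) and the
    CV report. Labeled pairs carry their held-out-fold score; all remaining
    pairs in the feature table are scored by models refit on every labeled
    pair. Deterministic given the seed.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    for m in models:
        if m not in MODELS:
            raise ValueError(f"unknown model {m!r}; valid: {MODELS}")
    single = [m for m in SINGLE_MODELS
              if m in models or "ensemble" in models]

    labels = training.labels()
    missing = labels.index.difference(features.table.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} training pairs absent from the feature table "
            f"(e.g. {tuple(missing[0])})")
    x_all = features.table
    x_lab = x_all.loc[labels.index].to_numpy(dtype=float)
    y = labels.to_numpy()

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    cv_scores = {m: np.full(len(y), np.nan) for m in single}
    fold_of = np.full(len(y), -1)
    try:
        splits = list(skf.split(x_lab, y))
    except ValueError as err:
        raise ValueError(
            "stratified folds cannot hold both classes; increase training "
            f"data or reduce k_folds ({err})") from err
    for fold, (tr, te) in enumerate(splits):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                "a CV fold contains a single class; increase training data "
                "or reduce k_folds")
        fold_of[te] = fold
        for m in single:
            clf = _make_model(m, seed)
            clf.fit(x_lab[tr], y[tr])
            cv_scores[m][te] = clf.predict_proba(x_lab[te])[:, 1]

    scores_lab = dict(cv_scores)
    scores_lab["ensemble"] = np.mean([cv_scores[m] for m in SINGLE_MODELS
                                      if m in cv_scores], axis=0)

    per_model: dict[str, ModelCv] = {}
    for m in models:
        s = scores_lab[m]
        folds = [float(roc_auc_score(y[fold_of == f], s[fold_of == f]))
                 for f in range(k_folds)]
        fpr, tpr, cut = roc_curve(y, s)
        per_model[m] = ModelCv(folds, float(roc_auc_score(y, s)),
                               fpr, tpr, np.clip(cut, 0.0, 1.0))

    # refit on all labeled pairs to score the unlabeled remainder
    unlabeled = x_all.index.difference(labels.index)
    full_scores = {m: pd.Series(scores_lab[m], index=labels.index)
                   for m in scores_lab}
    if len(unlabeled):
        x_unlab = x_all.loc[unlabeled].to_numpy(dtype=float)
        preds = {}
        for m in single:
            clf = _make_model(m, seed)
            clf.fit(x_lab, y)
            preds[m] = clf.predict_proba(x_unlab)[:, 1]
        preds["ensemble"] = np.mean([preds[m] for m in single], axis=0)
        for m in full_scores:
            if m in preds:
                full_scores[m] = pd.concat(
                    [full_scores[m], pd.Series(preds[m], index=unlabeled)])

    table = pd.DataFrame({m: full_scores[m] for m in models}
                         ).reindex(x_all.index)
    fold_map = {tuple(p): int(f) for p, f in zip(labels.index, fold_of)}
    report = CvReport(per_model=per_model, k_folds=k_folds,
                      fold_of_pair=fold_map)
    return table, report


def select_threshold(report: CvReport, rule: str = "youden",
                     model: str = "ensemble") -> float:
    """Pick a probability cutoff from pooled CV ROC points.

    Rules: ``youden`` (maximize tpr - fpr, ties toward the higher cutoff),
    ``fixed:<v>`` (the literal value), ``fpr_at:<v>`` (smallest cutoff whose
    fpr stays <= v).
    """
    if rule.startswith("fixed:"):
        return float(rule.split(":", 1)[1])
    if model not in report.per_model:
        raise ValueError(f"no ROC for model {model!r}")
    cv = report.per_model[model]
    if len(cv.roc_cutoffs) == 0:
        raise ValueError("empty ROC")
    if rule == "youden":
        j = cv.roc_tpr - cv.roc_fpr
        # roc_curve cutoffs are descending; first argmax = highest cutoff
        return float(cv.roc_cutoffs[int(np.argmax(j))])
    if rule.startswith("fpr_at:"):
        target = float(rule.split(":", 1)[1])
        ok = np.flatnonzero(cv.roc_fpr <= target)
        if len(ok) == 0:
            raise ValueError(f"no cutoff achieves fpr <= {target}")
        return float(cv.roc_cutoffs[ok[-1]])
    raise ValueError(f"unknown threshold rule {rule!r}")


def network_from_scores(scores: pd.Series, threshold: float,
                        genotype: str = "", extract: str = "") -> ScoredNetwork:
    """Threshold a per-pair score series into a ScoredNetwork."""
    kept = scores[scores >= threshold]
    edges = {canonical_pair(a, b): float(s)
             for (a, b), s in kept.items()}
    return ScoredNetwork(edges, threshold=threshold, genotype=genotype,
                         extract=extract)


@dataclass
class PlausibilityReport:
    removed: list[tuple[str, str, str]] = field(default_factory=list)  # a, b, reason
    flagged_unannotated: list[tuple[str, str]] = field(default_factory=list)


def filter_implausible(network: ScoredNetwork,
                       compartments: Mapping[str, str],
                       forbidden_pairs: Iterable[frozenset[str]] = FORBIDDEN_PAIRS,
                       ) -> tuple[ScoredNetwork, PlausibilityReport]:
    """Drop edges joining biologically implausible subcompartment pairs.

    Edges with an unannotated endpoint pass by default but are flagged in
    the report.
    """
    forbidden = {frozenset(p) for p in forbidden_pairs}
    report = PlausibilityReport()
    kept: dict[tuple[str, str], float] = {}
    for (a, b), s in network.edges.items():
        ca, cb = compartments.get(a), compartments.get(b)
        if ca is None or cb is None:
            report.flagged_unannotated.append((a, b))
            kept[(a, b)] = s
            continue
        pair = frozenset({ca, cb})
        if len(pair) == 2 and pair in forbidden:
            report.removed.append((a, b, "–".join(sorted(pair))))
        else:
            kept[(a, b)] = s
    return (ScoredNetwork(kept, threshold=network.threshold,
                          genotype=network.genotype, extract=network.extract),
            report)
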