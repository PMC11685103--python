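"""Gene-level layer: aggregate site scores and classify interactions.

Each (miRNA, gene) pair is summarized by the maximum site score observed
separately in the 3' UTR and CDS regions (0 when a region has no site);
those two maxima are the only model features of a gradient-boosted
classifier, evaluated with stratified 5-fold cross-validation and refit on
the full data for deployment.

For meta-learner training-set construction, sites of positive interactions
with score > 0.5 are retained and sites of negative interactions with
score < 0.5 are retained (strict inequalities; a score of exactly 0.5 is
dropped from both); interactions left without sites keep zero maxima.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from mretarget.errors import DataError
from mretarget.evaluation import auc_score
from mretarget.site_scanner import CandidateSite

FEATURE_COLUMNS = ("max_utr3_score", "max_cds_score")


@dataclass(frozen=True)
class InteractionFeatures:
    """Per-(miRNA, gene) aggregated site-score features."""

    mirna_id: str
    gene_id: str
    max_utr3_score: float
    max_cds_score: float
    n_utr3_sites: int = 0  # diagnostic only
    n_cds_sites: int = 0   # diagnostic only


def aggregate_mre_scores(
    scored_sites: Sequence[tuple[CandidateSite, float]]
) -> list[InteractionFeatures]:
    """One row per (mirna_id, gene_id) with per-region score maxima.

    Deterministic and permutation-invariant; rows are sorted by
    (mirna_id, gene_id).  A region with no contributing site yields a
    maximum of 0.0 and a count of 0.
    """
    acc: dict[tuple[str, str], dict] = {}
    for site, score in scored_sites:
        if not 0.0 <= score <= 1.0:
            raise DataError(f"site score {score} outside [0, 1]")
        key = (site.mirna_id, site.gene_id)
        entry = acc.setdefault(
            key, {"max_utr3": 0.0, "max_cds": 0.0, "n_utr3": 0, "n_cds": 0}
        )
        if site.region == "UTR3":
            entry["max_utr3"] = max(entry["max_utr3"], score)
            entry["n_utr3"] += 1
        elif site.region == "CDS":
            entry["max_cds"] = max(entry["max_cds"], score)
            entry["n_cds"] += 1
        else:
            raise DataError(f"site with unknown region {site.region!r}")
    return [
        InteractionFeatures(
            mirna_id=mirna,
            gene_id=gene,
            max_utr3_score=entry["max_utr3"],
            max_cds_score=entry["max_cds"],
            n_utr3_sites=entry["n_utr3"],
            n_cds_sites=entry["n_cds"],
        )
        for (mirna, gene), entry in sorted(acc.items())
    ]


def filter_training_sites(
    scored_sites: Sequence[tuple[CandidateSite, float]],
    interaction_labels: Mapping[tuple[str, str], int],
) -> list[tuple[CandidateSite, float]]:
    """Retain sites consistent with their interaction label.

    Positive interactions keep sites with score > 0.5; negative interactions
    keep sites with score < 0.5.  Sites of unlabeled interactions and sites
    scoring exactly 0.5 are dropped.
    """
    kept = []
    for site, score in scored_sites:
        label = interaction_labels.get((site.mirna_id, site.gene_id))
        if label is None:
            continue
        if label == 1 and score > 0.5:
            kept.append((site, score))
        elif label == 0 and score < 0.5:
            kept.append((site, score))
    return kept


def features_frame(features: Sequence[InteractionFeatures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna_id": [f.mirna_id for f in features],
            "gene_id": [f.gene_id for f in features],
            "max_utr3_score": [f.max_utr3_score for f in features],
            "max_cds_score": [f.max_cds_score for f in features],
            "n_utr3_sites": [f.n_utr3_sites for f in features],
            "n_cds_sites": [f.n_cds_sites for f in features],
        }
    )


@dataclass
class TrainedMeta:
    model: GradientBoostingClassifier
    cv_report: pd.DataFrame
    threshold_default: float = 0.5

    @property
    def cv_auc(self) -> float:
        return float(self.cv_report["auc"].mean())


def _feature_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise DataError(f"feature table missing columns {missing}")
        return features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    return np.array(
        [[f.max_utr3_score, f.max_cds_score] for f in features], dtype=float
    )


def train_meta_learner(
    features,
    labels: Sequence[int],
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 3,
    learning_rate: float = 0.1,
    n_folds: int = 5,
) -> TrainedMeta:
    """Fit the gradient-boosted meta-learner on the two max-score features.

    Reports stratified ``n_folds``-fold cross-validated AUC and accuracy,
    then refits on all data for deployment.
    """
    X = _feature_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise DataError(f"{len(X)} feature rows vs {len(y)} labels")
    if len(y) < 20:
        raise DataError(f"need at least 20 interactions to train, got {len(y)}")
    if len(np.unique(y)) < 2:
        raise DataError("meta-learner training requires both classes")

    def make_model():
        return GradientBoostingClassifier(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
            random_state=seed,
        )

    folds = []
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for k, (tr, te) in enumerate(skf.split(X, y), start=1):
        m = make_model().fit(X[tr], y[tr])
        p = m.predict_proba(X[te])[:, 1]
        folds.append(
            {
                "fold": k,
                "auc": auc_score(p, y[te]),
                "accuracy": float(np.mean((p >= 0.5) == y[te])),
                "n": len(te),
            }
        )
    final = make_model().fit(X, y)
    return TrainedMeta(model=final, cv_report=pd.DataFrame(folds))


def score_interactions(meta: TrainedMeta, features) -> np.ndarray:
    """Interaction probability per row, order preserved."""
    X = _feature_matrix(features)
    return meta.model.predict_proba(X)[:, 1]
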