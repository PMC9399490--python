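"""Patient-vs-control classification with boosted trees and network importance.

Features are the unique-edge FC values plus age, sex, AUDIT and FTND.  A
gradient-boosted tree classifier (XGBoost) is evaluated with stratified
5-fold cross-validation and mean held-out AUC-ROC.  Per-feature additive
attributions (TreeSHAP, computed natively by XGBoost) are taken on the
held-out subjects of each fold and pooled, so importances are not inflated
by training-set fit.  Edge importances are finally rolled up to large-scale
networks: each edge feature contributes to every distinct endpoint network,
and a network's importance is the mean absolute attribution over the edges
touching it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .atlas import EdgeIndex, Parcellation

COVARIATE_COLUMNS = ("age", "sex", "audit", "ftnd")

DEFAULT_XGB_PARAMS = {
    "n_estimators": 100,
    "max_depth": 3,
    "learning_rate": 0.1,
    "tree_method": "hist",
    "n_jobs": 1,
    "eval_metric": "logloss",
}

#: small declared grid for the optional inner random search
TUNING_GRID = {
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1, 0.3],
    "n_estimators": [50, 100, 200],
}


def edge_feature_name(i: int, j: int) -> str:
    return f"fc_{i}_{j}"


def parse_edge_feature(name: str) -> Optional[tuple[int, int]]:
    if not name.startswith("fc_"):
        return None
    _, i, j = name.split("_")
    return int(i), int(j)


@dataclass
class FeatureTable:
    """Subjects x (edge features + covariates), with binary labels."""

    X: pd.DataFrame
    y: np.ndarray  # 1 = patient, 0 = control
    subject_ids: list[str]
    edge_columns: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def build_feature_table(
    matrices: Mapping[str, np.ndarray],
    phenotype: pd.DataFrame,
    edge_index: EdgeIndex,
    symmetry_tol: float = 1e-9,
) -> FeatureTable:
    """Assemble the classification table from baseline FC and covariates.

    Subjects are ordered by subject_id, so the table is invariant to the
    row order of the phenotype file.
    """
    pheno = phenotype.sort_values("subject_id").reset_index(drop=True)
    edge_cols = [
        edge_feature_name(i, j)
        for i, j in zip(edge_index.row.tolist(), edge_index.col.tolist())
    ]
    rows, labels, sids = [], [], []
    for _, r in pheno.iterrows():
        sid = str(r["subject_id"])
        if sid not in matrices:
            raise ValueError(f"subject {sid!r} has no baseline FC matrix")
        m = np.asarray(matrices[sid], dtype=float)
        if m.shape != (edge_index.n_regions, edge_index.n_regions):
            raise ValueError(
                f"subject {sid!r}: matrix shape {m.shape} does not match "
                f"{edge_index.n_regions} regions"
            )
        if np.max(np.abs(m - m.T)) > symmetry_tol:
            raise ValueError(f"subject {sid!r}: FC matrix is not symmetric")
        covs = []
        for c in COVARIATE_COLUMNS:
            v = r.get(c)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                raise ValueError(f"subject {sid!r}: missing covariate {c!r}")
            covs.append(float(v))
        rows.append(np.concatenate([edge_index.edge_values(m), covs]))
        labels.append(1 if r["group"] == "patient" else 0)
        sids.append(sid)
    X = pd.DataFrame(rows, columns=edge_cols + list(COVARIATE_COLUMNS), index=sids)
    return FeatureTable(
        X=X, y=np.asarray(labels), subject_ids=sids, edge_columns=edge_cols
    )


@dataclass
class CrossValResult:
    fold_aucs: list[float]
    models: list[xgb.XGBClassifier]
    test_indices: list[np.ndarray]
    params: dict
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def crossval_classify(
    table: FeatureTable,
    folds: int = 5,
    seed: int = 0,
    tune: bool = False,
    xgb_params: Optional[dict] = None,
) -> CrossValResult:
    """Stratified k-fold cross-validated boosted-trees classification.

    Returns per-fold held-out AUC-ROC and the fitted fold models.  With
    ``tune=True`` an inner 3-fold random search over a small grid picks the
    hyperparameters per outer fold (off by default: fixed sensible values).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(table.y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} subjects per class for {folds}-fold stratification"
        )
    params = dict(DEFAULT_XGB_PARAMS)
    if xgb_params:
        params.update(xgb_params)
    X = table.X.to_numpy(dtype=np.float32)
    y = table.y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aucs, models, test_indices = [], [], []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_params = dict(params)
        if tune:
            fold_params.update(
                _tune_inner(X[tr], y[tr], params, seed=seed + 1000 + fold)
            )
        model = xgb.XGBClassifier(random_state=seed + fold, **fold_params)
        model.fit(X[tr], y[tr])
        prob = model.predict_proba(X[te])[:, 1]
        fold_aucs.append(float(roc_auc_score(y[te], prob)))
        models.append(model)
        test_indices.append(te)
    return CrossValResult(
        fold_aucs=fold_aucs,
        models=models,
        test_indices=test_indices,
        params=params,
        seed=seed,
    )


def _tune_inner(
    X: np.ndarray, y: np.ndarray, base_params: dict, seed: int, n_iter: int = 6
) -> dict:
    """Random search over TUNING_GRID with inner 3-fold stratified CV."""
    rng = np.random.default_rng(seed)
    keys = list(TUNING_GRID)
    best_auc, best = -np.inf, {}
    for _ in range(n_iter):
        cand = {k: TUNING_GRID[k][rng.integers(len(TUNING_GRID[k]))] for k in keys}
        aucs = []
        inner = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
        for tr, te in inner.split(X, y):
            p = dict(base_params)
            p.update(cand)
            m = xgb.XGBClassifier(random_state=seed, **p)
            m.fit(X[tr], y[tr])
            aucs.append(roc_auc_score(y[te], m.predict_proba(X[te])[:, 1]))
        if np.mean(aucs) > best_auc:
            best_auc, best = float(np.mean(aucs)), cand
    return best


@dataclass
class Attributions:
    """Pooled held-out additive attributions.

    values: subjects x features matrix of signed TreeSHAP contributions,
    rows computed by the fold model for which the subject was held out.
    bias: per-subject expected value (base margin) of that fold model.
    """

    values: pd.DataFrame
    bias: np.ndarray

    def mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=0)

    def margin(self) -> np.ndarray:
        """Reconstructed margin output: attributions + bias (additivity)."""
        return self.values.to_numpy().sum(axis=1) + self.bias


def feature_attributions(cv: CrossValResult, table: FeatureTable) -> Attributions:
    """TreeSHAP contributions for every subject, from its held-out fold model."""
    if not cv.models:
        raise ValueError("no fitted models: run crossval_classify first")
    n, p = table.X.shape
    values = np.full((n, p), np.nan)
    bias = np.full(n, np.nan)
    X = table.X.to_numpy(dtype=np.float32)
    for model, te in zip(cv.models, cv.test_indices):
        booster = model.get_booster()
        contribs = booster.predict(xgb.DMatrix(X[te]), pred_contribs=True)
        values[te] = contribs[:, :-1]
        bias[te] = contribs[:, -1]
    return Attributions(
        values=pd.DataFrame(values, columns=table.X.columns, index=table.subject_ids),
        bias=bias,
    )


def top_features(
    attr: Attributions, table: FeatureTable, k: int = 20
) -> pd.DataFrame:
    """Top-k features by mean |attribution|, with the value-attribution sign.

    ``value_attr_corr`` > 0 means high feature values push the model toward
    the patient class (the red side of a beeswarm plot).
    """
    mean_abs = attr.mean_abs().sort_values(ascending=False)
    rows = []
    for name in mean_abs.index[:k]:
        v = table.X[name].to_numpy(dtype=float)
        a = attr.values[name].to_numpy()
        if np.std(v) == 0 or np.std(a) == 0:
            corr = 0.0
        else:
            corr = float(np.corrcoef(v, a)[0, 1])
        rows.append(
            {
                "feature": name,
                "mean_abs_attribution": float(mean_abs[name]),
                "value_attr_corr": corr,
            }
        )
    return pd.DataFrame(rows)


def network_importance(
    importances: pd.Series,
    edge_index: EdgeIndex,
    parc: Parcellation,
    mode: str = "mean",
) -> dict[str, float]:
    """Roll edge-feature importances up to large-scale networks.

    Each edge feature is attributed to every distinct endpoint network;
    a network's importance is the mean (default, or sum) of the importances
    of the edges touching it.  Covariate features are excluded.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    nets = parc.network_array()
    per_network: dict[str, list[float]] = {n: [] for n in parc.networks}
    for name, imp in importances.items():
        pair = parse_edge_feature(str(name))
        if pair is None:
            continue
        i, j = pair
        for network in {nets[i], nets[j]}:
            per_network[network].append(float(imp))
    agg = np.mean if mode == "mean" else np.sum
    return {
        n: float(agg(v)) if v else 0.0 for n, v in per_network.items()
    }
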