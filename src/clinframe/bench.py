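"""Grouped cross-validation and the framing x model benchmark matrix.

Cross-validation is patient-grouped fivefold: patients are shuffled once and
split into five 20% portions; each fold holds one portion out and halves it
into validation and test (10% / 10%), training on the remaining 80%.  All
samples of a patient share the patient's role, so no individual contributes
to two roles within a fold.

Model families are the standard tabular quintet: extremely randomized trees,
random forest, LightGBM, XGBoost and logistic regression.  Families that
cannot consume missing values natively get a train-fitted median imputation
adapter (plus standardization for the logistic regression); the boosting
families consume NaN directly and use the validation split for early
stopping only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .framing import ClassBalance, FramingConfig, class_balance, frame_cohort
from .features import featurize_samples
from .metrics import FoldSummary, ace, discrimination, stratified_brier, summarize_folds

logger = logging.getLogger(__name__)

MODEL_FAMILIES = (
    "extra_trees",
    "random_forest",
    "lightgbm",
    "xgboost",
    "logistic_regression",
)

METRIC_NAMES = ("auprc", "auroc", "brier_pos_x100", "brier_neg_x100", "ace_percent")


# -- fold plan --------------------------------------------------------------


@dataclass(frozen=True)
class Fold:
    train: frozenset[str]
    validation: frozenset[str]
    test: frozenset[str]


@dataclass(frozen=True)
class FoldPlan:
    folds: tuple[Fold, ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def split_folds(patient_ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldPlan:
    """Patient-grouped k-fold plan with 80/10/10 train/validation/test roles.

    Deterministic given the seed.  The k held-out portions are disjoint and
    exhaust the patients; each is halved into validation and test.
    """
    patients = np.array(sorted(set(map(str, patient_ids))))
    if len(patients) < 2 * k:
        raise ValueError(f"need at least {2 * k} patients for {k} folds, got {len(patients)}")
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)
    portions = np.array_split(patients, k)
    folds = []
    for i in range(k):
        held = portions[i]
        half = len(held) // 2
        validation = frozenset(held[:half])
        test = frozenset(held[half:])
        train = frozenset(np.concatenate([portions[j] for j in range(k) if j != i]))
        folds.append(Fold(train, validation, test))
    return FoldPlan(tuple(folds), seed)


# -- models -----------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


def _needs_imputation(family: str) -> bool:
    return family in ("extra_trees", "random_forest", "logistic_regression")


def make_estimator(spec: ModelSpec):
    params = dict(spec.hyperparameters)
    if spec.family == "extra_trees":
        from sklearn.ensemble import ExtraTreesClassifier

        return ExtraTreesClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "lightgbm":
        from lightgbm import LGBMClassifier

        params.setdefault("verbose", -1)
        return LGBMClassifier(random_state=spec.seed, n_jobs=1, **params)
    if spec.family == "xgboost":
        from xgboost import XGBClassifier

        params.setdefault("eval_metric", "logloss")
        return XGBClassifier(random_state=spec.seed, n_jobs=1, verbosity=0, **params)
    from sklearn.linear_model import LogisticRegression

    params.setdefault("max_iter", 1000)
    return LogisticRegression(random_state=spec.seed, **params)


def train_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> np.ndarray:
    """Fit one model family and return predicted positive-class probabilities.

    Raises on degenerate single-class training labels.
    """
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class; cannot fit a classifier")
    X_train = np.asarray(X_train, dtype=float)
    X_eval = np.asarray(X_eval, dtype=float)

    if _needs_imputation(spec.family):
        from sklearn.impute import SimpleImputer

        imputer = SimpleImputer(strategy="median", keep_empty_features=True)
        X_train = imputer.fit_transform(X_train)
        X_eval = imputer.transform(X_eval)
        if spec.family == "logistic_regression":
            from sklearn.preprocessing import StandardScaler

            scaler = StandardScaler()
            X_train = scaler.fit_transform(X_train)
            X_eval = scaler.transform(X_eval)

    est = make_estimator(spec)
    if spec.family in ("lightgbm", "xgboost") and X_val is not None and y_val is not None:
        X_val = np.asarray(X_val, dtype=float)
        if spec.family == "lightgbm":
            import lightgbm as lgb

            est.fit(
                X_train,
                y_train,
                eval_set=[(X_val, np.asarray(y_val, dtype=int))],
                callbacks=[lgb.early_stopping(20, verbose=False)],
            )
        else:
            est.set_params(early_stopping_rounds=20)
            est.fit(X_train, y_train, eval_set=[(X_val, np.asarray(y_val, dtype=int))], verbose=False)
    else:
        est.fit(X_train, y_train)
    return est.predict_proba(X_eval)[:, 1]


# -- benchmark matrix -------------------------------------------------------


@dataclass
class CellResult:
    """Per-fold and summarized metrics for one (framing, model) cell."""

    framing: str
    model: str
    per_fold: pd.DataFrame  # fold, auprc, auroc, brier_pos_x100, brier_neg_x100, ace_percent
    summaries: dict[str, FoldSummary]
    defined: bool = True


@dataclass
class BenchmarkReport:
    cells: list[CellResult]
    balances: dict[str, ClassBalance]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for cell in self.cells:
            row: dict = {"framing": cell.framing, "model": cell.model, "defined": cell.defined}
            for m in METRIC_NAMES:
                if cell.defined and m in cell.summaries:
                    s = cell.summaries[m]
                    row[m] = s.mean
                    row[f"{m}_ci"] = f"({s.ci_low:.3f}-{s.ci_high:.3f})"
                else:
                    row[m] = np.nan
                    row[f"{m}_ci"] = ""
            rows.append(row)
        return pd.DataFrame(rows)


def _metric_row(y: np.ndarray, p: np.ndarray) -> dict[str, float]:
    auroc, auprc = discrimination(y, p)
    bp, bn = stratified_brier(y, p)
    return {
        "auprc": auprc,
        "auroc": auroc,
        "brier_pos_x100": bp,
        "brier_neg_x100": bn,
        "ace_percent": ace(y, p),
    }


def benchmark_matrix(
    cohort,
    labels,
    framing_configs: Mapping[str, FramingConfig],
    model_specs: Sequence[ModelSpec],
    fold_plan: FoldPlan,
    sofa_provider=None,
    feature_cache: dict | None = None,
) -> BenchmarkReport:
    """Run the full framing x model grid under one grouped fold plan.

    Samples are framed and featurized once per framing; each (framing, model,
    fold) fit trains on the fold's train patients, early-stops on validation
    (boosting families) and is scored on test.  A cell whose test split lacks
    positive samples in some fold is marked undefined and the run continues.
    """
    adm_to_patient = dict(
        zip(cohort.admissions["admission_id"].astype(str), cohort.admissions["patient_id"].astype(str))
    )
    cells: list[CellResult] = []
    balances: dict[str, ClassBalance] = {}

    for framing_name, cfg in framing_configs.items():
        samples = frame_cohort(cohort, labels, cfg, sofa_provider=sofa_provider)
        balances[framing_name] = class_balance(samples)
        if feature_cache is not None and framing_name in feature_cache:
            feats = feature_cache[framing_name]
        else:
            feats = featurize_samples(cohort, samples, cfg.observation_window)
            if feature_cache is not None:
                feature_cache[framing_name] = feats
        feat_cols = [c for c in feats.columns if c not in ("sample_id", "label")]
        X = feats[feat_cols].to_numpy(dtype=float)
        y = feats["label"].to_numpy(dtype=int)
        patient = samples["admission_id"].map(adm_to_patient).to_numpy()

        role_masks = []
        for fold in fold_plan.folds:
            tr = np.isin(patient, list(fold.train))
            va = np.isin(patient, list(fold.validation))
            te = np.isin(patient, list(fold.test))
            role_masks.append((tr, va, te))

        for spec in model_specs:
            rows = []
            defined = True
            for fold_idx, (tr, va, te) in enumerate(role_masks):
                y_te = y[te]
                if y_te.sum() == 0 or y_te.sum() == len(y_te) or len(np.unique(y[tr])) < 2:
                    defined = False
                    logger.warning(
                        "cell (%s, %s) fold %d: degenerate split, marked undefined",
                        framing_name,
                        spec.family,
                        fold_idx,
                    )
                    break
                probs = train_predict(spec, X[tr], y[tr], X[te], X[va], y[va])
                rows.append({"fold": fold_idx, **_metric_row(y_te, probs)})
            if defined:
                per_fold = pd.DataFrame(rows)
                summaries = {m: summarize_folds(per_fold[m].to_numpy()) for m in METRIC_NAMES}
                cells.append(CellResult(framing_name, spec.family, per_fold, summaries, True))
            else:
                cells.append(
                    CellResult(framing_name, spec.family, pd.DataFrame(), {}, False)
                )
    return BenchmarkReport(cells, balances)


def default_model_specs(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(family, {}, seed) for family in MODEL_FAMILIES]
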