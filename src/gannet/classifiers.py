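"""Data splitting, the fixed ANN training protocol, and baseline models.

The split scheme mirrors the study design: a class-balanced train+validation
pool (100 cases + 100 controls when 262 samples are available, scaled
proportionally otherwise), 10% of that pool held out for validation, and the
remaining samples as the test set.

The ANN is a two-hidden-layer ReLU net with a sigmoid head; hidden width
follows the input-size rule (3->8, 10->16, 16->32, 92->64). Training is 100
epochs of Adam (lr 5e-3, per-update decay 1e-5, batch 32) with binary
cross-entropy, restoring the epoch checkpoint with the lowest validation
loss (ties: higher training accuracy, then earlier epoch).

Six conventional baselines (SVM, random forest, XGBoost, logistic
regression, LightGBM, AdaBoost) are exposed under one seeded factory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from . import _mlp
from .genotype_data import GenotypeDataset

__all__ = [
    "SplitSpec", "make_split", "ANNSpec", "TrainedANN", "ann_width",
    "train_ann", "BASELINE_ALGORITHMS", "train_baseline", "BaselineScorer",
]

#: hidden width by the listed input sizes
_WIDTH_RULE = {3: 8, 10: 16, 16: 32, 92: 64}


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Disjoint train/validation/test sample-id sets."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int
    stratified: bool = True

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise ValueError("train/val/test ids overlap")


def make_split(dataset: GenotypeDataset, seed: int) -> SplitSpec:
    """Seeded stratified split with the study's proportions.

    For 262 samples this yields exactly 180 train / 20 validation / 62 test
    with a class-balanced 100+100 train+validation pool; other totals scale
    the 200/262 pool fraction proportionally. Validation is a stratified 10%
    of the pool.
    """
    rng = np.random.default_rng(seed)
    ids = np.asarray(dataset.sample_ids)
    y = dataset.phenotypes
    case_idx = np.nonzero(y == 1)[0]
    ctrl_idx = np.nonzero(y == 0)[0]
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValueError("need at least 2 samples per class")

    n = len(ids)
    pool = int(round(n * 200 / 262))
    per_class = pool // 2
    if per_class >= len(case_idx) or per_class >= len(ctrl_idx):
        need = 2 * (min(len(case_idx), len(ctrl_idx)))
        raise ValueError(
            f"cannot draw a balanced pool of {pool}; smaller class supports at "
            f"most {need - 2} pooled samples with a non-empty test set")

    case_perm = rng.permutation(case_idx)
    ctrl_perm = rng.permutation(ctrl_idx)
    pool_case, pool_ctrl = case_perm[:per_class], ctrl_perm[:per_class]
    test = np.concatenate([case_perm[per_class:], ctrl_perm[per_class:]])

    val_per_class = max(1, int(round(0.10 * per_class)))
    val = np.concatenate([pool_case[:val_per_class], pool_ctrl[:val_per_class]])
    train = np.concatenate([pool_case[val_per_class:], pool_ctrl[val_per_class:]])
    return SplitSpec(
        train_ids=sorted(ids[train].tolist()),
        val_ids=sorted(ids[val].tolist()),
        test_ids=sorted(ids[test].tolist()),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ANN
# ---------------------------------------------------------------------------

def ann_width(n_snps: int) -> int:
    """Hidden width for an input size: 3->8, 10->16, 16->32, 92->64.

    Unlisted sizes take the width of the nearest listed size, ties toward
    the larger one (an extension of the published rule).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_snps in _WIDTH_RULE:
        return _WIDTH_RULE[n_snps]
    nearest = min(sorted(_WIDTH_RULE), key=lambda k: (abs(k - n_snps), -k))
    return _WIDTH_RULE[nearest]


@dataclass
class ANNSpec:
    """Architecture and training hyperparameters of the fixed ANN."""

    n_inputs: int
    hidden_width: int | None = None
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 5e-3
    decay: float = 1e-5

    def __post_init__(self) -> None:
        if self.hidden_width is None:
            self.hidden_width = ann_width(self.n_inputs)

    @property
    def n_parameters(self) -> int:
        return _mlp.n_parameters(self.n_inputs, self.hidden_width)


@dataclass
class TrainedANN:
    """A trained net restored to its best validation-loss checkpoint."""

    spec: ANNSpec
    params: dict = field(repr=False)
    train_loss: float
    val_loss: float
    train_accuracy: float
    best_epoch: int
    history: list = field(repr=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"expected {self.spec.n_inputs} input columns, got {x.shape[1]}")
        return _mlp.forward(self.params, x)


def train_ann(
    spec: ANNSpec,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    seed: int,
) -> TrainedANN:
    """Train the fixed ANN; reproducible for a fixed seed and data."""
    y_train = np.asarray(y_train)
    if np.isnan(np.asarray(x_train, dtype=float)).any():
        raise ValueError("training inputs contain missing dosages; impute first")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    result = _mlp.train_mlp(
        x_train, y_train, x_val, y_val,
        width=spec.hidden_width, seed=seed, epochs=spec.epochs,
        batch_size=spec.batch_size, lr0=spec.learning_rate, decay=spec.decay,
    )
    return TrainedANN(
        spec=spec,
        params=result["params"],
        train_loss=result["train_loss"],
        val_loss=result["val_loss"],
        train_accuracy=result["train_accuracy"],
        best_epoch=result["epoch"],
        history=result["history"],
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

BASELINE_ALGORITHMS = (
    "svm",
    "random_forest",
    "extreme_gradient_boosting",
    "logistic_regression",
    "light_gradient_boosting",
    "adaptive_boosting",
)


class BaselineScorer:
    """Fitted baseline exposing a 1-D case-probability scorer."""

    def __init__(self, name: str, model):
        self.name = name
        self._model = model

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names on plain arrays
            _warnings.filterwarnings("ignore", message=".*feature names.*")
            return self._model.predict_proba(np.asarray(x, dtype=float))[:, 1]


def train_baseline(algorithm: str, x_train: np.ndarray, y_train: np.ndarray,
                   seed: int = 0) -> BaselineScorer:
    """Fit one of the six conventional classifiers at seeded defaults."""
    x = np.asarray(x_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if algorithm == "svm":
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", FutureWarning)
            model = SVC(probability=True, random_state=seed)
            model.fit(x, y)
        return BaselineScorer(algorithm, model)
    elif algorithm == "random_forest":
        model = RandomForestClassifier(random_state=seed)
    elif algorithm == "extreme_gradient_boosting":
        from xgboost import XGBClassifier
        model = XGBClassifier(random_state=seed, eval_metric="logloss",
                              n_jobs=1, verbosity=0)
    elif algorithm == "logistic_regression":
        model = LogisticRegression(max_iter=2000)
    elif algorithm == "light_gradient_boosting":
        from lightgbm import LGBMClassifier
        model = LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                               deterministic=True, force_row_wise=True)
    elif algorithm == "adaptive_boosting":
        model = AdaBoostClassifier(random_state=seed)
    else:
        raise ValueError(
            f"unknown algorithm {algorithm!r}; valid: {list(BASELINE_ALGORITHMS)}")
    model.fit(x, y)
    return BaselineScorer(algorithm, model)
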