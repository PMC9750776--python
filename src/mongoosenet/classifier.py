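"""Fire-module network classifier trained by dwarf mongoose optimization.

`DMOASqueezeNetClassifier` is a scikit-learn estimator: `fit` runs the
DMOA minimizing the mean-squared error between the network's
abnormal-class probability and the 0/1 labels over the flat weight
vector; `predict`/`predict_proba` run the deterministic forward pass.
`build_pipeline` assembles the full detection pipeline (normalize →
impute → select → classify) for a given attribute typing.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from . import squeezenet as sn
from .dmoa import DwarfMongooseOptimizer, fitness_mse
from .featsel import CongruenceKHSSelector
from .preprocess import MixedTypeImputer, QuantileNormalizer

__all__ = ["DMOASqueezeNetClassifier", "build_pipeline"]


class DMOASqueezeNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier: 1-D fire-module network + DMOA weight search.

    Parameters
    ----------
    spec : "micro" (compact default), "full8" (eight fire modules), or an
        explicit :class:`~mongoosenet.squeezenet.NetworkSpec`.
    weight_bound : box half-width; every weight is searched in
        [-weight_bound, weight_bound].
    n_mongooses, max_iter, peep, n_babysitters, exchange_period,
    patience, alpha_weighting : optimizer settings, see
        :class:`~mongoosenet.dmoa.DwarfMongooseOptimizer`.
    random_state : seed for population initialization and moves.

    Attributes
    ----------
    spec_ : the resolved network architecture.
    params_ : best flat weight vector found.
    best_fitness_ : training MSE of ``params_``.
    history_ : convergence trace (list of FitnessRecord).
    """

    def __init__(
        self,
        spec="micro",
        weight_bound: float = 1.0,
        n_mongooses: int = 30,
        max_iter: int = 150,
        peep: float = 2.0,
        n_babysitters: int = 3,
        exchange_period: int | None = None,
        patience: int | None = 50,
        alpha_weighting: str = "printed",
        random_state: int | None = None,
    ):
        self.spec = spec
        self.weight_bound = weight_bound
        self.n_mongooses = n_mongooses
        self.max_iter = max_iter
        self.peep = peep
        self.n_babysitters = n_babysitters
        self.exchange_period = exchange_period
        self.patience = patience
        self.alpha_weighting = alpha_weighting
        self.random_state = random_state

    def _resolve_spec(self, n_features: int) -> sn.NetworkSpec:
        if isinstance(self.spec, sn.NetworkSpec):
            if self.spec.input_length != n_features:
                raise ValueError(
                    f"spec expects {self.spec.input_length} features, data has {n_features}"
                )
            return self.spec
        if self.spec == "micro":
            return sn.NetworkSpec.micro(n_features)
        if self.spec == "full8":
            return sn.NetworkSpec.full8(n_features)
        raise ValueError(f"unknown spec {self.spec!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        classes = np.unique(y)
        if not np.isin(classes, [0, 1]).all():
            raise ValueError("labels must be binary {0, 1}")
        self.classes_ = np.array([0, 1])
        self.spec_ = self._resolve_spec(X.shape[1])
        dim = sn.parameter_count(self.spec_)
        y01 = y.astype(float)

        def fitness(vec: np.ndarray) -> float:
            _, probs = sn.predict_batch(self.spec_, vec, X)
            return fitness_mse(probs[:, 1], y01)

        opt = DwarfMongooseOptimizer(
            n_mongooses=self.n_mongooses,
            max_iter=self.max_iter,
            peep=self.peep,
            n_babysitters=self.n_babysitters,
            exchange_period=self.exchange_period,
            patience=self.patience,
            alpha_weighting=self.alpha_weighting,
            seed=self.random_state,
        )
        result = opt.optimize(fitness, dim, (-self.weight_bound, self.weight_bound))
        self.params_ = result.best_solution
        self.best_fitness_ = result.best_fitness
        self.history_ = result.history
        self.n_evaluations_ = result.n_evaluations
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        _, probs = sn.predict_batch(self.spec_, self.params_, X)
        return probs

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = check_array(X, dtype=float)
        labels, _ = sn.predict_batch(self.spec_, self.params_, X)
        return labels


def build_pipeline(
    numeric_features,
    categorical_features,
    o: int | None = None,
    z: int | None = None,
    rank_by_abs: bool = True,
    congruence_form: str = "tucker",
    classifier_params: dict | None = None,
    random_state: int | None = None,
) -> Pipeline:
    """The full detection pipeline as a scikit-learn ``Pipeline``.

    Normalization and imputation learn their statistics on the training
    data only, so the pipeline is safe inside cross-validation.
    """
    params = dict(classifier_params or {})
    params.setdefault("random_state", random_state)
    return Pipeline([
        ("normalize", QuantileNormalizer(numeric_features=list(numeric_features))),
        ("impute", MixedTypeImputer(categorical_features=list(categorical_features))),
        ("select", CongruenceKHSSelector(o=o, z=z, rank_by_abs=rank_by_abs,
                                         congruence_form=congruence_form)),
        ("classify", DMOASqueezeNetClassifier(**params)),
    ])
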