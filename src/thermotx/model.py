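"""Estimator facade: the full model as a scikit-learn style object.

:class:`TranscriptionModel` wraps the pipeline and fitting machinery behind
the familiar ``fit`` / ``predict`` / ``get_params`` interface so it composes
with scikit-learn tooling (cloning, grid search over optimizer settings).
``fit`` takes a :class:`~thermotx.fitting.TrainingSet`; ``predict`` maps
constructs to expression profiles with the fitted parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .fitting import TrainingSet, fit as _fit, objective
from .params import ModelParams
from .pipeline import Construct, predict_profile
from .pwm import PWM
from .synth import toy_pwms

__all__ = ["TranscriptionModel"]


class TranscriptionModel(BaseEstimator):
    """Thermodynamic sequence-to-expression model with annealing-based fitting.

    Parameters
    ----------
    pwms : dict[str, PWM] or None
        Binding specificity per factor; the synthetic toy matrices by default.
    start_params : ModelParams or None
        Starting parameter vector (also defines roles/wiring and which
        entries are free).  Defaults to the nine-factor configuration.
    optimizer : {'generic_sa', 'lam_sa', 'multistart_local'}
    budget : int
        Objective-evaluation budget for the fit.
    seed : int
        Seed for the optimizer's randomness; fits are reproducible.

    Attributes
    ----------
    params_ : ModelParams
        Best-found parameters after :meth:`fit`.
    rms_ : float
        Root-mean-square residual of the fit.
    trace_ : ndarray
        Best-so-far objective value per evaluation.

    Examples
    --------
    >>> from thermotx.synth import demo_training_set
    >>> data = demo_training_set(seed=1)
    >>> model = TranscriptionModel(budget=2000, seed=1)
    >>> model.fit(data).rms_  # doctest: +SKIP
    """

    def __init__(
        self,
        pwms: dict[str, PWM] | None = None,
        start_params: ModelParams | None = None,
        optimizer: str = "generic_sa",
        budget: int = 50_000,
        seed: int = 0,
    ):
        self.pwms = pwms
        self.start_params = start_params
        self.optimizer = optimizer
        self.budget = budget
        self.seed = seed

    def _resolve(self, data: TrainingSet | None = None):
        pwms = self.pwms if self.pwms is not None else toy_pwms()
        start = self.start_params
        if start is None:
            if data is not None and data.true_params is not None:
                start = data.true_params.copy()
            else:
                start = ModelParams.defaults()
        return pwms, start

    def fit(self, X: TrainingSet, y=None) -> "TranscriptionModel":
        """Fit free parameters to a training set (``y`` is ignored)."""
        if not isinstance(X, TrainingSet):
            raise TypeError("X must be a TrainingSet")
        pwms, start = self._resolve(X)
        res = _fit(
            X, pwms, start,
            optimizer=self.optimizer, seed=self.seed, budget=self.budget,
        )
        self.params_ = res.params
        self.rms_ = res.rms
        self.ssq_ = res.ssq
        self.trace_ = res.trace
        self.result_ = res
        return self

    def predict(
        self,
        X: TrainingSet | list[Construct],
        tf_profiles: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        """Predicted rate profiles, one column per construct."""
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted; call fit first")
        if isinstance(X, TrainingSet):
            constructs, profiles = X.constructs, X.tf_profiles
        else:
            if tf_profiles is None:
                raise ValueError("tf_profiles required when predicting from constructs")
            constructs, profiles = X, tf_profiles
        pwms, _ = self._resolve()
        out = {}
        for c in constructs:
            p = predict_profile(c, pwms, profiles, self.params_)
            out[c.construct_id] = p.values
        return pd.DataFrame(out, index=profiles.index)

    def score(self, X: TrainingSet, y=None) -> float:
        """Negative mean squared residual (higher is better, sklearn style)."""
        pwms, _ = self._resolve(X)
        params = self.params_ if hasattr(self, "params_") else self._resolve(X)[1]
        ssq, _rms = objective(params, X, pwms)
        return -ssq / X.n_observations
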