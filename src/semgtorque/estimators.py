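"""Uniform fit/predict contract over all six torque estimators.

The experiment harness holds full-rate processed recordings and a set of
decimated sample indices; matrix models (OLS, RLS, SVR, ANN, LWPR) see
only the decimated design matrix, while the physiological model runs its
forward dynamics at the full rate and is read out at the same indices,
so every model is trained and scored on identical timestamps.
"""

from __future__ import annotations

import numpy as np

from . import linear, ml, pbm
from .exceptions import InvalidParameterError

MODEL_KINDS = ("pbm", "ols", "rls", "svr", "ann", "lwpr")


class TorqueEstimator:
    """fit on (full-rate envelopes, torque, indices); predict at indices."""

    kind: str = "base"

    def fit(self, envelopes, torque, sample_rate_hz, idx):
        raise NotImplementedError

    def predict(self, envelopes, sample_rate_hz, idx):
        raise NotImplementedError


class MatrixEstimator(TorqueEstimator):
    """Shared plumbing for models that consume a plain design matrix."""

    def _fit_matrix(self, X, y):
        raise NotImplementedError

    def _predict_matrix(self, X):
        raise NotImplementedError

    def fit(self, envelopes, torque, sample_rate_hz, idx):
        self._fit_matrix(np.asarray(envelopes)[idx], np.asarray(torque)[idx])
        return self

    def predict(self, envelopes, sample_rate_hz, idx):
        return self._predict_matrix(np.asarray(envelopes)[idx])


class OLSEstimator(MatrixEstimator):
    kind = "ols"

    def _fit_matrix(self, X, y):
        self.coefs_ = linear.ols_fit(linear.RegressionProblem(X, y))

    def _predict_matrix(self, X):
        return linear.linear_predict(self.coefs_, X)


class RLSEstimator(MatrixEstimator):
    kind = "rls"

    def __init__(self, lam: float = linear.DEFAULT_LAMBDA):
        self.lam = lam

    def _fit_matrix(self, X, y):
        self.coefs_ = linear.rls_fit(linear.RegressionProblem(X, y), self.lam)

    def _predict_matrix(self, X):
        return linear.linear_predict(self.coefs_, X)


class MLEstimator(MatrixEstimator):
    def __init__(self, kind: str, seed: int = 0,
                 config: ml.EstimatorConfig | None = None):
        if kind not in ("svr", "ann", "lwpr"):
            raise InvalidParameterError(f"unknown ML kind {kind!r}")
        self.kind = kind
        self.config = config or ml.EstimatorConfig(kind=kind, seed=seed)

    def _fit_matrix(self, X, y):
        self.fitted_ = ml.fit_estimator(
            linear.RegressionProblem(X, y), self.config
        )

    def _predict_matrix(self, X):
        return ml.estimator_predict(self.fitted_, X)


class PBMEstimator(TorqueEstimator):
    """GA-calibrated physiological model over a named channel subset."""

    kind = "pbm"

    def __init__(self, channel_names, ga_config: pbm.GAConfig | None = None,
                 muscle_table=None):
        self.channel_names = tuple(channel_names)
        self.ga_config = ga_config or pbm.GAConfig()
        self.muscle_table = muscle_table

    def fit(self, envelopes, torque, sample_rate_hz, idx):
        from .processing import ProcessedRecording

        rec = ProcessedRecording(
            sample_rate_hz=sample_rate_hz,
            envelopes=np.asarray(envelopes),
            torque=np.asarray(torque),
            channel_names=self.channel_names,
        )
        template = pbm.default_parameters(self.channel_names,
                                          self.muscle_table)
        self.calibration_ = pbm.calibrate_pbm(
            rec, template=template, ga_config=self.ga_config,
            train_indices=np.asarray(idx),
        )
        return self

    def predict(self, envelopes, sample_rate_hz, idx):
        tau = pbm.forward_pbm(
            np.asarray(envelopes), self.calibration_.parameters,
            sample_rate_hz=sample_rate_hz,
        )
        return tau[np.asarray(idx)]


def make_estimator(
    kind: str,
    channel_names,
    seed: int = 0,
    ga_config: pbm.GAConfig | None = None,
    ml_configs: dict | None = None,
    rls_lambda: float = linear.DEFAULT_LAMBDA,
) -> TorqueEstimator:
    """Build a fresh estimator of the requested kind."""
    if kind == "pbm":
        if ga_config is None:
            ga_config = pbm.GAConfig(seed=seed)
        return PBMEstimator(channel_names, ga_config=ga_config)
    if kind == "ols":
        return OLSEstimator()
    if kind == "rls":
        return RLSEstimator(rls_lambda)
    if kind in ("svr", "ann", "lwpr"):
        config = (ml_configs or {}).get(kind)
        return MLEstimator(kind, seed=seed, config=config)
    raise InvalidParameterError(
        f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}"
    )
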