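"""Minimal scikit-learn-compatible estimator base.

Provides ``get_params``/``set_params``/``repr`` by introspecting the
constructor signature, so the transformers and classifiers in this
package compose with scikit-learn pipelines and model selection without
making scikit-learn a runtime dependency.
"""

from __future__ import annotations

import inspect


class BaseEstimator:
    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            p.name
            for p in sig.parameters.values()
            if p.name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params):
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"invalid parameter {key!r} for {type(self).__name__}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        args = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({args})"


class TransformerMixin:
    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)


def check_is_fitted(est, attr: str) -> None:
    if not hasattr(est, attr):
        raise RuntimeError(
            f"{type(est).__name__} is not fitted yet; call fit() first"
        )
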