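"""Minimal estimator base class implementing the scikit-learn parameter contract.

Estimators in this package follow the sklearn conventions (``__init__`` stores
parameters verbatim, ``fit`` learns attributes with a trailing underscore,
``get_params``/``set_params`` expose the constructor signature) so they can be
dropped into sklearn pipelines and model-selection utilities without this
package depending on scikit-learn at run time.
"""

from __future__ import annotations

import inspect
from typing import Any


class BaseEstimator:
    """Parameter introspection identical in spirit to sklearn's BaseEstimator."""

    @classmethod
    def _param_names(cls) -> list[str]:
        sig = inspect.signature(cls.__init__)
        return [
            name
            for name, p in sig.parameters.items()
            if name != "self" and p.kind not in (p.VAR_POSITIONAL, p.VAR_KEYWORD)
        ]

    def get_params(self, deep: bool = True) -> dict[str, Any]:
        return {name: getattr(self, name) for name in self._param_names()}

    def set_params(self, **params: Any) -> "BaseEstimator":
        valid = set(self._param_names())
        for key, value in params.items():
            if key not in valid:
                raise ValueError(
                    f"Invalid parameter {key!r} for estimator {type(self).__name__}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"


def check_is_fitted(estimator: Any, attribute: str) -> None:
    if not hasattr(estimator, attribute):
        raise RuntimeError(
            f"{type(estimator).__name__} is not fitted yet; call fit() first."
        )
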