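"""Minimal sklearn-compatible estimator plumbing and shared exceptions."""

from __future__ import annotations

import inspect
from typing import Any


class BaseEstimator:
    """get_params/set_params via the ``__init__`` signature, sklearn-style.

    Duck-type compatible with sklearn pipelines and model selection without
    importing sklearn at runtime.
    """

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
                    f"Invalid parameter {key!r} for estimator "
                    f"{type(self).__name__}. Valid parameters: {sorted(valid)}"
                )
            setattr(self, key, value)
        return self

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        params = ", ".join(f"{k}={v!r}" for k, v in self.get_params().items())
        return f"{type(self).__name__}({params})"


def check_is_fitted(estimator: Any, attribute: str) -> None:
    if not hasattr(estimator, attribute):
        raise NotFittedError(
            f"{type(estimator).__name__} is not fitted yet; call 'fit' first."
        )


class BrsRiskError(Exception):
    """Base class for all package errors."""


class NotFittedError(BrsRiskError):
    pass


class DomainError(BrsRiskError, ValueError):
    """Invalid value for a mathematical operation (nonpositive interval, ...)."""


class SchemaError(BrsRiskError, ValueError):
    """A required column or variable is missing or malformed."""


class ValidationError(BrsRiskError, ValueError):
    """A record or cohort violates an invariant."""


class DegenerateTableError(BrsRiskError, ValueError):
    """A contingency table with an empty margin."""


class ZeroCellError(BrsRiskError, ValueError):
    """A 2x2 table cell is zero and no continuity correction was requested."""


class SeparationError(BrsRiskError, ArithmeticError):
    """Complete or quasi-complete separation in a logistic fit."""


class RankError(BrsRiskError, ArithmeticError):
    """Singular information matrix in a logistic fit."""


class StratificationError(BrsRiskError, ValueError):
    """A cross-validation fold cannot contain both outcome classes."""


class CalibrationError(BrsRiskError, ArithmeticError):
    """Requested outcome prevalence unattainable by intercept calibration."""
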