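"""Monotone maps between constrained model parameters and the real line.

Optimization and the group-level Gaussian both live on an unconstrained
scale; the fitted boxes are respected by construction:

* lam    — scaled logit on [0.001, 0.3]
* gamma  — scaled logit on [2, 10]
* epsilon— logit on (0, 1)
* tau    — log
* alpha  — log(alpha - 1), keeping the state prior strictly decreasing
"""

from __future__ import annotations

import numpy as np

from .planner import ModelParams, VARIANT_FIELDS
from .priors import GAMMA_BOUNDS, LAMBDA_BOUNDS

__all__ = ["to_unconstrained", "to_constrained", "n_params", "param_names"]

_CLIP = 30.0  # logit saturation guard


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log(p / (1.0 - p)))


_FORWARD = {
    "tau": lambda v: float(np.log(v)),
    "epsilon": _logit,
    "lam": lambda v: _logit((v - LAMBDA_BOUNDS[0]) / (LAMBDA_BOUNDS[1] - LAMBDA_BOUNDS[0])),
    "gamma": lambda v: _logit((v - GAMMA_BOUNDS[0]) / (GAMMA_BOUNDS[1] - GAMMA_BOUNDS[0])),
    "alpha": lambda v: float(np.log(v - 1.0)),
}

_BACKWARD = {
    "tau": lambda x: float(np.exp(np.clip(x, -_CLIP, _CLIP))),
    "epsilon": _sigmoid,
    "lam": lambda x: LAMBDA_BOUNDS[0] + (LAMBDA_BOUNDS[1] - LAMBDA_BOUNDS[0]) * _sigmoid(x),
    "gamma": lambda x: GAMMA_BOUNDS[0] + (GAMMA_BOUNDS[1] - GAMMA_BOUNDS[0]) * _sigmoid(x),
    "alpha": lambda x: 1.0 + float(np.exp(np.clip(x, -_CLIP, _CLIP))),
}


def param_names(variant: str) -> tuple[str, ...]:
    return VARIANT_FIELDS[variant]


def n_params(variant: str) -> int:
    return len(VARIANT_FIELDS[variant])


def to_unconstrained(variant: str, params: ModelParams) -> np.ndarray:
    """Map a variant's parameters to a real vector (order: VARIANT_FIELDS)."""
    return np.array([_FORWARD[name](getattr(params, name))
                     for name in VARIANT_FIELDS[variant]])


def to_constrained(variant: str, theta: np.ndarray) -> ModelParams:
    """Inverse of :func:`to_unconstrained`."""
    values = {name: _BACKWARD[name](float(x))
              for name, x in zip(VARIANT_FIELDS[variant], theta)}
    return ModelParams(**values)
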