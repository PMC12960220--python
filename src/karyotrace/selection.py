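"""Selection-coefficient proxy from lifetime euploid-embryo output.

An aneuploidy risk allele reduces the expected lifetime production of
chromosomally normal embryos.  With per-meiosis aneuploidy risk
``p_g(a)`` for genotype ``g`` at maternal age ``a`` (logistic in age,
age² and allele count), the weighted lifetime euploid output is

    W(g) = ∫ f(a) · (1 − p_g(a)) da        over the reproductive window,

with ``f`` a normalized age-weighting (uniform by default).  The
selection-coefficient proxy contrasts carriers with non-carriers,

    s_proxy = 1 − W(1) / W(0),

and a scaling factor ``alpha`` in (0, 1] relates the proxy to realized
fitness: the allele evolves effectively neutrally when
``alpha · s_proxy < 1 / (2 Ne)``; the threshold scaling is
``alpha* = 1 / (2 Ne s_proxy)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class RiskModel:
    """Logit-scale aneuploidy risk: b0 + b1·age + b2·age² + bg·g."""

    b0: float
    b1: float = 0.0
    b2: float = 0.0
    bg: float = 0.0

    def risk(self, age, g: int = 0):
        age = np.asarray(age, dtype=np.float64)
        return expit(self.b0 + self.b1 * age + self.b2 * age * age + self.bg * g)


@dataclass(frozen=True)
class SelectionParams:
    """Reproductive window, age weighting, population size, scaling."""

    a0: float = 18.0
    a1: float = 35.0
    Ne: float = 1e4
    alpha: float = 1.0
    #: optional un-normalized weight function f(a); uniform when None
    weight: Callable[[np.ndarray], np.ndarray] | None = None
    step: float = 0.05                 # integration step, years

    def __post_init__(self):
        if self.a1 <= self.a0:
            raise ValueError("reproductive window must satisfy a1 > a0")
        if self.Ne <= 0:
            raise ValueError("Ne must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class SelectionResult:
    W0: float
    W1: float
    s_proxy: float
    alpha_threshold: float             # NaN when s_proxy <= 0
    neutral: bool


def risk_at_age(model: RiskModel, age: float, g: int = 0) -> tuple[float, float]:
    """(risk, per-allele marginal increase) at one maternal age."""
    p = float(model.risk(age, g))
    return p, float(model.risk(age, g + 1)) - p


def lifetime_fitness_proxy(model: RiskModel, params: SelectionParams,
                           g: int) -> float:
    """W(g): weight-averaged probability of a euploid meiosis.

    Trapezoid rule at ``params.step``-year resolution; weights are
    normalized over the window, so a constant risk p gives W = 1 − p.
    """
    n = max(2, int(np.ceil((params.a1 - params.a0) / params.step)) + 1)
    a = np.linspace(params.a0, params.a1, n)
    f = np.ones_like(a) if params.weight is None else np.asarray(params.weight(a), float)
    if np.any(f < 0):
        raise ValueError("age weights must be non-negative")
    norm = np.trapezoid(f, a)
    return float(np.trapezoid(f * (1.0 - model.risk(a, g)), a) / norm)


def alpha_threshold(s_proxy: float, Ne: float) -> float:
    """Scaling alpha* at which alpha·s_proxy meets the 1/(2Ne) drift bound."""
    if s_proxy <= 0:
        raise ValueError("alpha threshold undefined for s_proxy <= 0")
    return 1.0 / (2.0 * Ne * s_proxy)


def selection_proxy(model: RiskModel, params: SelectionParams,
                    g_carrier: int = 1) -> SelectionResult:
    """Contrast carrier (g copies) vs non-carrier lifetime euploid output."""
    W0 = lifetime_fitness_proxy(model, params, 0)
    W1 = lifetime_fitness_proxy(model, params, g_carrier)
    if W0 <= 0:
        raise ValueError("non-carrier fitness proxy must be positive")
    s = 1.0 - W1 / W0
    thr = alpha_threshold(s, params.Ne) if s > 0 else float("nan")
    neutral = params.alpha * s < 1.0 / (2.0 * params.Ne)
    return SelectionResult(W0=W0, W1=W1, s_proxy=s, alpha_threshold=thr,
                           neutral=neutral)


def alpha_grid_scan(model: RiskModel, params: SelectionParams,
                    alphas: np.ndarray) -> list[dict]:
    """Neutral-vs-selected status of the proxy over a grid of alpha."""
    base = selection_proxy(model, params)
    out = []
    for a in np.asarray(alphas, dtype=np.float64):
        out.append({
            "alpha": float(a),
            "s_proxy": base.s_proxy,
            "scaled_s": float(a * base.s_proxy),
            "neutral": bool(a * base.s_proxy < 1.0 / (2.0 * params.Ne)),
        })
    return out
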