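"""Closed-form reinitiation probabilities for the two-factor and one-factor
scanning models.

A 40S subunit that resumes scanning downstream of uORF1 must re-acquire
the ternary complex (TC) — and, in the two-factor model, an additional
factor required only for main-ORF start-codon selection — before reaching
the main ORF.  At every nucleotide the embedded jump chain of the
underlying continuous-time kinetics chooses between advancing one step and
binding one of the still-missing factors, with probabilities proportional
to the propensities.  The survival probability of scanning ``n`` steps
against a disappearance (binding) rate ``a_D`` is ``[a_S/(a_S+a_D)]**n``;
everything else in this module is finite sums of such survival terms,
written as direct summations so the code stays isomorphic to the model
definitions (``n`` never exceeds a few hundred in practice).

Probability bookkeeping for the construct carrying uORF1, uORF4 and the
main ORF:

* ``model1_p1(n)`` — both factors acquired within ``n`` scanning steps
  (no intervening uORF4; used for the uORF1-only construct).
* ``model1_p2(n1, n2)`` — the extra factor is bound within the first
  ``n1`` steps, the ribosome passes the uORF4 start codon without TC, and
  binds TC within the remaining ``n2`` steps.
* ``model1_p3(n1, n2)`` — the ribosome passes uORF4 with neither factor
  and acquires both within the remaining ``n2`` steps.

A ribosome holding TC at the uORF4 start codon initiates there (no leaky
scanning), so main-ORF reinitiation for the full construct is ``p2 + p3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .layout import RateSet

__all__ = [
    "ReinitPrediction",
    "survival_probability",
    "transit_density",
    "model1_p1",
    "model1_p2",
    "model1_p3",
    "model1_gcn4_construct_d_pct",
    "model1_uorf4_pct",
    "model1_gcn4_with_uorf4_pct",
    "model2_uorf4_pct",
    "model2_gcn4_pct",
    "observed_uorf4_pct",
    "observed_gcn4_pct",
    "predict",
    "tc_dependence_curve",
    "factorx_sensitivity",
    "distance_sweep",
]


def _check_counts(*ns: int) -> None:
    for n in ns:
        if n < 0 or int(n) != n:
            raise ValueError(f"step count must be a non-negative integer, got {n}")


def survival_probability(a_s: float, a_d: float, n: int) -> float:
    """Probability of scanning ``n`` nucleotides against disappearance rate
    ``a_d`` without disappearing: ``[a_s/(a_s+a_d)]**n``.

    Evaluated in log space so that very long scans underflow gracefully.
    """
    if a_s <= 0:
        raise ValueError("a_s must be positive")
    if a_d < 0:
        raise ValueError("a_d must be non-negative")
    _check_counts(n)
    if a_d == 0.0:
        return 1.0
    return math.exp(n * (math.log(a_s) - math.log(a_s + a_d)))


def transit_density(a_s: float, a_d: float, n: int, t: float) -> float:
    """Joint density of being at position ``n`` at time ``t`` for a scanner
    subject to disappearance: ``a_s**n t**n / n! * exp(-(a_s+a_d) t)``.

    Gamma-shaped in ``t`` with mode ``n/(a_s+a_d)``; its time integral is
    ``survival_probability(a_s, a_d, n) / (a_s + a_d)``.
    """
    if a_s <= 0 or a_d < 0:
        raise ValueError("rates must satisfy a_s > 0, a_d >= 0")
    _check_counts(n)
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0.0:
        return 1.0 if n == 0 else 0.0
    log_p = (
        n * (math.log(a_s) + math.log(t))
        - math.lgamma(n + 1)
        - (a_s + a_d) * t
    )
    return math.exp(log_p)


def _pow(p: float, k: np.ndarray | int) -> np.ndarray | float:
    """p**k via exp(k log p), stable for p in (0, 1] and large k."""
    if p == 1.0:
        return np.ones_like(np.asarray(k, dtype=float)) if np.ndim(k) else 1.0
    return np.exp(np.asarray(k, dtype=float) * math.log(p))


def model1_p1(rates: RateSet, n: int) -> float:
    """Probability that a scanner acquires both factors within ``n`` steps."""
    _check_counts(n)
    if n == 0 or (rates.a_TC == 0.0 and rates.a_X == 0.0):
        # with at most one factor available the two-factor assembly never
        # completes; the empty scan offers no binding opportunity at all
        if rates.a_TC == 0.0 or rates.a_X == 0.0:
            return 0.0
    if n == 0:
        return 0.0
    i = np.arange(n + 1)
    lead = _pow(rates.p_s1, i)
    # 1 - p**k computed as -expm1(k log p) to keep tiny complements exact
    tail_tc = -np.expm1((n - i) * math.log(rates.p_s2)) if rates.a_X > 0 else 0.0
    tail_x = -np.expm1((n - i) * math.log(rates.p_s3)) if rates.a_TC > 0 else 0.0
    total = float(np.sum(lead * (rates.p_tc1 * tail_tc + rates.p_x1 * tail_x)))
    return min(total, 1.0)


def model1_p2(rates: RateSet, n1: int, n2: int) -> float:
    """Extra factor bound before uORF4, TC bound between uORF4 and the
    main ORF."""
    _check_counts(n1, n2)
    if rates.a_X == 0.0 or rates.a_TC == 0.0 or n2 == 0:
        return 0.0
    i = np.arange(n1 + 1)
    lead = _pow(rates.p_s1, i) * _pow(rates.p_s3, n1 - i)
    tail = -math.expm1(n2 * math.log(rates.p_s3))
    return float(rates.p_x1 * tail * np.sum(lead))


def model1_p3(rates: RateSet, n1: int, n2: int) -> float:
    """Neither factor bound before uORF4, both bound before the main ORF."""
    _check_counts(n1, n2)
    return _pow(rates.p_s1, n1) * model1_p1(rates, n2)


def model1_gcn4_construct_d_pct(rates: RateSet, n_total: int) -> float:
    """Main-ORF reinitiation percentage for the uORF1-only construct."""
    return 100.0 * model1_p1(rates, n_total)


def model1_uorf4_pct(rates: RateSet, n1: int, n2: int) -> float:
    """uORF4 reinitiation percentage, conditioned on eventual two-factor
    assembly: ``100 * (P1 - P2 - P3) / P1``."""
    p1 = model1_p1(rates, n1 + n2)
    if p1 == 0.0:
        raise ZeroDivisionError(
            "P1(n1+n2) = 0: the uORF4 percentage is an undefined ratio"
        )
    p2 = model1_p2(rates, n1, n2)
    p3 = model1_p3(rates, n1, n2)
    return 100.0 * (p1 - p2 - p3) / p1


def model1_gcn4_with_uorf4_pct(rates: RateSet, n1: int, n2: int) -> float:
    """Main-ORF reinitiation percentage for the full uORF1+uORF4 construct:
    ``100 * (P2 + P3)``."""
    return 100.0 * (model1_p2(rates, n1, n2) + model1_p3(rates, n1, n2))


@dataclass(frozen=True)
class ReinitPrediction:
    """Bundle of the two-factor model outputs for one (n1, n2) geometry."""

    p1: float
    p2: float
    p3: float
    p_uorf4_pct: float
    p_gcn4_construct_d_pct: float
    p_gcn4_with_uorf4_pct: float

    @classmethod
    def compute(cls, rates: RateSet, n1: int, n2: int) -> "ReinitPrediction":
        p1 = model1_p1(rates, n1 + n2)
        p2 = model1_p2(rates, n1, n2)
        p3 = model1_p3(rates, n1, n2)
        return cls(
            p1=p1,
            p2=p2,
            p3=p3,
            p_uorf4_pct=(100.0 * (p1 - p2 - p3) / p1) if p1 > 0 else float("nan"),
            p_gcn4_construct_d_pct=100.0 * p1,
            p_gcn4_with_uorf4_pct=100.0 * (p2 + p3),
        )


def model2_uorf4_pct(a_s: float, a_tc: float, n1: int) -> float:
    """One-factor model: uORF4 reinitiation percentage ``100 (1 - P_S^n1)``."""
    _check_counts(n1)
    p_surv = survival_probability(a_s, a_tc, n1)
    return 100.0 * (1.0 - p_surv)


def model2_gcn4_pct(a_s: float, a_tc: float, n1: int, n2: int) -> float:
    """One-factor model: main-ORF reinitiation percentage
    ``100 (P_S^n1 - P_S^(n1+n2))`` — pass uORF4 TC-free, bind TC after."""
    _check_counts(n1, n2)
    return 100.0 * (
        survival_probability(a_s, a_tc, n1)
        - survival_probability(a_s, a_tc, n1 + n2)
    )


def observed_uorf4_pct(act) -> float:
    """Observed uORF4 reinitiation from a reporter pair:
    ``100 (A2 - A1) / A2``."""
    if act.a2 <= 0:
        raise ValueError("A2 must be positive")
    return 100.0 * (act.a2 - act.a1) / act.a2


def observed_gcn4_pct(act) -> float:
    """Observed main-ORF reinitiation, normalised to the wild-type-spacing
    reference pair: ``100 (A2/A3) / (A2_ref/A3_ref)``."""
    if act.a3 <= 0 or act.a2_ref <= 0 or act.a3_ref <= 0:
        raise ValueError("A3 and the reference activities must be positive")
    return 100.0 * (act.a2 / act.a3) / (act.a2_ref / act.a3_ref)


Model = Literal["model1", "model2"]


def predict(
    rates: RateSet,
    construct_class: str,
    n1: int,
    n2: int,
    model: Model = "model1",
) -> float:
    """Predicted reinitiation percentage for one dataset row.

    ``construct_class`` selects the measured quantity: ``"uORF1-uORF4"``
    rows are uORF4 reinitiation percentages from a reporter pair with and
    without uORF4; ``"uORF1-only"`` rows are main-ORF reinitiation
    percentages for constructs whose uORF4 start codon is inactivated
    (TC — and in the two-factor model the extra factor — may be acquired
    anywhere over the full ``n1 + n2`` span).
    """
    if model == "model1":
        if construct_class == "uORF1-uORF4":
            return model1_uorf4_pct(rates, n1, n2)
        if construct_class == "uORF1-only":
            return model1_gcn4_construct_d_pct(rates, n1 + n2)
    elif model == "model2":
        if construct_class == "uORF1-uORF4":
            return model2_uorf4_pct(rates.a_S, rates.a_TC, n1)
        if construct_class == "uORF1-only":
            return 100.0 * (
                1.0 - survival_probability(rates.a_S, rates.a_TC, n1 + n2)
            )
    else:
        raise ValueError(f"unknown model {model!r}")
    raise ValueError(f"unknown construct class {construct_class!r}")


def _gcn4_full_pct(rates: RateSet, n1: int, n2: int, model: Model) -> float:
    if model == "model1":
        return model1_gcn4_with_uorf4_pct(rates, n1, n2)
    if model == "model2":
        return model2_gcn4_pct(rates.a_S, rates.a_TC, n1, n2)
    raise ValueError(f"unknown model {model!r}")


def tc_dependence_curve(
    rates: RateSet,
    n1: int,
    n2: int,
    a_tc_grid: Sequence[float],
    model: Model = "model1",
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Main-ORF reinitiation percentage as a function of the TC binding
    rate, for the full uORF1+uORF4 construct.

    Returns the curve as a tidy table and the ``(a_TC, percentage)`` of the
    optimum.  Reinitiation is maximal at an intermediate TC level: high TC
    diverts ribosomes into uORF4, while very low TC leaves the post-uORF4
    ribosomes factor-free when they reach the main ORF.
    """
    grid = list(a_tc_grid)
    if not grid:
        raise ValueError("a_tc_grid must be non-empty")
    pct = [
        _gcn4_full_pct(
            RateSet(rates.a_S, float(a_tc), rates.a_X), n1, n2, model
        )
        for a_tc in grid
    ]
    df = pd.DataFrame({"a_TC": grid, "gcn4_pct": pct})
    best = int(np.argmax(pct))
    return df, (float(grid[best]), float(pct[best]))


def factorx_sensitivity(
    rates: RateSet,
    n1: int,
    n2: int,
    fold_reductions: Iterable[float],
    a_tc_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Optimum of the TC-dependence curve after reducing the extra-factor
    binding rate by each fold in ``fold_reductions``."""
    if a_tc_grid is None:
        a_tc_grid = np.geomspace(1e-4, 0.1, 200) * rates.a_S
    rows = []
    for fold in fold_reductions:
        if fold <= 0:
            raise ValueError("fold reductions must be positive")
        reduced = rates.scaled(x_fold=1.0 / fold)
        _, (a_tc_opt, pct_opt) = tc_dependence_curve(
            reduced, n1, n2, a_tc_grid, model="model1"
        )
        rows.append(
            {"fold_reduction": fold, "a_TC_opt": a_tc_opt, "optimum_pct": pct_opt}
        )
    return pd.DataFrame(rows)


def distance_sweep(
    rates: RateSet,
    vary: Literal["n1", "n2"],
    fixed_value: int,
    grid: Sequence[int],
    model: Model = "model1",
) -> pd.DataFrame:
    """Main-ORF reinitiation percentage while one intercistronic distance
    is varied and the other held fixed."""
    if vary not in ("n1", "n2"):
        raise ValueError("vary must be 'n1' or 'n2'")
    rows = []
    for g in grid:
        n1, n2 = (g, fixed_value) if vary == "n1" else (fixed_value, g)
        rows.append(
            {
                "n1": n1,
                "n2": n2,
                "gcn4_pct": _gcn4_full_pct(rates, n1, n2, model),
            }
        )
    return pd.DataFrame(rows)
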