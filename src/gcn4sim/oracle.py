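"""Brute-force Monte-Carlo oracle for the two-factor scanning model.

Each walker is the embedded jump chain of the reaction scheme: at every
nucleotide position the walker repeatedly chooses among {advance, bind TC,
bind extra factor} with probabilities proportional to the propensities of
the events still available in its current carriage state.  Binding events
keep the walker at the same position; advancing moves it one nucleotide.
The embedded chain is exact for splitting probabilities, so at large
walker counts the estimates converge to the closed forms at the binomial
1/sqrt(n) rate — which is precisely what makes this an independent check
of the analytic module rather than a re-derivation of it.

For each walker we record the advance-index at which each factor was
bound (a binding while sitting at position ``p`` has index ``p``).  The
classification rules mirror the no-leaky-scanning commitment rule: a
walker holding TC on arrival at the uORF4 start codon (TC bound at index
< n1) initiates there and is lost to the main ORF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import RateSet

__all__ = ["WalkerEstimates", "run_walkers"]


@dataclass(frozen=True)
class WalkerEstimates:
    """Binomial estimates of the three splitting probabilities."""

    p1_hat: float
    p2_hat: float
    p3_hat: float
    se_p1: float
    se_p2: float
    se_p3: float
    n_walkers: int

    def as_tuple(self) -> tuple[float, float, float]:
        return self.p1_hat, self.p2_hat, self.p3_hat


def _binding_indices(
    rates: RateSet, n: int, n_walkers: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the jump chain and return the advance-index of each
    factor's binding (``n`` where a factor was never bound within the
    scan).  States: 0 = bare 40S, 1 = +TC, 2 = +X, 3 = both."""
    a_s, a_tc, a_x = rates.a_S, rates.a_TC, rates.a_X
    i_tc = np.full(n_walkers, n, dtype=np.int64)
    i_x = np.full(n_walkers, n, dtype=np.int64)
    state = np.zeros(n_walkers, dtype=np.int8)
    for pos in range(n):
        # at most two bindings can occur at one position before the
        # advance; resolve the sub-decisions in up to three rounds
        advanced = np.zeros(n_walkers, dtype=bool)
        while not advanced.all():
            pending = ~advanced
            u = rng.random(n_walkers)
            state_round = state.copy()  # one decision per walker per round
            for s, (p_adv, p_tc) in {
                0: (a_s / (a_s + a_tc + a_x), a_tc / (a_s + a_tc + a_x)),
                1: (a_s / (a_s + a_x), 0.0),
                2: (a_s / (a_s + a_tc), a_tc / (a_s + a_tc)),
                3: (1.0, 0.0),
            }.items():
                sel = pending & (state_round == s)
                if not sel.any():
                    continue
                adv = sel & (u < p_adv)
                advanced |= adv
                bind_tc = sel & ~adv & (u < p_adv + p_tc)
                bind_x = sel & ~adv & ~bind_tc
                if bind_tc.any():
                    i_tc[bind_tc] = pos
                    state[bind_tc] += 1
                if bind_x.any():
                    i_x[bind_x] = pos
                    state[bind_x] += 2
    return i_tc, i_x


def run_walkers(
    rates: RateSet,
    n1: int,
    n2: int,
    n_walkers: int,
    seed: int,
) -> WalkerEstimates:
    """Estimate the three splitting probabilities by simulation.

    ``p1_hat`` is the fraction of walkers binding both factors within
    ``n1 + n2`` advances on a track with no intervening start codon (the
    uORF1-only construct).  ``p2_hat``/``p3_hat`` split the main-ORF
    reinitiation events of the full construct by whether the extra factor
    was bound before or after the uORF4 start codon; walkers carrying TC
    at uORF4 commit there and are excluded.
    """
    if n_walkers < 1:
        raise ValueError("n_walkers must be at least 1")
    if n1 < 0 or n2 < 0:
        raise ValueError("distances must be non-negative")
    n = n1 + n2
    rng = np.random.default_rng(seed)
    i_tc, i_x = _binding_indices(rates, n, n_walkers, rng)

    both_within = (i_tc < n) & (i_x < n)
    committed_uorf4 = i_tc < n1
    # the closed forms' index conventions: the X-first path sums X-binding
    # indices 0..n1 inclusive, so a binding at the uORF4 position itself
    # belongs to both the X-first and the bare-arrival path (the boundary
    # term is shared by the two summations)
    p2_events = (i_x <= n1) & ~committed_uorf4 & (i_tc < n)
    p3_events = (i_x >= n1) & (i_x < n) & ~committed_uorf4 & (i_tc < n)

    def est(mask: np.ndarray) -> tuple[float, float]:
        p = float(mask.mean())
        return p, float(np.sqrt(p * (1.0 - p) / n_walkers))

    p1, se1 = est(both_within)
    p2, se2 = est(p2_events)
    p3, se3 = est(p3_events)
    return WalkerEstimates(p1, p2, p3, se1, se2, se3, n_walkers)
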