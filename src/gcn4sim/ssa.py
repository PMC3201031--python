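"""Exact stochastic simulation of multi-ribosome traffic on the mRNA.

The mRNA is a 1-based lattice on which each ribosome occupies a fixed
36-nt footprint (position = the 5'-most nucleotide of the footprint) and
ribosomes cannot overlap, so slow steps upstream cause queuing as in a
totally asymmetric exclusion process.  The simulated lifecycle is:

1. 5'-initiation at rate ``a_I`` whenever the first 36 nt are free; the
   loaded 43S complex carries ternary complex (TC) and scans toward uORF1.
2. Scanning advances one nucleotide at rate ``a_S`` (exclusion-checked).
   A scanner holding TC that arrives at a start codon commits there —
   there is no leaky scanning.
3. A committed ribosome joins its 60S subunit at ``rate_60S``, then
   elongates codon-by-codon (3-nt steps) at the per-codon rate, and
   terminates at the stop codon at the termination rate.
4. After uORF1 termination the 40S resumes scanning *without* TC with
   probability ``p_resume_uorf1`` (otherwise it leaves the mRNA); it may
   re-acquire TC at rate ``a_TC`` anywhere downstream.  Termination at
   uORF4 or at the main ORF always releases the ribosome.
5. A TC-less scanner arriving at the main-ORF start codon dissociates:
   there is no further start codon to serve, and the closed-form models
   count TC acquisition only up to that arrival.  (Defensively, a scanner
   reaching the 3' lattice end also drops off.)

Rates are carried on the common nt/s scale: each value is the per-second
propensity of its elementary event (1-nt scan step, 3-nt codon step,
factor binding, subunit joining, termination).

Trajectories are generated with the direct-method Gillespie algorithm and
summarised by time-weighted averages over an analysis window, discarding a
burn-in so the quasi-steady state is measured.  The module-level sweeps
reproduce the standard in-silico experiments: initiation-vs-scanning
grids, joint rescaling of ``a_I`` and ``a_S`` at fixed ratio, TC-binding
scans, and histidine-codon starvation scans.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .layout import MrnaLayout

__all__ = [
    "Phase",
    "RibosomeState",
    "CodonRateTable",
    "SimParams",
    "TrajectorySummary",
    "Event",
    "propensities",
    "run_trajectory",
    "run_replicates",
    "initiation_scan_sweep",
    "joint_scaling_sweep",
    "tc_sweep",
    "his_codon_sweep",
]

SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in ("UAA", "UAG", "UGA")
)
STOP_CODONS: tuple[str, ...] = ("UAA", "UAG", "UGA")
HIS_CODONS: tuple[str, ...] = ("CAU", "CAC")


@dataclass(frozen=True)
class CodonRateTable:
    """Per-codon elongation rates plus stop-codon termination rates.

    Rates are on the common nt/s scale (one 3-nt elongation event per
    firing).  The table must cover all 61 sense codons and at least one
    stop codon.  Since the simulator works on an abstract lattice rather
    than a nucleotide sequence, the main ORF is decoded at the table's
    mean sense rate, except at the annotated histidine-codon positions
    which use the CAU/CAC rates — the codons affected by histidine
    starvation.
    """

    rates: dict[str, float]
    stop_rates: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.rates]
        if missing:
            raise ValueError(
                f"codon table missing {len(missing)} sense codons: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        if not self.stop_rates:
            raise ValueError("codon table must define at least one stop codon")
        bad = {c: r for c, r in {**self.rates, **self.stop_rates}.items() if r <= 0}
        if bad:
            raise ValueError(f"non-positive codon rates: {bad}")

    @classmethod
    def uniform(cls, rate: float = 30.0, stop_rate: float | None = None) -> "CodonRateTable":
        stop = stop_rate if stop_rate is not None else rate
        return cls(
            rates={c: float(rate) for c in SENSE_CODONS},
            stop_rates={c: float(stop) for c in STOP_CODONS},
        )

    @property
    def mean_sense_rate(self) -> float:
        return float(np.mean([self.rates[c] for c in SENSE_CODONS]))

    @property
    def his_rate(self) -> float:
        return float(np.mean([self.rates[c] for c in HIS_CODONS]))

    @property
    def mean_stop_rate(self) -> float:
        return float(np.mean(list(self.stop_rates.values())))


class Phase(enum.IntEnum):
    """Ribosome lifecycle phases."""

    SCANNING_WITH_TC_PRE_UORF1 = 0
    SCANNING_NO_TC = 1
    SCANNING_WITH_TC = 2
    AWAITING_60S = 3
    ELONGATING = 4
    TERMINATING = 5


_SCANNING_PHASES = (
    Phase.SCANNING_WITH_TC_PRE_UORF1,
    Phase.SCANNING_NO_TC,
    Phase.SCANNING_WITH_TC,
)


@dataclass(frozen=True)
class RibosomeState:
    """One ribosome: footprint 5'-position, lifecycle phase and, once
    committed, the ORF it is initiating/translating (0 = uORF1,
    1 = uORF4, 2 = main ORF)."""

    position: int
    phase: Phase
    current_orf: int | None = None


@dataclass(frozen=True)
class SimParams:
    """Kinetic parameterisation and simulation protocol.

    All rates in per-second propensities (nt/s scale, see module docs).
    ``duration``/``burn_in`` in seconds; statistics are time-averaged over
    ``[burn_in, duration]``.
    """

    a_I: float = 0.087
    a_S: float = 30.0
    a_TC: float = 0.045 * 30.0
    rate_60S: float = 30.0
    codon_rates: CodonRateTable = field(default_factory=CodonRateTable.uniform)
    his_fold: float = 1.0
    p_resume_uorf1: float = 0.5
    footprint: int = 36
    duration: float = 3600.0
    burn_in: float = 600.0
    replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.a_I, self.a_S, self.a_TC, self.rate_60S) < 0:
            raise ValueError("rates must be non-negative")
        if self.a_S <= 0:
            raise ValueError("a_S must be positive")
        if not (0.0 <= self.p_resume_uorf1 <= 1.0):
            raise ValueError("p_resume_uorf1 must be a probability")
        if self.footprint < 1:
            raise ValueError("footprint must be at least 1 nt")
        if not (0.0 <= self.burn_in < self.duration):
            raise ValueError("require 0 <= burn_in < duration")
        if self.replicates < 1:
            raise ValueError("replicates must be at least 1")


@dataclass(frozen=True)
class TrajectorySummary:
    """Time-averaged statistics of one trajectory (or replicate mean ± SD)."""

    mean_occupancy_5p: float
    mean_occupancy_3p: float
    p_5prime_free: float
    rate_uorf1: float
    rate_gcn4: float
    counters: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    replicates: int = 1

    STAT_FIELDS = (
        "mean_occupancy_5p",
        "mean_occupancy_3p",
        "p_5prime_free",
        "rate_uorf1",
        "rate_gcn4",
    )


@dataclass(frozen=True)
class Event:
    """One enabled reaction channel in a lattice state."""

    kind: str  # initiate | scan | bind_tc | join_60s | elongate | terminate
    rate: float
    ribosome_index: int | None = None


def _elongation_rate_array(params: SimParams, layout: MrnaLayout) -> np.ndarray:
    """Propensity of the 3-nt elongation step for each lattice position."""
    rate = np.full(layout.total_length + 2, params.codon_rates.mean_sense_rate)
    his = params.codon_rates.his_rate * params.his_fold
    if his <= 0:
        raise ValueError("histidine codon rate must stay positive")
    for p in layout.his_codon_positions:
        rate[p] = his
    return rate


def _start_positions(layout: MrnaLayout) -> dict[int, int]:
    """Map start-codon position -> ORF id."""
    return {layout.uorf1_start: 0, layout.uorf4_start: 1, layout.gcn4_start: 2}


def _stop_first_nt(layout: MrnaLayout) -> tuple[int, int, int]:
    return (layout.uorf1_end - 2, layout.uorf4_end - 2, layout.gcn4_end - 2)


def propensities(
    state: Sequence[RibosomeState],
    params: SimParams,
    layout: MrnaLayout,
) -> list[Event]:
    """Enumerate the enabled reaction channels for a lattice state.

    ``state`` must be ordered 5'->3'-most last ... i.e. sorted by
    decreasing position (index 0 is the most downstream ribosome).  This
    is the readable reference implementation of the reaction scheme; the
    trajectory engine applies the same rules in a compiled loop.
    """
    f = params.footprint
    starts = _start_positions(layout)
    elong = _elongation_rate_array(params, layout)
    stop_rate = params.codon_rates.mean_stop_rate
    events: list[Event] = []
    positions = [r.position for r in state]
    for i in range(1, len(state)):
        if positions[i - 1] - positions[i] < f:
            raise ValueError(
                f"lattice invariant violated: ribosomes {i-1} and {i} "
                f"overlap ({positions[i-1]} vs {positions[i]})"
            )
    # 5'-initiation requires nt 1..footprint to be unoccupied
    if not state or state[-1].position >= f + 1:
        events.append(Event("initiate", params.a_I))
    for i, r in enumerate(state):
        gap_ok = lambda step: i == 0 or positions[i - 1] - r.position >= f + step
        if r.phase in _SCANNING_PHASES:
            committed = (
                r.phase is Phase.SCANNING_WITH_TC_PRE_UORF1
                and r.position == layout.uorf1_start
            ) or (
                r.phase is Phase.SCANNING_WITH_TC and r.position in starts
            )
            if committed:
                # commitment is resolved on arrival; a TC-holding scanner
                # sitting on a start codon only awaits its 60S subunit
                events.append(Event("join_60s", params.rate_60S, i))
            elif gap_ok(1):
                events.append(Event("scan", params.a_S, i))
            if r.phase is Phase.SCANNING_NO_TC:
                events.append(Event("bind_tc", params.a_TC, i))
        elif r.phase is Phase.AWAITING_60S:
            events.append(Event("join_60s", params.rate_60S, i))
        elif r.phase is Phase.ELONGATING:
            if gap_ok(3):
                events.append(Event("elongate", float(elong[r.position]), i))
        elif r.phase is Phase.TERMINATING:
            events.append(Event("terminate", stop_rate, i))
    return [e for e in events if e.rate > 0]


# ---------------------------------------------------------------------------
# trajectory engine
# ---------------------------------------------------------------------------

# output slots of the core loop
_NOUT = 20
(
    _O_OCC5, _O_OCC3, _O_P5FREE, _O_RATE_U1, _O_RATE_G, _O_VIOL,
    _O_NINIT, _O_NC0, _O_NC1, _O_NC2, _O_SCANOFF, _O_DROP_U1,
    _O_RESUME, _O_COMMIT_U4, _O_COMMIT_G, _O_FP_SUM, _O_FP_SSQ,
    _O_FP_N, _O_REMAIN, _O_NEVENTS,
) = range(_NOUT)


def _ssa_core(
    a_I, a_S, a_TC, rate_60S, p_resume, f,
    duration, burn_in,
    L, u1_start, u1_stop, u4_start, g_start, g_stop,
    boundary, elong_rate, term_rate,
    seed, max_events,
):
    np.random.seed(seed)
    M = L // f + 3
    pos = np.zeros(M, dtype=np.int64)
    phase = np.zeros(M, dtype=np.int64)
    orf = np.zeros(M, dtype=np.int64)
    load_t = np.zeros(M, dtype=np.float64)
    seen_u4 = np.zeros(M, dtype=np.int64)
    pa = np.zeros(M, dtype=np.float64)
    pb = np.zeros(M, dtype=np.float64)
    out = np.zeros(_NOUT, dtype=np.float64)
    stop0 = u1_stop
    stop1 = u4_start + 12  # uORFs are four sense codons + stop
    n = 0
    t = 0.0
    occ5 = 0
    occ3 = 0
    pos_max = L - f + 1
    while t < duration and out[_O_NEVENTS] < max_events:
        # propensities
        a0 = 0.0
        init_ok = (n == 0) or (pos[n - 1] >= f + 1)
        a_init = a_I if init_ok else 0.0
        a0 += a_init
        for i in range(n):
            ph = phase[i]
            ra = 0.0
            rb = 0.0
            if ph <= 2:
                if (i == 0) or (pos[i - 1] - pos[i] >= f + 1):
                    ra = a_S
                if ph == 1:
                    rb = a_TC
            elif ph == 3:
                ra = rate_60S
            elif ph == 4:
                if (i == 0) or (pos[i - 1] - pos[i] >= f + 3):
                    ra = elong_rate[pos[i]]
            else:
                ra = term_rate
            pa[i] = ra
            pb[i] = rb
            a0 += ra + rb
        if a0 <= 0.0:
            break
        r1 = np.random.random()
        while r1 <= 0.0:
            r1 = np.random.random()
        tau = -math.log(r1) / a0
        t_new = t + tau
        if t_new > duration:
            t_new = duration
        # accumulate time-weighted stats over the analysis window
        lo = t if t > burn_in else burn_in
        hi = t_new if t_new < duration else duration
        if hi > lo:
            w = hi - lo
            out[_O_OCC5] += occ5 * w
            out[_O_OCC3] += occ3 * w
            if init_ok:
                out[_O_P5FREE] += w
        t = t + tau
        if t >= duration:
            break
        out[_O_NEVENTS] += 1.0
        in_window = burn_in <= t <= duration
        u = np.random.random() * a0
        if u < a_init:
            # load a 43S complex at the 5' end
            pos[n] = 1
            phase[n] = 0
            orf[n] = -1
            load_t[n] = t
            seen_u4[n] = 0
            n += 1
            occ5 += 1
            out[_O_NINIT] += 1.0
            if u1_start == 1:
                phase[n - 1] = 3
                orf[n - 1] = 0
            continue
        u -= a_init
        target = -1
        is_b = False
        for i in range(n):
            if u < pa[i]:
                target = i
                break
            u -= pa[i]
            if u < pb[i]:
                target = i
                is_b = True
                break
            u -= pb[i]
        if target < 0:
            # numerical leak; skip
            continue
        i = target
        ph = phase[i]
        if is_b:
            phase[i] = 2  # TC re-acquired while scanning
            continue
        if ph <= 2:
            # scan one nucleotide (or fall off the 3' end)
            if pos[i] >= pos_max:
                # scanner reaches the lattice end without committing
                if pos[i] <= boundary:
                    occ5 -= 1
                else:
                    occ3 -= 1
                out[_O_SCANOFF] += 1.0
                for j in range(i, n - 1):
                    pos[j] = pos[j + 1]
                    phase[j] = phase[j + 1]
                    orf[j] = orf[j + 1]
                    load_t[j] = load_t[j + 1]
                    seen_u4[j] = seen_u4[j + 1]
                n -= 1
                continue
            old = pos[i]
            pos[i] = old + 1
            if old <= boundary < pos[i]:
                occ5 -= 1
                occ3 += 1
            if i > 0 and pos[i - 1] - pos[i] < f:
                out[_O_VIOL] += 1.0
            p = pos[i]
            if p == u4_start and seen_u4[i] == 0:
                seen_u4[i] = 1
                dt_fp = t - load_t[i]
                out[_O_FP_SUM] += dt_fp
                out[_O_FP_SSQ] += dt_fp * dt_fp
                out[_O_FP_N] += 1.0
            if phase[i] == 0 and p == u1_start:
                phase[i] = 3
                orf[i] = 0
            elif phase[i] == 2:
                if p == u4_start:
                    phase[i] = 3
                    orf[i] = 1
                    out[_O_COMMIT_U4] += 1.0
                elif p == g_start:
                    phase[i] = 3
                    orf[i] = 2
                    out[_O_COMMIT_G] += 1.0
            elif phase[i] == 1 and p == g_start:
                # bare arrival at the last start codon: dissociate
                if p <= boundary:
                    occ5 -= 1
                else:
                    occ3 -= 1
                out[_O_SCANOFF] += 1.0
                for j in range(i, n - 1):
                    pos[j] = pos[j + 1]
                    phase[j] = phase[j + 1]
                    orf[j] = orf[j + 1]
                    load_t[j] = load_t[j + 1]
                    seen_u4[j] = seen_u4[j + 1]
                n -= 1
        elif ph == 3:
            phase[i] = 4  # 60S joined, start elongating
        elif ph == 4:
            old = pos[i]
            pos[i] = old + 3
            if old <= boundary < pos[i]:
                occ5 -= 1
                occ3 += 1
            if i > 0 and pos[i - 1] - pos[i] < f:
                out[_O_VIOL] += 1.0
            if orf[i] == 0 and pos[i] == stop0:
                phase[i] = 5
            elif orf[i] == 1 and pos[i] == stop1:
                phase[i] = 5
            elif orf[i] == 2 and pos[i] == g_stop:
                phase[i] = 5
        else:
            # termination
            which = orf[i]
            if in_window:
                if which == 0:
                    out[_O_RATE_U1] += 1.0
                elif which == 2:
                    out[_O_RATE_G] += 1.0
            if which == 0:
                out[_O_NC0] += 1.0
            elif which == 1:
                out[_O_NC1] += 1.0
            else:
                out[_O_NC2] += 1.0
            if which == 0 and np.random.random() < p_resume:
                phase[i] = 1  # resume scanning TC-free from the stop codon
                orf[i] = -1
                out[_O_RESUME] += 1.0
            else:
                if which == 0:
                    out[_O_DROP_U1] += 1.0
                if pos[i] <= boundary:
                    occ5 -= 1
                else:
                    occ3 -= 1
                for j in range(i, n - 1):
                    pos[j] = pos[j + 1]
                    phase[j] = phase[j + 1]
                    orf[j] = orf[j + 1]
                    load_t[j] = load_t[j + 1]
                    seen_u4[j] = seen_u4[j + 1]
                n -= 1
    window = duration - burn_in
    out[_O_OCC5] /= window
    out[_O_OCC3] /= window
    out[_O_P5FREE] /= window
    out[_O_RATE_U1] /= window
    out[_O_RATE_G] /= window
    out[_O_REMAIN] = n
    return out


try:  # optional JIT acceleration; the pure-Python loop is the fallback
    from numba import njit as _njit

    _ssa_core_jit = _njit(cache=True)(_ssa_core)
except Exception:  # pragma: no cover - exercised only without numba
    _ssa_core_jit = _ssa_core


def _run_core(params: SimParams, layout: MrnaLayout, seed: int,
              max_events: float = 1e12) -> np.ndarray:
    elong = _elongation_rate_array(params, layout)
    stop_rate = params.codon_rates.mean_stop_rate
    return _ssa_core_jit(
        float(params.a_I), float(params.a_S), float(params.a_TC),
        float(params.rate_60S), float(params.p_resume_uorf1),
        int(params.footprint),
        float(params.duration), float(params.burn_in),
        int(layout.total_length), int(layout.uorf1_start),
        int(layout.uorf1_end - 2), int(layout.uorf4_start),
        int(layout.gcn4_start), int(layout.gcn4_end - 2),
        int(layout.section_boundary),
        elong.astype(np.float64),
        float(stop_rate),
        int(seed), float(max_events),
    )


_COUNTER_NAMES = {
    "initiations": _O_NINIT,
    "uorf1_completions": _O_NC0,
    "uorf4_completions": _O_NC1,
    "gcn4_completions": _O_NC2,
    "scan_offs": _O_SCANOFF,
    "uorf1_releases": _O_DROP_U1,
    "resumes": _O_RESUME,
    "uorf4_commits": _O_COMMIT_U4,
    "gcn4_commits": _O_COMMIT_G,
    "exclusion_violations": _O_VIOL,
    "first_passage_sum": _O_FP_SUM,
    "first_passage_sumsq": _O_FP_SSQ,
    "first_passage_count": _O_FP_N,
    "ribosomes_remaining": _O_REMAIN,
    "events": _O_NEVENTS,
}


def _summary_from_out(out: np.ndarray) -> TrajectorySummary:
    return TrajectorySummary(
        mean_occupancy_5p=float(out[_O_OCC5]),
        mean_occupancy_3p=float(out[_O_OCC3]),
        p_5prime_free=float(out[_O_P5FREE]),
        rate_uorf1=float(out[_O_RATE_U1]),
        rate_gcn4=float(out[_O_RATE_G]),
        counters={k: float(out[v]) for k, v in _COUNTER_NAMES.items()},
    )


def run_trajectory(
    params: SimParams, layout: MrnaLayout, seed: int | None = None
) -> TrajectorySummary:
    """Simulate one trajectory and return its time-averaged summary."""
    s = params.seed if seed is None else seed
    out = _run_core(params, layout, int(s) % (2**32 - 1))
    return _summary_from_out(out)


def run_replicates(
    params: SimParams, layout: MrnaLayout
) -> tuple[TrajectorySummary, pd.DataFrame]:
    """Average ``params.replicates`` independent trajectories.

    Per-trajectory seeds are spawned from the master seed, so the whole
    aggregate is reproducible bit-for-bit.  Returns the aggregate summary
    (mean with per-statistic replicate SD) and the tidy per-replicate
    table.
    """
    child_seeds = np.random.SeedSequence(params.seed).generate_state(
        params.replicates
    )
    rows = []
    for r, s in enumerate(child_seeds):
        summ = run_trajectory(params, layout, seed=int(s))
        row = {"replicate": r, "seed": int(s)}
        for name in TrajectorySummary.STAT_FIELDS:
            row[name] = getattr(summ, name)
        row.update(summ.counters)
        rows.append(row)
    df = pd.DataFrame(rows)
    means = {f: float(df[f].mean()) for f in TrajectorySummary.STAT_FIELDS}
    sds = {
        f: float(df[f].std(ddof=1)) if len(df) > 1 else 0.0
        for f in TrajectorySummary.STAT_FIELDS
    }
    counters = {
        k: float(df[k].mean()) for k in _COUNTER_NAMES if k in df.columns
    }
    agg = TrajectorySummary(
        **means, counters=counters, sd=sds, replicates=params.replicates
    )
    return agg, df


def _sweep_row(params: SimParams, layout: MrnaLayout, **meta) -> dict:
    agg, _ = run_replicates(params, layout)
    row = dict(meta)
    for name in TrajectorySummary.STAT_FIELDS:
        row[name] = getattr(agg, name)
        row[f"{name}_sd"] = agg.sd[name]
    row["gcn4_to_uorf1_ratio"] = (
        agg.rate_gcn4 / agg.rate_uorf1 if agg.rate_uorf1 > 0 else float("nan")
    )
    return row


def initiation_scan_sweep(
    params: SimParams,
    layout: MrnaLayout,
    a_I_grid: Iterable[float],
    a_S_grid: Iterable[float],
) -> pd.DataFrame:
    """Grid of summaries over 5'-initiation and scanning rates (other
    rates held fixed)."""
    rows = []
    for a_s in a_S_grid:
        for a_i in a_I_grid:
            p = replace(params, a_I=float(a_i), a_S=float(a_s))
            rows.append(_sweep_row(p, layout, a_I=float(a_i), a_S=float(a_s)))
    return pd.DataFrame(rows)


def joint_scaling_sweep(
    params: SimParams,
    layout: MrnaLayout,
    folds: Iterable[float],
    scale_tc: bool = True,
) -> pd.DataFrame:
    """Scale ``a_I`` and ``a_S`` together by each fold, holding their
    ratio constant.

    ``scale_tc`` also scales the TC binding rate so the per-nucleotide
    splitting probabilities (and hence the reinitiation pattern) are
    preserved; 60S joining, elongation and termination stay fixed.
    """
    rows = []
    for fold in folds:
        if fold <= 0:
            raise ValueError("folds must be positive")
        p = replace(
            params,
            a_I=params.a_I * fold,
            a_S=params.a_S * fold,
            a_TC=params.a_TC * fold if scale_tc else params.a_TC,
        )
        rows.append(_sweep_row(p, layout, fold=float(fold)))
    return pd.DataFrame(rows)


def tc_sweep(
    params: SimParams, layout: MrnaLayout, a_TC_grid: Iterable[float]
) -> pd.DataFrame:
    """Summaries over a grid of TC binding rates."""
    rows = []
    for a_tc in a_TC_grid:
        p = replace(params, a_TC=float(a_tc))
        rows.append(_sweep_row(p, layout, a_TC=float(a_tc)))
    return pd.DataFrame(rows)


def his_codon_sweep(
    params: SimParams, layout: MrnaLayout, fold_grid: Iterable[float]
) -> pd.DataFrame:
    """Summaries while the histidine-codon elongation rate is scaled by
    each fold (1 = replete; small folds emulate histidine starvation)."""
    rows = []
    for fold in fold_grid:
        if fold <= 0:
            raise ValueError("histidine-rate folds must be positive")
        p = replace(params, his_fold=float(fold))
        rows.append(_sweep_row(p, layout, his_fold=float(fold)))
    return pd.DataFrame(rows)
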