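"""Shared I/O: strict TSV schemas, codon-rate table parsing, run
manifests, and the headline regression/interpolation reports."""

from __future__ import annotations

import datetime as _dt
import json
from importlib import metadata as _metadata
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .analytic import model1_gcn4_with_uorf4_pct
from .layout import ConditionProfile, DEREPRESSING, REPRESSING
from .reference import MUTANT_DISTANCES, REPORTED_GCN4_PCT
from .ssa import CodonRateTable, SENSE_CODONS, STOP_CODONS

__all__ = [
    "read_observed_tsv",
    "write_tidy_tsv",
    "read_codon_table",
    "write_manifest",
    "table2_report",
    "loading_ratio_report",
]

OBSERVED_COLUMNS = ("construct_class", "n1", "n2", "condition", "observed_pct")


class ParseError(ValueError):
    """Raised for malformed input files, with line/column context."""


def write_tidy_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy long-format table as tab-separated text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_observed_tsv(path: str | Path) -> pd.DataFrame:
    """Read an observed-reinitiation dataset (header required).

    Columns: construct_class, n1, n2, condition, observed_pct.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in OBSERVED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: observed dataset missing required columns {missing}"
        )
    for col in ("n1", "n2"):
        if (df[col] < 0).any():
            raise ParseError(f"{path}: column {col} contains negative distances")
    if ((df["observed_pct"] < 0) | (df["observed_pct"] > 110)).any():
        raise ParseError(
            f"{path}: observed_pct outside [0, 110] "
            "(measurement noise may exceed 100, but not by that much)"
        )
    return df


def read_codon_table(path: str | Path) -> CodonRateTable:
    """Parse a whitespace-delimited codon-rate table.

    Each non-comment line is ``CODON RATE`` with an optional third field
    ``STOP`` flagging termination entries (the stop codons UAA/UAG/UGA are
    recognised without the flag as well).  Codons use the RNA alphabet;
    DNA-style ``T`` is accepted and converted.  All 61 sense codons must
    be present.
    """
    rates: dict[str, float] = {}
    stop_rates: dict[str, float] = {}
    for lineno, raw in enumerate(
        Path(path).read_text().splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 'CODON RATE [STOP]', got {raw!r}"
            )
        codon = parts[0].upper().replace("T", "U")
        if len(codon) != 3 or any(b not in "ACGU" for b in codon):
            raise ParseError(f"{path}:{lineno}: invalid codon {parts[0]!r}")
        try:
            rate = float(parts[1])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: rate {parts[1]!r} is not a number"
            ) from None
        if rate <= 0:
            raise ParseError(f"{path}:{lineno}: rate must be positive")
        is_stop = (len(parts) == 3 and parts[2].upper() == "STOP") or (
            codon in STOP_CODONS
        )
        target = stop_rates if is_stop else rates
        if codon in target:
            raise ParseError(f"{path}:{lineno}: duplicate entry for {codon}")
        target[codon] = rate
    missing = [c for c in SENSE_CODONS if c not in rates]
    if missing:
        raise ParseError(
            f"{path}: table missing {len(missing)} sense codon(s): "
            f"{', '.join(missing[:8])}{' ...' if len(missing) > 8 else ''}"
        )
    if not stop_rates:
        raise ParseError(f"{path}: no stop-codon (termination) entry found")
    return CodonRateTable(rates=rates, stop_rates=stop_rates)


def write_manifest(
    path: str | Path,
    parameters: dict,
    master_seed: int,
    replicate_seeds: Sequence[int] = (),
    outputs: Sequence[str] = (),
) -> dict:
    """Write a JSON run manifest sufficient to reproduce the outputs."""
    try:
        version = _metadata.version("gcn4sim")
    except _metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "tool": "gcn4sim",
        "version": version,
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "master_seed": int(master_seed),
        "replicate_seeds": [int(s) for s in replicate_seeds],
        "parameters": parameters,
        "outputs": list(outputs),
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def table2_report(
    condition_profiles: Iterable[ConditionProfile] = (DEREPRESSING, REPRESSING),
    mutants: Sequence[tuple[int, int]] = MUTANT_DISTANCES,
) -> pd.DataFrame:
    """Recompute the spacing-mutant main-ORF reinitiation predictions and
    compare them with the packaged reported values.

    One row per (mutant, condition); ``predicted_pct`` is the freshly
    computed ``100 (P2 + P3)``, alongside the reported measured and
    predicted percentages and the relative deviation from the latter.
    """
    known = {
        (cond, d): (measured, predicted)
        for cond, cells in REPORTED_GCN4_PCT.items()
        for d, (measured, predicted) in zip(MUTANT_DISTANCES, cells)
    }
    rows = []
    for profile in condition_profiles:
        for n1, n2 in mutants:
            pred = model1_gcn4_with_uorf4_pct(profile.rates, n1, n2)
            measured, reported = known.get((profile.label, (n1, n2)), (np.nan, np.nan))
            rows.append(
                {
                    "condition": profile.label,
                    "n1": n1,
                    "n2": n2,
                    "predicted_pct": pred,
                    "reported_measured_pct": measured,
                    "reported_predicted_pct": reported,
                    "relative_deviation": (
                        (pred - reported) / reported
                        if np.isfinite(reported) and reported != 0
                        else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def loading_ratio_report(
    sweep: pd.DataFrame,
    ratio_col: str = "ratio",
    occupancy_col: str = "mean_occupancy_5p",
    levels: tuple[float, float] = (1.0, 2.0),
) -> pd.DataFrame:
    """Interpolate the initiation/scanning-rate ratios at which the mean
    5'-occupancy crosses the given levels and report their fold change.

    Linear interpolation between grid points of an occupancy-vs-ratio
    sweep; a level the sweep never reaches is flagged as not crossed.
    """
    df = sweep.sort_values(ratio_col).reset_index(drop=True)
    x = df[ratio_col].to_numpy(dtype=float)
    y = df[occupancy_col].to_numpy(dtype=float)
    rows = []
    crossings: dict[float, float] = {}
    for level in levels:
        at = np.nan
        for i in range(len(x) - 1):
            y0, y1 = y[i], y[i + 1]
            if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
                at = x[i] + (level - y0) * (x[i + 1] - x[i]) / (y1 - y0)
                break
        if np.isnan(at) and np.any(np.isclose(y, level)):
            at = float(x[np.argmin(np.abs(y - level))])
        crossings[level] = at
        rows.append(
            {
                "occupancy_level": level,
                "ratio_at_level": at,
                "crossed": bool(np.isfinite(at)),
            }
        )
    out = pd.DataFrame(rows)
    lo, hi = (crossings[level] for level in levels)
    out["fold_change"] = (
        hi / lo if np.isfinite(lo) and np.isfinite(hi) and lo != 0 else np.nan
    )
    return out
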