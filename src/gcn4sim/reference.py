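"""Packaged literature reference values used by regression reports.

The four *GCN4-lacZ* spacing mutants probed experimentally, with the
reported measured and two-factor-model predicted main-ORF reinitiation
percentages under derepressing (DR) and repressing (R) conditions.  These
constants back the regression report that recomputes the predictions from
the packaged condition rate sets and shows the relative deviations.
"""

from __future__ import annotations

#: (n1, n2) for spacing mutants 1-4.
MUTANT_DISTANCES: tuple[tuple[int, int], ...] = (
    (32, 151),
    (32, 294),
    (200, 100),
    (200, 150),
)

#: Reported main-ORF reinitiation percentages, keyed by condition label;
#: per mutant: (measured, predicted).
REPORTED_GCN4_PCT: dict[str, tuple[tuple[float, float], ...]] = {
    "derepressing": ((38.8, 48.4), (55.4, 68.3), (13.7, 13.9), (27.9, 18.5)),
    "repressing": ((14.1, 17.6), (30.3, 21.8), (1.23, 0.0115), (2.81, 0.0121)),
}
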