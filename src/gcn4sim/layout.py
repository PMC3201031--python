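"""mRNA architecture and kinetic-parameter containers.

The *GCN4* mRNA is represented as a linear lattice of nucleotides carrying
two short upstream ORFs (uORF1 and uORF4, four sense codons plus a stop
each) followed by the main *GCN4* coding sequence.  All coordinates are
1-based and inclusive: a feature's ``start`` is the first nucleotide of its
start codon and its ``end`` the last nucleotide of its stop codon.  The two
intercistronic distances that govern reinitiation control are

* ``n1`` -- nucleotides strictly between the uORF1 stop codon and the uORF4
  start codon,
* ``n2`` -- nucleotides strictly between the uORF4 stop codon and the
  *GCN4* start codon.

Kinetic rates are carried on a common nt/s scale: each rate is the
per-second propensity of one elementary event (a 1-nt scanning step, or a
binding event), so ratios such as ``a_TC / a_S`` can be read directly as
binding-versus-scanning competition odds.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

import yaml

__all__ = [
    "MrnaLayout",
    "RateSet",
    "ConditionProfile",
    "ReporterActivities",
    "LayoutError",
    "UORF_LENGTH",
    "DEFAULT_LAYOUT",
    "REPRESSING",
    "DEREPRESSING",
    "REPRESSING_MODEL2",
    "DEREPRESSING_MODEL2",
    "condition_profile",
    "load_layout",
    "layout_from_distances",
    "intercistronic_distances",
]

#: Length of each uORF in nucleotides: four sense codons plus a stop codon.
UORF_LENGTH = 15


class LayoutError(ValueError):
    """Raised when an mRNA layout violates a structural invariant."""


@dataclass(frozen=True)
class MrnaLayout:
    """Coordinates of the two uORFs and the main ORF on a linear mRNA.

    ``section_boundary`` is the last nucleotide of the 5'-section used when
    summarising ribosome loading (the 5'-leader vs. the coding/3' region).
    ``his_codon_positions`` are the first nucleotides of the histidine
    codons inside the main ORF; these are the codons starved of charged
    tRNA under 3-AT treatment.
    """

    total_length: int
    uorf1_start: int
    uorf1_end: int
    uorf4_start: int
    uorf4_end: int
    gcn4_start: int
    gcn4_end: int
    section_boundary: int
    his_codon_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "his_codon_positions", tuple(self.his_codon_positions)
        )
        self.validate()

    def validate(self) -> None:
        order = (
            1, self.uorf1_start, self.uorf1_end, self.uorf4_start,
            self.uorf4_end, self.gcn4_start, self.gcn4_end,
        )
        names = (
            "1", "uorf1_start", "uorf1_end", "uorf4_start", "uorf4_end",
            "gcn4_start", "gcn4_end",
        )
        for (a, na), (b, nb) in zip(
            zip(order, names), zip(order[1:], names[1:])
        ):
            ok = a <= b if na == "1" else a < b
            if not ok:
                raise LayoutError(
                    f"feature order violated: require {na} < {nb}, "
                    f"got {a} and {b}"
                )
        if self.gcn4_end > self.total_length:
            raise LayoutError(
                f"gcn4_end {self.gcn4_end} exceeds total_length "
                f"{self.total_length}"
            )
        for name, s, e in (
            ("uORF1", self.uorf1_start, self.uorf1_end),
            ("uORF4", self.uorf4_start, self.uorf4_end),
        ):
            if e - s + 1 != UORF_LENGTH:
                raise LayoutError(
                    f"{name} spans {e - s + 1} nt; expected {UORF_LENGTH} "
                    "(four sense codons plus stop)"
                )
        if (self.gcn4_end - self.gcn4_start + 1) % 3 != 0:
            raise LayoutError("main ORF length is not a multiple of 3")
        if not (
            self.uorf4_end < self.section_boundary <= self.gcn4_end
            or self.section_boundary == self.gcn4_start - 1
        ):
            raise LayoutError(
                f"section_boundary {self.section_boundary} must lie "
                "strictly downstream of uORF4 and not beyond the main ORF"
            )
        for p in self.his_codon_positions:
            if not (self.gcn4_start <= p <= self.gcn4_end - 2):
                raise LayoutError(
                    f"histidine codon at {p} lies outside the main ORF"
                )
            if (p - self.gcn4_start) % 3 != 0:
                raise LayoutError(
                    f"histidine codon at {p} is out of frame with the "
                    f"main ORF start {self.gcn4_start}"
                )

    @property
    def n1(self) -> int:
        """Intercistronic distance uORF1 -> uORF4 (nt)."""
        return self.uorf4_start - self.uorf1_end - 1

    @property
    def n2(self) -> int:
        """Intercistronic distance uORF4 -> main ORF (nt)."""
        return self.gcn4_start - self.uorf4_end - 1


def intercistronic_distances(layout: MrnaLayout) -> tuple[int, int]:
    """Return ``(n1, n2)`` for a validated layout."""
    return layout.n1, layout.n2


#: Default layout: a 1534-nt mRNA whose 5'-section spans nt 1-555 and whose
#: main ORF occupies nt 556-1398, with the natural spacings n1 = 200 and
#: n2 = 151 and four in-frame histidine codons spread over the main ORF.
DEFAULT_LAYOUT = MrnaLayout(
    total_length=1534,
    uorf1_start=175,
    uorf1_end=189,
    uorf4_start=390,
    uorf4_end=404,
    gcn4_start=556,
    gcn4_end=1398,
    section_boundary=555,
    his_codon_positions=(700, 901, 1066, 1240),
)


def layout_from_distances(
    n1: int,
    n2: int,
    *,
    uorf1_start: int = DEFAULT_LAYOUT.uorf1_start,
    gcn4_length: int | None = None,
    trailer: int | None = None,
) -> MrnaLayout:
    """Synthesize a layout with prescribed intercistronic distances.

    The uORF1 position, main-ORF length and 3'-trailer length are taken
    from the default layout unless overridden; only the spacings move.
    """
    if n1 < 0 or n2 < 0:
        raise LayoutError("intercistronic distances must be non-negative")
    if gcn4_length is None:
        gcn4_length = DEFAULT_LAYOUT.gcn4_end - DEFAULT_LAYOUT.gcn4_start + 1
    if trailer is None:
        trailer = DEFAULT_LAYOUT.total_length - DEFAULT_LAYOUT.gcn4_end
    uorf1_end = uorf1_start + UORF_LENGTH - 1
    uorf4_start = uorf1_end + n1 + 1
    uorf4_end = uorf4_start + UORF_LENGTH - 1
    gcn4_start = uorf4_end + n2 + 1
    gcn4_end = gcn4_start + gcn4_length - 1
    # keep the his codons at the same in-frame offsets into the main ORF
    his = tuple(
        gcn4_start + (p - DEFAULT_LAYOUT.gcn4_start)
        for p in DEFAULT_LAYOUT.his_codon_positions
    )
    return MrnaLayout(
        total_length=gcn4_end + trailer,
        uorf1_start=uorf1_start,
        uorf1_end=uorf1_end,
        uorf4_start=uorf4_start,
        uorf4_end=uorf4_end,
        gcn4_start=gcn4_start,
        gcn4_end=gcn4_end,
        section_boundary=gcn4_start - 1,
        his_codon_positions=his,
    )


_COORD_KEYS = (
    "total_length", "uorf1_start", "uorf1_end", "uorf4_start", "uorf4_end",
    "gcn4_start", "gcn4_end", "section_boundary",
)


def load_layout(config_text: str) -> MrnaLayout:
    """Parse a YAML layout configuration into a validated :class:`MrnaLayout`.

    Two forms are accepted: a full coordinate set (flat keys named as the
    :class:`MrnaLayout` fields, plus optional ``his_codon_positions``), or
    the pair ``n1``/``n2`` from which coordinates are synthesized around
    the default architecture.
    """
    cfg = yaml.safe_load(_io.StringIO(config_text))
    if not isinstance(cfg, dict):
        raise LayoutError("layout config must be a mapping")
    if "n1" in cfg or "n2" in cfg:
        unknown = set(cfg) - {"n1", "n2", "uorf1_start"}
        if unknown:
            raise LayoutError(
                "distance-form config accepts only n1, n2 and uorf1_start; "
                f"unexpected keys: {sorted(unknown)}"
            )
        kw = {"uorf1_start": cfg["uorf1_start"]} if "uorf1_start" in cfg else {}
        return layout_from_distances(
            int(cfg.get("n1", DEFAULT_LAYOUT.n1)),
            int(cfg.get("n2", DEFAULT_LAYOUT.n2)),
            **kw,
        )
    missing = [k for k in _COORD_KEYS if k not in cfg]
    if missing:
        raise LayoutError(f"layout config missing keys: {missing}")
    his = tuple(int(p) for p in cfg.get("his_codon_positions", ()))
    return MrnaLayout(
        **{k: int(cfg[k]) for k in _COORD_KEYS},
        his_codon_positions=his,
    )


@dataclass(frozen=True)
class RateSet:
    """Scanning and factor-binding rates for the reinitiation models.

    ``a_S`` is the scanning rate, ``a_TC`` the ternary-complex binding rate
    and ``a_X`` the binding rate of the hypothetical extra factor required
    for main-ORF (but not uORF4) start-codon selection.  The derived
    quantities are the per-nucleotide competition probabilities of the
    embedded jump chain: at every scanning step the ribosome either
    advances or binds one of the factors still missing.
    """

    a_S: float
    a_TC: float
    a_X: float = 0.0

    def __post_init__(self) -> None:
        if self.a_S <= 0:
            raise ValueError("scanning rate a_S must be positive")
        if self.a_TC < 0 or self.a_X < 0:
            raise ValueError("binding rates must be non-negative")

    @property
    def p_s1(self) -> float:
        """P(scan) while carrying neither factor."""
        return self.a_S / (self.a_S + self.a_TC + self.a_X)

    @property
    def p_tc1(self) -> float:
        """P(bind TC first) while carrying neither factor."""
        return self.a_TC / (self.a_S + self.a_TC + self.a_X)

    @property
    def p_x1(self) -> float:
        """P(bind the extra factor first) while carrying neither factor."""
        return self.a_X / (self.a_S + self.a_TC + self.a_X)

    @property
    def p_s2(self) -> float:
        """P(scan) while carrying TC only (competes with the extra factor)."""
        return self.a_S / (self.a_S + self.a_X)

    @property
    def p_s3(self) -> float:
        """P(scan) while carrying the extra factor only (competes with TC)."""
        return self.a_S / (self.a_S + self.a_TC)

    def scaled(self, *, tc_fold: float = 1.0, x_fold: float = 1.0) -> "RateSet":
        """Return a copy with the binding rates rescaled."""
        return replace(
            self, a_TC=self.a_TC * tc_fold, a_X=self.a_X * x_fold
        )


@dataclass(frozen=True)
class ConditionProfile:
    """A labelled nutritional condition with its fitted rate set."""

    label: str
    rates: RateSet


_A_S_DEFAULT = 30.0

#: Two-factor model fits (amino-acid replete cells): TC binding 4.6% and
#: extra-factor binding 0.72% of the 30 nt/s scanning rate.
REPRESSING = ConditionProfile(
    "repressing", RateSet(_A_S_DEFAULT, 0.046 * _A_S_DEFAULT, 0.0072 * _A_S_DEFAULT)
)
#: Two-factor model fits (starved cells): TC binding 0.57%, extra factor 5.4%.
DEREPRESSING = ConditionProfile(
    "derepressing", RateSet(_A_S_DEFAULT, 0.0057 * _A_S_DEFAULT, 0.054 * _A_S_DEFAULT)
)
#: One-factor (TC-only) model fits used by the traffic simulator.
REPRESSING_MODEL2 = ConditionProfile(
    "repressing", RateSet(_A_S_DEFAULT, 0.045 * _A_S_DEFAULT, 0.0)
)
DEREPRESSING_MODEL2 = ConditionProfile(
    "derepressing", RateSet(_A_S_DEFAULT, 0.0066 * _A_S_DEFAULT, 0.0)
)


def condition_profile(label: str, model: str = "model1") -> ConditionProfile:
    """Look up the packaged fitted rates for a condition label."""
    table = {
        ("repressing", "model1"): REPRESSING,
        ("derepressing", "model1"): DEREPRESSING,
        ("repressing", "model2"): REPRESSING_MODEL2,
        ("derepressing", "model2"): DEREPRESSING_MODEL2,
    }
    try:
        return table[(label, model)]
    except KeyError:
        raise KeyError(
            f"unknown condition/model combination: {label!r}/{model!r}"
        ) from None


@dataclass(frozen=True)
class ReporterActivities:
    """lacZ-fusion reporter activities used to estimate reinitiation.

    ``a1`` is the activity of the construct carrying both uORF1 and uORF4,
    ``a2`` that of its pair with the uORF4 start codon mutated, and ``a3``
    that of the construct with both uORF start codons mutated.  ``a2_ref``
    and ``a3_ref`` are the activities of the wild-type-spacing reference
    pair used to normalise main-ORF reinitiation.
    """

    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    a2_ref: float = 1.0
    a3_ref: float = 1.0
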