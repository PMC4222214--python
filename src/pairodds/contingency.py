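"""Closed-form mathematics of the directed (asymmetric) odds ratio.

Two species observed over a set of surveys give a 2x2 presence table

==========  =========  ========
            B present  B absent
==========  =========  ========
A present   c          d
A absent    e          f
==========  =========  ========

The *directed* odds ratio for species A indicated by species B is the odds
of A's presence given that B is present, divided by A's marginal odds:

    OR(A | B) = (c/e) / ((c+d)/(e+f))

It measures how useful B is as an indicator of A (or of A's absence, when
the ratio is below 1), and in general differs from OR(B | A): a rare
species can strongly indicate a common one while the reverse indication is
weak. This is the quantity drawn as an arrow in an association diagram.
The classical symmetric odds ratio (the cross-product ratio c*f/(d*e)) is
also provided; it ignores how common each species is.

The directed OR is algebraically identical to the positive likelihood
ratio of a diagnostic test: treating B's presence as a "test" for A,
sensitivity/(1 - specificity) equals OR(A | B). Both forms are implemented
and the identity is verified exhaustively in the test suite.

Cells may be counts or percentages; only the proportions matter. Zero and
infinite ratios are returned as exact ``0.0`` and ``math.inf`` (they are
displayed specially, not corrected); an optional Haldane-Anscombe
continuity correction (+0.5 per cell) is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "PairContingency",
    "DirectedPair",
    "UndefinedOddsRatioError",
    "directed_odds_ratio",
    "symmetric_odds_ratio",
    "conditional_presence",
    "apply_or_to_baseline",
    "positive_likelihood_ratio",
]

Target = Literal["A", "B"]


class UndefinedOddsRatioError(ValueError):
    """The requested ratio is not defined for this table.

    Raised when the target species is absent from every survey or present
    in every survey (its marginal odds are 0 or infinite), when the
    predictor is never present (the conditional odds are 0/0), or for the
    0*inf form of the symmetric ratio.
    """


@dataclass(frozen=True)
class PairContingency:
    """2x2 presence table for an ordered species pair (A, B).

    ``c`` both present, ``d`` A only, ``e`` B only, ``f`` neither.
    Cells may be survey counts or percentages; they are normalised to
    proportions internally, so only ratios matter.
    """

    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        cells = (self.c, self.d, self.e, self.f)
        if any(x < 0 for x in cells):
            raise ValueError(f"negative cell in contingency table: {cells}")
        if not any(x > 0 for x in cells):
            raise ValueError("contingency table is empty (all cells zero)")

    @property
    def total(self) -> float:
        return self.c + self.d + self.e + self.f

    @property
    def prevalence_a(self) -> float:
        """Marginal presence proportion of species A."""
        return (self.c + self.d) / self.total

    @property
    def prevalence_b(self) -> float:
        """Marginal presence proportion of species B."""
        return (self.c + self.e) / self.total

    def continuity_corrected(self, add: float = 0.5) -> "PairContingency":
        """Haldane-Anscombe corrected copy (``add`` added to every cell)."""
        return PairContingency(self.c + add, self.d + add, self.e + add, self.f + add)

    def swapped(self) -> "PairContingency":
        """The same data with the species roles exchanged (A <-> B)."""
        return PairContingency(self.c, self.e, self.d, self.f)


@dataclass(frozen=True)
class DirectedPair:
    """An ordered association: ``predictor`` indicating ``target``."""

    predictor: str
    target: str

    def __post_init__(self) -> None:
        if self.predictor == self.target:
            raise ValueError("predictor and target must be distinct species")


def _cells(table: PairContingency, target: Target) -> tuple[float, float, float, float]:
    """Return (c, d, e, f) with the *target* playing the role of A."""
    if target == "A":
        return table.c, table.d, table.e, table.f
    if target == "B":
        t = table.swapped()
        return t.c, t.d, t.e, t.f
    raise ValueError(f"target must be 'A' or 'B', got {target!r}")


def _check_margins(c: float, d: float, e: float, f: float) -> None:
    n = c + d + e + f
    target_prev = (c + d) / n
    if target_prev == 0.0 or target_prev == 1.0:
        raise UndefinedOddsRatioError(
            f"target species has marginal presence {target_prev:.0%}; "
            "its odds ratio is undefined"
        )
    if c + e == 0.0:
        raise UndefinedOddsRatioError(
            "predictor species is never present; conditional odds are undefined"
        )


def directed_odds_ratio(
    table: PairContingency,
    target: Target = "A",
    *,
    continuity_correction: bool = False,
) -> float:
    """Directed odds ratio of the target species indicated by the other.

    For ``target="A"`` this is (c/e) / ((c+d)/(e+f)): the odds of A given
    B present, over A's marginal odds. Returns exact ``0.0`` when the two
    species never co-occur (c = 0) and ``math.inf`` when the target is
    present in every survey where the predictor is (e = 0 with c > 0).

    Raises
    ------
    UndefinedOddsRatioError
        If the target is ubiquitous or absent everywhere, or the
        predictor is never present.
    """
    if continuity_correction:
        table = table.continuity_corrected()
    c, d, e, f = _cells(table, target)
    _check_margins(c, d, e, f)
    # (c/e) / ((c+d)/(e+f)) cross-multiplied to avoid intermediate 0/0
    num = c * (e + f)
    den = e * (c + d)
    if den == 0.0:
        return math.inf
    return num / den


def symmetric_odds_ratio(
    table: PairContingency, *, continuity_correction: bool = False
) -> float:
    """Classical symmetric (cross-product) odds ratio c*f / (d*e).

    Identical whichever species is taken first, and insensitive to how
    common each species is. Returns 0.0 / ``inf`` for a zero numerator /
    denominator with the other positive.

    Raises
    ------
    UndefinedOddsRatioError
        For the indeterminate 0/0 form (e.g. d = e = 0 with c, f > 0, or
        a species absent from every survey).
    """
    if continuity_correction:
        table = table.continuity_corrected()
    num = table.c * table.f
    den = table.d * table.e
    if num == 0.0 and den == 0.0:
        raise UndefinedOddsRatioError(
            "symmetric odds ratio is indeterminate (0/0) for this table"
        )
    if table.d == 0.0 and table.e == 0.0:
        # (c/d)/(e/f) is an inf/0 form even though c*f/(d*e) looks like c*f/0
        raise UndefinedOddsRatioError(
            "symmetric odds ratio is indeterminate (the two species perfectly "
            "co-occur: both off-diagonal cells are zero)"
        )
    if den == 0.0:
        return math.inf
    return num / den


def conditional_presence(table: PairContingency, target: Target = "A") -> float:
    """P(target present | predictor present).

    For ``target="A"`` this is c/(c+e); for ``target="B"``, c/(c+d).

    Raises
    ------
    UndefinedOddsRatioError
        If the predictor species is never present.
    """
    c, d, e, f = _cells(table, target)
    if c + e == 0.0:
        raise UndefinedOddsRatioError(
            "predictor species is never present; conditional presence undefined"
        )
    return c / (c + e)


def apply_or_to_baseline(odds_ratio: float, baseline: float) -> float:
    """Presence probability after applying an odds ratio to a baseline.

    Multiplies the odds implied by ``baseline`` by ``odds_ratio`` and
    converts back: logit^-1(logit(baseline) + ln(odds_ratio)). An odds
    ratio of 3 maps 10% -> 25%, 25% -> 50%, 50% -> 75%, 75% -> 90%; an
    odds ratio of 1/3 reverses each of those changes. This is how an
    estimated association translates into an interpretable change in
    percentage presence, and it can never leave (0, 1).
    """
    if not 0.0 < baseline < 1.0:
        raise ValueError(f"baseline must be strictly inside (0, 1), got {baseline}")
    if not odds_ratio > 0.0 or math.isinf(odds_ratio):
        raise ValueError(f"odds ratio must be finite and positive, got {odds_ratio}")
    odds = baseline / (1.0 - baseline) * odds_ratio
    return odds / (1.0 + odds)


def positive_likelihood_ratio(table: PairContingency, target: Target = "A") -> float:
    """Directed OR computed as a diagnostic positive likelihood ratio.

    Viewing the predictor's presence as a screening test for the target,
    this is sensitivity / (1 - specificity): for ``target="A"``,
    {c/(c+d)} / {e/(e+f)}. Algebraically equal to
    :func:`directed_odds_ratio` on every table where both are defined;
    the reciprocal is the analogous likelihood ratio for the target's
    absence, so one statistic serves indication and contraindication.
    """
    c, d, e, f = _cells(table, target)
    _check_margins(c, d, e, f)
    sensitivity = c / (c + d)  # P(test + | target +)
    one_minus_spec = e / (e + f)  # P(test + | target -)
    if one_minus_spec == 0.0:
        return math.inf
    return sensitivity / one_minus_spec
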