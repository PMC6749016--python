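"""Two-platform agreement statistics for variant and fusion call sets.

Events (one variant or fusion in one sample) from a *test* method are
cross-tabulated against a *reference* method over a shared sample scope.
Agreement is summarized by positive percent agreement (PPA = fraction of
reference-positive events also detected by the test method), negative
percent agreement (NPA, requiring an explicit panel of assayable targets to
define negatives), and the confirmation rate (fraction of test-positive
events corroborated by the reference).  All intervals are two-sided exact
binomial (Clopper-Pearson) confidence intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

from scipy.stats import beta as _beta

from .callset import CallSet, VariantKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConcordanceCounts:
    """Event tallies from one test-vs-reference cross-tabulation.

    ``n_neither`` (jointly negative sample x target pairs) is defined only
    when an assayable target panel was supplied.
    """

    n_both: int
    n_ref_only: int
    n_test_only: int
    n_neither: Optional[int] = None
    unit: str = "variant_event"

    def __post_init__(self) -> None:
        for name in ("n_both", "n_ref_only", "n_test_only"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_neither is not None and self.n_neither < 0:
            raise ValueError("n_neither must be non-negative")

    @property
    def n_ref_positive(self) -> int:
        return self.n_both + self.n_ref_only

    @property
    def n_test_positive(self) -> int:
        return self.n_both + self.n_test_only


@dataclass(frozen=True)
class ProportionWithCI:
    """A binomial proportion with its exact two-sided confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    conf_level: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError(
                f"require 0 <= ci_low <= point <= ci_high <= 1, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )

    def format_percent(self, decimals: int = 0, ci_decimals: Optional[int] = None) -> str:
        """Render as e.g. ``74%[67-80]`` (half-away-from-zero rounding).

        ``ci_decimals`` lets the interval print coarser than the point
        estimate (report tables show ``98.5%[95-100]``).
        """
        if ci_decimals is None:
            ci_decimals = decimals
        pt = _round_half_up(100 * self.point, decimals)
        lo = _round_half_up(100 * self.ci_low, ci_decimals)
        hi = _round_half_up(100 * self.ci_high, ci_decimals)
        return f"{pt}%[{lo}-{hi}]"


def _round_half_up(value: float, decimals: int) -> str:
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP)
    return str(d)


def round_percent(fraction: float, decimals: int = 0) -> float:
    """Percentage on the 0-100 scale, rounded half away from zero to the
    report's printed precision."""
    return float(_round_half_up(100 * fraction, decimals))


def exact_binomial_ci(x: int, n: int, conf_level: float = 0.95) -> tuple:
    """Two-sided Clopper-Pearson interval for ``x`` successes in ``n`` trials.

    Uses the beta-quantile closed form; the lower bound is 0 at ``x = 0``
    and the upper bound 1 at ``x = n``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    alpha = 1.0 - conf_level
    low = 0.0 if x == 0 else float(_beta.ppf(alpha / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(_beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return low, high


def proportion_with_ci(x: int, n: int, conf_level: float = 0.95) -> ProportionWithCI:
    low, high = exact_binomial_ci(x, n, conf_level)
    return ProportionWithCI(
        point=x / n, ci_low=low, ci_high=high,
        numerator=x, denominator=n, conf_level=conf_level,
    )


def cross_tabulate(
    test: CallSet,
    reference: CallSet,
    sample_ids: Iterable[str],
    unit: str = "variant_event",
    target_panel: Optional[Iterable] = None,
) -> ConcordanceCounts:
    """Cross-tabulate test vs reference events over a shared sample scope.

    ``unit`` selects variant events (``(sample, VariantKey)``) or fusion
    events (``(sample, canonical 5'/3' id)``).  When ``target_panel`` — the
    set of assayable keys — is given, jointly negative (sample, target)
    pairs are counted into ``n_neither`` so that NPA is defined.
    """
    scope = set(sample_ids)
    if not scope:
        raise ValueError("empty sample scope")
    test = test.restrict_to_samples(scope)
    reference = reference.restrict_to_samples(scope)
    if unit == "variant_event":
        test_ev, ref_ev = test.variant_events(), reference.variant_events()
    elif unit == "fusion_event":
        test_ev, ref_ev = test.fusion_events(), reference.fusion_events()
    else:
        raise ValueError(f"unknown unit {unit!r}")

    n_both = len(test_ev & ref_ev)
    n_ref_only = len(ref_ev - test_ev)
    n_test_only = len(test_ev - ref_ev)
    n_neither = None
    if target_panel is not None:
        panel = {_panel_key(k, unit) for k in target_panel}
        positive_pairs = {
            (s, _panel_key(k, unit)) for (s, k) in (test_ev | ref_ev)
        } & {(s, k) for s in scope for k in panel}
        n_neither = len(scope) * len(panel) - len(positive_pairs)
    return ConcordanceCounts(
        n_both=n_both, n_ref_only=n_ref_only, n_test_only=n_test_only,
        n_neither=n_neither, unit=unit,
    )


def _panel_key(key, unit: str):
    if unit == "variant_event" and isinstance(key, VariantKey):
        return key
    return str(key) if not isinstance(key, str) else key


def ppa(counts: ConcordanceCounts, conf_level: float = 0.95) -> ProportionWithCI:
    """Positive percent agreement: share of reference-positive events the
    test method also detected."""
    n = counts.n_ref_positive
    if n == 0:
        raise ZeroDivisionError("PPA undefined: no reference-positive events")
    return proportion_with_ci(counts.n_both, n, conf_level)


def confirmation(counts: ConcordanceCounts, conf_level: float = 0.95) -> ProportionWithCI:
    """Confirmation rate: share of test-positive events corroborated by the
    reference method."""
    n = counts.n_test_positive
    if n == 0:
        raise ZeroDivisionError("confirmation undefined: no test-positive events")
    return proportion_with_ci(counts.n_both, n, conf_level)


def npa(counts: ConcordanceCounts, conf_level: float = 0.95) -> ProportionWithCI:
    """Negative percent agreement over (sample, panel target) pairs.

    Requires ``n_neither``, i.e. a target panel at cross-tabulation time.
    """
    if counts.n_neither is None:
        raise ValueError(
            "NPA requires joint negatives: supply a target panel to cross_tabulate"
        )
    n = counts.n_neither + counts.n_test_only
    if n == 0:
        raise ZeroDivisionError("NPA undefined: no reference-negative pairs")
    return proportion_with_ci(counts.n_neither, n, conf_level)


def adjudicate_discordants(
    test: CallSet, reference: CallSet, truth: CallSet, unit: str = "fusion_event"
):
    """Resolve test/reference discordant events against a third (arbiter)
    method, e.g. qPCR.

    Returns a list of dicts with the event, which side called it, and the
    adjudication label: ``test_correct`` when the arbiter agrees with the
    test method, ``reference_correct`` when it agrees with the reference,
    ``unresolved`` when the arbiter did not assay the event's sample.
    """
    if unit == "fusion_event":
        test_ev, ref_ev, truth_ev = (
            test.fusion_events(), reference.fusion_events(), truth.fusion_events(),
        )
        truth_samples = {c.sample_id for c in truth.fusion_calls}
    else:
        test_ev, ref_ev, truth_ev = (
            test.variant_events(), reference.variant_events(), truth.variant_events(),
        )
        truth_samples = {c.sample_id for c in truth.variant_calls}

    table = []
    for sample, key in sorted(test_ev ^ ref_ev, key=lambda e: (e[0], str(e[1]))):
        in_test = (sample, key) in test_ev
        if sample not in truth_samples:
            label = "unresolved"
            logger.warning("discordant event %s:%s absent from arbiter calls", sample, key)
        else:
            truth_positive = (sample, key) in truth_ev
            correct_side_is_test = truth_positive == in_test
            label = "test_correct" if correct_side_is_test else "reference_correct"
        table.append(
            {
                "sample_id": sample,
                "key": str(key),
                "called_by": "test" if in_test else "reference",
                "adjudication": label,
            }
        )
    return table
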