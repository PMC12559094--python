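"""Exact paired sign tests across model variants.

Each model variant yields one metric value under condition A (e.g. the
balanced test set) and one under condition B (the random test set).  The
sign test counts the signs of the paired differences, drops ties, and refers
the larger sign count k out of m effective pairs to Binomial(m, 1/2):
p_two_sided = min(1, 2 * P(X >= k)), computed exactly.  With 8 variants all
moving the same way this gives p = 2 / 2^8 = 0.0078125, which prints as
0.008 at three decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import binom

__all__ = [
    "PairedSample",
    "SignTestResult",
    "AllTiesError",
    "sign_test",
    "compare_conditions",
    "format_p",
]


class AllTiesError(ValueError):
    """Raised when every pair is tied: no sign information to test."""


@dataclass
class PairedSample:
    """Metric values per variant under two conditions, index-aligned."""

    variant_names: list[str]
    values_a: list[float]
    values_b: list[float]

    def __post_init__(self) -> None:
        if not (len(self.variant_names) == len(self.values_a) == len(self.values_b)):
            raise ValueError("variant_names, values_a, values_b must be equal length")
        if len(self.variant_names) < 1:
            raise ValueError("need at least one pair")


@dataclass(frozen=True)
class SignTestResult:
    n_pos: int
    n_neg: int
    n_ties: int
    p_two_sided: float


def sign_test(sample: PairedSample) -> SignTestResult:
    """Exact two-sided sign test on paired differences (ties dropped)."""
    n_pos = n_neg = n_ties = 0
    for a, b in zip(sample.values_a, sample.values_b):
        d = a - b
        if d > 0:
            n_pos += 1
        elif d < 0:
            n_neg += 1
        else:
            n_ties += 1
    m = n_pos + n_neg
    if m == 0:
        raise AllTiesError("all pairs are tied")
    k = max(n_pos, n_neg)
    # exact upper tail: P(X >= k) for X ~ Binomial(m, 1/2)
    p = min(1.0, 2.0 * float(binom.sf(k - 1, m, 0.5)))
    return SignTestResult(n_pos=n_pos, n_neg=n_neg, n_ties=n_ties, p_two_sided=p)


def compare_conditions(
    reports_a: Mapping[str, Mapping[str, float]],
    reports_b: Mapping[str, Mapping[str, float]],
    metric_names: Sequence[str],
) -> list[dict]:
    """One sign test per metric across variants shared by two condition reports.

    ``reports_*`` map variant name -> {metric name -> value}.  Returns table
    rows with keys metric, n_pos, n_neg, n_ties, p; a metric where every pair
    ties gets p = None and note = "not testable (all ties)".
    """
    if set(reports_a) != set(reports_b):
        raise ValueError(
            f"variant mismatch between conditions: {sorted(set(reports_a) ^ set(reports_b))}"
        )
    variants = sorted(reports_a)
    rows: list[dict] = []
    for metric in metric_names:
        sample = PairedSample(
            variant_names=list(variants),
            values_a=[reports_a[v][metric] for v in variants],
            values_b=[reports_b[v][metric] for v in variants],
        )
        try:
            res = sign_test(sample)
            rows.append(
                {
                    "metric": metric,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "n_ties": res.n_ties,
                    "p": res.p_two_sided,
                    "note": "",
                }
            )
        except AllTiesError:
            rows.append(
                {
                    "metric": metric,
                    "n_pos": 0,
                    "n_neg": 0,
                    "n_ties": len(variants),
                    "p": None,
                    "note": "not testable (all ties)",
                }
            )
    return rows


def format_p(p: float | None, decimals: int = 3) -> str:
    """Round a p-value for report display (0.0078125 -> '0.008')."""
    if p is None:
        return "n/a"
    return f"{p:.{decimals}f}"
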