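"""Channel ranking by the Welch two-sample t-test.

Each channel's spectral-entropy values are compared between the
alcoholic and control groups with the unequal-variance (Welch) t-test

    t = (x̄₁ − x̄₂) / sqrt(s₁²/n₁ + s₂²/n₂)

with unbiased sample variances and Welch–Satterthwaite degrees of
freedom. Channels are ranked by putting the statistically significant
ones (two-sided p < alpha) first and ordering each block by descending
|t|; ties break toward the lower channel index. A higher rank marks a
channel whose in-band complexity separates the groups more strongly.

A Kolmogorov–Smirnov normality diagnostic is provided for judging the
suitability of the t-test; it never gates the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import FeatureMatrix
from .errors import DegenerateSamplesError, GroupingError, SizeError


@dataclass
class TTestResult:
    """Welch t-test outcome for one channel."""

    t: float
    df: float
    p: float
    mean1: float
    mean2: float
    var1: float
    var2: float
    n1: int
    n2: int


def welch_t(x, y) -> TTestResult:
    """Welch's unequal-variance t-test, two-sided.

    Group 1 is ``x`` (alcoholic convention), group 2 is ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise SizeError(f"need >= 2 samples per group, got {n1} and {n2}")
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise DegenerateSamplesError("both sample variances are zero")
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (
        (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(
        t=float(t), df=float(df), p=float(p),
        mean1=float(m1), mean2=float(m2),
        var1=float(v1), var2=float(v2), n1=n1, n2=n2,
    )


@dataclass
class RankResult:
    """Per-channel test outcomes and the induced channel ordering."""

    order: np.ndarray  # permutation of 0..n_channels-1, best channel first
    per_channel: list[TTestResult]
    significant: np.ndarray  # boolean mask indexed by channel, p < alpha
    alpha: float
    channel_names: list[str]

    def to_table(self, electrode_names: list[str] | None = None) -> pd.DataFrame:
        """Rank table with 1-based channel numbers, best channel first."""
        rows = []
        for rank, ch in enumerate(self.order, start=1):
            res = self.per_channel[ch]
            row = {
                "rank": rank,
                "channel": int(ch) + 1,  # reported indices are 1-based
                "t": res.t,
                "p": res.p,
                "mean_alcoholic": res.mean1,
                "mean_control": res.mean2,
                "significant": bool(self.significant[ch]),
            }
            if electrode_names is not None:
                row["electrode"] = electrode_names[ch]
            else:
                row["electrode"] = self.channel_names[ch]
            rows.append(row)
        return pd.DataFrame(rows)


def rank_channels(
    fm: FeatureMatrix, alpha: float = 0.05, order_by: str = "t"
) -> RankResult:
    """Rank channels by group separability of their SE values.

    Ordering: significant channels (p < ``alpha``) before non-significant
    ones; within each block descending |t| (``order_by="t"``, the default)
    or descending |mean difference| (``order_by="mean_gap"``); remaining
    ties broken by ascending channel index.
    """
    if order_by not in ("t", "mean_gap"):
        raise ValueError(f"order_by must be 't' or 'mean_gap', got {order_by!r}")
    alco = fm.group_values("alcoholic")
    ctrl = fm.group_values("control")
    if alco.shape[0] < 2 or ctrl.shape[0] < 2:
        raise GroupingError(
            "both groups must be present with >= 2 epochs each "
            f"(got {alco.shape[0]} alcoholic, {ctrl.shape[0]} control)"
        )
    per_channel = [welch_t(alco[:, c], ctrl[:, c]) for c in range(fm.n_channels)]
    significant = np.asarray([r.p < alpha for r in per_channel], dtype=bool)

    def key(ch: int):
        res = per_channel[ch]
        score = abs(res.t) if order_by == "t" else abs(res.mean1 - res.mean2)
        return (not significant[ch], -score, ch)

    order = np.asarray(sorted(range(fm.n_channels), key=key), dtype=int)
    return RankResult(
        order=order,
        per_channel=per_channel,
        significant=significant,
        alpha=alpha,
        channel_names=list(fm.channel_names),
    )


def ks_normality(values) -> tuple[float, float]:
    """One-sample KS statistic against a normal fitted to the sample.

    The normal's mean and standard deviation are estimated from the data,
    so the returned p-value is anti-conservative (the Lilliefors caveat);
    this is reported as a diagnostic only and never gates the pipeline.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise SizeError(f"need >= 5 samples for the KS diagnostic, got {values.size}")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateSamplesError("constant sample: normality test undefined")
    stat, p = stats.kstest(values, "norm", args=(values.mean(), sd))
    return float(stat), float(p)
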