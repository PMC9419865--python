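"""Group-comparison statistics for the pipeline's summary tables.

The study design compares each readout between two substrates with a
paired t-test; an unpaired (Welch) alternative is provided for designs
where pairing is not defensible, plus an optional Holm step-down
correction across a family of comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import InvalidParameterError

__all__ = ["GroupComparison", "compare_groups", "holm_correction"]


@dataclass
class GroupComparison:
    """Result of a two-group comparison.

    ``degenerate`` marks zero-variance inputs where the t statistic is
    not finite: identical paired samples give t = 0, p = 1; a constant
    nonzero difference gives p below machine precision.
    """

    statistic: float
    df: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool
    mean_diff: float
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidParameterError("p-value outside [0, 1]")


def compare_groups(a: Sequence[float], b: Sequence[float], paired: bool = True) -> GroupComparison:
    """Two-sided t-test between groups ``a`` and ``b``.

    paired : t = mean(d) / (SD(d)/sqrt(n)) on the differences d = a - b,
    df = n - 1.  Unpaired: Welch statistic with Welch-Satterthwaite df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise InvalidParameterError("paired test requires equal group sizes")
        if a.size < 2:
            raise InvalidParameterError("need n >= 2 per group")
        d = a - b
        n = d.size
        md = float(d.mean())
        sd = float(d.std(ddof=1))
        df = float(n - 1)
        if sd == 0.0:
            if md == 0.0:
                return GroupComparison(0.0, df, 1.0, n, n, True, 0.0, degenerate=True)
            t = np.inf if md > 0 else -np.inf
            return GroupComparison(float(t), df, np.nextafter(0.0, 1.0), n, n, True, md,
                                   degenerate=True)
        t = md / (sd / np.sqrt(n))
    else:
        if a.size < 2 or b.size < 2:
            raise InvalidParameterError("need n >= 2 per group")
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = a.size, b.size
        md = float(a.mean() - b.mean())
        se2 = va / na + vb / nb
        if se2 == 0.0:
            if md == 0.0:
                return GroupComparison(0.0, float(na + nb - 2), 1.0, na, nb, False, 0.0,
                                       degenerate=True)
            t = np.inf if md > 0 else -np.inf
            return GroupComparison(float(t), float(na + nb - 2), np.nextafter(0.0, 1.0),
                                   na, nb, False, md, degenerate=True)
        t = md / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        n, df = na, float(df)
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparison(float(t), float(df), float(min(p, 1.0)),
                           int(a.size), int(b.size), paired, md)


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
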