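"""Weighted resistant-vs-susceptible differential-expression calling.

The measure of differential expression for a gene at a time point is the
difference between its normalized expression (treatment x gene BLUPs) in
the resistant and susceptible breed lines, with the high sub-lines given
twice the weight of the low sub-lines (they carry more of the selection
signal):

    T0:  (2*RH0 + RL0)/3 - (2*SH0 + SL0)/3
    T1:  (2*RH1 + RL1)/3 - (2*SH1 + SL1)/3
    T2:  RH2 - SH2            (no low sub-line samples exist at T2)

A measure further than 2.58 empirical standard deviations from the mean of
all gene measures at that time point is called significant (two-sided
P < 0.01 under normality).  The chance-call summary reports how many calls
alpha would produce among independent null tests and the implied
false-positive rate among the calls actually made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: contrast weights per time point, reconstructed from the double-weighting
#: of the high sub-lines; positive side = resistant line.
CONTRASTS: dict[str, dict[str, float]] = {
    "T0": {"RH0": 2 / 3, "RL0": 1 / 3, "SH0": -2 / 3, "SL0": -1 / 3},
    "T1": {"RH1": 2 / 3, "RL1": 1 / 3, "SH1": -2 / 3, "SL1": -1 / 3},
    "T2": {"RH2": 1.0, "SH2": -1.0},
}


class ContrastConfigError(ValueError):
    pass


@dataclass
class DECallSummary:
    n_tests: int
    alpha: float
    n_de: dict[str, int]
    expected_chance_calls: int
    fpr_percent: dict[str, int]


def weighted_contrast(normalized: pd.DataFrame, time: str) -> pd.Series:
    """Per-gene DE measure (log2 units) at one time point."""
    if time not in CONTRASTS:
        raise ContrastConfigError(f"unknown time point {time!r}; expected one of "
                                  f"{sorted(CONTRASTS)}")
    weights = CONTRASTS[time]
    missing = [t for t in weights if t not in normalized.columns]
    if missing:
        raise ContrastConfigError(
            f"normalized expression lacks treatment column(s) {missing} needed for {time}")
    measure = sum(w * normalized[t] for t, w in weights.items())
    measure.name = f"de_{time}"
    return measure


def significance_threshold(alpha: float = 0.01) -> float:
    """Two-sided normal critical value, rounded to two decimals (2.58 at 0.01)."""
    return round(float(stats.norm.ppf(1 - alpha / 2)), 2)


def fold_change(de: np.ndarray | pd.Series) -> np.ndarray:
    """Signed ratio convention: 2**de for up, negative reciprocal for down
    (a de of -0.6 reports as about -1.52-fold)."""
    de = np.asarray(de, dtype=float)
    return np.where(de >= 0, 2.0 ** de, -(2.0 ** (-de)))


def call_significant(
    de_measures: dict[str, pd.Series] | pd.DataFrame,
    alpha: float = 0.01,
    pooled: bool = False,
) -> pd.DataFrame:
    """Standardize DE measures and flag genes beyond the critical value.

    By default the mean and SD are taken over genes within each time point;
    ``pooled=True`` standardizes against the measures of all three time
    points combined.
    """
    if isinstance(de_measures, dict):
        de_measures = pd.DataFrame(de_measures)
    if len(de_measures) < 10:
        raise ValueError("need at least 10 genes to estimate the SD of the measures")
    thr = significance_threshold(alpha)

    if pooled:
        allv = de_measures.to_numpy().ravel()
        mu, sd = float(np.mean(allv)), float(np.std(allv, ddof=1))
    frames = []
    for time in de_measures.columns:
        m = de_measures[time]
        if not pooled:
            mu, sd = float(m.mean()), float(m.std(ddof=1))
        if sd == 0:
            warnings.warn(f"zero SD of DE measures at {time}; nothing called",
                          stacklevel=2)
            z = pd.Series(0.0, index=m.index)
        else:
            z = (m - mu) / sd
        frames.append(pd.DataFrame({
            "gene_id": m.index, "time": str(time).replace("de_", ""),
            "de_measure": m.to_numpy(), "z": z.to_numpy(),
            "fold_change": fold_change(m.to_numpy()),
            "significant": np.abs(z.to_numpy()) > thr}))
    return pd.concat(frames, ignore_index=True)


def chance_call_summary(n_tests: int, alpha: float,
                        n_de: dict[str, int]) -> DECallSummary:
    """Expected chance calls and per-time false-positive rate.

    expected = round(n_tests * alpha); FPR_t = 100 * expected / n_de_t as a
    rounded percent, capped at 100.
    """
    expected = int(round(n_tests * alpha))
    fpr = {}
    for time, n in n_de.items():
        if n < 1:
            raise ValueError(f"n_de for {time} must be >= 1")
        fpr[time] = min(int(round(100.0 * expected / n)), 100)
    return DECallSummary(n_tests=n_tests, alpha=alpha, n_de=dict(n_de),
                         expected_chance_calls=expected, fpr_percent=fpr)


def overlap_sets(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of significant genes shared between time points (Venn-style)."""
    sets = {t: set(g["gene_id"][g["significant"]])
            for t, g in calls.groupby("time")}
    times = sorted(sets)
    out = {t: len(sets[t]) for t in times}
    for i, a in enumerate(times):
        for b in times[i + 1:]:
            out[f"{a}&{b}"] = len(sets[a] & sets[b])
    if len(times) >= 3:
        inter = set.intersection(*sets.values())
        out["&".join(times)] = len(inter)
    out["union"] = len(set.union(*sets.values())) if sets else 0
    return out
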