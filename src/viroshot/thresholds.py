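"""E-value threshold sensitivity analysis of top-hit compositions.

Given one top hit per query, these operations compute (a) the composition
of significant hits among collapsed source groups (virus / prokaryote /
eukaryote by default) as a running function of the E-value threshold,
together with the cumulative fraction of queries significant at each
threshold; (b) the same composition within half-open decade bins
[10^k, 10^(k+1)); and (c) the adjacent decade pair across which the summed
virus + prokaryote proportion falls the most -- an empirical "break point"
beyond which hit quality degrades.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .annotation import filter_significant

#: Default collapse of raw source categories into plotted groups. Mobile
#: elements are kept as their own group rather than folded into viruses;
#: metagenome-derived and unknown categories are not collapsed and are
#: excluded from the composition (they have no taxonomic assignment).
DEFAULT_COLLAPSE = {
    "bacteriophage": "virus",
    "eukaryotic_virus": "virus",
    "bacteria": "prokaryote",
    "archaea": "prokaryote",
    "eukaryote": "eukaryote",
    "mobile_element": "mobile",
}

#: Decade thresholds 1e-10 ... 1e-1, descending (loosest first).
DEFAULT_THRESHOLDS = tuple(10.0 ** -k for k in range(1, 11))


@dataclass
class ThresholdSweep:
    thresholds: tuple[float, ...]          # descending E-values
    proportions: tuple[dict[str, float], ...]
    cumulative_fraction: tuple[float, ...]
    n_queries: int
    groups: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, props, cum in zip(
            self.thresholds, self.proportions, self.cumulative_fraction
        ):
            rows.append({"threshold": t, **props, "cumulative_fraction": cum})
        return pd.DataFrame(rows)


@dataclass
class BinnedDistribution:
    bins: tuple[tuple[float, float], ...]  # ascending decade intervals
    counts: tuple[dict[str, int], ...]     # raw source-category counts
    proportions: tuple[dict[str, float], ...]
    n_out_of_range: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (lo, hi), cnt, props in zip(self.bins, self.counts, self.proportions):
            rows.append(
                {"bin_lo": lo, "bin_hi": hi, "n": sum(cnt.values()), **props}
            )
        return pd.DataFrame(rows)


def sweep_thresholds(
    top_hits: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    collapse: dict[str, str] = DEFAULT_COLLAPSE,
    n_queries: int | None = None,
) -> ThresholdSweep:
    """Composition of significant top hits as a function of threshold.

    At each threshold t the proportions are computed over top hits with
    E-value <= t whose category collapses into one of the groups; they sum
    to 1 whenever any such hit exists. ``cumulative_fraction`` is the
    fraction of all queries (denominator ``n_queries``, default the
    distinct queries in the table) whose top hit is significant at t.
    """
    if len(thresholds) == 0:
        raise ValueError("threshold list must be non-empty")
    thresholds = tuple(sorted(set(float(t) for t in thresholds), reverse=True))
    groups = tuple(dict.fromkeys(collapse.values()))
    n_table = top_hits["query_id"].nunique() if not top_hits.empty else 0
    total = n_table if n_queries is None else int(n_queries)
    props_out, cum_out = [], []
    for t in thresholds:
        sig = filter_significant(top_hits, t)
        grouped = sig["source_category"].map(collapse).dropna()
        denom = len(grouped)
        props = {g: 0.0 for g in groups}
        if denom:
            for g, n in grouped.value_counts().items():
                props[g] = n / denom
        props_out.append(props)
        cum_out.append(len(sig) / total if total else 0.0)
    return ThresholdSweep(
        thresholds=thresholds,
        proportions=tuple(props_out),
        cumulative_fraction=tuple(cum_out),
        n_queries=total,
        groups=groups,
    )


def _decade_of(evalue: float) -> int:
    k = math.floor(math.log10(evalue))
    # guard against log10 landing a hair below an exact decade edge
    if math.isclose(evalue, 10.0 ** (k + 1), rel_tol=1e-9):
        k += 1
    return k


def bin_by_decade(
    top_hits: pd.DataFrame, k_min: int, k_max: int
) -> BinnedDistribution:
    """Assign each top hit to its half-open decade bin [10^k, 10^(k+1)).

    Bins run from k_min to k_max - 1; an E-value exactly on an edge belongs
    to the bin whose lower edge it is (consistent with the inclusive
    significance boundary). Hits outside the range are counted in
    ``n_out_of_range`` and excluded.
    """
    if k_min >= k_max:
        raise ValueError("require k_min < k_max")
    ks = list(range(k_min, k_max))
    counts: list[dict[str, int]] = [dict() for _ in ks]
    n_out = 0
    for evalue, cat in zip(top_hits["evalue"], top_hits["source_category"]):
        k = _decade_of(float(evalue))
        if not k_min <= k < k_max:
            n_out += 1
            continue
        cnt = counts[k - k_min]
        cnt[cat] = cnt.get(cat, 0) + 1
    props = []
    for cnt in counts:
        tot = sum(cnt.values())
        props.append({c: n / tot for c, n in sorted(cnt.items())} if tot else {})
    return BinnedDistribution(
        bins=tuple((10.0 ** k, 10.0 ** (k + 1)) for k in ks),
        counts=tuple(counts),
        proportions=tuple(props),
        n_out_of_range=n_out,
    )


def detect_breakpoint(
    obj: ThresholdSweep | BinnedDistribution,
    categories: frozenset[str] = frozenset({"virus", "prokaryote"}),
    collapse: dict[str, str] = DEFAULT_COLLAPSE,
) -> tuple[float, float] | None:
    """Adjacent decade pair with the steepest drop in summed proportion.

    The series is ordered stringent to loose; the returned pair gives the
    stringent and loose labels (thresholds for a sweep, bin lower edges for
    a binned distribution) flanking the maximal decrease. Ties go to the
    most stringent pair; a series with no decrease returns None.
    """
    if isinstance(obj, ThresholdSweep):
        order = sorted(
            zip(obj.thresholds, obj.proportions), key=lambda x: x[0]
        )
        series = [
            (t, sum(p.get(g, 0.0) for g in categories)) for t, p in order
        ]
    elif isinstance(obj, BinnedDistribution):
        series = []
        for (lo, _hi), props in zip(obj.bins, obj.proportions):
            if not props:  # empty bin: no composition defined
                continue
            value = sum(
                v for c, v in props.items() if collapse.get(c) in categories
            )
            series.append((lo, value))
    else:
        raise TypeError(f"unsupported input {type(obj).__name__}")
    if len(series) < 2:
        raise ValueError("need at least two thresholds/bins")
    best_pair, best_drop = None, 0.0
    for (lab1, v1), (lab2, v2) in zip(series, series[1:]):
        drop = v1 - v2
        if drop > best_drop:
            best_pair, best_drop = (lab1, lab2), drop
    return best_pair


def viral_hit_ratio(count_a: int, count_b: int) -> float:
    """Ratio of two hit counts, rounded half-up to one decimal."""
    if count_b <= 0:
        raise ValueError("denominator count must be positive")
    return round_half_up(count_a / count_b, 1)
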