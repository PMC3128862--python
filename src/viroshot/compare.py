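"""Reciprocal, read-length-normalized comparison of shotgun libraries.

Two libraries are compared through cross-similarity searches run in both
directions. Three parameters summarize a pair: the percentage of reference
sequences with hits, the percentage of query-library sequences with hits,
and the reciprocal of hits per 100 (length-normalized) query sequences --
an inter-library distance. "Hit" always means a distinct query sequence
with at least one match at or below the E-value threshold, never raw HSP
rows.

``naive_cross_search`` provides a desk-scale stand-in for a translated
BLAST comparison: two reads match if they share an exact nucleotide word
of a minimum length on either strand, with a pseudo E-value monotone in
the longest shared word. Real search output in the same TSV dialect is
accepted interchangeably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._util import revcomp
from .annotation import HIT_COLUMNS
from .assembly import Read

DEFAULT_COMPARISON_THRESHOLD = 1e-5
DEFAULT_WORD_SIZE = 20


@dataclass(frozen=True)
class LibraryProfile:
    name: str
    n_sequences: int
    mean_read_length: float

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if self.mean_read_length <= 0:
            raise ValueError("mean_read_length must be positive")

    @classmethod
    def from_reads(cls, name: str, reads: list[Read]) -> "LibraryProfile":
        return cls(
            name=name,
            n_sequences=len(reads),
            mean_read_length=sum(r.length for r in reads) / len(reads),
        )


@dataclass(frozen=True)
class ComparisonResult:
    ref_name: str
    query_name: str
    evalue_threshold: float
    hits_in_ref: int        # query-library sequences with >=1 hit into ref
    hits_in_query: int      # ref sequences with >=1 hit into query
    pct_ref: float          # parameter 1: 100 * hits_in_ref / N_ref
    pct_query: float        # parameter 2: 100 * hits_in_query / N_query
    hits_per_100: float     # per 100 (length-normalized) query sequences
    distance: float         # parameter 3: 1 / hits_per_100 (inf if no hits)
    length_normalized: bool


def length_normalized_size(n: int, mean_len: float, ref_mean_len: float) -> float:
    """Effective library size after read-length normalization.

    A library whose mean read length is half the reference's counts as
    half its sequences: ``n * mean_len / ref_mean_len``.
    """
    if n <= 0 or mean_len <= 0 or ref_mean_len <= 0:
        raise ValueError("all inputs must be positive")
    return n * mean_len / ref_mean_len


def _n_hit_queries(hits: pd.DataFrame, threshold: float) -> int:
    if hits.empty:
        return 0
    sig = hits[hits["evalue"] <= threshold]
    return int(sig["query_id"].nunique())


def compare_pair(
    ref: LibraryProfile,
    query: LibraryProfile,
    hits_query_into_ref: pd.DataFrame,
    hits_ref_into_query: pd.DataFrame,
    threshold: float = DEFAULT_COMPARISON_THRESHOLD,
    length_normalized: bool = False,
) -> ComparisonResult:
    """Compute the three pairwise comparison parameters for one pair.

    ``hits_query_into_ref`` holds matches of query-library reads searched
    against the reference; ``hits_ref_into_query`` the reverse direction.
    With ``length_normalized`` the hits-per-100 denominator is the query
    library's length-normalized size relative to the reference's mean read
    length. Zero hits give an infinite distance sentinel, not an error.
    """
    hits_in_ref = _n_hit_queries(hits_query_into_ref, threshold)
    hits_in_query = _n_hit_queries(hits_ref_into_query, threshold)
    eff_n_query = (
        length_normalized_size(
            query.n_sequences, query.mean_read_length, ref.mean_read_length
        )
        if length_normalized
        else float(query.n_sequences)
    )
    hits_per_100 = 100.0 * hits_in_ref / eff_n_query
    return ComparisonResult(
        ref_name=ref.name,
        query_name=query.name,
        evalue_threshold=threshold,
        hits_in_ref=hits_in_ref,
        hits_in_query=hits_in_query,
        pct_ref=100.0 * hits_in_ref / ref.n_sequences,
        pct_query=100.0 * hits_in_query / query.n_sequences,
        hits_per_100=hits_per_100,
        distance=math.inf if hits_per_100 == 0 else 1.0 / hits_per_100,
        length_normalized=length_normalized,
    )


def rank_libraries(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Stable ascending ordering by distance; infinite sentinels sort last."""
    refs = {r.ref_name for r in results}
    if len(refs) > 1:
        raise ValueError(f"results reference multiple libraries: {sorted(refs)}")
    return sorted(results, key=lambda r: r.distance)


def naive_cross_search(
    query_reads: list[Read],
    target_reads: list[Read],
    word_size: int = DEFAULT_WORD_SIZE,
    target_name: str = "target",
) -> pd.DataFrame:
    """Exact shared-word search of one library against another.

    A query read hits a target read if they share an exact nucleotide word
    of length >= ``word_size`` on either strand. Each hit pair is reported
    once with its longest shared word L and a pseudo E-value
    ``1e-5 * 4**(word_size - L)``: monotone decreasing in L and equal to
    the conventional comparison threshold (1e-5) at the minimum word.
    Deterministic; a stand-in for translated BLAST at desk scale.
    """
    if word_size < 8:
        raise ValueError("word_size must be >= 8")
    index: dict[str, list[tuple[int, int]]] = {}
    for ti, t in enumerate(target_reads):
        s = t.sequence
        for i in range(len(s) - word_size + 1):
            index.setdefault(s[i:i + word_size], []).append((ti, i))

    best: dict[tuple[int, int], int] = {}
    for qi, q in enumerate(query_reads):
        for s in (q.sequence, revcomp(q.sequence)):
            n = len(s)
            for i in range(n - word_size + 1):
                for ti, j in index.get(s[i:i + word_size], ()):
                    tseq = target_reads[ti].sequence
                    if i > 0 and j > 0 and s[i - 1] == tseq[j - 1]:
                        continue  # not the start of a maximal run
                    length = word_size
                    while (
                        i + length < n
                        and j + length < len(tseq)
                        and s[i + length] == tseq[j + length]
                    ):
                        length += 1
                    key = (qi, ti)
                    if length > best.get(key, 0):
                        best[key] = length

    rows = []
    for (qi, ti), length in sorted(best.items()):
        q, t = query_reads[qi], target_reads[ti]
        rows.append(
            {
                "query_id": q.id,
                "subject_id": t.id,
                "percent_identity": 100.0,
                "evalue": 1e-5 * 4.0 ** (word_size - length),
                "bit_score": 2.0 * length,
                "database": target_name,
                "subject_description": f"{length} bp exact shared word with {t.id}",
                "source_category": "unknown",
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
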