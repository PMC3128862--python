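"""Tabular similarity-hit parsing, significance filtering and annotation.

Hit tables are tab-separated with one row per query-subject match and a
fixed header (see ``HIT_COLUMNS``). The phylogenetic source of each subject
is carried as a closed-vocabulary column (``source_category``), populated
by the synthetic generator or by a user's own curation; automated taxonomy
lookup against live databases is deliberately out of scope.

Virus-related hits are additionally flagged by a case-insensitive substring
match against a fixed eight-keyword list (phage, virus, capsid, tail,
integrase, base plate, baseplate, portal). Substring matching is permissive
by design ("cocktail" matches "tail"), so flagged hits are candidates to be
confirmed by the category column, mirroring a manual-verification workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "percent_identity",
    "evalue",
    "bit_score",
    "database",
    "subject_description",
    "source_category",
]

SOURCE_CATEGORIES = (
    "bacteriophage",
    "eukaryotic_virus",
    "mobile_element",
    "bacteria",
    "archaea",
    "eukaryote",
    "microbial_metagenome",
    "viral_metagenome",
    "unknown",
)

#: Categories counted as known viruses (excludes viral-metagenome reads,
#: whose taxonomic identity is itself unresolved).
KNOWN_VIRUS_CATEGORIES = frozenset({"bacteriophage", "eukaryotic_virus"})
ANY_VIRAL_CATEGORIES = KNOWN_VIRUS_CATEGORIES | {"viral_metagenome"}

VIRUS_KEYWORDS = (
    "phage",
    "virus",
    "capsid",
    "tail",
    "integrase",
    "base plate",
    "baseplate",
    "portal",
)

DEFAULT_EVALUE_THRESHOLD = 1e-3


@dataclass(frozen=True)
class HitRecord:
    """One query-subject similarity match."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bit_score: float
    database: str
    subject_description: str
    source_category: str

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValueError(f"evalue must be > 0, got {self.evalue}")
        if self.source_category not in SOURCE_CATEGORIES:
            raise ValueError(
                f"unknown source_category {self.source_category!r}"
            )


@dataclass(frozen=True)
class VirusSummary:
    """Any-hit virus bookkeeping over a set of queries."""

    n_any_viral_incl_metagenome: int
    n_known_virus: int
    n_phage: int
    n_eukaryotic_virus: int
    pct_phage: int | None
    pct_eukaryotic: int | None


def parse_hit_table(path) -> pd.DataFrame:
    """Read a hit TSV, validating the header and every row.

    Missing columns raise a ValueError naming the column. Malformed rows
    (non-positive or non-numeric E-value, category outside the vocabulary)
    are dropped with a logged warning giving the row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"query_id": str, "subject_id": str})
    for col in HIT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"hit table {path}: missing column {col!r}")
    df = df[HIT_COLUMNS]
    evalue = pd.to_numeric(df["evalue"], errors="coerce")
    bad = evalue.isna() | (evalue <= 0) | ~df["source_category"].isin(
        SOURCE_CATEGORIES
    )
    if bad.any():
        for row in df.index[bad]:
            logger.warning("hit table %s: rejected malformed row %d", path, row)
        df = df[~bad]
    df = df.assign(evalue=evalue[~bad] if bad.any() else evalue)
    return df.sort_values("query_id", kind="mergesort").reset_index(drop=True)


def filter_significant(
    hits: pd.DataFrame, threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> pd.DataFrame:
    """Retain hits with E-value <= threshold (inclusive boundary)."""
    return hits[hits["evalue"] <= threshold]


def top_hit_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: minimal E-value, ties broken by maximal bit
    score then lexicographically smallest subject id."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["query_id", "evalue", "bit_score", "subject_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return ordered.groupby("query_id", sort=True).head(1).reset_index(drop=True)


def keyword_virus_flag(description: str) -> tuple[bool, tuple[str, ...]]:
    """Case-insensitive substring match against the virus keyword list.

    Returns the flag and all matched keywords. Because matching is plain
    substring, flagged descriptions are candidates, not confirmations.
    """
    low = str(description).lower()
    matched = tuple(k for k in VIRUS_KEYWORDS if k in low)
    return (bool(matched), matched)


def annotate_keywords(hits: pd.DataFrame) -> pd.DataFrame:
    """Add ``keyword_flag`` and ``matched_keywords`` columns."""
    flags, words = [], []
    for desc in hits["subject_description"]:
        f, w = keyword_virus_flag(desc)
        flags.append(f)
        words.append(",".join(w))
    return hits.assign(keyword_flag=flags, matched_keywords=words)


def any_viral_hit_summary(
    hits: pd.DataFrame, threshold: float = DEFAULT_EVALUE_THRESHOLD
) -> VirusSummary:
    """Count queries with *any* significant viral hit, not only top hits.

    A query counts toward ``n_any_viral_incl_metagenome`` if at least one
    significant hit (across all databases) is to a bacteriophage, a
    eukaryotic virus, or a viral-metagenome sequence. ``n_known_virus``
    drops queries whose only viral evidence is a viral-metagenome match.
    Each known-virus query is attributed to phage or eukaryotic virus by
    its best-scoring known-virus hit; percentages (integer, half-up) are
    over ``n_known_virus``.
    """
    sig = filter_significant(hits, threshold)
    if sig.empty:
        return VirusSummary(0, 0, 0, 0, None, None)
    viral = sig[sig["source_category"].isin(ANY_VIRAL_CATEGORIES)]
    n_any = viral["query_id"].nunique()
    known = sig[sig["source_category"].isin(KNOWN_VIRUS_CATEGORIES)]
    if known.empty:
        return VirusSummary(n_any, 0, 0, 0, None, None)
    best_known = top_hit_per_query(known)
    n_phage = int((best_known["source_category"] == "bacteriophage").sum())
    n_euk = int((best_known["source_category"] == "eukaryotic_virus").sum())
    n_known = n_phage + n_euk
    return VirusSummary(
        n_any_viral_incl_metagenome=int(n_any),
        n_known_virus=n_known,
        n_phage=n_phage,
        n_eukaryotic_virus=n_euk,
        pct_phage=round_half_up(100.0 * n_phage / n_known),
        pct_eukaryotic=round_half_up(100.0 * n_euk / n_known),
    )


def top_hit_source_distribution(
    top_hits: pd.DataFrame,
    threshold: float = DEFAULT_EVALUE_THRESHOLD,
    n_queries: int | None = None,
) -> dict[str, float]:
    """Proportion of queries whose significant top hit falls in each source
    category, plus a ``no_hit`` bucket; proportions sum to 1.

    ``n_queries`` sets the denominator (total queries, including those with
    no hit row at all); by default it is the number of distinct queries in
    the table.
    """
    n_table = top_hits["query_id"].nunique() if not top_hits.empty else 0
    total = n_table if n_queries is None else int(n_queries)
    if total < n_table:
        raise ValueError("n_queries smaller than queries present in table")
    if total == 0:
        return {"no_hit": 1.0}
    sig = filter_significant(top_hits, threshold)
    counts = sig["source_category"].value_counts().to_dict()
    out = {cat: n / total for cat, n in sorted(counts.items())}
    out["no_hit"] = (total - len(sig)) / total
    return out


def nr_vs_env_preference(
    hits: pd.DataFrame,
    group_a: set[str],
    group_b: set[str],
    n_queries: int | None = None,
) -> float:
    """Percentage of queries whose best hit in database group A strictly
    beats (smaller E-value than) their best hit in group B.

    A query with hits only in A counts toward A; equal best E-values count
    toward neither. The denominator is the number of distinct queries in
    the table unless ``n_queries`` is given.
    """
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError(f"database groups overlap: {sorted(group_a & group_b)}")
    n_table = hits["query_id"].nunique() if not hits.empty else 0
    total = n_table if n_queries is None else int(n_queries)
    if total == 0:
        raise ValueError("no queries to evaluate")
    in_a = hits[hits["database"].isin(group_a)]
    in_b = hits[hits["database"].isin(group_b)]
    best_a = in_a.groupby("query_id")["evalue"].min()
    best_b = in_b.groupby("query_id")["evalue"].min()
    n_better = 0
    for q, ea in best_a.items():
        eb = best_b.get(q, np.inf)
        if ea < eb:
            n_better += 1
    return 100.0 * n_better / total


def functional_tally(
    virus_hits: pd.DataFrame, function_map: dict[str, str]
) -> pd.DataFrame:
    """Tally functional categories over virus-matching queries.

    Each query is attributed the function of its best virus hit's subject
    via ``function_map``; unmapped subjects fall in ``unknown_function``.
    Returns a DataFrame indexed by function with ``count`` and
    ``proportion`` columns (empty for an empty hit set).
    """
    if virus_hits.empty:
        return pd.DataFrame(columns=["count", "proportion"])
    best = top_hit_per_query(virus_hits)
    funcs = best["subject_id"].map(
        lambda s: function_map.get(s, "unknown_function")
    )
    counts = funcs.value_counts().sort_index()
    return pd.DataFrame(
        {"count": counts, "proportion": counts / counts.sum()}
    )
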