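"""Read trimming, greedy overlap assembly, and contig classification.

Sanger-style shotgun reads are trimmed to a length window, assembled by a
deterministic greedy longest-overlap-first strategy (minimum overlap length
and ungapped percent identity over the overlap, both strands considered),
and the resulting contigs are classified by the plate/well identity encoded
in the clone ids: contigs joining the forward and reverse read of one clone
(``same_clone``), contigs joining clones from adjacent wells of the same
plate (``adjacent_well_suspect``, a cross-contamination signature), and
contigs joining independent clones (``independent``).

Clone ids follow the grammar ``<lib>_P<plate>_<rowletter><colnumber>.<F|R>``
(e.g. ``LIBA_P03_A05.F``). Reads whose ids do not parse are still assembled;
their contigs are classified ``unknown``.
"""

from __future__ import annotations

import heapq
import logging
import math
import re
from dataclasses import dataclass

from ._util import revcomp

logger = logging.getLogger(__name__)

DEFAULT_MAX_LEN = 500
DEFAULT_MIN_LEN = 100
DEFAULT_MIN_OVERLAP = 21
DEFAULT_MIN_IDENTITY = 0.98

CLONE_ID_RE = re.compile(
    r"^(?P<lib>.+)_P(?P<plate>\d+)_(?P<row>[A-Pa-p])(?P<col>\d{1,2})"
    r"(?:\.(?P<dir>[FRfr]))?$"
)


@dataclass(frozen=True)
class CloneIdentity:
    library: str
    plate: int
    row: str          # well row letter, upper case
    col: int          # well column number, 1-based
    direction: str    # "F", "R" or "unknown"

    @property
    def well(self) -> tuple[str, int]:
        return (self.row, self.col)


def parse_clone_id(read_id: str) -> CloneIdentity | None:
    """Parse a read id under the clone-id grammar; None if it does not fit."""
    m = CLONE_ID_RE.match(read_id)
    if m is None:
        return None
    direction = (m.group("dir") or "unknown").upper()
    if direction not in ("F", "R"):
        direction = "unknown"
    return CloneIdentity(
        library=m.group("lib"),
        plate=int(m.group("plate")),
        row=m.group("row").upper(),
        col=int(m.group("col")),
        direction=direction,
    )


@dataclass
class Read:
    """A (possibly trimmed) sequencing read."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"read {self.id}: non-ACGTN characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def identity(self) -> CloneIdentity | None:
        return parse_clone_id(self.id)


@dataclass
class Contig:
    id: str
    member_ids: list[str]
    consensus: str
    classification: str = "unclassified"

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class AssemblyResult:
    contigs: list[Contig]
    singletons: list[Read]
    n_input_reads: int

    @property
    def post_assembly_count(self) -> int:
        return len(self.singletons) + len(self.contigs)


def trim_reads(
    reads: list[Read],
    max_len: int = DEFAULT_MAX_LEN,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[Read]:
    """Truncate reads at the 3' end to ``max_len`` and drop reads shorter
    than ``min_len`` (boundary inclusive: a read of exactly ``min_len`` is
    kept). Order is preserved and the operation is idempotent."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    out = []
    for r in reads:
        if r.length < min_len:
            continue
        if r.length > max_len:
            out.append(Read(r.id, r.sequence[:max_len]))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# Greedy assembly
# ---------------------------------------------------------------------------

class _Item:
    """A read or partial contig in the greedy assembly working set.

    ``counts``/``first`` are per-column base profiles used for the majority
    consensus; ``first`` holds the base of the earliest-created member
    covering that column, used to break majority ties deterministically.
    ``key`` (the lexicographically smallest member read id) orders
    tie-broken merge candidates; ``birth`` orders "earlier-merged".
    """

    __slots__ = ("key", "birth", "members", "counts", "first")

    def __init__(self, key, birth, members, counts, first):
        self.key = key
        self.birth = birth
        self.members = members
        self.counts = counts
        self.first = first

    @classmethod
    def from_read(cls, read: Read, birth: int) -> "_Item":
        seq = read.sequence
        return cls(
            key=read.id,
            birth=birth,
            members=[read.id],
            counts=[{b: 1} for b in seq],
            first=list(seq),
        )

    def consensus(self) -> str:
        out = []
        for cnt, fb in zip(self.counts, self.first):
            best = max(cnt.values())
            winners = [b for b, c in cnt.items() if c == best]
            out.append(fb if fb in winners else min(winners))
        return "".join(out)

    def rc(self) -> "_Item":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        counts = [
            {comp[b]: c for b, c in cnt.items()} for cnt in reversed(self.counts)
        ]
        first = [comp[b] for b in reversed(self.first)]
        return _Item(self.key, self.birth, list(self.members), counts, first)


def _mismatch_budget(overlap_len: int, min_identity: float) -> int:
    return overlap_len - math.ceil(min_identity * overlap_len - 1e-9)


def _overlap_len_at(sa: str, sb: str, d: int, min_overlap: int,
                    min_identity: float) -> int | None:
    """Overlap length of placing ``sb`` at offset ``d`` relative to ``sa``,
    or None if the placement is too short or below the identity floor."""
    start = max(0, d)
    end = min(len(sa), d + len(sb))
    overlap = end - start
    if overlap < min_overlap:
        return None
    budget = _mismatch_budget(overlap, min_identity)
    mismatches = 0
    for i in range(start, end):
        if sa[i] != sb[i - d]:
            mismatches += 1
            if mismatches > budget:
                return None
    return overlap


def _scan_candidates(key_x, consensus, index, versions, seed_len):
    """Canonical (keyA, keyB, strand, offset) placements between item
    ``key_x`` and every other live item, supported by a shared exact seed
    word. strand 0: B forward; strand 1: B reverse-complemented, with
    keyA < keyB. For identity >= 0.98 and overlap >= 21 any qualifying
    ungapped overlap necessarily contains an exact 21 bp word, so the seed
    filter loses no candidates."""
    sx = consensus[key_x]
    len_x = len(sx)
    out: set[tuple[str, str, int, int]] = set()
    for strand, scan in ((0, sx), (1, revcomp(sx))):
        for i in range(len(scan) - seed_len + 1):
            for key_y, ver, j in index.get(scan[i:i + seed_len], ()):
                if key_y == key_x or versions.get(key_y) != ver:
                    continue
                len_y = len(consensus[key_y])
                # placement of Y (in orientation `strand`) relative to X
                d = (i - j) if strand == 0 else len_x - len_y - (i - j)
                if key_x < key_y:
                    out.add((key_x, key_y, strand, d))
                elif strand == 0:
                    out.add((key_y, key_x, 0, -d))
                else:
                    out.add((key_y, key_x, 1, d + len_y - len_x))
    return out


def _index_item(index, key, ver, seq, seed_len):
    for i in range(len(seq) - seed_len + 1):
        index.setdefault(seq[i:i + seed_len], []).append((key, ver, i))


def _merge(a: _Item, b: _Item, strand: int, d: int, birth: int) -> _Item:
    if strand == 1:
        b = b.rc()
    shift = -min(0, d)
    length = max(shift + len(a.counts), shift + d + len(b.counts))
    counts: list[dict[str, int]] = [dict() for _ in range(length)]
    first: list[str | None] = [None] * length
    earlier, later = (a, b) if a.birth <= b.birth else (b, a)
    for item, off in ((a, shift), (b, shift + d)):
        for i, cnt in enumerate(item.counts):
            col = counts[off + i]
            for base, c in cnt.items():
                col[base] = col.get(base, 0) + c
    for item in (later, earlier):  # earlier overwrites later
        off = shift if item is a else shift + d
        for i, fb in enumerate(item.first):
            first[off + i] = fb
    return _Item(
        key=min(a.key, b.key),
        birth=birth,
        members=a.members + b.members,
        counts=counts,
        first=first,  # type: ignore[arg-type]
    )


def assemble_greedy(
    reads: list[Read],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> AssemblyResult:
    """Greedy longest-overlap-first assembly.

    Repeatedly merges the pair of reads/contigs with the longest ungapped
    overlap of at least ``min_overlap`` bp at identity >= ``min_identity``
    (both strands considered, containments allowed) until no qualifying
    merge remains. Ties are broken by lexicographic member read id, then by
    orientation and placement, making the result deterministic. Consensus
    is per-column majority, ties resolved to the earlier-merged member.
    """
    if not 0 < min_identity <= 1:
        raise ValueError("min_identity must be in (0, 1]")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in assembly input")

    by_id = {r.id: r for r in reads}
    items: dict[str, _Item] = {}
    for birth, r in enumerate(sorted(reads, key=lambda r: r.id)):
        items[r.id] = _Item.from_read(r, birth)
    next_birth = len(items)
    seed_len = min(min_overlap, 21)

    # Incremental greedy loop: a versioned seed-word index and a heap of
    # evaluated candidate merges. Item consensus never changes while the
    # item is live, so candidate evaluations stay valid until one of the
    # two items is consumed (checked via versions on pop).
    consensus = {k: it.consensus() for k, it in items.items()}
    versions = {k: 0 for k in items}
    index: dict[str, list[tuple[str, int, int]]] = {}
    for key in items:
        _index_item(index, key, 0, consensus[key], seed_len)

    def evaluate(cands):
        out = []
        for key_a, key_b, strand, d in cands:
            sa = consensus[key_a]
            sb = consensus[key_b] if strand == 0 else revcomp(consensus[key_b])
            ov = _overlap_len_at(sa, sb, d, min_overlap, min_identity)
            if ov is not None:
                out.append((-ov, key_a, key_b, strand, d,
                            versions[key_a], versions[key_b]))
        return out

    heap: list[tuple] = []
    seen: set[tuple[str, str, int, int]] = set()
    for key in sorted(items):
        cands = _scan_candidates(key, consensus, index, versions, seed_len)
        heap.extend(evaluate(cands - seen))
        seen |= cands
    heapq.heapify(heap)

    while heap:
        _, key_a, key_b, strand, d, ver_a, ver_b = heapq.heappop(heap)
        if versions.get(key_a) != ver_a or versions.get(key_b) != ver_b:
            continue  # stale: one side was already merged
        merged = _merge(items[key_a], items[key_b], strand, d, next_birth)
        next_birth += 1
        for k in (key_a, key_b):
            del items[k], versions[k]
        key_m = merged.key
        items[key_m] = merged
        consensus[key_m] = merged.consensus()
        versions[key_m] = next_birth  # any value unseen in old heap entries
        _index_item(index, key_m, versions[key_m], consensus[key_m], seed_len)
        cands = _scan_candidates(key_m, consensus, index, versions, seed_len)
        for entry in evaluate(cands):
            heapq.heappush(heap, entry)

    contigs = []
    singleton_ids = set()
    for key in sorted(items):
        item = items[key]
        if len(item.members) == 1:
            singleton_ids.add(item.members[0])
        else:
            contigs.append(
                Contig(
                    id=f"contig_{len(contigs) + 1}",
                    member_ids=list(item.members),
                    consensus=item.consensus(),
                )
            )
    singletons = [by_id[i] for i in ids if i in singleton_ids]
    result = AssemblyResult(contigs=contigs, singletons=singletons,
                            n_input_reads=len(reads))
    assert len(singletons) + sum(c.n_members for c in contigs) == len(reads)
    return result


# ---------------------------------------------------------------------------
# Contig bookkeeping
# ---------------------------------------------------------------------------

def classify_contigs(contigs: list[Contig]) -> list[Contig]:
    """Set each contig's classification from its members' clone identities.

    ``same_clone``: all members share library, plate and well (the
    forward/reverse reads of one clone). ``adjacent_well_suspect``: members
    share library and plate and every pair of distinct wells is at Manhattan
    distance 1 (row letters mapped to integers; diagonals are not adjacent).
    Otherwise ``independent``. Unparseable member ids give ``unknown``.
    """
    for contig in contigs:
        idents = [parse_clone_id(m) for m in contig.member_ids]
        if any(i is None for i in idents):
            logger.warning(
                "contig %s: unparseable member id(s); classification unknown",
                contig.id,
            )
            contig.classification = "unknown"
            continue
        keys = {(i.library, i.plate) for i in idents}
        wells = {(i.row, i.col) for i in idents}
        if len(keys) == 1 and len(wells) == 1:
            contig.classification = "same_clone"
            continue
        if len(keys) == 1:
            coords = [(ord(r) - ord("A"), c) for r, c in wells]
            adjacent = all(
                abs(r1 - r2) + abs(c1 - c2) == 1
                for i, (r1, c1) in enumerate(coords)
                for (r2, c2) in coords[i + 1:]
            )
            if adjacent and len(wells) > 1:
                contig.classification = "adjacent_well_suspect"
                continue
        contig.classification = "independent"
    return contigs


def post_assembly_count(n_reads: int, contigs: list[Contig]) -> int:
    """Sequences remaining after assembly: singletons plus one entry per
    contig, i.e. ``n_reads - sum(members) + n_contigs``."""
    n = n_reads - sum(c.n_members for c in contigs) + len(contigs)
    if n < 0:
        raise ValueError("contigs contain more member reads than n_reads")
    return n


def interclone_read_fraction(n_reads: int, contigs: list[Contig]) -> float:
    """Percentage of reads absorbed into contigs that join different clone
    names (classification other than same_clone), at one decimal."""
    from ._util import round_half_up

    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if any(c.classification == "unclassified" for c in contigs):
        raise ValueError("run classify_contigs first")
    n = sum(c.n_members for c in contigs if c.classification != "same_clone")
    return round_half_up(100.0 * n / n_reads, 1)
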