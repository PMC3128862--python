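"""Brute-force greedy assembler used as an independent oracle.

Implements the same published contract -- merge the longest qualifying
ungapped overlap first, ties by lexicographic member read id, both strands,
containments allowed -- but finds overlaps by an exhaustive scan over every
relative placement of every pair, with no seed-word indexing. Intended for
instances of ~20 reads or fewer.
"""

from dataclasses import dataclass

from viroshot._util import revcomp


@dataclass
class _BFItem:
    key: str
    birth: int
    members: list
    seq: str


def _bf_overlap(sa: str, sb: str, d: int, min_overlap: int,
                min_identity: float) -> int | None:
    start, end = max(0, d), min(len(sa), d + len(sb))
    length = end - start
    if length < min_overlap:
        return None
    allowed = length * (1.0 - min_identity) + 1e-9
    mismatches = 0
    for i in range(start, end):
        if sa[i] != sb[i - d]:
            mismatches += 1
            if mismatches > allowed:
                return None
    return length


def _bf_best(items, min_overlap, min_identity):
    best = None
    keys = sorted(items)
    for ai, key_a in enumerate(keys):
        sa = items[key_a].seq
        for key_b in keys[ai + 1:]:
            for strand, sb in ((0, items[key_b].seq),
                               (1, revcomp(items[key_b].seq))):
                for d in range(-(len(sb) - min_overlap),
                               len(sa) - min_overlap + 1):
                    ov = _bf_overlap(sa, sb, d, min_overlap, min_identity)
                    if ov is None:
                        continue
                    cand = (-ov, key_a, key_b, strand, d)
                    if best is None or cand < best:
                        best = cand
    return best


def _bf_merge(a: _BFItem, b: _BFItem, strand: int, d: int,
              birth: int) -> _BFItem:
    sb = b.seq if strand == 0 else revcomp(b.seq)
    shift = -min(0, d)
    length = max(shift + len(a.seq), shift + d + len(sb))
    earlier_first = a.birth <= b.birth
    cols = [None] * length
    # later item first, earlier item overwrites (earlier member wins ties)
    order = [(b, sb, shift + d), (a, a.seq, shift)]
    if not earlier_first:
        order.reverse()
    for _item, seq, off in order:
        for i, base in enumerate(seq):
            cols[off + i] = base
    return _BFItem(
        key=min(a.key, b.key),
        birth=birth,
        members=a.members + b.members,
        seq="".join(cols),
    )


def assemble_bruteforce(reads, min_overlap=21, min_identity=0.98):
    """Returns (contig member-id tuples with consensus lengths, singleton ids)."""
    items = {}
    for birth, r in enumerate(sorted(reads, key=lambda r: r.id)):
        items[r.id] = _BFItem(key=r.id, birth=birth, members=[r.id],
                              seq=r.sequence)
    birth = len(items)
    while True:
        best = _bf_best(items, min_overlap, min_identity)
        if best is None:
            break
        _, key_a, key_b, strand, d = best
        merged = _bf_merge(items[key_a], items[key_b], strand, d, birth)
        birth += 1
        del items[key_a], items[key_b]
        items[merged.key] = merged
    contigs = sorted(
        (tuple(item.members), len(item.seq))
        for item in items.values() if len(item.members) > 1
    )
    singletons = sorted(
        item.members[0] for item in items.values() if len(item.members) == 1
    )
    return contigs, singletons
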