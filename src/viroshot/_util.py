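"""Small shared helpers: rounding, reverse complement, seed derivation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Fixed per-stream offsets so each generator can be re-run independently from
# one global seed.
_SEED_OFFSETS = {
    "genomes": 1,
    "reads": 2,
    "hits": 3,
    "gradient": 4,
    "pair": 5,
    "benchmark": 6,
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 0) -> float | int:
    """Round with ties away from zero-ward halves going up (2.25 -> 2.3).

    Reports in this package round half-up at the printed precision rather
    than using banker's rounding. Returns an int when ndigits == 0.
    """
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d) if ndigits > 0 else int(d)


def subseed(seed: int, stream: str) -> int:
    """Derive a per-stream integer seed from one global seed.

    Uses fixed additive offsets (mod 2**31) so that, e.g., the read
    generator draws the same stream whether or not genomes were generated
    in the same session.
    """
    if stream not in _SEED_OFFSETS:
        raise KeyError(f"unknown seed stream: {stream!r}")
    return (int(seed) * 1000003 + _SEED_OFFSETS[stream]) % (2**31)
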