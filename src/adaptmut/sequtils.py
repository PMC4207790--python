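"""Small sequence helpers shared by the simulator and the caller."""

from __future__ import annotations

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_ROMAN = [
    (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def roman(n: int) -> str:
    """Roman numeral for a small positive integer (chromosome naming)."""
    if n < 1:
        raise ValueError("roman() requires n >= 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def chrom_name(i: int) -> str:
    """1-based chromosome index to a yeast-style name ('chrI', 'chrII', ...)."""
    return "chr" + roman(i)


def is_low_complexity(
    seq: str,
    start: int,
    length: int = 1,
    *,
    min_homopolymer: int = 6,
    min_tandem_span: int = 12,
) -> bool:
    """True when the 1-based interval [start, start+length-1] sits in a
    low-complexity context: a homopolymer run of >= ``min_homopolymer`` bases,
    or a perfect 2- or 3-mer tandem repeat spanning >= ``min_tandem_span`` bp.

    ``length`` may be 0 for an insertion anchored at ``start``; the anchor
    base is then used as the event footprint.
    """
    length = max(length, 1)
    ev_lo = start  # 1-based inclusive
    ev_hi = start + length - 1
    # restrict scanning to a window; repeats are local by definition
    pad = max(min_tandem_span, min_homopolymer) + 6
    win_lo = max(1, ev_lo - pad)
    win_hi = min(len(seq), ev_hi + pad)
    s = seq[win_lo - 1 : win_hi]

    def overlaps(run_lo: int, run_hi: int) -> bool:
        # run coords are 1-based genome positions
        return run_lo <= ev_hi and run_hi >= ev_lo

    # homopolymer runs
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        if j - i + 1 >= min_homopolymer and overlaps(win_lo + i, win_lo + j):
            return True
        i = j + 1

    # period-2 / period-3 perfect tandem repeats
    for k in (2, 3):
        run = 0
        for p in range(k, len(s)):
            if s[p] == s[p - k]:
                run += 1
                span = run + k
                if span >= min_tandem_span:
                    run_hi = win_lo + p
                    run_lo = run_hi - span + 1
                    if overlaps(run_lo, run_hi):
                        return True
            else:
                run = 0
    return False
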