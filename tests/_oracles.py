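"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (plain loops, textbook dynamic
programming) and shares no code with the package implementation.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def edit_dp(a: str, b: str) -> int:
    """Textbook global edit distance (N never matches anything)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            match = a[i - 1] == b[j - 1] and a[i - 1] != "N"
            cur[j] = min(prev[j - 1] + (0 if match else 1), prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[n]


def infix_dp(pattern: str, text: str) -> tuple[int, list[tuple[int, int]]]:
    """Min edit distance of pattern against any substring of text.

    Returns (distance, [(start, end), ...]) for every optimal substring,
    computed by trying all start positions (quadratic, small inputs only).
    """
    best = len(pattern) + len(text)
    spans: list[tuple[int, int]] = []
    m = len(pattern)
    for s in range(len(text) + 1):
        # column DP anchored at text position s, free end:
        # d[e-s] = distance of pattern vs text[s:e]
        d = {0: m}
        col = list(range(m + 1))
        for j, ch in enumerate(text[s:], start=1):
            newcol = [j]
            for i in range(1, m + 1):
                match = pattern[i - 1] == ch and pattern[i - 1] != "N"
                newcol.append(
                    min(col[i - 1] + (0 if match else 1), col[i] + 1, newcol[i - 1] + 1)
                )
            col = newcol
            d[j] = col[m]
        for e_off, dist in d.items():
            if dist < best:
                best = dist
                spans = [(s, s + e_off)]
            elif dist == best:
                spans.append((s, s + e_off))
    return best, spans


def prefix_anchored_best(pattern: str, text: str, threshold: int):
    """Longest pattern prefix placeable in text within the threshold.

    Returns (prefix_len, distance) or None. Free text start and end.
    """
    best = None
    for plen in range(1, len(pattern) + 1):
        dist, _ = infix_dp(pattern[:plen], text)
        if dist <= threshold:
            best = (plen, dist)
    return best


def brute_minimizers(seq: str, k: int, w: int, use_hash=None):
    """All-window scan minimizer extraction over both strands.

    ``use_hash`` maps a 2-bit k-mer integer to its key (identity if None).
    Returns a set of (pos, key, strand) with strand in '+-'.
    """
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    h = use_hash or (lambda x: x)
    kmers = []
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        if any(c not in enc for c in sub):
            kmers.append(None)
            continue
        fwd = 0
        for c in sub:
            fwd = fwd * 4 + enc[c]
        rev = 0
        for c in rc(sub):
            rev = rev * 4 + enc[c]
        hf, hr = h(fwd), h(rev)
        if hf == hr:
            kmers.append("skip")
        elif hf < hr:
            kmers.append((hf, "+"))
        else:
            kmers.append((hr, "-"))
    out = set()
    for ws in range(len(kmers) - w + 1):
        window = kmers[ws : ws + w]
        if any(x is None for x in window):
            continue
        keys = [x[0] for x in window if x != "skip"]
        if not keys:
            continue
        lo = min(keys)
        for off, x in enumerate(window):
            if x != "skip" and x[0] == lo:
                out.add((ws + off, x[0], x[1]))
    return out


def brute_merge_candidates(positions, threshold, min_support):
    """Group sorted raw positions into runs of gap <= threshold."""
    out = []
    run = []
    for p in sorted(positions):
        if run and p - run[-1] > threshold:
            if len(run) >= min_support:
                out.append((run[0], len(run)))
            run = []
        run.append(p)
    if run and len(run) >= min_support:
        out.append((run[0], len(run)))
    return out


def string_neighbors(barcode: str):
    """All single-substitution variants as strings."""
    out = set()
    for i in range(len(barcode)):
        for b in "ACGT":
            if b != barcode[i]:
                out.add(barcode[:i] + b + barcode[i + 1 :])
    return out
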