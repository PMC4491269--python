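"""Independent brute-force oracles used only by the test suite.

The motif oracle enumerates every candidate six-cysteine window
literally and applies the grammar rules one by one; it shares no code
with stpscan.motif. The metric oracle recomputes each statistic from
its definition with plain Python arithmetic.
"""

from __future__ import annotations

import math

NON_CYS = "ADEFGHIKLMNPQRSTVWY"


def oracle_scan(residues: str) -> dict:
    """Literal rule-by-rule motif scan; returns a comparable dict."""
    positions = [i + 1 for i, ch in enumerate(residues) if ch == "C"]
    n = len(positions)
    loops = [positions[i + 1] - positions[i] - 1 for i in range(n - 1)]

    def result(valid, reason, pos, lps):
        mli = None
        if lps:
            mli = lps.index(min(lps))
        return {
            "valid": valid,
            "reason": reason,
            "positions": tuple(pos),
            "loops": tuple(lps),
            "min_loop_index": mli,
        }

    if n < 6:
        return result(False, "fewer_than_six_cysteines", positions, loops)

    m = loops.index(min(loops))  # most N-terminal global minimum
    if loops[m] > 3:
        return result(False, "min_loop_gt_three", positions, loops)

    # every six-cysteine window containing the minimum pair, with the
    # role offset the pair would play in it (0 => C1-C2 ... 4 => C5-C6)
    candidates = [
        (start, m - start)
        for start in range(0, n - 5)
        if start <= m <= start + 4
    ]
    exact = [c for c in candidates if c[1] == 2]
    if exact:
        start, _ = exact[0]
    else:
        above = [c for c in candidates if c[1] > 2]
        below = [c for c in candidates if c[1] < 2]
        if above:  # too few downstream cysteines: shift role up, minimally
            start, _ = min(above, key=lambda c: c[1])
        else:      # too few upstream cysteines: slide role down, minimally
            start, _ = max(below, key=lambda c: c[1])

    window = positions[start : start + 6]
    wloops = [window[i + 1] - window[i] - 1 for i in range(5)]
    w_min = wloops.index(min(wloops))
    if w_min in (0, 1):
        return result(False, "min_loop_in_first_two", window, wloops)
    return result(True, "none", window, wloops)


def random_chain(rng, min_len=20, max_len=160, max_cys=12) -> str:
    """Random peptide with 0..max_cys cysteines at random positions."""
    n = int(rng.integers(min_len, max_len + 1))
    res = [NON_CYS[i] for i in rng.integers(0, len(NON_CYS), size=n)]
    k = int(rng.integers(0, max_cys + 1))
    for pos in rng.choice(n, size=min(k, n), replace=False):
        res[pos] = "C"
    return "".join(res)


def oracle_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Plain-arithmetic recomputation of the five summary statistics."""

    def div(a, b):
        return a / b if b else math.nan

    return {
        "sensitivity": div(tp, tp + fn),
        "specificity": div(tn, tn + fp),
        "precision": div(tp, tp + fp),
        "accuracy": div(tp + tn, tp + fp + tn + fn),
        "mcc": div(
            tp * tn - fp * fn,
            math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)),
        ),
    }
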