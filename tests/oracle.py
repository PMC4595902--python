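"""Independent brute-force placement oracle for aligner checks.

Enumerates every (offset, left-trim, right-trim) ungapped core of a read on
a hairpin and returns the maximum number of matching core columns over all
admissible cores (core length >= min_core, core mismatches <= max_mm, core
bounded by matching columns -- terminal mismatches belong to the overhang by
definition).  Written against the raw alignment contract, not against the
aligner's windowing algorithm.
"""

from __future__ import annotations

import numpy as np


def best_core_matches(
    seq: str, hairpin: str, max_mm: int = 2, min_core: int = 15
) -> int:
    """Max core matches over all placements on one hairpin (0 if unmappable)."""
    r = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    h = np.frombuffer(hairpin.encode("ascii"), dtype=np.uint8)
    L, Lh = len(r), len(h)
    best = 0
    for offset in range(-(L - min_core), Lh - min_core + 1):
        lo, hi = max(0, -offset), min(L, Lh - offset)
        n = hi - lo
        if n < min_core:
            continue
        m = r[lo:hi] == h[offset + lo : offset + hi]
        mm_cum = np.concatenate(([0], np.cumsum(~m)))
        for a in range(n - min_core + 1):
            if not m[a]:
                continue
            bs = np.arange(a + min_core, n + 1)
            ends_match = m[bs - 1]
            mm = mm_cum[bs] - mm_cum[a]
            ok = ends_match & (mm <= max_mm)
            if ok.any():
                matches = (bs[ok] - a) - mm[ok]
                best = max(best, int(matches.max()))
    return best


def best_over_reference(
    seq: str, hairpins: dict[str, str], max_mm: int = 2, min_core: int = 15
) -> int:
    return max(
        (best_core_matches(seq, hp, max_mm, min_core) for hp in hairpins.values()),
        default=0,
    )
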