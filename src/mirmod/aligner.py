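"""Ungapped sense-strand placement of reads onto hairpin precursors.

Hairpin references are short, so the aligner scans every ungapped offset of
the read against every hairpin (sense strand only; antisense matches are
never emitted).  At each offset the best local core is chosen: a maximal
read interval whose aligned columns start and end on matches, contain at
most ``max_mismatches`` mismatching columns, and span at least ``min_core``
bases.  Read bases outside the core -- terminal mismatch runs and positions
hanging off the hairpin -- become overhangs, which is what lets a
non-templated "TT" tail surface as a tail instead of two mismatches.  The
core-trim choice is exact (optimal over all left/right trim points), not
greedy, so the best core-match count matches brute-force enumeration.

Indels are out of scope: the modification model concerns substitutions and
terminal additions only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import ReferenceSet

Mismatch = tuple[int, int, str, str]  # (read_pos, hairpin_pos, read_base, ref_base)


@dataclass(frozen=True)
class Placement:
    """One ungapped placement of a read on a hairpin.

    ``offset`` is the 0-based hairpin position of read base 0 (negative when
    the read starts upstream of the hairpin).  ``core_start``/``core_end``
    bound the aligned core in read coordinates; everything outside is
    overhang.  N bases in reads mismatch every reference base.
    """

    read_seq: str
    hairpin_id: str
    offset: int
    core_start: int
    core_end: int
    mismatches: tuple[Mismatch, ...]

    @property
    def n_core_mismatch(self) -> int:
        return len(self.mismatches)

    @property
    def n_core_match(self) -> int:
        return (self.core_end - self.core_start) - len(self.mismatches)

    @property
    def left_overhang(self) -> str:
        return self.read_seq[: self.core_start]

    @property
    def right_overhang(self) -> str:
        return self.read_seq[self.core_end :]

    @property
    def overhang_len(self) -> int:
        return len(self.read_seq) - (self.core_end - self.core_start)


@dataclass(frozen=True)
class MultiMapPolicy:
    """How tied paralogue hits share a read: 'first_hit' or 'fractional'."""

    mode: str = "first_hit"

    def __post_init__(self):
        if self.mode not in ("first_hit", "fractional"):
            raise ValueError(f"unknown multimap mode {self.mode!r}")


class HairpinAligner:
    """Places reads on a fixed reference; encodes hairpins once."""

    def __init__(self, ref: ReferenceSet, max_mismatches: int = 2, min_core: int = 15):
        if min_core < 1:
            raise ValueError("min_core must be >= 1")
        self.ref = ref
        self.max_mismatches = max_mismatches
        self.min_core = min_core
        self._enc = {
            hid: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for hid, seq in sorted(ref.hairpins.items())
        }

    def _best_window(self, mrow: np.ndarray, col_lo: int, col_hi: int):
        """Best admissible core within on-hairpin columns [col_lo, col_hi).

        Returns (n_match, n_mismatch, a, b) maximising matches, then fewest
        mismatches, or None.  Enumerates maximal windows bounded by
        consecutive mismatch positions (at most max_mismatches inside), then
        shrinks window ends onto matching columns.
        """
        m = mrow[col_lo:col_hi]
        n = col_hi - col_lo
        if n < self.min_core:
            return None
        P = np.flatnonzero(~m)
        npos = len(P)
        k = self.max_mismatches
        best = None
        for i in range(npos + 1):
            left = P[i - 1] if i > 0 else -1
            j = i + k
            right = P[j] if j < npos else n
            a, b = int(left) + 1, int(right)
            while a < b and not m[a]:
                a += 1
            while b > a and not m[b - 1]:
                b -= 1
            if b - a < self.min_core:
                continue
            inside = int(np.searchsorted(P, b) - np.searchsorted(P, a))
            matches = (b - a) - inside
            key = (matches, -inside)
            if best is None or key > best[0]:
                best = (key, a + col_lo, b + col_lo)
        if best is None:
            return None
        (matches, neg_mm), a, b = best
        return matches, -neg_mm, a, b

    def place(self, read) -> list[Placement]:
        """All best-scoring placements of a read (empty list if unmapped).

        The returned set contains every placement achieving the maximum
        number of core matches, sorted by (fewest core mismatches, shortest
        total overhang, hairpin_id, offset) -- 'first optimal hit' is
        therefore deterministic.
        """
        seq = read if isinstance(read, str) else read.seq
        L = len(seq)
        if L < self.min_core:
            return []
        r = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        pad = L - self.min_core
        floor = self.min_core - self.max_mismatches
        candidates: list[tuple[int, str, int, np.ndarray]] = []
        for hid, hp in self._enc.items():
            Lh = len(hp)
            padded = np.zeros(Lh + 2 * pad, dtype=np.uint8)
            padded[pad : pad + Lh] = hp
            if len(padded) < L:
                continue
            match = sliding_window_view(padded, L) == r
            counts = match.sum(axis=1)
            for row in np.flatnonzero(counts >= floor):
                candidates.append((int(counts[row]), hid, int(row) - pad, match[row]))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

        best_matches = 0
        results: list[tuple[Placement, int]] = []
        for count, hid, offset, mrow in candidates:
            if count < max(best_matches, floor):
                break
            col_lo = max(0, -offset)
            col_hi = min(L, len(self._enc[hid]) - offset)
            win = self._best_window(mrow, col_lo, col_hi)
            if win is None:
                continue
            matches, n_mm, a, b = win
            if matches < best_matches:
                continue
            hp_seq = self.ref.hairpins[hid]
            mismatches = tuple(
                (int(p), offset + int(p), seq[int(p)], hp_seq[offset + int(p)])
                for p in np.flatnonzero(~mrow)
                if a <= p < b
            )
            placement = Placement(seq, hid, offset, a, b, mismatches)
            if matches > best_matches:
                best_matches = matches
                results = [(placement, matches)]
            else:
                results.append((placement, matches))
        placements = [p for p, _ in results]
        placements.sort(
            key=lambda p: (p.n_core_mismatch, p.overhang_len, p.hairpin_id, p.offset)
        )
        return placements


def place_read(
    read, ref: ReferenceSet, max_mismatches: int = 2, min_core: int = 15
) -> list[Placement]:
    """One-shot placement (builds a throwaway :class:`HairpinAligner`)."""
    return HairpinAligner(ref, max_mismatches, min_core).place(read)


def resolve_multimap(
    placements: Sequence[Placement], policy: MultiMapPolicy
) -> list[tuple[Placement, float]]:
    """Assign per-placement weights: all on the first hit, or equal shares."""
    if not placements:
        return []
    if policy.mode == "first_hit":
        return [(placements[0], 1.0)]
    n = len(placements)
    return [(p, 1.0 / n) for p in placements]
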