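"""3' adapter inference and trimming, size selection, and read collapsing.

The adapter inference is a seeded greedy extension: find the most frequent
10-mer in the 3' halves of a read sample, then extend it rightward one base at
a time while the extended string stays frequent.  Trimming takes the leftmost
junction where a prefix of the adapter matches the read suffix, the behaviour
of common small-RNA trimmers (adapter dimers therefore trim to length 0 and
are removed by size selection).  Collapsing merges identical sequences into a
single record that stores the total read depth.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Iterator

from .io_formats import ReadRecord


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read: one distinct sequence with its total depth."""

    seq: str
    depth: int
    sample_id: str


@dataclass(frozen=True)
class AdapterCall:
    adapter: str
    support: float  # fraction of sampled reads containing the 10-nt seed


def _seq_of(read) -> str:
    return read.seq if isinstance(read, ReadRecord) else read


def infer_adapter(
    reads: Iterable,
    k: int = 10,
    sample_cap: int = 100_000,
    min_support: float = 0.2,
    ext_frac: float = 0.5,
) -> AdapterCall | None:
    """Infer the 3' sequencing adapter from a sample of reads.

    Counts distinct k-mers over the 3' half of each read (each read votes at
    most once per k-mer), seeds on the most frequent one (lexicographically
    smallest on ties), and greedily extends it one base at a time -- leftward
    first, then rightward -- while the extended string is still seen in at
    least ``ext_frac`` of the seed's supporting reads.  Leftward extension
    stops at the insert/adapter junction (upstream bases are random insert
    sequence), so the call converges onto the adapter's true 5' start.
    Returns ``None`` when no k-mer reaches ``min_support`` ("no adapter
    detected"), which is distinct from a low-support :class:`AdapterCall`.
    """
    tails = [_seq_of(r)[len(_seq_of(r)) // 2 :] for r in islice(iter(reads), sample_cap)]
    if len(tails) < 1000:
        warnings.warn(
            f"adapter inference on only {len(tails)} reads (<1000); call may be unreliable",
            stacklevel=2,
        )
    if not tails:
        return None
    counts: Counter[str] = Counter()
    for t in tails:
        if len(t) >= k:
            counts.update({t[i : i + k] for i in range(len(t) - k + 1)})
    if not counts:
        return None
    seed = min(counts, key=lambda s: (-counts[s], s))
    seed_n = counts[seed]
    support = seed_n / len(tails)
    if support < min_support:
        return None
    adapter = seed
    max_len = max(len(t) for t in tails)

    def _extend(current: str, left: bool) -> str:
        while len(current) < max_len:
            ext_counts = {
                (b + current if left else current + b): sum(
                    1 for t in tails if (b + current if left else current + b) in t
                )
                for b in "ACGT"
            }
            best = min(ext_counts, key=lambda s: (-ext_counts[s], s))
            if ext_counts[best] >= ext_frac * seed_n:
                current = best
            else:
                break
        return current

    adapter = _extend(adapter, left=True)
    adapter = _extend(adapter, left=False)
    return AdapterCall(adapter, support)


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.125,
) -> ReadRecord:
    """Truncate ``read`` at the leftmost position where the adapter starts.

    A junction at position ``i`` qualifies when ``read[i:]`` aligns to a
    prefix of the adapter over at least ``min_overlap`` bases with a mismatch
    rate of at most ``max_mismatch_rate``.  No qualifying junction returns the
    read unchanged; the quality string is truncated in parallel.  Idempotent.
    """
    if len(adapter) < min_overlap:
        raise ValueError(f"adapter shorter than min_overlap={min_overlap}")
    seq = read.seq
    for i in range(0, len(seq) - min_overlap + 1):
        aligned = min(len(seq) - i, len(adapter))
        mm = sum(1 for a, b in zip(seq[i : i + aligned], adapter) if a != b)
        if mm <= max_mismatch_rate * aligned:
            return read.truncated(i)
    return read


def size_select(
    reads: Iterable[ReadRecord],
    min_len: int = 16,
    max_len: int = 35,
    stats: Counter | None = None,
) -> Iterator[ReadRecord]:
    """Keep reads with ``min_len <= length <= max_len`` (bounds inclusive).

    When a ``stats`` Counter is supplied, 'kept' and 'discarded' tallies are
    accumulated into it for the per-sample run log.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    for r in reads:
        if min_len <= len(r.seq) <= max_len:
            if stats is not None:
                stats["kept"] += 1
            yield r
        elif stats is not None:
            stats["discarded"] += 1


def collapse(reads: Iterable, sample_id: str) -> list[UniqueRead]:
    """De-duplicate reads into depth-annotated unique sequences.

    The sum of output depths equals the number of input reads.  Output is
    sorted by descending depth, then lexicographically by sequence.
    """
    counts = Counter(_seq_of(r) for r in reads)
    return [
        UniqueRead(seq, depth, sample_id)
        for seq, depth in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
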