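"""Classify placement mismatches and overhangs into modification events.

A read attributed to a mature miRNA contributes events for every base that
cannot derive from the precursor: overhang bases that differ from (or lie
beyond) the hairpin, and core mismatches.  Events are classed by where they
fall relative to the canonical mature placement:

* 3'-modifications: offsets -5..+6 about the 3'-terminal base (0 = the
  terminal base itself, +1 = first base downstream);
* 5'-modifications: offsets -8..+5 about the 5' end (0 = the first base);
* internal: everything outside both windows, one event per substituted base.

The terminal windows deliberately reach into the mature body so that
substitutions near either end are absorbed into the terminal classes rather
than confused with length-variant isomiRs.  Templated extension beyond the
mature end (bases matching the hairpin) generates no event.  Contiguous
non-templated runs in one window form a single multi-base pattern ("TT"),
indexed at the run's first base.

Internal events are pooled across samples and thresholded on the ratio of
modified to total depth: ratio >= 0.70 calls a SNP (inclusive); below the
threshold, an A->G substitution is an ADAR edit (A-to-I editing read as G on
the sense strand) and anything else stays ``other_internal``.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .aligner import Placement
from .io_formats import ReferenceSet
from .reference_db import CanonicalDB, MatureLocus

WINDOW_3P = (-5, 6)  # inclusive offsets about the 3'-terminal base
WINDOW_5P = (-8, 5)  # inclusive offsets about the 5' end

MOD3P = "mod3p"
MOD5P = "mod5p"
INTERNAL = "internal"


@dataclass(frozen=True)
class ModEvent:
    """One classified modification with its position and weighted depth.

    ``index`` is the absolute position index (0 at the mature 5' end);
    ``offset`` is the class-relative coordinate (about the 3' end for mod3p,
    about the 5' end for mod5p, equal to ``index`` for internal events).
    ``ref_base`` is set for single-base substitutions with a templated
    reference position, empty for pure tails.
    """

    mature_id: str
    sample_id: str
    mod_class: str
    pattern: str
    ref_base: str
    index: int
    offset: int
    depth: float


@dataclass(frozen=True)
class InternalCall:
    mature_id: str
    index: int
    ref_base: str
    alt: str
    modified_depth: float
    total_depth: float
    ratio: float
    label: str  # SNP | ADAR_edit | other_internal


def _classify_offset(idx: int, length: int, window_3p, window_5p) -> str:
    off3 = idx - (length - 1)
    off5 = idx
    in3 = window_3p[0] <= off3 <= window_3p[1]
    in5 = window_5p[0] <= off5 <= window_5p[1]
    if in3 and in5:  # only possible for very short matures; assign nearer end
        return MOD3P if abs(off3) <= abs(off5) else MOD5P
    if in3:
        return MOD3P
    if in5:
        return MOD5P
    return INTERNAL


def attribute_placement(
    placement: Placement,
    db: CanonicalDB,
    min_overlap_frac: float = 0.5,
) -> MatureLocus | None:
    """Mature locus a placement belongs to, or None (hairpin-only hit).

    Requires the aligned core to overlap the locus by at least
    ``min_overlap_frac`` of the mature length; ties go to the larger overlap,
    then lexicographic mature ID.
    """
    core_lo = placement.offset + placement.core_start
    core_hi = placement.offset + placement.core_end
    best: tuple[int, str, MatureLocus] | None = None
    for locus in db.by_hairpin.get(placement.hairpin_id, []):
        ov = min(core_hi, locus.end) - max(core_lo, locus.start)
        if ov < min_overlap_frac * locus.length:
            continue
        key = (-ov, locus.mature_id)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], locus)
    return best[2] if best else None


def assign_events(
    placement: Placement,
    weight: float,
    ref: ReferenceSet,
    db: CanonicalDB,
    sample_id: str,
    read_depth: int = 1,
    window_3p: tuple[int, int] = WINDOW_3P,
    window_5p: tuple[int, int] = WINDOW_5P,
    min_overlap_frac: float = 0.5,
) -> list[ModEvent]:
    """Classified modification events of one weighted placement.

    Returns an empty list when the read is not attributable to any mature.
    Each event carries depth ``weight * read_depth``.
    """
    locus = attribute_placement(placement, db, min_overlap_frac)
    if locus is None:
        return []
    return events_for_locus(
        placement, locus, weight * read_depth, ref, sample_id, window_3p, window_5p
    )


def events_for_locus(
    placement: Placement,
    locus: MatureLocus,
    depth: float,
    ref: ReferenceSet,
    sample_id: str,
    window_3p: tuple[int, int] = WINDOW_3P,
    window_5p: tuple[int, int] = WINDOW_5P,
) -> list[ModEvent]:
    seq = placement.read_seq
    hp = ref.hairpins[placement.hairpin_id]
    mm_at = {p[0]: p[3] for p in placement.mismatches}  # read_pos -> ref_base
    L = locus.length

    # candidate non-templated positions: (read_pos, index, ref_base, class)
    cands: list[tuple[int, int, str]] = []
    for j in range(len(seq)):
        h = placement.offset + j
        idx = h - locus.start
        if placement.core_start <= j < placement.core_end:
            if j in mm_at:
                cands.append((j, idx, mm_at[j]))
        else:
            rb = hp[h] if 0 <= h < len(hp) else ""
            if rb == seq[j]:
                continue  # templated extension: matches the hairpin, no event
            cands.append((j, idx, rb))

    events: list[ModEvent] = []

    def flush(run: list[tuple[int, int, str]], cls: str) -> None:
        j0, idx0, rb0 = run[0]
        pattern = seq[j0 : run[-1][0] + 1]
        ref_base = rb0 if len(run) == 1 and rb0 else ""
        if cls == MOD3P:
            off = idx0 - (L - 1)
        elif cls == MOD5P:
            off = idx0
        else:
            off = idx0
        events.append(
            ModEvent(locus.mature_id, sample_id, cls, pattern, ref_base, idx0, off, depth)
        )

    run: list[tuple[int, int, str]] = []
    run_cls: str | None = None
    for j, idx, rb in cands:
        cls = _classify_offset(idx, L, window_3p, window_5p)
        contiguous = run and j == run[-1][0] + 1 and cls == run_cls and cls != INTERNAL
        if contiguous:
            run.append((j, idx, rb))
        else:
            if run:
                flush(run, run_cls)
            run = [(j, idx, rb)]
            run_cls = cls
    if run:
        flush(run, run_cls)
    return events


class EventCaller:
    """Streams weighted placements into events plus positional coverage.

    Coverage (per mature and absolute index, pooled over samples) counts
    every read base spanning the position, overhangs included, weighted by
    depth x multimap weight -- the denominator of the SNP/edit ratio, derived
    from the same placements as the events so it can never be zero where an
    event exists.
    """

    def __init__(
        self,
        ref: ReferenceSet,
        db: CanonicalDB,
        window_3p: tuple[int, int] = WINDOW_3P,
        window_5p: tuple[int, int] = WINDOW_5P,
        min_overlap_frac: float = 0.5,
    ):
        self.ref = ref
        self.db = db
        self.window_3p = window_3p
        self.window_5p = window_5p
        self.min_overlap_frac = min_overlap_frac
        self.events: list[ModEvent] = []
        self.coverage: Counter = Counter()  # (mature_id, index) -> depth
        self.unattributed_depth: float = 0.0

    def process(
        self, placement: Placement, weight: float, sample_id: str, read_depth: int
    ) -> str | None:
        """Record events/coverage; returns the attributed mature ID or None."""
        locus = attribute_placement(placement, self.db, self.min_overlap_frac)
        depth = weight * read_depth
        if locus is None:
            self.unattributed_depth += depth
            return None
        for j in range(len(placement.read_seq)):
            idx = placement.offset + j - locus.start
            self.coverage[(locus.mature_id, idx)] += depth
        self.events.extend(
            events_for_locus(
                placement, locus, depth, self.ref, sample_id,
                self.window_3p, self.window_5p,
            )
        )
        return locus.mature_id


def classify_internal(
    events: Iterable[ModEvent],
    coverage: dict[tuple[str, int], float],
    snp_threshold: float = 0.70,
) -> list[InternalCall]:
    """Label pooled internal events as SNP / ADAR_edit / other_internal.

    Depths are pooled across samples per (mature, index, substitution): a SNP
    is a property of the source genome, not of one library.  The ratio
    boundary is inclusive (ratio == snp_threshold calls SNP).
    """
    agg: dict[tuple[str, int, str, str], float] = defaultdict(float)
    for e in events:
        if e.mod_class != INTERNAL:
            continue
        agg[(e.mature_id, e.index, e.ref_base, e.pattern)] += e.depth
    calls: list[InternalCall] = []
    for (mid, idx, rb, alt), mod in sorted(agg.items()):
        total = coverage.get((mid, idx), 0.0)
        if total <= 0:
            raise ValueError(
                f"no coverage at {mid} index {idx}: events and coverage must "
                f"derive from the same placements"
            )
        ratio = min(mod / total, 1.0)
        if ratio >= snp_threshold:
            label = "SNP"
        elif (rb, alt) == ("A", "G"):
            label = "ADAR_edit"
        else:
            label = "other_internal"
        calls.append(InternalCall(mid, idx, rb, alt, mod, total, ratio, label))
    return calls


@dataclass
class ModProfile:
    """Pattern x position x sample tensor of event depths, per class.

    ``table()`` renders one class (class-relative offsets) or, with
    ``mod_class=None``, the global profile summing all classes on absolute
    position indices.
    """

    events: list[ModEvent]
    samples: list[str]
    matures: frozenset | None = None

    def table(self, mod_class: str | None = None) -> pd.DataFrame:
        rows: dict[tuple[str, int], Counter] = defaultdict(Counter)
        for e in self.events:
            if mod_class is not None and e.mod_class != mod_class:
                continue
            pos = e.offset if mod_class is not None else e.index
            rows[(e.pattern, pos)][e.sample_id] += e.depth
        index = pd.MultiIndex.from_tuples(
            sorted(rows), names=["pattern", "position"]
        ) if rows else pd.MultiIndex.from_arrays([[], []], names=["pattern", "position"])
        df = pd.DataFrame(
            [[rows[key].get(s, 0.0) for s in self.samples] for key in sorted(rows)],
            index=index,
            columns=self.samples,
            dtype=float,
        )
        return df

    def for_mirna(self, mature_id: str) -> "ModProfile":
        if self.matures is not None and mature_id not in self.matures:
            raise KeyError(f"unknown mature miRNA {mature_id!r}")
        return ModProfile(
            [e for e in self.events if e.mature_id == mature_id],
            self.samples,
            self.matures,
        )

    @property
    def total_depth(self) -> float:
        return float(sum(e.depth for e in self.events))


def build_profiles(
    events: Sequence[ModEvent],
    samples: Sequence[str],
    matures: Iterable[str] | None = None,
) -> ModProfile:
    """Aggregate events into a :class:`ModProfile` (depth is conserved)."""
    return ModProfile(
        list(events), list(samples),
        frozenset(matures) if matures is not None else None,
    )


def profile_for_mirna(profile: ModProfile, mature_id: str) -> ModProfile:
    """Per-miRNA slice of a profile; raises KeyError for unknown IDs."""
    return profile.for_mirna(mature_id)


def render_rna(pattern: str) -> str:
    """Render a pattern in the RNA alphabet (T tails shown as U)."""
    return pattern.replace("T", "U")
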