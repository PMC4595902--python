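"""Canonical placements of mature miRNAs on their hairpins.

The canonical alignment of each mature on its hairpin defines the coordinate
frame for every modification position reported by the pipeline: index 0 is
the mature 5' end, index L-1 the 3'-terminal base of an L-nt mature, indices
beyond L are downstream extension and negative indices are upstream of the
5' end.  The display layer renders 3'-side positions as offsets about the 3'
end (+1 = first base after the terminal base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io_formats import ReferenceSet


@dataclass(frozen=True)
class MatureLocus:
    """0-based half-open placement of a mature miRNA on its hairpin."""

    mature_id: str
    hairpin_id: str
    start: int
    end: int
    n_mismatch: int = 0
    ambiguous: bool = False  # multiple equal-score placements; leftmost kept

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CanonicalDB:
    loci: dict[str, MatureLocus]
    by_hairpin: dict[str, list[MatureLocus]]
    rejects: list[tuple[str, str]] = field(default_factory=list)

    def __contains__(self, mature_id: str) -> bool:
        return mature_id in self.loci


def _hamming_le(a: str, b: str, bound: int) -> int | None:
    """Hamming distance if <= bound, else None (early exit)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > bound:
                return None
    return mm


def build_canonical_db(ref: ReferenceSet, max_mismatch: int = 1) -> CanonicalDB:
    """Place every mature on its hairpin by exact substring search.

    Falls back to the unique best placement with at most ``max_mismatch``
    mismatches (miRBase pairs occasionally disagree by a base); ties keep the
    leftmost placement and set ``ambiguous``.  Unplaceable matures are
    rejected, not fatal.  Iteration is over sorted mature IDs, so the result
    is independent of FASTA record order.
    """
    loci: dict[str, MatureLocus] = {}
    by_hairpin: dict[str, list[MatureLocus]] = {}
    rejects: list[tuple[str, str]] = []
    for mature_id in sorted(ref.matures):
        seq, hairpin_id = ref.matures[mature_id]
        hp = ref.hairpins[hairpin_id]
        pos = hp.find(seq)
        if pos >= 0:
            locus = MatureLocus(
                mature_id, hairpin_id, pos, pos + len(seq),
                n_mismatch=0, ambiguous=hp.find(seq, pos + 1) >= 0,
            )
        else:
            hits: list[tuple[int, int]] = []  # (mismatches, offset)
            for off in range(len(hp) - len(seq) + 1):
                mm = _hamming_le(hp[off : off + len(seq)], seq, max_mismatch)
                if mm is not None:
                    hits.append((mm, off))
            if not hits:
                rejects.append((mature_id, f"no placement with <={max_mismatch} mismatch"))
                continue
            best_mm = min(mm for mm, _ in hits)
            best = [off for mm, off in hits if mm == best_mm]
            locus = MatureLocus(
                mature_id, hairpin_id, best[0], best[0] + len(seq),
                n_mismatch=best_mm, ambiguous=len(best) > 1,
            )
        loci[mature_id] = locus
        by_hairpin.setdefault(hairpin_id, []).append(locus)
    for lst in by_hairpin.values():
        lst.sort(key=lambda l: (l.start, l.mature_id))
    return CanonicalDB(loci, by_hairpin, rejects)


def index_of(locus: MatureLocus, hairpin_pos: int) -> int:
    """Position index of a hairpin coordinate: 0 at the mature 5' end.

    The 3'-terminal base of an L-nt mature gets index L-1; the first base
    past the 3' end gets L; positions upstream of the 5' end are negative.
    """
    return hairpin_pos - locus.start


def offset3(locus: MatureLocus, index: int) -> int:
    """Offset about the 3' end: 0 at the terminal base, +1 just downstream."""
    return index - (locus.length - 1)


def offset5(locus: MatureLocus, index: int) -> int:
    """Offset about the 5' end (identical to the absolute index)."""
    return index


def save_db(db: CanonicalDB, path: str | Path) -> None:
    """Serialise the canonical DB as an inspectable TSV sidecar."""
    with open(path, "w") as fh:
        fh.write("#mature_id\thairpin_id\tstart\tend\tn_mismatch\tambiguous\n")
        for mid in sorted(db.loci):
            l = db.loci[mid]
            fh.write(
                f"{l.mature_id}\t{l.hairpin_id}\t{l.start}\t{l.end}\t"
                f"{l.n_mismatch}\t{int(l.ambiguous)}\n"
            )


def load_db(path: str | Path) -> CanonicalDB:
    loci: dict[str, MatureLocus] = {}
    by_hairpin: dict[str, list[MatureLocus]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"missing header in {path}")
        for line in fh:
            mid, hid, start, end, mm, amb = line.rstrip("\n").split("\t")
            locus = MatureLocus(mid, hid, int(start), int(end), int(mm), bool(int(amb)))
            loci[mid] = locus
            by_hairpin.setdefault(hid, []).append(locus)
    for lst in by_hairpin.values():
        lst.sort(key=lambda l: (l.start, l.mature_id))
    return CanonicalDB(loci, by_hairpin)
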