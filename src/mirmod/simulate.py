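"""Synthetic small RNA-seq data with known modification ground truth.

Generates a random hairpin/mature reference pair plus per-sample reads that
carry the signal classes the pipeline detects: non-templated 3' tails
(uridylation read as T, adenylation as A), 5' variants, internal A->G edits,
fixed SNP loci with an allele fraction, templated length variants, a 3'
sequencing adapter and uniform per-base sequencing error.  Every read's
injected events are recorded in a truth table, so parameter recovery can be
checked end to end without downloading anything.

A tail base that happens to equal the templated hairpin base downstream of
the mature is biologically indistinguishable from templated extension; the
truth table flags each tail with ``distinguishable`` accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_formats import ReadRecord, ReferenceSet, write_fasta, write_fastq
from .reference_db import MatureLocus

BASES = "ACGT"


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset (seed fixes all bytes)."""

    n_hairpins: int = 20
    hairpin_len: tuple[int, int] = (60, 90)
    mature_len: tuple[int, int] = (20, 24)
    # probability that a read carries a mono-/oligo-nucleotide 3' tail of
    # the given base (uridylation read as T)
    tail_rates: dict[str, float] = field(default_factory=lambda: {"T": 0.30, "A": 0.15})
    tail_length_probs: dict[int, float] = field(default_factory=lambda: {1: 1.0})
    templated_ext_rate: float = 0.10  # templated 3' length variant (isomiR)
    five_prime_rate: float = 0.05     # non-templated base upstream of the 5' end
    adar_rate: float = 0.10           # internal A->G edit per read
    n_snp_loci: int = 1
    snp_allele_fraction: float = 0.80
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_prob: float = 1.0
    seq_error: float = 0.001
    reads_per_sample: int = 5000
    n_samples: int = 2
    expression: str = "uniform"  # or "lognormal"
    paralogues: int = 0  # extra hairpins carrying a copy of family 1's mature
    margin: int = 12     # hairpin flank on each side of the embedded mature
    seed: int = 0

    def validate(self) -> None:
        rates = [
            *self.tail_rates.values(), self.templated_ext_rate,
            self.five_prime_rate, self.adar_rate, self.snp_allele_fraction,
            self.adapter_prob, self.seq_error,
        ]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ConfigError("all rates must lie in [0, 1]")
        if self.templated_ext_rate + sum(self.tail_rates.values()) > 1.0:
            raise ConfigError("templated_ext_rate + tail rates must not exceed 1")
        if self.mature_len[1] + 2 * self.margin > self.hairpin_len[0]:
            raise ConfigError(
                "mature plus flanks does not fit in the hairpin: need "
                f"hairpin length >= {self.mature_len[1] + 2 * self.margin}"
            )
        if self.expression not in ("uniform", "lognormal"):
            raise ConfigError(f"unknown expression model {self.expression!r}")
        if abs(sum(self.tail_length_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("tail_length_probs must sum to 1")


@dataclass(frozen=True)
class SnpLocus:
    mature_id: str
    index: int
    ref_base: str
    alt: str
    allele_fraction: float


@dataclass
class SimReference:
    ref: ReferenceSet
    loci: dict[str, MatureLocus]  # ground-truth placements
    snp_loci: list[SnpLocus]


@dataclass
class SimData:
    config: SimConfig
    reference: SimReference
    reads: dict[str, list[ReadRecord]]
    truth: pd.DataFrame  # one row per injected event


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _internal_range(length: int, window_5p=(-8, 5), window_3p=(-5, 6)) -> range:
    # indices outside both terminal windows
    lo = window_5p[1] + 1
    hi = (length - 1) + window_3p[0] - 1  # last index strictly upstream of 3' window
    return range(lo, hi + 1)


def make_reference(cfg: SimConfig, rng: np.random.Generator | None = None) -> SimReference:
    """Random hairpins with embedded matures at known, unique offsets.

    Hairpins are rejection-sampled so every mature sequence occurs exactly
    once across the whole reference (controlled multimapping); the
    ``paralogues`` option then copies family 1's mature into extra hairpins
    to exercise fractional counting.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    hairpins: dict[str, str] = {}
    matures: dict[str, tuple[str, str]] = {}
    loci: dict[str, MatureLocus] = {}

    def embed(hid: str, mid: str, forced_mature: str | None = None) -> None:
        for _ in range(1000):
            lh = int(rng.integers(cfg.hairpin_len[0], cfg.hairpin_len[1] + 1))
            lm = (
                len(forced_mature)
                if forced_mature is not None
                else int(rng.integers(cfg.mature_len[0], cfg.mature_len[1] + 1))
            )
            start = int(rng.integers(cfg.margin, lh - lm - cfg.margin + 1))
            hp = _random_seq(rng, lh)
            if forced_mature is not None:
                hp = hp[:start] + forced_mature + hp[start + lm :]
            mat = hp[start : start + lm]
            n_here = hp.count(mat)
            expected = 1
            if n_here != expected:
                continue
            clash = any(mat in other for other in hairpins.values()) or any(
                mseq in hp for mseq, _ in matures.values()
            )
            if clash and forced_mature is None:
                continue
            if forced_mature is not None and any(
                mseq in hp for mseq, _ in matures.values() if mseq != forced_mature
            ):
                continue
            hairpins[hid] = hp
            matures[mid] = (mat, hid)
            loci[mid] = MatureLocus(mid, hid, start, start + lm)
            return
        raise ConfigError(f"could not place a unique mature for {hid}")

    for i in range(1, cfg.n_hairpins + 1):
        embed(f"sim-mir-{i}", f"sim-miR-{i}-5p")
    first_mature = matures["sim-miR-1-5p"][0] if cfg.n_hairpins else None
    for j in range(cfg.paralogues):
        suffix = chr(ord("b") + j)
        embed(f"sim-mir-1{suffix}", f"sim-miR-1{suffix}-5p", forced_mature=first_mature)

    snp_loci: list[SnpLocus] = []
    if cfg.n_snp_loci and loci:
        mids = sorted(loci)
        for _ in range(cfg.n_snp_loci):
            for _try in range(1000):
                mid = mids[int(rng.integers(len(mids)))]
                locus = loci[mid]
                candidates = list(_internal_range(locus.length))
                if not candidates:
                    continue
                idx = candidates[int(rng.integers(len(candidates)))]
                ref_base = matures[mid][0][idx]
                alts = [b for b in BASES if b != ref_base]
                alt = alts[int(rng.integers(3))]
                key = (mid, idx)
                if key not in {(s.mature_id, s.index) for s in snp_loci}:
                    snp_loci.append(SnpLocus(mid, idx, ref_base, alt, cfg.snp_allele_fraction))
                    break
    return SimReference(ReferenceSet(hairpins, matures), loci, snp_loci)


def _sample_tail(cfg: SimConfig, u: float) -> str | None:
    """Map a uniform draw onto {templated-extension handled by caller} tails."""
    acc = cfg.templated_ext_rate
    for base in sorted(cfg.tail_rates):
        acc += cfg.tail_rates[base]
        if u < acc:
            return base
    return None


def make_reads(
    cfg: SimConfig,
    simref: SimReference,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Per-sample reads plus the injected-event truth table.

    Templated extension and 3' tailing are mutually exclusive per read, so
    every injected tail starts exactly 1 nt after the 3' end; 5' variants,
    internal edits and SNP substitutions are drawn independently.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    mids = sorted(simref.loci)
    if not mids:
        raise ConfigError("empty reference")
    if cfg.expression == "lognormal":
        weights = rng.lognormal(0.0, 1.0, size=len(mids))
        weights /= weights.sum()
    else:
        weights = np.full(len(mids), 1.0 / len(mids))
    snp_by_mid: dict[str, list[SnpLocus]] = {}
    for s in simref.snp_loci:
        snp_by_mid.setdefault(s.mature_id, []).append(s)

    tail_lens = sorted(cfg.tail_length_probs)
    tail_len_p = np.array([cfg.tail_length_probs[l] for l in tail_lens])

    reads: dict[str, list[ReadRecord]] = {}
    truth_rows: list[dict] = []
    for si in range(1, cfg.n_samples + 1):
        sample = f"sample{si}"
        sample_reads: list[ReadRecord] = []
        for n in range(cfg.reads_per_sample):
            rid = f"{sample}.r{n:06d}"
            mid = mids[int(rng.choice(len(mids), p=weights))]
            locus = simref.loci[mid]
            hp = simref.ref.hairpins[locus.hairpin_id]
            body = list(hp[locus.start : locus.end])
            L = locus.length

            def record(kind, pattern, offset, distinguishable=True):
                truth_rows.append(
                    dict(sample_id=sample, read_id=rid, mature_id=mid, kind=kind,
                         pattern=pattern, offset=offset,
                         distinguishable=bool(distinguishable))
                )

            # internal ADAR edit
            if rng.random() < cfg.adar_rate:
                a_pos = [i for i in _internal_range(L) if body[i] == "A"]
                if a_pos:
                    i = a_pos[int(rng.integers(len(a_pos)))]
                    body[i] = "G"
                    record("adar", "G", i)
            # SNP loci
            for s in snp_by_mid.get(mid, []):
                if rng.random() < s.allele_fraction and body[s.index] == s.ref_base:
                    body[s.index] = s.alt
                    record("snp", s.alt, s.index)
            # 3' end: templated extension XOR non-templated tail
            suffix = ""
            u = rng.random()
            if u < cfg.templated_ext_rate:
                k = 1 + int(rng.random() < 0.3)
                suffix = hp[locus.end : locus.end + k]
                record("ext_templated", suffix, 1)
            else:
                tail_base = _sample_tail(cfg, u)
                if tail_base is not None:
                    tl = int(rng.choice(tail_lens, p=tail_len_p))
                    suffix = tail_base * tl
                    templ = hp[locus.end] if locus.end < len(hp) else ""
                    record("tail3p", suffix, 1, distinguishable=(templ != tail_base))
            # 5' variant: one non-templated prepended base
            prefix = ""
            if rng.random() < cfg.five_prime_rate:
                templ5 = hp[locus.start - 1] if locus.start > 0 else ""
                choices = [b for b in BASES if b != templ5]
                prefix = choices[int(rng.integers(len(choices)))]
                record("var5p", prefix, -1)

            seq = prefix + "".join(body) + suffix
            if rng.random() < cfg.adapter_prob:
                seq += cfg.adapter
            if cfg.seq_error > 0:
                arr = list(seq)
                hits = np.flatnonzero(rng.random(len(arr)) < cfg.seq_error)
                for i in hits:
                    alts = [b for b in BASES if b != arr[i]]
                    arr[i] = alts[int(rng.integers(3))]
                if len(hits):
                    seq = "".join(arr)
            sample_reads.append(ReadRecord(rid, seq, "I" * len(seq)))
        reads[sample] = sample_reads
    columns = ["sample_id", "read_id", "mature_id", "kind", "pattern", "offset",
               "distinguishable"]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return reads, truth


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Reference + reads + truth from one config (fully seed-determined)."""
    rng = np.random.default_rng(cfg.seed)
    simref = make_reference(cfg, rng)
    reads, truth = make_reads(cfg, simref, rng)
    return SimData(cfg, simref, reads, truth)


def write_simulation(data: SimData, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA references, per-sample FASTQs and truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["hairpins"] = outdir / "hairpins.fa"
    write_fasta(dict(sorted(data.reference.ref.hairpins.items())), paths["hairpins"])
    paths["matures"] = outdir / "matures.fa"
    write_fasta(
        {mid: seq for mid, (seq, _) in sorted(data.reference.ref.matures.items())},
        paths["matures"],
    )
    for sample in sorted(data.reads):
        p = outdir / f"{sample}.fastq"
        write_fastq(data.reads[sample], p)
        paths[sample] = p
    paths["truth_loci"] = outdir / "truth_loci.tsv"
    with open(paths["truth_loci"], "w") as fh:
        fh.write("#mature_id\thairpin_id\tstart\tend\n")
        for mid in sorted(data.reference.loci):
            l = data.reference.loci[mid]
            fh.write(f"{l.mature_id}\t{l.hairpin_id}\t{l.start}\t{l.end}\n")
    paths["truth_snps"] = outdir / "truth_snps.tsv"
    with open(paths["truth_snps"], "w") as fh:
        fh.write("#mature_id\tindex\tref_base\talt\tallele_fraction\n")
        for s in data.reference.snp_loci:
            fh.write(f"{s.mature_id}\t{s.index}\t{s.ref_base}\t{s.alt}\t{s.allele_fraction}\n")
    paths["truth_events"] = outdir / "truth_events.tsv"
    data.truth.to_csv(paths["truth_events"], sep="\t", index=False)
    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(asdict(data.config), fh, sort_keys=True)
    return paths
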