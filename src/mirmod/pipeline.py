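"""End-to-end orchestration: preprocess, align, quantify, call modifications.

Runs every stage in a fixed order with deterministic, sorted outputs, so a
rerun with the same config produces byte-identical files.  The run log
records per-stage read tallies (input, trimmed, size-selected, unique,
mapped) which are monotone non-increasing through the filters.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import aligner, modcaller, preprocess, quantify
from .io_formats import load_reference, read_sequences, write_matrix
from .reference_db import build_canonical_db, save_db


class ConfigError(ValueError):
    pass


@dataclass
class SampleSpec:
    path: str
    adapter: str | None = None


@dataclass
class RunConfig:
    samples: dict[str, SampleSpec]
    hairpin_fasta: str
    mature_fasta: str
    outdir: str
    multimap: str = "first_hit"          # or "fractional"
    max_mismatches: int = 2
    min_core: int = 15
    min_len: int = 16
    max_len: int = 35
    window_3p: tuple[int, int] = modcaller.WINDOW_3P
    window_5p: tuple[int, int] = modcaller.WINDOW_5P
    snp_threshold: float = 0.70
    pseudo: float = 1.0                  # fold-change pseudo-count
    sf_pseudocount: float = 0.0          # size-factor fallback pseudo-count
    infer_adapters: bool = False
    rna_patterns: bool = False           # render tail patterns with U instead of T
    top_n: int = 10
    group_a: list[str] = field(default_factory=list)
    group_b: list[str] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = {
            sid: SampleSpec(**spec) if isinstance(spec, dict) else SampleSpec(spec)
            for sid, spec in raw.pop("samples").items()
        }
        for key in ("window_3p", "window_5p"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(samples=samples, **raw)

    def validate(self) -> None:
        if not self.samples:
            raise ConfigError("no samples configured")
        for sid, spec in self.samples.items():
            if not Path(spec.path).exists():
                raise ConfigError(f"sample {sid!r}: file not found: {spec.path}")
        for p in (self.hairpin_fasta, self.mature_fasta):
            if not Path(p).exists():
                raise ConfigError(f"reference file not found: {p}")
        if self.multimap not in ("first_hit", "fractional"):
            raise ConfigError(f"unknown multimap policy {self.multimap!r}")
        if not 0.0 < self.snp_threshold <= 1.0:
            raise ConfigError("snp_threshold must lie in (0, 1]")
        if self.min_len > self.max_len or self.min_len < 1:
            raise ConfigError("invalid size-selection window")


def _render(pattern: str, rna: bool) -> str:
    return modcaller.render_rna(pattern) if rna else pattern


def run(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline; returns the paths of every written table."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log = logging.getLogger("mirmod.run")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.propagate = False

    try:
        ref = load_reference(config.hairpin_fasta, config.mature_fasta)
    except Exception as exc:
        log.error("stage reference: %s", exc)
        raise
    db = build_canonical_db(ref)
    log.info(
        "reference: %d hairpins, %d matures placed, %d linkage rejects, %d placement rejects",
        len(ref.hairpins), len(db.loci), len(ref.rejects), len(db.rejects),
    )

    hp_aligner = aligner.HairpinAligner(ref, config.max_mismatches, config.min_core)
    policy = aligner.MultiMapPolicy(config.multimap)
    caller = modcaller.EventCaller(
        ref, db, window_3p=config.window_3p, window_5p=config.window_5p
    )

    samples = sorted(config.samples)
    attributions: list[tuple[str, str, float]] = []
    stage_rows = []
    placement_cache: dict[str, list[aligner.Placement]] = {}
    for sample in samples:
        spec = config.samples[sample]
        raw = list(read_sequences(spec.path))
        adapter = spec.adapter
        if adapter is None and config.infer_adapters:
            call = preprocess.infer_adapter(raw)
            adapter = call.adapter if call else None
            log.info("sample %s: inferred adapter %s", sample, adapter or "none")
        trimmed = (
            [preprocess.trim_adapter(r, adapter) for r in raw] if adapter else list(raw)
        )
        n_trimmed = sum(1 for r, t in zip(raw, trimmed) if len(t.seq) < len(r.seq))
        stats: Counter = Counter()
        selected = list(
            preprocess.size_select(trimmed, config.min_len, config.max_len, stats)
        )
        uniq = preprocess.collapse(selected, sample)
        mapped_depth = 0
        for u in uniq:
            if u.seq not in placement_cache:
                placement_cache[u.seq] = hp_aligner.place(u.seq)
            placements = placement_cache[u.seq]
            if not placements:
                continue
            mapped_depth += u.depth
            for p, w in aligner.resolve_multimap(placements, policy):
                mid = caller.process(p, w, sample, u.depth)
                if mid is not None:
                    attributions.append((mid, sample, w * u.depth))
        stage_rows.append(
            dict(sample=sample, input=len(raw), trimmed=n_trimmed,
                 size_selected=len(selected), unique=len(uniq), mapped=mapped_depth)
        )
        log.info(
            "sample %s: input=%d trimmed=%d size_selected=%d unique=%d mapped=%d",
            sample, len(raw), n_trimmed, len(selected), len(uniq), mapped_depth,
        )

    matures = sorted(db.loci)
    counts = quantify.plain_counts(attributions, samples, matures)
    if len(samples) >= 2:
        try:
            factors = quantify.size_factors(counts, config.sf_pseudocount)
        except ValueError as exc:
            log.error("stage normalize: %s", exc)
            raise
    else:
        factors = pd.Series(1.0, index=samples, name="size_factor")
    norm = quantify.normalize(counts, factors)

    calls = modcaller.classify_internal(
        caller.events, caller.coverage, config.snp_threshold
    )
    profile = modcaller.build_profiles(caller.events, samples, matures)

    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        paths[name] = outdir / f"{name}.tsv"
        write_matrix(df, paths[name])

    counts.index.name = "mature_id"
    norm.index.name = "mature_id"
    emit("counts_raw", counts)
    emit("counts_norm", norm)
    emit("size_factors", factors.to_frame())
    emit("qc_total_counts", quantify.total_counts(counts).to_frame())

    for name, cls in (
        ("mods_3p", modcaller.MOD3P),
        ("mods_5p", modcaller.MOD5P),
        ("internal", modcaller.INTERNAL),
    ):
        table = profile.table(cls)
        if config.rna_patterns and len(table):
            table.index = table.index.map(
                lambda t: (_render(t[0], True), t[1])
            ).set_names(["pattern", "position"])
        emit(name, table)
    emit("profile_global", profile.table(None))

    calls_df = pd.DataFrame(
        [
            dict(mature_id=c.mature_id, index=c.index, ref_base=c.ref_base,
                 alt=c.alt, modified_depth=c.modified_depth,
                 total_depth=c.total_depth, ratio=c.ratio, label=c.label)
            for c in calls
        ],
        columns=["mature_id", "index", "ref_base", "alt", "modified_depth",
                 "total_depth", "ratio", "label"],
    ).set_index(["mature_id", "index", "ref_base", "alt"])
    emit("internal_calls", calls_df)

    if len(samples) >= 2:
        group_a = config.group_a or samples[: len(samples) // 2]
        group_b = config.group_b or samples[len(samples) // 2 :]
        emit("top_n", quantify.top_expressed(norm, group_a, group_b, config.top_n))
        emit("pairwise", quantify.pairwise_table(norm, group_a, group_b, config.pseudo))

    stage_df = pd.DataFrame(stage_rows).set_index("sample")
    emit("stage_counts", stage_df)

    paths["reference_db"] = outdir / "reference_db.tsv"
    save_db(db, paths["reference_db"])
    with open(outdir / "rejects.tsv", "w") as fh:
        fh.write("#id\tstage\treason\n")
        for mid, reason in sorted(ref.rejects):
            fh.write(f"{mid}\tlinkage\t{reason}\n")
        for mid, reason in sorted(db.rejects):
            fh.write(f"{mid}\tplacement\t{reason}\n")
    paths["rejects"] = outdir / "rejects.tsv"

    log.info("done: %d tables written", len(paths))
    handler.close()
    log.removeHandler(handler)
    return paths
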