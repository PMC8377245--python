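"""End-to-end orchestration: ingest -> randomize -> score -> profile -> report.

A single :class:`RunConfig` (usually loaded from YAML) drives deterministic
runs. Every report is a TSV whose header comments record the package
version, the seed, and a hash of the configuration, so outputs are
self-describing and byte-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .cohort import compare_content, comparisons_frame
from .nulls import RandomizationSpec, randomize_proteome
from .profiles import (
    gc_tracks,
    positional_profile,
    profile_pair_frame,
    truncate_termini,
    zscore_profile,
)
from .proteomes import Proteome, attach_annotations, attach_cds, filter_proteins, read_fasta
from .scoring import default_scale, disorder_content_table, score_proteome
from .synthetic import SyntheticSpec, generate_proteome

log = logging.getLogger("disprof")

PROFILE_MODELS = ("terminal_conserved", "column_wise")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """All parameters of one pipeline run."""

    protein_fasta: Optional[str] = None
    cds_fasta: Optional[str] = None
    go_table: Optional[str] = None
    expression_table: Optional[str] = None
    exon_table: Optional[str] = None
    synth: Optional[dict] = None  # SyntheticSpec overrides; used when no FASTA given

    terminal_window: int = 200
    replicates: int = 10
    scorer_window: int = 21
    call_threshold: float = 0.5
    n_positions: int = 150
    min_length: int = 200
    truncation_k: int = 50

    models: tuple = PROFILE_MODELS
    run_gc: bool = False
    run_truncation: bool = False
    run_go: bool = False
    run_expression: bool = False
    run_splice: bool = False
    expression_q: float = 0.25
    go_min_proteins: int = 100
    splice_window_bp: int = 300

    outdir: str = "disprof_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.models, list):
            cfg.models = tuple(cfg.models)
        return cfg

    def validate(self) -> None:
        if self.protein_fasta is None and self.synth is None:
            raise ConfigError("either protein_fasta or a synth block is required")
        for name in ("protein_fasta", "cds_fasta", "go_table",
                     "expression_table", "exon_table"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        for model in self.models:
            if model not in PROFILE_MODELS:
                raise ConfigError(f"unknown profile model {model!r}")
        if self.run_gc and self.cds_fasta is None and not self._synth_has_cds():
            raise ConfigError("run_gc requires cds_fasta (or a synth target_gc)")
        if self.run_go and self.go_table is None:
            raise ConfigError("run_go requires go_table")
        if self.run_expression and self.expression_table is None:
            raise ConfigError("run_expression requires expression_table")
        if self.run_splice and self.exon_table is None:
            raise ConfigError("run_splice requires exon_table")

    def _synth_has_cds(self) -> bool:
        return bool(self.synth) and self.synth.get("target_gc") is not None

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


def write_report(df: pd.DataFrame, path, config: RunConfig) -> Path:
    """Write a TSV with provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# disprof {__version__}\n")
        fh.write(f"# seed={config.seed} config_sha={config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def load_proteome(config: RunConfig) -> Proteome:
    """Read (or synthesize), filter, and annotate the input proteome."""
    if config.protein_fasta is not None:
        proteome = read_fasta(config.protein_fasta, alphabet="amino")
        if config.cds_fasta is not None:
            cds = read_fasta(config.cds_fasta, alphabet="nucleotide")
            proteome, unmatched = attach_cds(proteome, cds)
            if unmatched:
                log.warning("%d proteins without a matching CDS", unmatched)
    else:
        spec = SyntheticSpec(**{"seed": config.seed, **(config.synth or {})})
        proteome, _ = generate_proteome(spec)
    proteome, rejected = filter_proteins(proteome)
    if len(rejected):
        log.info("filtered out %d records", len(rejected))
    for table, kind in ((config.go_table, "go"),
                        (config.expression_table, "expression"),
                        (config.exon_table, "exon")):
        if table is not None:
            proteome, note = attach_annotations(proteome, table, kind)
            log.info("%s annotations: %s", kind, note)
    return proteome


def run_content_comparison(config: RunConfig) -> Path:
    """Disorder-content comparison against the length-conserved null.

    Writes one TSV with a row per metric (Dis_all and Dis_30 percentages),
    comparing real proteins with the pooled R-replicate random sample by
    Mann-Whitney U.
    """
    config.validate()
    proteome = load_proteome(config)
    scale = default_scale(window=config.scorer_window)
    real = disorder_content_table(proteome, scale, config.call_threshold)
    spec = RandomizationSpec(model="length_conserved", replicates=config.replicates,
                             seed=config.seed)
    reps = randomize_proteome(proteome, spec)
    rep_tables = [
        disorder_content_table(rep.proteome, scale, config.call_threshold) for rep in reps
    ]
    comparisons = [
        compare_content(
            real[metric], [t[metric] for t in rep_tables], metric,
            group_label=proteome.species_label or "all",
        )
        for metric in ("pct_dis_all", "pct_dis30")
    ]
    return write_report(
        comparisons_frame(comparisons),
        Path(config.outdir) / "content_comparison.tsv",
        config,
    )


def _zprofile_frames(proteome: Proteome, config: RunConfig, model: str,
                     tag: str = "") -> pd.DataFrame:
    """N+C Z-profiles of the baseline disorder score against one null model."""
    scale = default_scale(window=config.scorer_window)
    tracks = score_proteome(proteome, scale)
    spec = RandomizationSpec(model=model, terminal_window=config.terminal_window,
                             replicates=config.replicates, seed=config.seed)
    reps = randomize_proteome(proteome, spec)
    rep_tracks = [score_proteome(rep.proteome, scale) for rep in reps]
    frames = []
    for anchor in ("N", "C"):
        real_prof = positional_profile(proteome, tracks, anchor,
                                       config.n_positions, config.min_length)
        rep_profs = [
            positional_profile(rep.proteome, rt, anchor, config.n_positions,
                               config.min_length)
            for rep, rt in zip(reps, rep_tracks)
        ]
        zp = zscore_profile(real_prof, rep_profs)
        frames.append(zp.to_frame())
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "model", model)
    if tag:
        df.insert(0, "subset", tag)
    return df


def _gc_zprofile_frames(proteome: Proteome, config: RunConfig, model: str) -> pd.DataFrame:
    """N+C Z-profiles of per-codon GC against a codon-level null model."""
    with_cds = proteome.with_records([r for r in proteome if r.cds is not None],
                                     note="records with CDS")
    tracks = gc_tracks(with_cds)
    spec = RandomizationSpec(model=model, terminal_window=config.terminal_window,
                             replicates=config.replicates, seed=config.seed,
                             level="codon")
    reps = randomize_proteome(with_cds, spec)
    frames = []
    for anchor in ("N", "C"):
        real_prof = positional_profile(with_cds, tracks, anchor,
                                       config.n_positions, config.min_length)
        rep_profs = [
            positional_profile(rep.proteome, gc_tracks(rep.proteome), anchor,
                               config.n_positions, config.min_length)
            for rep in reps
        ]
        frames.append(zscore_profile(real_prof, rep_profs).to_frame())
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "model", model)
    df.insert(0, "track", "gc")
    return df


def run_position_analysis(config: RunConfig) -> list[Path]:
    """Position-wise Z-profiles against the configured null models.

    Always writes ``zprofile_<model>.tsv`` for each configured model;
    config toggles add the truncated-terminus control, codon-level GC
    profiles, and GO / expression / splice-filtered stratifications.
    """
    config.validate()
    proteome = load_proteome(config)
    out = Path(config.outdir)
    written: list[Path] = []

    for model in config.models:
        df = _zprofile_frames(proteome, config, model)
        written.append(write_report(df, out / f"zprofile_{model}.tsv", config))

    if config.run_truncation:
        truncated, dropped = truncate_termini(proteome, config.truncation_k)
        log.info("truncation control: dropped %d short records", len(dropped))
        for model in config.models:
            df = _zprofile_frames(truncated, config, model,
                                  tag=f"truncated{config.truncation_k}")
            written.append(
                write_report(df, out / f"zprofile_{model}_truncated.tsv", config)
            )

    if config.run_gc:
        for model in config.models:
            df = _gc_zprofile_frames(proteome, config, model)
            written.append(write_report(df, out / f"zprofile_gc_{model}.tsv", config))

    if config.run_go:
        from .cohort import group_by_go

        groups = group_by_go(proteome, config.go_min_proteins, config.min_length)
        frames = []
        for term, sub in groups.items():
            df = _zprofile_frames(sub, config, "terminal_conserved", tag=term)
            frames.append(df)
        if frames:
            written.append(
                write_report(pd.concat(frames, ignore_index=True),
                             out / "zprofile_go_terms.tsv", config)
            )

    if config.run_expression:
        from .cohort import stratify_by_expression

        high, low = stratify_by_expression(proteome, config.expression_q)
        frames = []
        for tag, sub in (("high_expression", high), ("low_expression", low)):
            for model in config.models:
                frames.append(_zprofile_frames(sub, config, model, tag=tag))
        written.append(
            write_report(pd.concat(frames, ignore_index=True),
                         out / "zprofile_expression.tsv", config)
        )

    if config.run_splice:
        from .cohort import filter_splice_free

        subset, unannotated = filter_splice_free(proteome, config.splice_window_bp)
        log.info("splice filter: %d retained, %d unannotated",
                 len(subset), len(unannotated))
        frames = [
            _zprofile_frames(subset, config, model, tag="splice_free")
            for model in config.models
        ]
        written.append(
            write_report(pd.concat(frames, ignore_index=True),
                         out / "zprofile_splice_free.tsv", config)
        )
    return written
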