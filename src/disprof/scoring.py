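"""Per-residue disorder scores, binary calls, consensus, and content metrics.

Scores come either from the built-in baseline scorer — a sliding-window mean
of a per-residue disorder propensity scale, a deliberately simple stand-in
with the same interface as external predictors — or from ingested predictor
output (one score per residue, IUPred-style three-column TSV). Binary calls
are thresholded scores; calls from several predictors combine through a
generic k-of-n agreement rule with two presets: *strict* (all predictors
agree) and *majority* (more than half agree).

Per-protein disorder content is summarized two ways: ``percent_dis_all``
(percentage of all called residues) and ``percent_dis30`` (percentage of
called residues lying in runs of >= 30 consecutive calls, the conventional
long-disordered-region cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .proteomes import Proteome, ProteinRecord

LONG_REGION_MIN_RUN = 30


class TrackAlignmentError(ValueError):
    """External track disagrees with the protein sequence."""


@dataclass(frozen=True)
class PropensityScale:
    """Map from the 20 canonical residues to disorder propensities in [0, 1]."""

    values: dict
    window: int = 21
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale is missing residues: {sorted(missing)}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd positive integer")
        for aa, v in self.values.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"scale value for {aa} outside [0, 1]: {v}")

    def lookup_table(self) -> np.ndarray:
        lut = np.full(128, np.nan)
        for aa, v in self.values.items():
            lut[ord(aa)] = float(v)
        return lut


def default_scale(window: int = 21) -> PropensityScale:
    """The packaged rescaled disorder-propensity scale."""
    raw = yaml.safe_load(
        resources.files("disprof").joinpath("data/disorder_propensity.yaml").read_text()
    )
    return PropensityScale(values=raw["values"], window=window, name=raw.get("name", "packaged"))


@dataclass
class ScoreTrack:
    """Per-residue real-valued scores in [0, 1] for one protein."""

    protein_id: str
    scores: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("scores must be a non-empty 1-D sequence")
        if np.nanmin(self.scores) < 0.0 or np.nanmax(self.scores) > 1.0:
            raise ValueError("scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class CallTrack:
    """Per-residue binary disorder calls for one protein."""

    protein_id: str
    calls: np.ndarray
    rule: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)

    def __len__(self) -> int:
        return self.calls.size


@dataclass
class ConsensusSpec:
    """k-of-n agreement rule over named predictors.

    ``thresholds`` maps predictor name to its binary-call cutoff (each
    predictor's published cutoff in practice; 0.5 by default).
    """

    predictor_names: list[str]
    agreement_k: int
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.predictor_names)
        if not 1 <= self.agreement_k <= n:
            raise ValueError(f"agreement_k must be in 1..{n}, got {self.agreement_k}")

    @classmethod
    def strict(cls, predictor_names: Sequence[str], thresholds: Optional[dict] = None):
        """All predictors must agree (mutual-agreement preset)."""
        names = list(predictor_names)
        return cls(names, agreement_k=len(names), thresholds=thresholds or {})

    @classmethod
    def majority(cls, predictor_names: Sequence[str], thresholds: Optional[dict] = None):
        """More than half of the predictors must agree (majority-vote preset)."""
        names = list(predictor_names)
        return cls(names, agreement_k=len(names) // 2 + 1, thresholds=thresholds or {})

    def threshold_for(self, name: str) -> float:
        return float(self.thresholds.get(name, 0.5))


def score_values(seq: str, scale: PropensityScale) -> np.ndarray:
    """Sliding-window mean propensity, window truncated at sequence ends."""
    lut = scale.lookup_table()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    vals = lut[codes]
    if np.isnan(vals).any():
        bad = seq[int(np.flatnonzero(np.isnan(vals))[0])]
        raise KeyError(f"residue {bad!r} absent from propensity scale")
    h = scale.window // 2
    L = vals.size
    cs = np.concatenate(([0.0], np.cumsum(vals)))
    idx = np.arange(L)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, L)
    return (cs[hi] - cs[lo]) / (hi - lo)


def baseline_score(record: ProteinRecord, scale: Optional[PropensityScale] = None) -> ScoreTrack:
    """Score one protein with the sliding-window propensity baseline."""
    scale = scale or default_scale()
    return ScoreTrack(
        protein_id=record.id,
        scores=score_values(record.seq, scale),
        source=f"baseline:{scale.name}:w{scale.window}",
    )


def score_proteome(proteome: Proteome, scale: Optional[PropensityScale] = None) -> dict:
    """Score every record; returns ``{id: np.ndarray of scores}``."""
    scale = scale or default_scale()
    return {rec.id: score_values(rec.seq, scale) for rec in proteome}


def read_external_track(path, record: ProteinRecord, source: str = "external") -> ScoreTrack:
    """Read a per-residue score track (TSV: position, residue, score; 1-based).

    The residue column is cross-checked against the protein sequence; a
    length or residue mismatch raises :class:`TrackAlignmentError` naming the
    first discrepant position. Scores outside [0, 1] are clipped with a
    warning reporting how many values were affected.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["position", "residue", "score"])
    if len(df) != len(record.seq):
        raise TrackAlignmentError(
            f"{record.id!r}: track has {len(df)} rows for a "
            f"{len(record.seq)}-residue protein (first discrepancy at position "
            f"{min(len(df), len(record.seq)) + 1})"
        )
    residues = df["residue"].astype(str).str.upper().to_numpy()
    seq_arr = np.array(list(record.seq))
    mismatch = np.flatnonzero(residues != seq_arr)
    if mismatch.size:
        p = int(mismatch[0])
        raise TrackAlignmentError(
            f"{record.id!r}: residue mismatch at position {p + 1}: "
            f"track has {residues[p]!r}, sequence has {seq_arr[p]!r}"
        )
    scores = df["score"].astype(float).to_numpy()
    n_out = int(((scores < 0.0) | (scores > 1.0)).sum())
    if n_out:
        warnings.warn(
            f"{record.id!r}: clipped {n_out} score(s) outside [0, 1] to the unit interval",
            stacklevel=2,
        )
        scores = np.clip(scores, 0.0, 1.0)
    return ScoreTrack(protein_id=record.id, scores=scores, source=source)


def call_binary(track: ScoreTrack, threshold: float) -> CallTrack:
    """Binary calls: residue is disordered iff score >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return CallTrack(
        protein_id=track.protein_id,
        calls=track.scores >= threshold,
        rule=f"{track.source}>= {threshold:g}",
    )


def consensus_calls(tracks: Sequence[CallTrack], spec: ConsensusSpec) -> CallTrack:
    """Combine call tracks for one protein with the k-of-n agreement rule."""
    if len(tracks) != len(spec.predictor_names):
        raise ValueError(
            f"got {len(tracks)} tracks for {len(spec.predictor_names)} predictors"
        )
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError(f"call tracks have mismatched lengths: {sorted(lengths)}")
    votes = np.sum([t.calls for t in tracks], axis=0)
    return CallTrack(
        protein_id=tracks[0].protein_id,
        calls=votes >= spec.agreement_k,
        rule=f"{spec.agreement_k}-of-{len(tracks)}",
    )


def _run_lengths(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run_value, run_length) pairs of a boolean array."""
    if calls.size == 0:
        return np.array([], dtype=bool), np.array([], dtype=int)
    change = np.flatnonzero(np.diff(calls.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [calls.size]))
    return calls[starts], ends - starts


def percent_dis_all(calls: CallTrack) -> float:
    """Percentage of residues called disordered."""
    return 100.0 * float(np.count_nonzero(calls.calls)) / len(calls)


def percent_dis30(calls: CallTrack, min_run: int = LONG_REGION_MIN_RUN) -> float:
    """Percentage of residues in maximal disordered runs of >= ``min_run``.

    Runs are maximal stretches of consecutive calls; runs are never merged
    across gaps.
    """
    vals, lens = _run_lengths(calls.calls)
    hit = vals & (lens >= min_run)
    return 100.0 * float(lens[hit].sum()) / len(calls)


def disorder_content_table(
    proteome: Proteome,
    scale: Optional[PropensityScale] = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-protein Dis_all / Dis_30 percentages from the baseline scorer.

    Returns a frame with columns ``id``, ``pct_dis_all``, ``pct_dis30``.
    """
    scale = scale or default_scale()
    rows = []
    for rec in proteome:
        calls = call_binary(baseline_score(rec, scale), threshold)
        rows.append(
            {
                "id": rec.id,
                "pct_dis_all": percent_dis_all(calls),
                "pct_dis30": percent_dis30(calls),
            }
        )
    return pd.DataFrame(rows, columns=["id", "pct_dis_all", "pct_dis30"])
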