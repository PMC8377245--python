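"""Position-wise profiles anchored at protein termini and Z-score statistics.

Any per-residue quantity (disorder score, binary call, per-codon GC, an
external predictor track) is aggregated position-by-position from either
terminus over all sufficiently long proteins, then the real proteome's
per-position means are compared with those of R randomized replicate
proteomes.

The Z statistic
---------------
At each position the replicate proteomes provide R means; their average is
the null mean and their sample standard deviation the null spread. The plain
standardized deviation ``z_ratio = (real_mean - null_mean) / null_sd`` is
the quantity "in units of standard deviation". Because the null spread is
estimated from only R replicates — and because under a composition-
preserving shuffle the real mean is exchangeable with the replicate means —
``z_ratio`` is distributed as ``sqrt(1 + 1/R) * t_{R-1}`` under the null,
not as a standard normal. The profile therefore also carries a calibrated
deviate ``z``: the signed standard-normal quantile of the exact two-sided
``t_{R-1}`` p-value of ``z_ratio / sqrt(1 + 1/R)``. With the calibrated
``z``, the familiar 1.96 cutoff corresponds to a genuine 5% level for any R.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteomes import Proteome, ProteinRecord

DEFAULT_N_POSITIONS = 150
DEFAULT_MIN_LENGTH = 200


@dataclass
class PositionalProfile:
    """Per-position mean/sd/count over a proteome, anchored at one terminus.

    Position ``p`` (1-based, ``1..n_positions``) reads residue ``p`` from the
    N terminus, or residue ``L - p + 1`` for the C anchor. ``mean`` is NaN
    where no protein contributes.
    """

    anchor: str
    n_positions: int
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        if self.anchor not in ("N", "C"):
            raise ValueError("anchor must be 'N' or 'C'")


@dataclass
class ZProfile:
    """Per-position comparison of a real profile against R replicate profiles.

    ``z`` is the calibrated (standard-normal-equivalent) deviate used for
    significance thresholds; ``z_ratio`` is the plain
    ``(real_mean - null_mean)/null_sd`` ratio; ``p_value`` is the exact
    two-sided tail under the replicate-based null (Student t with R-1
    degrees of freedom for the default replicate dispersion).
    """

    anchor: str
    n_positions: int
    z: np.ndarray
    z_ratio: np.ndarray
    p_value: np.ndarray
    real_mean: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "anchor": self.anchor,
                "position": np.arange(1, self.n_positions + 1),
                "real_mean": self.real_mean,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "z": self.z,
                "z_ratio": self.z_ratio,
                "p": self.p_value,
                "n_replicates": self.n_replicates,
            }
        )


def positional_profile(
    proteome: Proteome,
    tracks: Mapping[str, Sequence[float]],
    anchor: str = "N",
    n_positions: int = DEFAULT_N_POSITIONS,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> PositionalProfile:
    """Aggregate per-residue values position-wise from one terminus.

    Only proteins with length strictly greater than ``min_length``
    contribute; each must have a track of matching length in ``tracks``.
    """
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if anchor not in ("N", "C"):
        raise ValueError("anchor must be 'N' or 'C'")
    rows = []
    for rec in proteome:
        L = len(rec.seq)
        if L <= min_length:
            continue
        t = np.asarray(tracks[rec.id], dtype=float)
        if t.size != L:
            raise ValueError(
                f"track for {rec.id!r} has {t.size} values for a {L}-residue protein"
            )
        head = t[:n_positions] if anchor == "N" else t[::-1][:n_positions]
        if head.size < n_positions:
            head = np.concatenate([head, np.full(n_positions - head.size, np.nan)])
        rows.append(head)
    if rows:
        mat = np.vstack(rows)
        valid = ~np.isnan(mat)
        count = valid.sum(axis=0)
        filled = np.where(valid, mat, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = filled.sum(axis=0) / count
            ssq = (np.where(valid, mat - mean, 0.0) ** 2).sum(axis=0)
            sd = np.sqrt(ssq / (count - 1))
        mean = np.where(count >= 1, mean, np.nan)
        sd = np.where(count >= 2, sd, np.nan)
    else:
        count = np.zeros(n_positions, dtype=int)
        mean = np.full(n_positions, np.nan)
        sd = np.full(n_positions, np.nan)
    return PositionalProfile(anchor=anchor, n_positions=n_positions,
                             mean=mean, sd=sd, count=count)


# A generic external/ingested track profiles through the identical contract.
profile_generic_track = positional_profile


def zscore_profile(
    real: PositionalProfile,
    replicate_profiles: Sequence[PositionalProfile],
    dispersion: str = "replicates",
) -> ZProfile:
    """Z-score profile of a real proteome against replicate null profiles.

    ``dispersion`` selects the null spread: ``"replicates"`` (default) uses
    the sample standard deviation of the R replicate means (exact
    t_{R-1}-based p-values after the ``sqrt(1+1/R)`` predictive correction);
    ``"pooled"`` uses the across-protein dispersion pooled over replicates,
    scaled to the standard error of a mean difference (normal p-values).

    Degenerate positions: ``null_sd == 0`` with ``real_mean == null_mean``
    gives ``z = 0`` (p = 1); ``null_sd == 0`` otherwise gives a signed
    infinity sentinel with ``p = 0``.
    """
    R = len(replicate_profiles)
    if R < 2:
        raise ValueError("need at least 2 replicate profiles")
    for prof in replicate_profiles:
        if prof.anchor != real.anchor or prof.n_positions != real.n_positions:
            raise ValueError("replicate profiles must match the real profile's "
                             "anchor and n_positions")
    if dispersion not in ("replicates", "pooled"):
        raise ValueError(f"unknown dispersion {dispersion!r}")

    rep_means = np.vstack([p.mean for p in replicate_profiles])
    valid = ~np.isnan(rep_means)
    n_valid = valid.sum(axis=0)
    filled = np.where(valid, rep_means, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_mean = filled.sum(axis=0) / n_valid
        ssq = (np.where(valid, rep_means - null_mean, 0.0) ** 2).sum(axis=0)
        null_sd = np.sqrt(ssq / (n_valid - 1))
    null_mean = np.where(n_valid >= 1, null_mean, np.nan)
    null_sd = np.where(n_valid >= 2, null_sd, np.nan)
    diff = real.mean - null_mean

    with np.errstate(divide="ignore", invalid="ignore"):
        z_ratio = diff / null_sd
    if dispersion == "replicates":
        t_stat = z_ratio / np.sqrt(1.0 + 1.0 / R)
        p = 2.0 * stats.t.sf(np.abs(t_stat), df=R - 1)
    else:
        counts = np.vstack([p_.count for p_ in replicate_profiles]).astype(float)
        sds = np.vstack([p_.sd for p_ in replicate_profiles])
        with np.errstate(invalid="ignore"):
            pooled_var = np.nansum(sds**2 * (counts - 1), axis=0) / np.maximum(
                np.nansum(counts - 1, axis=0), 1.0
            )
        n_real = np.maximum(real.count.astype(float), 1.0)
        se = np.sqrt(pooled_var * (1.0 / n_real + 1.0 / (R * n_real)))
        with np.errstate(divide="ignore", invalid="ignore"):
            z_ratio = diff / se
        t_stat = z_ratio
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
        null_sd = se

    # calibrated normal-equivalent deviate from the two-sided tail
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.sign(diff) * stats.norm.isf(np.minimum(p / 2.0, 0.5))

    zero_sd = np.isclose(null_sd, 0.0)
    equal = zero_sd & np.isclose(diff, 0.0)
    blown = zero_sd & ~equal
    with np.errstate(invalid="ignore"):
        signed_inf = np.sign(diff) * np.inf
    z = np.where(equal, 0.0, z)
    z_ratio = np.where(equal, 0.0, z_ratio)
    p = np.where(equal, 1.0, p)
    z = np.where(blown, signed_inf, z)
    z_ratio = np.where(blown, signed_inf, z_ratio)
    p = np.where(blown, 0.0, p)

    return ZProfile(
        anchor=real.anchor,
        n_positions=real.n_positions,
        z=z,
        z_ratio=z_ratio,
        p_value=p,
        real_mean=real.mean,
        null_mean=null_mean,
        null_sd=null_sd,
        n_replicates=R,
    )


def empirical_p(real: PositionalProfile, replicate_profiles: Sequence[PositionalProfile]) -> np.ndarray:
    """Rank-based two-sided p of the real mean among replicate means.

    Meaningful only for large replicate counts (R >= 100); the resolution is
    1/(R+1).
    """
    R = len(replicate_profiles)
    rep_means = np.vstack([p.mean for p in replicate_profiles])
    null_mean = np.nanmean(rep_means, axis=0)
    n_ge = np.sum(np.abs(rep_means - null_mean) >= np.abs(real.mean - null_mean), axis=0)
    return (n_ge + 1.0) / (R + 1.0)


def truncate_termini(proteome: Proteome, k: int) -> tuple[Proteome, list[str]]:
    """Remove the first and last ``k`` residues of every protein.

    The CDS, when present, is trimmed codon-wise in register (a terminal
    stop codon is kept). Records with length <= 2k are dropped; their ids
    are returned as the log.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    kept, dropped = [], []
    for rec in proteome:
        L = len(rec.seq)
        if L <= 2 * k:
            dropped.append(rec.id)
            continue
        new_seq = rec.seq[k : L - k]
        new_cds = None
        if rec.cds is not None:
            stop = rec.cds[3 * L :] if rec.has_stop_codon else ""
            new_cds = rec.cds[3 * k : 3 * (L - k)] + stop
        kept.append(replace(rec, seq=new_seq, cds=new_cds))
    return proteome.with_records(kept, note=f"termini truncated by {k}"), dropped


def gc_track(record: ProteinRecord) -> np.ndarray:
    """Per-codon GC fraction of a record's CDS, terminal stop excluded.

    Codon ``i`` aligns with residue ``i``, so GC profiles anchor exactly like
    residue profiles.
    """
    if record.cds is None:
        raise ValueError(f"record {record.id!r} has no CDS")
    vals = []
    for codon in record.coding_codons():
        vals.append((codon.count("G") + codon.count("C")) / 3.0)
    return np.asarray(vals)


def gc_tracks(proteome: Proteome) -> dict:
    return {rec.id: gc_track(rec) for rec in proteome}


def profile_pair_frame(n_profile: ZProfile, c_profile: ZProfile) -> pd.DataFrame:
    """Long-format frame of an N- and C-anchored Z-profile pair."""
    return pd.concat([n_profile.to_frame(), c_profile.to_frame()], ignore_index=True)


def heatmap_matrix(z_profiles: Mapping[str, tuple[ZProfile, ZProfile]]) -> pd.DataFrame:
    """Wide matrix for heatmaps: one row per group, columns N1..Nn then Cn..C1."""
    rows = {}
    for label, (n_prof, c_prof) in z_profiles.items():
        rows[label] = np.concatenate([n_prof.z, c_prof.z[::-1]])
    some = next(iter(z_profiles.values()))[0]
    cols = [f"N{p}" for p in range(1, some.n_positions + 1)] + [
        f"C{p}" for p in range(some.n_positions, 0, -1)
    ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
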