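"""Proteome-level and stratified statistics.

Mann–Whitney U comparisons of disorder content between real proteins and
pooled null replicates, Spearman rank correlations (GC content vs disorder
content; paired Z-profiles), and the stratifications used to probe
confounders: genic GC bins, GO-term groups, expression quantiles, and the
splice-junction-free subset.

The Mann–Whitney and Spearman primitives are implemented here (midranks,
exact small-sample enumeration, tie- and continuity-corrected normal
approximation) because exact-vs-approximate agreement is part of this
package's contract; scipy's versions serve as independent cross-checks in
the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .profiles import ZProfile
from .proteomes import Proteome

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration up to this pooled size
STAR_THRESHOLDS = ((1e-6, "***"), (1e-4, "**"), (0.05, "*"))


@dataclass
class GroupComparison:
    """Real-vs-random comparison of one disorder-content metric."""

    group_label: str
    metric: str
    n_real: int
    n_random: int
    real_mean: float
    random_mean: float
    u_statistic: float
    p_value: float
    stars: str


def significance_stars(p: float) -> str:
    """Star coding: ``***`` p<1e-6, ``**`` p<1e-4, ``*`` p<0.05, else ``ns``."""
    for cutoff, stars in STAR_THRESHOLDS:
        if p < cutoff:
            return stars
    return "ns"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    rx = ranks[: x.size].sum()
    return float(rx - x.size * (x.size + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by enumerating all label assignments (midranks)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx, n = x.size, pooled.size
    mu = nx * y.size / 2.0
    d_obs = abs(u_obs - mu)
    offset = nx * (nx + 1) / 2.0
    hits = 0
    for idx in combinations(range(n), nx):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n, nx)


def _asymptotic_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Tie-corrected, continuity-corrected normal approximation."""
    nx, ny = x.size, y.size
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Mann–Whitney U test with midranks for ties.

    Returns ``(U_x, p)``. ``method``: ``"exact"`` enumerates all label
    assignments (feasible for small pooled sizes), ``"asymptotic"`` uses the
    tie-corrected continuity-corrected normal approximation, and ``"auto"``
    picks exact when ``n_x + n_y <= 12``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if x.size + y.size <= EXACT_MAX_N else "asymptotic"
    if method == "exact":
        return u, _exact_p(x, y, u)
    if method == "asymptotic":
        return u, _asymptotic_p(x, y, u)
    raise ValueError(f"unknown method {method!r}")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation via the midrank product-moment formula.

    P values come from the usual t approximation with n-2 degrees of
    freedom. Constant input vectors raise (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def compare_content(
    real_values: Sequence[float],
    replicate_values: Sequence[Sequence[float]],
    metric: str,
    group_label: str = "all",
) -> GroupComparison:
    """Mann–Whitney comparison of a content metric, real vs pooled replicates.

    All replicate proteins are pooled into one random sample
    (``n_random = R * n_real`` for full replicates), matching the convention
    that the random dataset is R times the size of the real one.
    """
    if metric not in ("pct_dis_all", "pct_dis30"):
        raise ValueError(f"unknown metric {metric!r}")
    real = np.asarray(real_values, dtype=float)
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in replicate_values])
    u, p = mann_whitney_u(real, pooled, method="auto")
    return GroupComparison(
        group_label=group_label,
        metric=metric,
        n_real=real.size,
        n_random=pooled.size,
        real_mean=float(real.mean()),
        random_mean=float(pooled.mean()),
        u_statistic=u,
        p_value=p,
        stars=significance_stars(p),
    )


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": c.group_label,
                "metric": c.metric,
                "n_real": c.n_real,
                "n_random": c.n_random,
                "real_mean": c.real_mean,
                "random_mean": c.random_mean,
                "U": c.u_statistic,
                "p": c.p_value,
                "stars": c.stars,
            }
            for c in comparisons
        ]
    )


def genic_gc(record) -> float:
    """GC fraction of the full coding sequence (stop codon included)."""
    if record.cds is None:
        raise ValueError(f"record {record.id!r} has no CDS")
    cds = record.cds
    return (cds.count("G") + cds.count("C")) / len(cds)


def stratify_by_gc(proteome: Proteome, bins=5) -> list[tuple[str, Proteome]]:
    """Partition records into genic-GC bins.

    ``bins`` is either a bin count (equal-width bins over the observed GC
    range) or an increasing sequence of interior edges. Empty bins are kept
    (with zero records) so bin labels are stable.
    """
    missing = [rec.id for rec in proteome if rec.cds is None]
    if missing:
        raise ValueError(f"records without CDS: {', '.join(missing[:10])}")
    gc = np.array([genic_gc(rec) for rec in proteome])
    if isinstance(bins, int):
        lo, hi = float(gc.min()), float(gc.max())
        if lo == hi:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, bins + 1)[1:-1]
    else:
        edges = np.asarray(bins, dtype=float)
    assignment = np.searchsorted(edges, gc, side="right")
    full_edges = np.concatenate([[-np.inf], edges, [np.inf]])
    out = []
    for b in range(len(edges) + 1):
        recs = [rec for rec, a in zip(proteome.records, assignment) if a == b]
        label = f"gc[{full_edges[b]:.3f},{full_edges[b + 1]:.3f})"
        out.append((label, proteome.with_records(recs, note=f"GC bin {b}")))
    return out


def filter_splice_free(
    proteome: Proteome, window_bp: int = 300
) -> tuple[Proteome, list[str]]:
    """Keep proteins without splice junctions near either terminus.

    Retained: records flagged single-exon, or with both first and last exon
    strictly longer than ``window_bp`` (default 300 bp, i.e. no junction in
    the first/last 100 codons). Records without exon annotation are excluded
    and returned in the log.
    """
    kept, unannotated = [], []
    for rec in proteome:
        if rec.single_exon:
            kept.append(rec)
        elif rec.first_exon_len is None or rec.last_exon_len is None:
            unannotated.append(rec.id)
        elif rec.first_exon_len > window_bp and rec.last_exon_len > window_bp:
            kept.append(rec)
    return proteome.with_records(kept, note="splice-junction-free subset"), unannotated


def stratify_by_expression(
    proteome: Proteome, q: float = 0.25
) -> tuple[Proteome, Proteome]:
    """Split annotated records into the top and bottom expression fractions.

    Returns ``(high, low)`` where each holds the ``q`` fraction (default
    quartiles) of expression-annotated records; ties and the degenerate
    all-equal case resolve deterministically by annotation order.
    """
    if not 0.0 < q <= 0.5:
        raise ValueError("q must lie in (0, 0.5]")
    annotated = [rec for rec in proteome if rec.expression is not None]
    if len(annotated) < 2:
        raise ValueError("need at least 2 expression-annotated records")
    values = np.array([rec.expression for rec in annotated])
    if np.ptp(values) == 0:
        warnings.warn("all expression values equal; split is by record order",
                      stacklevel=2)
    order = np.argsort(values, kind="stable")
    m = max(1, int(round(q * len(annotated))))
    low_idx = set(order[:m].tolist())
    high_idx = set(order[-m:].tolist())
    low = [rec for i, rec in enumerate(annotated) if i in low_idx]
    high = [rec for i, rec in enumerate(annotated) if i in high_idx]
    return (
        proteome.with_records(high, note=f"top {q:g} by expression"),
        proteome.with_records(low, note=f"bottom {q:g} by expression"),
    )


def group_by_go(
    proteome: Proteome, min_proteins: int = 100, min_length: int = 200
) -> dict[str, Proteome]:
    """Group proteins by GO term.

    Per term, only proteins strictly longer than ``min_length`` qualify, and
    only terms with strictly more than ``min_proteins`` qualifying proteins
    are kept. A protein carrying several terms appears in every matching
    group.
    """
    groups: dict[str, list] = {}
    for rec in proteome:
        if rec.go_terms is None or len(rec.seq) <= min_length:
            continue
        for term in rec.go_terms:
            groups.setdefault(term, []).append(rec)
    return {
        term: proteome.with_records(recs, note=f"GO {term}")
        for term, recs in sorted(groups.items())
        if len(recs) > min_proteins
    }


def correlate_zprofiles(a: ZProfile, b: ZProfile) -> tuple[float, float]:
    """Spearman correlation between two Z-profiles over shared finite positions."""
    if a.anchor != b.anchor or a.n_positions != b.n_positions:
        raise ValueError("profiles must share anchor and n_positions")
    mask = np.isfinite(a.z) & np.isfinite(b.z)
    if mask.sum() < 3:
        raise ValueError("need at least 3 shared finite positions")
    return spearman_rho(a.z[mask], b.z[mask])
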