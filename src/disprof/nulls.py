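"""Composition-preserving randomized proteomes (null models).

Three shuffling schemes generate null proteomes from a real one, each
preserving per-protein length exactly:

- *length-conserved*: a uniform permutation of all residues of each protein
  (preserves per-protein amino-acid composition);
- *terminal-conserved*: independent permutations of the first and last
  ``window`` residues (default 200), middle untouched — for proteins of
  length ``L <= 2*window`` the sequence is split at the midpoint and the two
  halves are permuted as blocks (preserves per-block composition);
- *column-wise*: proteins are anchored from both ends (residue ``i`` of an
  ``L``-mer belongs to N-column ``i`` if ``i <= ceil(L/2)``, else to
  C-column ``L - i + 1``) and residues are permuted across proteins within
  each column (preserves per-column cross-proteome composition).

Each scheme also has a codon-level analogue in which the shuffled tokens are
the codons of the matched CDS (one token per residue; a terminal stop codon
stays fixed), so the nucleotide null mirrors the amino-acid null and
preserves per-sequence GC content exactly under the length-conserved model.

Replicates are generated in independent, deterministic RNG substreams
derived from ``(seed, replicate_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .proteomes import Proteome, ProteinRecord

MODELS = ("length_conserved", "terminal_conserved", "column_wise")

# codon <-> integer codecs (base-4 over A,C,G,T)
_BASE_CODE = np.full(128, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_CODON_STR = [
    "ACGT"[(c >> 4) & 3] + "ACGT"[(c >> 2) & 3] + "ACGT"[c & 3] for c in range(64)
]
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = np.zeros(64, dtype="<U1")
for _c in range(64):
    _s = _CODON_STR[_c]
    _CODON_AA[_c] = "*" if _s in _STANDARD_TABLE.stop_codons else _STANDARD_TABLE.forward_table[_s]


@dataclass
class RandomizationSpec:
    """Parameters of one randomization scheme.

    ``model`` is one of :data:`MODELS`; ``terminal_window`` applies to the
    terminal-conserved model only; ``replicates`` (R) controls how many
    independent null proteomes are drawn (default 10, i.e. the random
    dataset is 10x the real one); ``level`` selects amino-acid or codon
    tokens.
    """

    model: str
    terminal_window: int = 200
    replicates: int = 10
    seed: int = 0
    level: str = "amino"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.terminal_window < 1:
            raise ValueError("terminal_window must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.level not in ("amino", "codon"):
            raise ValueError(f"unknown level {self.level!r}")


@dataclass
class RandomReplicate:
    """One randomized proteome: same ids and per-record lengths as the source."""

    proteome: Proteome
    replicate_index: int
    spec: RandomizationSpec


def _aa_tokens(record: ProteinRecord) -> np.ndarray:
    return np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8).copy()


def _codon_tokens(record: ProteinRecord) -> tuple[np.ndarray, Optional[str]]:
    """Coding codons as base-4 integers, plus the fixed terminal stop (if any)."""
    if record.cds is None:
        raise ValueError(f"record {record.id!r} has no CDS for codon-level shuffling")
    arr = _BASE_CODE[np.frombuffer(record.cds.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError(f"record {record.id!r} CDS contains non-ACGT characters")
    codons = (arr[0::3] << 4) | (arr[1::3] << 2) | arr[2::3]
    stop = record.cds[-3:] if record.has_stop_codon else None
    n = len(record.seq)
    return codons[:n].astype(np.int16), stop


def _rebuild(record: ProteinRecord, tokens: np.ndarray, level: str,
             stop: Optional[str] = None) -> ProteinRecord:
    if level == "amino":
        seq = tokens.astype(np.uint8).tobytes().decode("ascii")
        # an amino-level shuffle breaks the residue<->codon pairing
        return replace(record, seq=seq, cds=None)
    cds = "".join(_CODON_STR[int(t)] for t in tokens) + (stop or "")
    seq = "".join(_CODON_AA[tokens])
    return replace(record, seq=seq, cds=cds)


def _tokens(record: ProteinRecord, level: str):
    if level == "amino":
        return _aa_tokens(record), None
    return _codon_tokens(record)


def _block_bounds(L: int, window: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Half-open index ranges of the N and C shuffle blocks."""
    if L > 2 * window:
        return (0, window), (L - window, L)
    h = ceil(L / 2)
    return (0, h), (h, L)


def shuffle_length_conserved(
    record: ProteinRecord, rng: np.random.Generator, level: str = "amino"
) -> ProteinRecord:
    """Uniformly permute all residues (or coding codons) of one record."""
    tokens, stop = _tokens(record, level)
    return _rebuild(record, rng.permutation(tokens), level, stop)


def shuffle_terminal_conserved(
    record: ProteinRecord,
    window: int,
    rng: np.random.Generator,
    level: str = "amino",
) -> ProteinRecord:
    """Permute the N- and C-terminal blocks separately, middle untouched.

    For ``L > 2*window`` positions ``1..window`` are permuted among
    themselves and likewise the last ``window`` positions; shorter sequences
    are split at ``ceil(L/2)`` into two blocks. Composition within each
    block is preserved exactly.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    tokens, stop = _tokens(record, level)
    out = tokens.copy()
    (n0, n1), (c0, c1) = _block_bounds(len(tokens), window)
    out[n0:n1] = rng.permutation(tokens[n0:n1])
    out[c0:c1] = rng.permutation(tokens[c0:c1])
    return _rebuild(record, out, level, stop)


def shuffle_column_wise(
    proteome: Proteome, rng: np.random.Generator, level: str = "amino"
) -> Proteome:
    """Permute residues across proteins within each dual-anchored column.

    Every residue belongs to exactly one column: N-anchored column ``i`` for
    ``i <= ceil(L/2)``, else C-anchored column ``L - i + 1``. Residues are
    permuted uniformly across proteins within each column, so every column's
    cross-proteome composition is preserved exactly, as are per-protein ids
    and lengths.
    """
    if len(proteome) == 0:
        raise ValueError("column-wise shuffling needs a non-empty proteome")
    toks, stops = [], []
    for rec in proteome:
        t, s = _tokens(rec, level)
        toks.append(t.astype(np.int32))
        stops.append(s)
    lengths = np.array([len(t) for t in toks])
    nhalf = (lengths + 1) // 2
    clen = lengths - nhalf
    nmax, cmax = int(nhalf.max()), int(clen.max()) if len(clen) else 0

    nmat = np.full((len(toks), nmax), -1, dtype=np.int32)
    cmat = np.full((len(toks), max(cmax, 1)), -1, dtype=np.int32)
    for i, t in enumerate(toks):
        nmat[i, : nhalf[i]] = t[: nhalf[i]]
        if clen[i]:
            cmat[i, : clen[i]] = t[nhalf[i] :][::-1]  # C-column j holds residue L-j+1
    for mat in (nmat, cmat):
        for j in range(mat.shape[1]):
            col = mat[:, j]
            mask = col >= 0
            if mask.sum() > 1:
                col[mask] = rng.permutation(col[mask])
    out = []
    for i, rec in enumerate(proteome):
        t = np.concatenate([nmat[i, : nhalf[i]], cmat[i, : clen[i]][::-1]])
        out.append(_rebuild(rec, t, level, stops[i]))
    return proteome.with_records(out, note="column-wise shuffled")


def randomize_proteome(proteome: Proteome, spec: RandomizationSpec) -> list[RandomReplicate]:
    """Draw ``spec.replicates`` independent randomized proteomes.

    Each replicate uses an RNG substream seeded with
    ``(spec.seed, replicate_index)`` so replicates are order-independent and
    reproducible. Codon-level randomization requires a CDS on every record.
    """
    if spec.level == "codon":
        missing = [rec.id for rec in proteome if rec.cds is None]
        if missing:
            raise ValueError(
                "codon-level randomization requires a CDS on every record; "
                f"missing for: {', '.join(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
    replicates = []
    for r in range(1, spec.replicates + 1):
        rng = np.random.default_rng([spec.seed, r])
        if spec.model == "column_wise":
            shuffled = shuffle_column_wise(proteome, rng, spec.level)
        else:
            recs = []
            for rec in proteome:
                if spec.model == "length_conserved":
                    recs.append(shuffle_length_conserved(rec, rng, spec.level))
                else:
                    recs.append(
                        shuffle_terminal_conserved(rec, spec.terminal_window, rng, spec.level)
                    )
            shuffled = proteome.with_records(recs, note=f"{spec.model} rep {r}")
        replicates.append(RandomReplicate(shuffled, r, spec))
    return replicates


def write_replicates_fasta(replicates: list[RandomReplicate], path, use_cds: bool = False) -> None:
    """Write all replicates to one FASTA with ``id|model|rep`` headers."""
    with open(path, "w") as fh:
        for rep in replicates:
            for rec in rep.proteome:
                seq = rec.cds if use_cds else rec.seq
                fh.write(f">{rec.id}|{rep.spec.model}|{rep.replicate_index}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
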