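"""Protein and coding-sequence I/O, validation, filtering, and annotation.

The in-memory unit is :class:`ProteinRecord` — one amino-acid sequence with
an optional matched coding sequence (CDS) and optional per-gene annotations
(GO terms, expression level, first/last exon lengths). A :class:`Proteome`
is an ordered, id-unique collection of records plus provenance.

Filtering implements the standard hygiene rules for comparative disorder
analyses: proteins containing ambiguous amino acids (B, J, O, U, X, Z) are
removed, as are proteins whose CDS has partial codons, an internal stop
codon, or a length inconsistent with the protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional

import pandas as pd
from Bio import SeqIO

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUOUS_AA = frozenset("BJOUXZ")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FastaError(ValueError):
    """Malformed, empty, or invariant-violating FASTA input."""


class AnnotationError(ValueError):
    """Unreadable or malformed annotation table."""


@dataclass
class ProteinRecord:
    """One protein: identifier, residues, optional CDS and annotations.

    Invariants (enforced by :func:`filter_proteins`, not the constructor, so
    that raw inputs can be represented before filtering): ``seq`` non-empty;
    if ``cds`` is present, ``len(cds)`` is ``3*len(seq)`` (no stop) or
    ``3*(len(seq)+1)`` (stop-terminated) with no internal stop codon.
    """

    id: str
    seq: str
    cds: Optional[str] = None
    go_terms: Optional[frozenset] = None
    expression: Optional[float] = None
    first_exon_len: Optional[int] = None
    last_exon_len: Optional[int] = None
    single_exon: bool = False

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def has_stop_codon(self) -> bool:
        return self.cds is not None and len(self.cds) == 3 * (len(self.seq) + 1)

    def coding_codons(self) -> list[str]:
        """Codons encoding residues, excluding a terminal stop codon."""
        if self.cds is None:
            raise ValueError(f"record {self.id!r} has no CDS")
        n = len(self.seq)
        return [self.cds[3 * i : 3 * i + 3] for i in range(n)]


@dataclass
class Proteome:
    """Ordered collection of :class:`ProteinRecord` with unique ids."""

    records: list[ProteinRecord]
    species_label: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
        self._index: dict[str, ProteinRecord] = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, key):
        if isinstance(key, str):
            return self._index[key]
        return self.records[key]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._index

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def with_records(self, records: list[ProteinRecord], note: str = "") -> "Proteome":
        prov = self.provenance if not note else f"{self.provenance}; {note}".lstrip("; ")
        return Proteome(records, species_label=self.species_label, provenance=prov)


def read_fasta(path, alphabet: str = "amino") -> Proteome:
    """Read a FASTA file into a :class:`Proteome`.

    The header token before the first whitespace becomes the record id;
    sequences are uppercased. A single trailing ``*`` (a stop symbol some
    exporters append to protein sequences) is stripped.

    Parameters
    ----------
    path : path-like
        FASTA file (protein or nucleotide).
    alphabet : {"amino", "nucleotide"}
        Declares the expected sequence type; only used for sanity checks —
        ambiguous residues are *not* rejected here (that is
        :func:`filter_proteins`'s job).
    """
    if alphabet not in ("amino", "nucleotide"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records: list[ProteinRecord] = []
    for sr in SeqIO.parse(str(path), "fasta"):
        seq = str(sr.seq).upper()
        if alphabet == "amino" and seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaError(f"record {sr.id!r} in {path.name} has an empty sequence")
        bad = re.search(r"[^A-Z]", seq)
        if bad:
            raise FastaError(
                f"record {sr.id!r} in {path.name} contains non-letter "
                f"character {bad.group()!r}"
            )
        records.append(ProteinRecord(id=sr.id, seq=seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return Proteome(records, provenance=f"read from {path.name} ({alphabet})")


def write_fasta(proteome: Proteome, path, use_cds: bool = False, wrap: int = 60) -> None:
    """Write a proteome (or its CDSs) as plain FASTA."""
    with open(path, "w") as fh:
        for rec in proteome:
            seq = rec.cds if use_cds else rec.seq
            if seq is None:
                raise ValueError(f"record {rec.id!r} has no CDS to write")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def attach_cds(
    proteome: Proteome,
    cds_proteome: Proteome,
    id_pattern: Optional[str] = None,
) -> tuple[Proteome, int]:
    """Pair coding sequences with proteins by exact id equality.

    ``id_pattern`` is an optional regex with one capture group applied to the
    CDS ids to normalize them before matching (e.g. strip a ``.cds`` suffix).
    Returns the paired proteome and the number of proteins left without CDS.
    """
    cds_by_id: dict[str, str] = {}
    for rec in cds_proteome:
        key = rec.id
        if id_pattern is not None:
            m = re.match(id_pattern, key)
            if m:
                key = m.group(1)
        cds_by_id[key] = rec.seq
    out, unmatched = [], 0
    for rec in proteome:
        cds = cds_by_id.get(rec.id)
        if cds is None:
            unmatched += 1
            out.append(rec)
        else:
            out.append(replace(rec, cds=cds))
    return proteome.with_records(out, note="cds attached"), unmatched


def _rejection_reason(rec: ProteinRecord) -> Optional[str]:
    """First matching rejection rule for a record, or None if it passes."""
    for ch in rec.seq:
        if ch in AMBIGUOUS_AA:
            return f"ambiguous residue {ch}"
        if ch not in CANONICAL_AA:
            return f"non-canonical residue {ch}"
    if rec.cds is not None:
        n, ncds = len(rec.seq), len(rec.cds)
        if ncds % 3 != 0:
            return "partial codon"
        if ncds not in (3 * n, 3 * (n + 1)):
            return "cds/protein length mismatch"
        for i in range(n):  # codons encoding residues; a stop here is internal
            if rec.cds[3 * i : 3 * i + 3] in STOP_CODONS:
                return "internal stop codon"
        if ncds == 3 * (n + 1) and rec.cds[-3:] not in STOP_CODONS:
            return "cds/protein length mismatch"
    return None


def filter_proteins(proteome: Proteome) -> tuple[Proteome, pd.DataFrame]:
    """Remove records violating the sequence hygiene rules.

    Rejects proteins containing ambiguous amino acids (B, J, O, U, X, Z) or
    any non-canonical letter, and — when a CDS is present — proteins whose
    CDS has partial codons, a length inconsistent with the protein length
    (with or without a terminal stop codon), or an internal stop codon.

    Returns the filtered proteome and a rejection log with one row per
    rejected record (columns ``id``, ``reason``; exactly one primary reason
    each). Filtering is total (never raises on content) and idempotent.
    """
    kept: list[ProteinRecord] = []
    rows: list[dict] = []
    for rec in proteome:
        reason = _rejection_reason(rec)
        if reason is None:
            kept.append(rec)
        else:
            rows.append({"id": rec.id, "reason": reason})
    log = pd.DataFrame(rows, columns=["id", "reason"])
    note = f"filtered: kept {len(kept)}/{len(proteome)}"
    return proteome.with_records(kept, note=note), log


def write_rejection_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)


def _read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - rewrap as domain error
        raise AnnotationError(f"could not parse annotation table {path}: {exc}") from exc


def attach_annotations(
    proteome: Proteome, table, kind: str
) -> tuple[Proteome, Mapping[str, int]]:
    """Attach a tabular annotation to matching records.

    ``kind`` selects the expected layout (all tab-separated with a header):

    - ``"expression"``: ``id<TAB>value`` (non-negative real);
    - ``"go"``: long format ``id<TAB>term``, one term per row;
    - ``"exon"``: ``id<TAB>first_exon_bp<TAB>last_exon_bp`` with an optional
      fourth column ``single_exon`` (0/1).

    Unmatched table rows are counted in the returned log; records without a
    table row keep their annotation absent.
    """
    if kind not in ("expression", "go", "exon"):
        raise ValueError(f"unknown annotation kind {kind!r}")
    df = table if isinstance(table, pd.DataFrame) else _read_table(table)
    if df.shape[1] < 2:
        raise AnnotationError(f"{kind} table needs at least two columns")

    ids = df.iloc[:, 0].astype(str)
    known = set(proteome.ids)
    unmatched_rows = int((~ids.isin(known)).sum())
    updates: dict[str, dict] = {}
    if kind == "expression":
        for rid, val in zip(ids, df.iloc[:, 1]):
            if rid in known:
                x = float(val)
                if x < 0:
                    raise AnnotationError(f"negative expression for {rid!r}")
                updates[rid] = {"expression": x}
    elif kind == "go":
        terms: dict[str, set] = {}
        for rid, term in zip(ids, df.iloc[:, 1].astype(str)):
            if rid in known:
                terms.setdefault(rid, set()).add(term)
        updates = {rid: {"go_terms": frozenset(ts)} for rid, ts in terms.items()}
    else:  # exon
        if df.shape[1] < 3:
            raise AnnotationError("exon table needs id, first_exon_bp, last_exon_bp")
        for _, row in df.iterrows():
            rid = str(row.iloc[0])
            if rid not in known:
                continue
            upd = {
                "first_exon_len": int(row.iloc[1]),
                "last_exon_len": int(row.iloc[2]),
            }
            if upd["first_exon_len"] <= 0 or upd["last_exon_len"] <= 0:
                raise AnnotationError(f"non-positive exon length for {rid!r}")
            if df.shape[1] >= 4 and str(row.iloc[3]).strip() not in ("", "nan"):
                upd["single_exon"] = str(row.iloc[3]).strip() in ("1", "true", "True")
            updates[rid] = upd
    out = [replace(rec, **updates[rec.id]) if rec.id in updates else rec for rec in proteome]
    log = {"matched": len(updates), "unmatched_rows": unmatched_rows}
    return proteome.with_records(out, note=f"{kind} annotations attached"), log
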