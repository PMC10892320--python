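"""Pairwise homology, identity matrices, MSA ingestion and column masking.

The homology matrix mirrors the published style for pheromone homolog
comparisons: percent identity from global (Needleman-Wunsch, affine gap)
protein alignments, reported to one decimal, upper-triangle layout with
species/megakaryotype row labels and cells above a similarity threshold
flagged.

Multiple alignments are ingested, not built: the reference analyses used a
manually curated MAFFT alignment, which is not reproducible by construction,
so this module reads aligned FASTA / Clustal and offers an automated
entropy-based stand-in for manual column curation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align, AlignIO
from Bio.Align import substitution_matrices

from .codec import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class AlignParams:
    """Global-alignment scoring; defaults echoed in every report header."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


@dataclass
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == "-" and y == "-":
                raise ValueError("column with gap in both rows")


@dataclass
class MultipleAlignment:
    records: list[SequenceRecord]
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("empty alignment")
        ncols = len(self.records[0].residues)
        for rec in self.records:
            if len(rec.residues) != ncols:
                raise ValueError(
                    f"row {rec.id!r} has length {len(rec.residues)}, expected {ncols}"
                )
        if self.reference_id is None:
            self.reference_id = self.records[0].id

    @property
    def ncols(self) -> int:
        return len(self.records[0].residues)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, rec_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def to_matrix(self) -> np.ndarray:
        return np.array([list(r.residues) for r in self.records])

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def reference_positions(self) -> np.ndarray:
        """1-based reference-sequence position per column; 0 where the reference is gapped."""
        ref = self.row(self.reference_id).residues
        out = np.zeros(self.ncols, dtype=int)
        pos = 0
        for j, ch in enumerate(ref):
            if ch != "-":
                pos += 1
                out[j] = pos
        return out

    def subset_columns(self, keep: Sequence[bool]) -> "MultipleAlignment":
        keep = np.asarray(keep, dtype=bool)
        recs = [
            SequenceRecord(
                id=r.id,
                residues="".join(np.array(list(r.residues))[keep]),
                alphabet="protein",
                species=r.species,
                megakaryotype=r.megakaryotype,
                mating_type=r.mating_type,
            )
            for r in self.records
        ]
        return MultipleAlignment(recs, reference_id=self.reference_id)


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # percent identities, symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(v), 100.0):
            raise ValueError("diagonal must be 100")
        if v.min() < 0 or v.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class ColumnMask:
    keep: np.ndarray  # boolean, length ncols
    rule_log: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.keep))


def align_pair(
    a: SequenceRecord, b: SequenceRecord, params: Optional[AlignParams] = None
) -> PairwiseAlignment:
    """Optimal global alignment of two ungapped protein records."""
    params = params or AlignParams()
    for rec in (a, b):
        if rec.alphabet != "protein":
            raise ValueError(f"{rec.id!r}: pairwise identity needs protein records")
        if not rec.residues:
            raise ValueError(f"{rec.id!r}: empty sequence")
        if "-" in rec.residues:
            raise ValueError(f"{rec.id!r}: input must be ungapped")
    aln = params.aligner().align(a.residues, b.residues)
    best = aln[0]  # Biopython's enumeration order is deterministic
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id, aligned_a=str(best[0]), aligned_b=str(best[1]),
        score=float(best.score),
    )


def percent_identity(aln: PairwiseAlignment, mode: str = "aligned_columns") -> float:
    """Percent identity of a pairwise alignment.

    mode="aligned_columns": identities / columns where both rows have residues.
    mode="shorter_seq": identities / length of the shorter ungapped sequence
    (the convention some alignment GUIs report).  Values unrounded; round to
    one decimal for reporting.
    """
    ident = both = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                ident += 1
    if mode == "aligned_columns":
        denom = both
    elif mode == "shorter_seq":
        denom = min(
            len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown identity mode {mode!r}")
    if denom == 0:
        raise ValueError("zero-length denominator for percent identity")
    return 100.0 * ident / denom


def build_identity_matrix(
    records: Sequence[SequenceRecord],
    params: Optional[AlignParams] = None,
    mode: str = "aligned_columns",
) -> IdentityMatrix:
    """All-against-all percent identity from pairwise global alignments."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(align_pair(records[i], records[j], params), mode)
            vals[i, j] = vals[j, i] = pid
    return IdentityMatrix(ids=ids, values=vals)


def ingest_msa(
    path: str | Path,
    fmt: str = "aligned-fasta",
    metadata: Optional[str | Path] = None,
    reference_id: Optional[str] = None,
) -> MultipleAlignment:
    """Read an aligned FASTA or Clustal file into a MultipleAlignment."""
    bioformat = {"aligned-fasta": "fasta", "clustal": "clustal"}.get(fmt)
    if bioformat is None:
        raise ValueError(f"unknown alignment format {fmt!r}")
    from .codec import _read_metadata

    meta = _read_metadata(metadata) if metadata else {}
    try:
        aln = AlignIO.read(str(path), bioformat)
    except ValueError as exc:
        raise ValueError(f"cannot read {path} as {fmt}: {exc}") from exc
    recs = []
    for row in aln:
        info = meta.get(row.id, {})
        recs.append(
            SequenceRecord(
                id=row.id,
                residues=str(row.seq),
                alphabet="protein",
                species=info.get("species", "unknown"),
                megakaryotype=info.get("megakaryotype", "other"),
                mating_type=info.get("mating_type") or None,
            )
        )
    return MultipleAlignment(recs, reference_id=reference_id)


def column_entropy(column: str) -> float:
    """Shannon entropy (natural log) over the residues present; gaps excluded."""
    residues = [c for c in column if c != "-"]
    if not residues:
        return 0.0
    n = len(residues)
    ent = 0.0
    for c in set(residues):
        p = residues.count(c) / n
        ent -= p * math.log(p)
    return ent


@dataclass
class MaskPolicy:
    drop_any_gap: bool = True
    entropy_threshold: float = 1.5
    flank_extension: int = 0


def mask_columns(msa: MultipleAlignment, policy: Optional[MaskPolicy] = None) -> ColumnMask:
    """Automated stand-in for manual alignment curation.

    Drops gapped columns (optional) and high-entropy columns together with
    `flank_extension` neighbours; every dropped column is logged with the
    rule that removed it.
    """
    policy = policy or MaskPolicy()
    ncols = msa.ncols
    keep = np.ones(ncols, dtype=bool)
    log: list[tuple[int, str]] = []
    cols = [msa.column(j) for j in range(ncols)]
    if policy.drop_any_gap:
        for j, col in enumerate(cols):
            if "-" in col:
                keep[j] = False
                log.append((j, "gap"))
    entropies = np.array([column_entropy(c) for c in cols])
    high = np.where(entropies > policy.entropy_threshold)[0]
    for j in high:
        lo = max(0, j - policy.flank_extension)
        hi = min(ncols, j + policy.flank_extension + 1)
        for jj in range(lo, hi):
            if keep[jj]:
                keep[jj] = False
                reason = "entropy" if jj == j else f"entropy-flank({j})"
                log.append((int(jj), reason))
    if not keep.any():
        logger.warning("column mask removed every column")
    return ColumnMask(keep=keep, rule_log=sorted(log))


def identity_table_text(
    matrix: IdentityMatrix,
    records: Optional[Sequence[SequenceRecord]] = None,
    flag_threshold: float = 87.0,
    decimals: int = 1,
) -> str:
    """Upper-triangle identity table with Mk/species row labels.

    Cells at or above `flag_threshold` are marked with ``*`` (the published
    table shades them instead).
    """
    ids = matrix.ids
    by_id = {r.id: r for r in records or []}
    lines = ["\t".join(["Mk", "species", "strain"] + ids[1:])]
    for i, rid in enumerate(ids[:-1]):
        rec = by_id.get(rid)
        label = [rec.megakaryotype if rec else "", rec.species if rec else "", rid]
        cells = []
        for j in range(1, len(ids)):
            if j <= i:
                cells.append("-")
            else:
                v = matrix.values[i, j]
                cell = f"{v:.{decimals}f}"
                if v >= flag_threshold:
                    cell += "*"
                cells.append(cell)
        lines.append("\t".join(label + cells))
    lines.append(f"# identity >= {flag_threshold:g}% flagged with *")
    return "\n".join(lines) + "\n"


def write_identity_tsv(matrix: IdentityMatrix, path: str | Path, **kwargs) -> None:
    Path(path).write_text(identity_table_text(matrix, **kwargs))
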