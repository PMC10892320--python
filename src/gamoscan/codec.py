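"""Sequence records, variant genetic codes, and coding-sequence translation.

*Blepharisma* uses a variant nuclear genetic code in which UGA encodes
tryptophan; UAA (and, by default here, UAG) terminate translation.  The
default code table ships with the package and can be overridden from a
two-column TSV (codon, amino acid, ``*`` for stop).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

IUPAC_DNA = set("ACGTRYSWKMBDHVN")
UNAMBIGUOUS_DNA = set("ACGT")
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
PROTEIN_ALPHABET = set(AMINO_ACIDS) | {"X", "-", "*"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gamoscan").joinpath("data", name)))


@dataclass
class SequenceRecord:
    """One strain's sequence plus its species/megakaryotype labels."""

    id: str
    residues: str
    alphabet: str = "dna"  # "dna" | "protein"
    species: str = "unknown"
    megakaryotype: str = "other"  # "Mk2" | "Mk3" | "Mk4" | "other"
    mating_type: Optional[str] = None  # "I" | "II" | None

    def __post_init__(self) -> None:
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        res = self.residues.upper()
        allowed = IUPAC_DNA | {"-"} if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(res) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid {self.alphabet} characters {sorted(bad)}"
            )
        self.residues = res

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneticCode:
    """A 64-entry codon table; stops encoded as ``*``."""

    codon_to_aa: dict[str, str]
    name: str = "custom"

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(f"code {self.name!r} has {len(self.codon_to_aa)} entries, need 64")
        if "*" not in self.codon_to_aa.values():
            raise ValueError(f"code {self.name!r} has no stop codon")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, a in self.codon_to_aa.items() if a == "*"))

    @classmethod
    def from_tsv(cls, path: str | Path, name: Optional[str] = None) -> "GeneticCode":
        table: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, aa = line.split("\t")[:2]
            if codon.lower() == "codon":
                continue
            table[codon.upper().replace("U", "T")] = aa.upper()
        return cls(table, name=name or Path(path).stem)

    @classmethod
    def blepharisma(cls) -> "GeneticCode":
        """Default variant code: UGA→Trp, UAA/UAG→stop."""
        return cls.from_tsv(_data_path("blepharisma_code.tsv"), name="blepharisma")

    @classmethod
    def standard(cls) -> "GeneticCode":
        code = cls.blepharisma()
        table = dict(code.codon_to_aa)
        table["TGA"] = "*"
        return cls(table, name="standard")


@dataclass
class OrfRecord:
    """A translated open reading frame of one source sequence."""

    source_id: str
    protein: str
    stop_codon: str  # "" when translation ran off the end
    frame: int
    start_offset: int  # 0-based offset of the first translated base
    strand: int = 1

    def __post_init__(self) -> None:
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain a stop symbol")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")

    @property
    def orf_length_aa(self) -> int:
        return len(self.protein)


def read_fasta(
    path: str | Path,
    metadata: Optional[str | Path] = None,
    alphabet: str = "dna",
) -> list[SequenceRecord]:
    """Read FASTA into records, joining an optional metadata TSV by id.

    The metadata table must have a header with at least an ``id`` column;
    recognised columns are species, megakaryotype and mating_type.  Records
    without metadata carry ``species="unknown"``.
    """
    meta: dict[str, dict[str, str]] = {}
    if metadata is not None:
        meta = _read_metadata(metadata)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        row = meta.get(rec.id, {})
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=str(rec.seq),
                alphabet=alphabet,
                species=row.get("species", "unknown"),
                megakaryotype=row.get("megakaryotype", "other"),
                mating_type=row.get("mating_type") or None,
            )
        )
    return records


def _read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        return {}
    header = lines[0].rstrip("\n").split("\t")
    if "id" not in header:
        raise ValueError(f"metadata {path}: no 'id' column in header {header}")
    out: dict[str, dict[str, str]] = {}
    for line in lines[1:]:
        row = dict(zip(header, line.rstrip("\n").split("\t")))
        out[row["id"]] = row
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at `width` columns; round-trips with read_fasta."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA")
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def write_metadata(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tspecies\tmegakaryotype\tmating_type\n")
        for r in records:
            fh.write(f"{r.id}\t{r.species}\t{r.megakaryotype}\t{r.mating_type or ''}\n")


def translate(dna: str, code: Optional[GeneticCode] = None, frame: int = 0,
              source_id: str = "") -> OrfRecord:
    """Translate codon-by-codon from `frame` until the first stop or sequence end.

    Codons containing IUPAC ambiguity codes translate to 'X' (logged);
    non-IUPAC characters raise.  The terminating stop codon is recorded
    ("" when translation ran off the end of the sequence).
    """
    if code is None:
        code = GeneticCode.blepharisma()
    dna = dna.upper().replace("U", "T")
    bad = set(dna) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-IUPAC DNA characters {sorted(bad)}")
    if len(dna) - frame < 3:
        raise ValueError("fewer than one codon downstream of the requested frame")
    protein: list[str] = []
    stop = ""
    for i in range(frame, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if set(codon) <= UNAMBIGUOUS_DNA:
            aa = code.codon_to_aa[codon]
        else:
            logger.warning("ambiguous codon %s at offset %d translated as X", codon, i)
            aa = "X"
        if aa == "*":
            stop = codon
            break
        protein.append(aa)
    return OrfRecord(source_id=source_id, protein="".join(protein), stop_codon=stop,
                     frame=frame, start_offset=frame)


def find_longest_orf(
    dna: str,
    code: Optional[GeneticCode] = None,
    six_frame: bool = False,
    source_id: str = "",
) -> Optional[OrfRecord]:
    """Longest ATG-initiated, stop-terminated ORF across the forward frames.

    Ties break to the smallest start offset (then forward strand).  Returns
    None when no complete ORF exists.  `six_frame=True` also scans the
    reverse complement; deposited gamone-1 CDS are forward, so the default
    searches forward frames only.
    """
    if code is None:
        code = GeneticCode.blepharisma()
    dna = dna.upper().replace("U", "T")
    if not dna:
        raise ValueError("empty DNA sequence")
    strands = [(1, dna)]
    if six_frame:
        strands.append((-1, dna.translate(_COMPLEMENT)[::-1]))
    best: Optional[OrfRecord] = None
    for strand, seq in strands:
        i = seq.find("ATG")
        while i != -1:
            if len(seq) - i >= 3:
                cand = translate(seq[i:], code, 0, source_id=source_id)
                if cand.stop_codon:  # complete ORF only
                    rec = OrfRecord(source_id=source_id, protein=cand.protein,
                                    stop_codon=cand.stop_codon, frame=i % 3,
                                    start_offset=i, strand=strand)
                    if _better_orf(rec, best):
                        best = rec
            i = seq.find("ATG", i + 1)
    return best


def _better_orf(cand: OrfRecord, best: Optional[OrfRecord]) -> bool:
    if best is None:
        return True
    key = (-cand.orf_length_aa, cand.start_offset, -cand.strand)
    ref = (-best.orf_length_aa, best.start_offset, -best.strand)
    return key < ref


def orf_summary(records: Iterable[SequenceRecord], code: Optional[GeneticCode] = None):
    """Per-record ORF table (id, length, stop codon) as a pandas DataFrame."""
    import pandas as pd

    code = code or GeneticCode.blepharisma()
    rows = []
    for rec in records:
        orf = find_longest_orf(rec.residues, code, source_id=rec.id)
        rows.append(
            dict(
                id=rec.id,
                species=rec.species,
                orf_length_aa=orf.orf_length_aa if orf else 0,
                stop_codon=orf.stop_codon if orf else "",
                found=orf is not None,
            )
        )
    return pd.DataFrame(rows)
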