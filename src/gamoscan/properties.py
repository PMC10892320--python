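"""Amino-acid property-group divergence, region calling, sequons, hydropathy.

The central question for a species-specific pheromone: where along the
protein do substitutions change the *physicochemical class* of the residue
across species boundaries?  Residues are bucketed into six property groups
(volume/polarity clustering after Miyata et al. 1979, shipped as an editable
table); an alignment column is flagged when at least two species carry
residues from different groups.  Runs of flagged columns are merged into
hypervariable ("mutable") regions and runs without them into conserved
regions.  N-glycosylation sequons (N-X-S/T, X != P) and Kyte-Doolittle
hydropathy profiles complete the per-sequence annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .align import MultipleAlignment
from .codec import AMINO_ACIDS, SequenceRecord, _data_path

logger = logging.getLogger(__name__)

AMBIGUOUS = -1  # species group id when residues straddle groups


def _load_two_col(path: Path, cast=float) -> dict[str, float]:
    out = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("aa\t"):
            continue
        k, v = line.split("\t")[:2]
        out[k] = cast(v)
    return out


@dataclass
class PropertyScheme:
    """Partition of the 20 amino acids into property groups."""

    group_of: dict[str, int]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.group_of)
        if missing:
            raise ValueError(f"scheme {self.name!r} misses amino acids {sorted(missing)}")

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    @classmethod
    def from_tsv(cls, path: str | Path, name: Optional[str] = None) -> "PropertyScheme":
        table = _load_two_col(Path(path), cast=int)
        return cls({k: int(v) for k, v in table.items()}, name=name or Path(path).stem)

    @classmethod
    def miyata(cls) -> "PropertyScheme":
        """Default six-group volume/polarity scheme."""
        return cls.from_tsv(_data_path("miyata_groups.tsv"), name="miyata6")

    def table_text(self) -> str:
        groups: dict[int, list[str]] = {}
        for aa, g in sorted(self.group_of.items()):
            groups.setdefault(g, []).append(aa)
        return "; ".join(f"group {g}: {''.join(aas)}" for g, aas in sorted(groups.items()))


@dataclass
class SiteClassification:
    column: int  # 0-based alignment column
    ref_position: Optional[int]  # 1-based reference numbering; None if ref gapped
    residues_by_species: dict[str, dict[str, int]]
    group_by_species: dict[str, int]  # group id or AMBIGUOUS
    cross_boundary_flag: bool
    reason: str = ""


@dataclass
class RegionCall:
    kind: str  # "conserved" | "mutable"
    start: int  # 1-based inclusive, reference numbering
    end: int
    density: float  # flagged-site fraction over the region's columns

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        if self.kind not in ("conserved", "mutable"):
            raise ValueError(f"unknown region kind {self.kind!r}")


@dataclass
class SequonSet:
    sequence_id: str
    sites: list[int]  # 1-based Asn positions, strictly increasing

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sequon positions must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.sites)


@dataclass
class HydropathyProfile:
    sequence_id: str
    window: int
    values: np.ndarray  # mean hydropathy per centred window
    scale_name: str = "kyte-doolittle"

    def positions(self) -> np.ndarray:
        """1-based positions of the window centres."""
        half = self.window // 2
        return np.arange(len(self.values)) + half + 1


def species_map_of(msa: MultipleAlignment) -> dict[str, str]:
    return {r.id: r.species for r in msa.records}


def classify_column(
    msa: MultipleAlignment,
    column: int,
    scheme: Optional[PropertyScheme] = None,
    species_map: Optional[dict[str, str]] = None,
    majority_fraction: float = 1.0,
    ref_positions: Optional[np.ndarray] = None,
) -> SiteClassification:
    """Per-species property-group call for one alignment column.

    A species' group is that of its majority residue when at least
    `majority_fraction` of its (ungapped) residues fall in one group,
    else AMBIGUOUS.  The cross-boundary flag is raised iff two or more
    species carry distinct, non-ambiguous groups — i.e. a substitution has
    changed the residue's property class across a species boundary.
    """
    scheme = scheme or PropertyScheme.miyata()
    species_map = species_map or species_map_of(msa)
    if not (0 <= column < msa.ncols):
        raise IndexError(f"column {column} out of range")
    if ref_positions is None:
        ref_positions = msa.reference_positions()
    refpos = int(ref_positions[column]) or None

    residues: dict[str, dict[str, int]] = {}
    for rec in msa.records:
        sp = species_map[rec.id]
        ch = rec.residues[column]
        if ch == "-":
            continue
        residues.setdefault(sp, {})
        residues[sp][ch] = residues[sp].get(ch, 0) + 1

    if not residues:
        return SiteClassification(column, refpos, {}, {}, False, reason="all-gap")

    group_by_species: dict[str, int] = {}
    for sp, counts in residues.items():
        group_counts: dict[int, int] = {}
        total = 0
        for ch, n in counts.items():
            total += n
            g = scheme.group_of.get(ch)
            if g is None:  # X or other unknown
                continue
            group_counts[g] = group_counts.get(g, 0) + n
        if not group_counts:
            group_by_species[sp] = AMBIGUOUS
            continue
        g_best, n_best = max(group_counts.items(), key=lambda kv: (kv[1], -kv[0]))
        group_by_species[sp] = g_best if n_best >= majority_fraction * total else AMBIGUOUS

    groups = {g for g in group_by_species.values() if g != AMBIGUOUS}
    flag = len(groups) >= 2
    return SiteClassification(
        column=column,
        ref_position=refpos,
        residues_by_species=residues,
        group_by_species=group_by_species,
        cross_boundary_flag=flag,
        reason="cross-boundary property change" if flag else "",
    )


def call_cross_boundary_sites(
    msa: MultipleAlignment,
    scheme: Optional[PropertyScheme] = None,
    species_map: Optional[dict[str, str]] = None,
    majority_fraction: float = 1.0,
) -> list[SiteClassification]:
    """classify_column over every column, ordered by column index."""
    species_map = species_map or species_map_of(msa)
    if len(set(species_map.values())) < 2:
        raise ValueError("cross-boundary calling needs >=2 species")
    refpos = msa.reference_positions()
    return [
        classify_column(msa, j, scheme, species_map, majority_fraction, refpos)
        for j in range(msa.ncols)
    ]


@dataclass
class RegionParams:
    window: int = 10
    mutable_min_density: float = 0.3
    conserved_max_density: float = 0.05
    min_length: int = 10


def detect_regions(
    sites: Sequence[SiteClassification], params: Optional[RegionParams] = None
) -> list[RegionCall]:
    """Delineate conserved and hypervariable intervals from flagged sites.

    A centred sliding window of flagged-site density classifies each column
    as mutable-candidate (density >= mutable_min_density), conserved-candidate
    (density <= conserved_max_density) or neither; maximal same-kind runs at
    least `min_length` columns long become regions.  Coordinates are reported
    in 1-based reference numbering.
    """
    params = params or RegionParams()
    n = len(sites)
    if params.window > n:
        raise ValueError("window longer than the alignment")
    flags = np.array([s.cross_boundary_flag for s in sites], dtype=float)
    half = params.window // 2
    kernel = np.ones(params.window)
    counts = np.convolve(flags, kernel, mode="same")
    width = np.convolve(np.ones(n), kernel, mode="same")  # edge windows are shorter
    density = counts / width

    kind = np.zeros(n, dtype=int)  # 0 neither, 1 mutable, -1 conserved
    kind[density >= params.mutable_min_density] = 1
    kind[density <= params.conserved_max_density] = -1

    refpos = np.array(
        [s.ref_position if s.ref_position is not None else 0 for s in sites]
    )
    regions: list[RegionCall] = []
    i = 0
    while i < n:
        k = kind[i]
        j = i
        while j < n and kind[j] == k:
            j += 1
        if k != 0 and j - i >= params.min_length:
            seg_ref = refpos[i:j]
            seg_ref = seg_ref[seg_ref > 0]
            if len(seg_ref):
                regions.append(
                    RegionCall(
                        kind="mutable" if k == 1 else "conserved",
                        start=int(seg_ref.min()),
                        end=int(seg_ref.max()),
                        density=float(flags[i:j].mean()),
                    )
                )
        i = j
    return regions


def scan_sequons(
    protein: SequenceRecord | str,
    exclude_proline_x: bool = True,
    exclude_terminal: int = 2,
) -> SequonSet:
    """N-glycosylation sequon (N-X-S/T) scan on an ungapped protein.

    X != P by default (proline blocks glycosylation); Asn positions within
    `exclude_terminal` residues of the C-terminus are ignored (the motif
    itself forces a minimum of 2).  Positions are 1-based Asn coordinates.
    """
    if isinstance(protein, SequenceRecord):
        seq_id, seq = protein.id, protein.residues
    else:
        seq_id, seq = "", protein
    if "-" in seq:
        raise ValueError("sequon scan requires an ungapped protein")
    seq = seq.upper()
    cutoff = len(seq) - max(exclude_terminal, 2)
    sites = []
    for i in range(len(seq) - 2):
        if i >= cutoff:
            break
        if seq[i] != "N":
            continue
        x, third = seq[i + 1], seq[i + 2]
        if exclude_proline_x and x == "P":
            continue
        if third in ("S", "T"):
            sites.append(i + 1)
    return SequonSet(sequence_id=seq_id, sites=sites)


def kyte_doolittle_scale() -> dict[str, float]:
    return _load_two_col(_data_path("kyte_doolittle.tsv"))


def hydropathy_profile(
    protein: SequenceRecord | str,
    window: int = 9,
    scale: Optional[dict[str, float]] = None,
    scale_name: str = "kyte-doolittle",
) -> HydropathyProfile:
    """Centred moving-average hydropathy (default Kyte-Doolittle, window 9).

    Unknown residues ('X') are excluded from the window mean (logged); a
    window of only unknowns yields NaN.
    """
    if isinstance(protein, SequenceRecord):
        seq_id, seq = protein.id, protein.ungapped
    else:
        seq_id, seq = "", protein.replace("-", "")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    if window > len(seq):
        raise ValueError("window longer than the sequence")
    scale = scale or kyte_doolittle_scale()
    vals = np.array([scale.get(c, np.nan) for c in seq])
    if np.isnan(vals).any():
        logger.warning("%s: residues without a hydropathy value excluded from windows",
                       seq_id or "<anonymous>")
    known = (~np.isnan(vals)).astype(float)
    filled = np.nan_to_num(vals)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="valid")
    counts = np.convolve(known, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return HydropathyProfile(sequence_id=seq_id, window=window, values=means,
                             scale_name=scale_name)


def sites_to_frame(sites: Sequence[SiteClassification]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            dict(
                column_1based=s.column + 1,
                ref_position=s.ref_position,
                flagged=s.cross_boundary_flag,
                groups=";".join(
                    f"{sp}={'?' if g == AMBIGUOUS else g}"
                    for sp, g in sorted(s.group_by_species.items())
                ),
                reason=s.reason,
            )
        )
    return pd.DataFrame(rows)


def regions_to_frame(regions: Sequence[RegionCall], sequence_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(sequence=sequence_id, start=r.start, end=r.end, kind=r.kind,
                 density=round(r.density, 4))
            for r in regions
        ],
        columns=["sequence", "start", "end", "kind", "density"],
    )


def regions_to_bed(regions: Sequence[RegionCall], sequence_id: str) -> str:
    """0-based half-open BED lines for the region calls."""
    lines = [
        f"{sequence_id}\t{r.start - 1}\t{r.end}\t{r.kind}\t{r.density:.4f}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")
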