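"""Unit-method titer arithmetic for conjugation-inducing activity.

A 1 mL sample is serially two-fold diluted (typically up to 2^16) and tester
cells are added to each dilution.  If pairs form even at dilution 2^N, the
sample carries 2^(N+1) units/mL; one unit induces one pair among 750-1000
tester cells in 1 mL.  Exponent 0 is the undiluted sample, so a sample
positive only undiluted titres at 2 U/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


@dataclass
class DilutionSeriesResult:
    pairs_observed: dict[int, bool]  # exponent -> pairs seen
    max_exponent_tested: int = 16
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.pairs_observed:
            raise ValueError("empty dilution series")
        for e in self.pairs_observed:
            if e < 0 or e > self.max_exponent_tested:
                raise ValueError(f"exponent {e} outside 0..{self.max_exponent_tested}")

    def max_positive_exponent(self) -> Optional[int]:
        pos = [e for e, seen in self.pairs_observed.items() if seen]
        return max(pos) if pos else None

    def inconsistencies(self) -> list[int]:
        """Exponents negative while a higher dilution was positive."""
        pos = self.max_positive_exponent()
        if pos is None:
            return []
        return sorted(
            e for e, seen in self.pairs_observed.items() if e < pos and not seen
        )


@dataclass
class TiterResult:
    units_per_ml: float
    censored: bool  # still positive at the highest dilution tested
    sample_id: str = ""

    def __post_init__(self) -> None:
        u = self.units_per_ml
        if u != 0 and (u <= 0 or abs(u - 2 ** round(_log2(u))) > 1e-9):
            raise ValueError("titer must be 0 or a power of two")


def _log2(x: float) -> float:
    import math

    return math.log2(x)


def titer_from_series(series: DilutionSeriesResult, strict: bool = True) -> TiterResult:
    """Titer = 2^(N+1) U/mL for max positive exponent N; 0 when never positive.

    A series positive at the highest dilution tested is right-censored (the
    true titer is at least the reported value).  Non-monotone observations
    (negative wells below a positive dilution) are rejected under strict mode
    and resolved by the maximum positive exponent otherwise.
    """
    bad = series.inconsistencies()
    if bad and strict:
        raise ValueError(
            f"non-monotone dilution series: negative at exponents {bad} below a "
            "positive dilution (pass strict=False to take the max positive exponent)"
        )
    n = series.max_positive_exponent()
    if n is None:
        return TiterResult(0.0, censored=False, sample_id=series.sample_id)
    return TiterResult(
        float(2 ** (n + 1)),
        censored=(n == series.max_exponent_tested),
        sample_id=series.sample_id,
    )


def read_series_tsv(path: str | Path) -> list[DilutionSeriesResult]:
    """TSV with columns sample_id, exponent, pairs_observed (0/1/true/false)."""
    rows: dict[str, dict[int, bool]] = {}
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    for line in lines[1:]:
        sample, exp, seen = line.split("\t")[:3]
        rows.setdefault(sample, {})[int(exp)] = seen.strip().lower() in ("1", "true", "yes")
    return [
        DilutionSeriesResult(
            pairs_observed=obs,
            max_exponent_tested=max(obs),
            sample_id=sample,
        )
        for sample, obs in rows.items()
    ]


def write_titers_tsv(titers: list[TiterResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tunits_per_ml\tcensored\n")
        for t in titers:
            fh.write(f"{t.sample_id}\t{t.units_per_ml:g}\t{int(t.censored)}\n")
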