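#!/usr/bin/env python
"""Validation against the deposited gamone 1 homolog accessions.

This tier needs the 16 public database records (not bundled; the build
environment has no network access).  Given a FASTA of the coding sequences —
fetched yourself, e.g. via NCBI efetch:

    efetch -db nuccore -format fasta \
        -id AB920333,AB920337,AB920335,AB920336,AB920338,AB920332,AB920334,\
LC795784,LC795785,LC795786,LC795787,LC795788,LC795789,LC795790,AB056696 \
        > accessions.fasta

this script recomputes, under a documented identity mode and sequon rule:

  * per-strain ORF lengths and stop codons under the variant genetic code
    (expected: 305/307/304/305/305 aa by species; all stops TAA),
  * N-glycosylation sequon counts (expected 4 for the R1072-group strains,
    5 or 6 for the others),
  * the pairwise homology matrix (reference points: CCAP1607/1 vs SM-III
    = 100; EN-II vs SDT1-II = 96.1; SDT0-III vs R1072 = 67.8).

Headers may be raw accession ids; --map renames them to strain names.

Usage:
    python scripts/validate_accessions.py accessions.fasta [--mode shorter_seq]
"""

from __future__ import annotations

import argparse
import sys

ACCESSION_TO_STRAIN = {
    "AB920333": "EN-II",
    "AB920337": "SDT2-II",
    "AB920335": "K78",
    "AB920336": "SDT1-II",
    "AB920338": "YC-IV",
    "AB920332": "ATCC30299",
    "AB920334": "HT-IV",
    "LC795784": "CCAP1607/1",
    "LC795785": "SDT0-III",
    "LC795786": "SG1-III",
    "LC795787": "SM-III",
    "LC795788": "KG-IV",
    "LC795789": "WK-IV",
    "LC795790": "KR-III",
    "AB056696": "R1072",
}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("fasta", help="FASTA of the deposited coding sequences")
    parser.add_argument("--mode", default="aligned_columns",
                        choices=["aligned_columns", "shorter_seq"],
                        help="percent-identity denominator")
    parser.add_argument("--no-exclude-proline", action="store_true",
                        help="count N-P-S/T as sequons too")
    args = parser.parse_args()

    from gamoscan.align import build_identity_matrix, identity_table_text
    from gamoscan.codec import GeneticCode, SequenceRecord, find_longest_orf, read_fasta
    from gamoscan.properties import scan_sequons

    code = GeneticCode.blepharisma()
    records = read_fasta(args.fasta, alphabet="dna")
    proteins = []
    print("id\tstrain\tlength_aa\tstop\tn_sequons")
    for rec in records:
        accession = rec.id.split(".")[0]
        strain = ACCESSION_TO_STRAIN.get(accession, rec.id)
        orf = find_longest_orf(rec.residues, code, source_id=rec.id)
        if orf is None:
            print(f"{rec.id}\t{strain}\tNO ORF")
            continue
        sequons = scan_sequons(
            orf.protein, exclude_proline_x=not args.no_exclude_proline
        )
        print(f"{rec.id}\t{strain}\t{orf.orf_length_aa}\t{orf.stop_codon}"
              f"\t{sequons.count}")
        proteins.append(
            SequenceRecord(id=strain, residues=orf.protein, alphabet="protein")
        )

    if len(proteins) >= 2:
        matrix = build_identity_matrix(proteins, mode=args.mode)
        print()
        print(f"pairwise identity (%), mode={args.mode}:")
        print(identity_table_text(matrix, proteins))
    return 0


if __name__ == "__main__":
    sys.exit(main())
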