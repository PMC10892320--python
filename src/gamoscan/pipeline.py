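"""End-to-end orchestration: sequences in, annotated reports out.

Stages run in dependency order -- translation, pairwise identity, property /
region / sequon / hydropathy annotation, column masking, ML phylogeny with
bootstrap and topology tests -- each writing plain-text artifacts into the
output directory.  A JSON manifest with SHA-256 checksums plus a verbatim
config echo make runs self-describing and reproducible: identical config and
seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import align as al
from . import codec, properties as props
from .phylo.mlmodel import MLPhylogeny
from .phylo.trees import parse_newick_subtree

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    dna_fasta: Optional[str] = None
    protein_fasta: Optional[str] = None
    metadata: Optional[str] = None
    msa_path: Optional[str] = None
    msa_format: str = "aligned-fasta"
    genetic_code: str = "blepharisma"  # name or TSV path
    identity_mode: str = "aligned_columns"
    identity_flag_threshold: float = 87.0
    gap_open: float = 10.0
    gap_extend: float = 1.0
    drop_any_gap: bool = True
    entropy_threshold: float = 1.5
    flank_extension: int = 0
    property_scheme: Optional[str] = None  # TSV path; default Miyata-6
    majority_fraction: float = 1.0
    region_window: int = 10
    mutable_min_density: float = 0.3
    conserved_max_density: float = 0.05
    region_min_length: int = 10
    sequon_exclude_proline: bool = True
    hydropathy_window: int = 9
    run_phylo: bool = True
    n_rate_categories: int = 4
    constraints_newick: list[str] = field(default_factory=list)
    n_bootstrap: int = 200
    n_rell: int = 10000
    au_scales: list[float] = field(default_factory=lambda: [round(0.5 + 0.1 * i, 1) for i in range(10)])
    seed: int = 0
    outdir: str = "gamoscan_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)


@dataclass
class RunReport:
    outdir: Path
    files: dict[str, Path] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)

    def manifest(self) -> dict:
        return {
            "completed_stages": self.completed_stages,
            "files": {
                name: {
                    "path": str(p.relative_to(self.outdir)),
                    "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
                }
                for name, p in sorted(self.files.items())
            },
        }


def _genetic_code(spec: str) -> codec.GeneticCode:
    if spec == "blepharisma":
        return codec.GeneticCode.blepharisma()
    if spec == "standard":
        return codec.GeneticCode.standard()
    return codec.GeneticCode.from_tsv(spec)


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(outdir=outdir)
    (outdir / "config.yaml").write_text(config.to_yaml())
    report.files["config"] = outdir / "config.yaml"

    code = _genetic_code(config.genetic_code)
    scheme = (
        props.PropertyScheme.from_tsv(config.property_scheme)
        if config.property_scheme
        else props.PropertyScheme.miyata()
    )
    aln_params = al.AlignParams(gap_open=config.gap_open, gap_extend=config.gap_extend)
    logger.info("genetic code: %s; identity mode: %s; scheme: %s",
                code.name, config.identity_mode, scheme.table_text())

    # --- stage: sequences and translation ---------------------------------
    proteins: list[codec.SequenceRecord] = []
    orf_rows = []
    if config.dna_fasta:
        dna = codec.read_fasta(config.dna_fasta, config.metadata, alphabet="dna")
        _check_metadata_ids(dna, config.metadata)
        for rec in dna:
            orf = codec.find_longest_orf(rec.residues, code, source_id=rec.id)
            if orf is None:
                logger.warning("%s: no complete ORF found", rec.id)
                continue
            proteins.append(
                codec.SequenceRecord(
                    id=rec.id, residues=orf.protein, alphabet="protein",
                    species=rec.species, megakaryotype=rec.megakaryotype,
                    mating_type=rec.mating_type,
                )
            )
            sequons = props.scan_sequons(
                orf.protein, exclude_proline_x=config.sequon_exclude_proline
            )
            orf_rows.append(
                (rec.id, rec.species, orf.orf_length_aa, orf.stop_codon, sequons.count)
            )
    elif config.protein_fasta:
        proteins = codec.read_fasta(config.protein_fasta, config.metadata,
                                    alphabet="protein")
        for rec in proteins:
            sequons = props.scan_sequons(
                rec.ungapped, exclude_proline_x=config.sequon_exclude_proline
            )
            orf_rows.append((rec.id, rec.species, len(rec.ungapped), "", sequons.count))
    else:
        raise ValueError("config must provide dna_fasta or protein_fasta")

    with open(outdir / "orf_summary.tsv", "w") as fh:
        fh.write("id\tspecies\tlength_aa\tstop_codon\tn_sequons\n")
        for row in orf_rows:
            fh.write("\t".join(map(str, row)) + "\n")
    report.files["orf_summary"] = outdir / "orf_summary.tsv"
    report.completed_stages.append("translate")

    # --- stage: identity matrix --------------------------------------------
    ungapped = [
        codec.SequenceRecord(id=r.id, residues=r.ungapped, alphabet="protein",
                             species=r.species, megakaryotype=r.megakaryotype)
        for r in proteins
    ]
    matrix = al.build_identity_matrix(ungapped, aln_params, mode=config.identity_mode)
    al.write_identity_tsv(
        matrix, outdir / "identity_matrix.tsv", records=ungapped,
        flag_threshold=config.identity_flag_threshold,
    )
    report.files["identity_matrix"] = outdir / "identity_matrix.tsv"
    report.completed_stages.append("identity")

    # --- stage: alignment-based annotation ---------------------------------
    msa = None
    if config.msa_path:
        msa = al.ingest_msa(config.msa_path, config.msa_format, config.metadata)
    elif len({len(r.residues) for r in proteins}) == 1:
        msa = al.MultipleAlignment(proteins)  # already aligned (e.g. simulated)
    if msa is not None:
        sites = props.call_cross_boundary_sites(
            msa, scheme, majority_fraction=config.majority_fraction
        )
        props.sites_to_frame(sites).to_csv(outdir / "site_classifications.tsv",
                                           sep="\t", index=False)
        regions = props.detect_regions(
            sites,
            props.RegionParams(
                window=config.region_window,
                mutable_min_density=config.mutable_min_density,
                conserved_max_density=config.conserved_max_density,
                min_length=config.region_min_length,
            ),
        )
        props.regions_to_frame(regions, msa.reference_id).to_csv(
            outdir / "region_calls.tsv", sep="\t", index=False
        )
        (outdir / "region_calls.bed").write_text(
            props.regions_to_bed(regions, msa.reference_id)
        )
        report.files["site_classifications"] = outdir / "site_classifications.tsv"
        report.files["region_calls"] = outdir / "region_calls.tsv"
        report.files["region_calls_bed"] = outdir / "region_calls.bed"
        report.completed_stages.append("property_scan")

        prof_rows = []
        for rec in ungapped:
            prof = props.hydropathy_profile(rec, window=config.hydropathy_window)
            for pos, v in zip(prof.positions(), prof.values):
                prof_rows.append(f"{rec.id}\t{pos}\t{v:.4f}")
        (outdir / "hydropathy.tsv").write_text(
            "id\tcenter\tmean_hydropathy\n" + "\n".join(prof_rows) + "\n"
        )
        report.files["hydropathy"] = outdir / "hydropathy.tsv"
        report.completed_stages.append("hydropathy")

    # --- stage: phylogeny ----------------------------------------------------
    if config.run_phylo and msa is not None and len(msa.records) >= 3:
        mask = al.mask_columns(
            msa,
            al.MaskPolicy(
                drop_any_gap=config.drop_any_gap,
                entropy_threshold=config.entropy_threshold,
                flank_extension=config.flank_extension,
            ),
        )
        logger.info("column mask: %d of %d columns kept", mask.n_kept, msa.ncols)
        constraints = [parse_newick_subtree(nwk) for nwk in config.constraints_newick]
        model = MLPhylogeny.from_alignment(
            msa, mask=mask,
            n_rate_categories=config.n_rate_categories,
            constraints=constraints or None,
        )
        results = model.fit()
        support = results.bootstrap(n_boot=config.n_bootstrap, seed=config.seed)
        (outdir / "ml_tree.nwk").write_text(results.newick(support) + "\n")
        tests = results.topology_tests(
            n_rell=config.n_rell, au_scales=config.au_scales, seed=config.seed
        )
        tests.to_csv(outdir / "topology_tests.tsv", sep="\t", index=False)
        site_lnl = results.site_log_likelihoods()
        with open(outdir / "site_loglik.tsv", "w") as fh:
            fh.write("topology\t" + "\t".join(
                f"site{j + 1}" for j in range(site_lnl.shape[1])) + "\n")
            for f, row in zip(results.fits, site_lnl):
                fh.write(f.topology.canonical_id + "\t"
                         + "\t".join(f"{v:.6f}" for v in row) + "\n")
        report.files["site_loglik"] = outdir / "site_loglik.tsv"
        (outdir / "phylo_summary.txt").write_text(results.summary() + "\n")
        report.files["ml_tree"] = outdir / "ml_tree.nwk"
        report.files["topology_tests"] = outdir / "topology_tests.tsv"
        report.files["phylo_summary"] = outdir / "phylo_summary.txt"
        report.completed_stages.append("phylo")

    (outdir / "manifest.json").write_text(json.dumps(report.manifest(), indent=2))
    return report


def _check_metadata_ids(records, metadata: Optional[str]) -> None:
    if not metadata:
        return
    from .codec import _read_metadata

    meta_ids = set(_read_metadata(metadata))
    rec_ids = {r.id for r in records}
    orphans = sorted(meta_ids - rec_ids)
    missing = sorted(rec_ids - meta_ids)
    if missing:
        raise ValueError(
            "FASTA records without metadata rows: " + ", ".join(missing)
        )
    if orphans:
        logger.warning("metadata rows without records: %s", ", ".join(orphans))


def topology_table_text(tests, max_rows: Optional[int] = None) -> str:
    """Topology-test table rendered as a ranked list (tree no., ΔlnL, AU/KH/SH)."""
    rows = ["tree\tdelta_lnL\tp_AU\tp_KH\tp_SH\tnewick"]
    it = tests.reset_index(drop=True)
    if max_rows:
        it = it.head(max_rows)
    for i, row in it.iterrows():
        rows.append(
            f"{i + 1}\t{row.delta_lnL:.2f}\t{row.p_au:.3f}\t{row.p_kh:.3f}"
            f"\t{row.p_sh:.3f}\t{row.get('newick', '')}"
        )
    return "\n".join(rows) + "\n"
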