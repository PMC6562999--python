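"""End-to-end orchestration: QC -> linkage -> autozygosity -> intersection ->
variant filtering -> consequence annotation -> segregation.

Mirrors the positional-cloning flow for a recessive trait: the genome is
first narrowed to intervals supported by both parametric linkage and
case-shared, control-excluded autozygosity; the sequenced case's private
homozygous variants inside those intervals are then annotated, and
protein-changing candidates are checked for perfect co-segregation across
the genotyped cohort.  Every stage is a pure function of its inputs and the
configuration, so a rerun reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import autozygosity as az
from . import linkage as lk
from .genotypes import GenotypeMatrix, qc_filter
from .intervals import GenomeInterval, to_bed_line
from .pedigree import AFFECTED, UNAFFECTED, Pedigree, validate_pedigree
from .segregation import perfect_segregation, tabulate
from .variants import (
    TranscriptModel,
    VariantRecord,
    candidate_report,
    private_hom_filter,
    restrict_to_intervals,
)


class PipelineError(RuntimeError):
    """Stage failure; the message names the failing stage."""


@dataclass
class PipelineParams:
    min_marker_call_rate: float = 0.90
    min_individual_call_rate: float = 0.90
    disease_allele_freq: float = 0.001
    theta_grid: tuple[float, ...] = lk.DEFAULT_THETA_GRID
    roh_min_markers: int = az.DEFAULT_MIN_MARKERS
    roh_min_length_bp: int = az.DEFAULT_MIN_LENGTH_BP
    roh_max_het: int = 0
    roh_max_missing: int = 2
    allele_aware_control_exclusion: bool = False
    linkage_family: tuple[str, ...] | None = None  # explicit loop-free subfamily


@dataclass
class RunReport:
    params: dict
    qc: dict
    linkage: dict
    autozygosity: dict
    critical_intervals: list[dict]
    funnel: dict
    candidates: list[dict]
    segregation: dict
    versions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _interval_dict(iv: GenomeInterval, **extra) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "length_bp": iv.length, **extra}


def _versions() -> dict:
    import numpy
    import pandas

    from . import __version__

    return {"ataxmap": __version__, "numpy": numpy.__version__, "pandas": pandas.__version__}


def select_linkage_family(ped: Pedigree, genotyped: Sequence[str]) -> list[str]:
    """Largest fully genotyped nuclear family with an affected child.

    On looped pedigrees (the two-litter template is looped through the
    shared dam and the father-son sire pair), exact peeling needs a loop-free
    unit; a single nuclear family is the natural choice and carries most of
    the two-point information.
    """
    have = set(genotyped)
    best: list[str] = []
    for sire, dam, kids in ped.nuclear_families():
        members = [sire, dam] + kids
        if not all(m in have for m in members):
            continue
        if not any(ped[k].phenotype == AFFECTED for k in kids):
            continue
        affected = sum(ped[k].phenotype == AFFECTED for k in kids)
        if len(members) > len(best) or (
            len(members) == len(best)
            and best
            and affected > sum(ped[k].phenotype == AFFECTED for k in best[2:])
        ):
            best = members
    if not best:
        raise PipelineError("linkage: no fully genotyped nuclear family with an affected child")
    return best


def run_pipeline(
    ped: Pedigree,
    gm: GenotypeMatrix,
    case_variants: Sequence[VariantRecord],
    control_index: Mapping[tuple[str, int, str, str], tuple[int, int]],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str] | None,
    cohort_genotypes: Mapping[tuple[str, int, str, str], Mapping[str, int]],
    case_id: str,
    params: PipelineParams | None = None,
    out_dir=None,
) -> RunReport:
    """Execute the full mapping pipeline on in-memory inputs.

    ``cohort_genotypes`` holds per-individual genotypes for candidate sites
    (the targeted-genotyping data used for the segregation stage).  When
    ``out_dir`` is set, intermediate artifacts (LOD table, BED intervals,
    candidate table, report JSON) are written there.
    """
    params = params or PipelineParams()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- validation + QC
    violations = validate_pedigree(ped)
    if any(v.rule in ("cycle", "unresolved-parent") for v in violations):
        raise PipelineError(f"pedigree: structural violations {violations}")
    gm_qc, qc_report = qc_filter(
        gm, params.min_marker_call_rate, params.min_individual_call_rate
    )
    if out is not None:
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    cases = [i for i in gm_qc.individual_ids if ped[i].phenotype == AFFECTED]
    controls = [i for i in gm_qc.individual_ids if ped[i].phenotype == UNAFFECTED]
    if not cases:
        raise PipelineError("qc: no affected, genotyped individual remains")

    # --- linkage on a loop-free family
    fam_ids = list(params.linkage_family) if params.linkage_family else select_linkage_family(
        ped, gm_qc.individual_ids
    )
    subped = ped.subfamily(fam_ids)
    model = lk.DiseaseModel.fully_penetrant_recessive(params.disease_allele_freq)
    curves, flagged = lk.two_point_lod(subped, gm_qc, model, params.theta_grid)
    regions = lk.linked_regions(curves, gm_qc.marker_map)
    if out is not None:
        lk.lod_table(curves, gm_qc.marker_map).to_csv(out / "lod.tsv", sep="\t", index=False)
        (out / "linked_regions.bed").write_text(
            "".join(to_bed_line(r.interval, f"lod={r.peak_lod:.3f}") + "\n" for r in regions)
        )

    # --- autozygosity
    roh = az.detect_roh(
        gm_qc,
        min_markers=params.roh_min_markers,
        min_length_bp=params.roh_min_length_bp,
        max_het=params.roh_max_het,
        max_missing=params.roh_max_missing,
    )
    case_shared = az.shared_case_homozygosity(
        {c: roh[c] for c in cases}, gm_qc, cases
    )
    control_segments = {c: roh[c] for c in controls}
    crit = az.critical_regions(
        regions,
        case_shared,
        control_segments,
        gm_qc.marker_map,
        min_length_bp=params.roh_min_length_bp,
        allele_aware=params.allele_aware_control_exclusion,
        gm=gm_qc,
        case_ids=cases,
    )
    if out is not None:
        with open(out / "roh.bed", "w") as fh:
            for iid, segs in roh.items():
                for s in segs:
                    fh.write(to_bed_line(s.interval, f"{iid};n={s.n_markers}") + "\n")
        (out / "critical_regions.bed").write_text(
            "".join(to_bed_line(c.interval, f"n_markers={c.n_markers}") + "\n" for c in crit)
        )

    # --- variant funnel
    private = private_hom_filter(list(case_variants), control_index, case_sample=case_id)
    in_interval = restrict_to_intervals(private, [c.interval for c in crit])
    table, funnel = candidate_report(in_interval, list(transcripts), genome)
    if out is not None:
        table.to_csv(out / "candidates.tsv", sep="\t", index=False)

    # --- segregation of protein-changing candidates
    phenotypes = {iid: ped[iid].phenotype for iid in ped.ids}
    protein_changing = table[table["consequence"].isin(["missense", "nonsense"])]
    seg_result: dict = {"candidate": None, "perfect": None, "discordant": None, "counts": None}
    for row in protein_changing.itertuples():
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        genos = cohort_genotypes.get(key)
        if genos is None:
            continue
        st = tabulate(genos, phenotypes)
        ok, discordant = perfect_segregation(st, model)
        seg_result = {
            "candidate": f"{row.chrom}:{row.pos}{row.ref}>{row.alt}",
            "c_notation": row.c_notation,
            "p_notation": row.p_notation,
            "perfect": bool(ok),
            "discordant": int(discordant),
            "counts": {
                r: {g: int(st.counts.loc[r, g]) for g in st.counts.columns}
                for r in st.counts.index
            },
        }
        if out is not None:
            st.to_tsv(out / "segregation.tsv")
        break  # report the top candidate; others are in the table

    report = RunReport(
        params=dataclasses.asdict(params) if isinstance(params, PipelineParams) else dict(params),
        qc={
            "n_markers_in": len(gm.marker_map),
            "n_markers_kept": len(gm_qc.marker_map),
            "n_individuals_kept": len(gm_qc.individual_ids),
            "removed": qc_report.loc[qc_report["action"] == "removed", "id"].tolist(),
        },
        linkage={
            "family": fam_ids,
            "n_markers_scanned": len(curves),
            "n_flagged_mendelian": len(flagged),
            "n_regions": len(regions),
            "regions": [
                _interval_dict(r.interval, peak_lod=r.peak_lod, n_markers=len(r.marker_ids))
                for r in regions
            ],
        },
        autozygosity={
            "cases": cases,
            "controls": controls,
            "n_case_shared": len(case_shared),
            "case_shared": [_interval_dict(iv) for iv in case_shared],
        },
        critical_intervals=[
            _interval_dict(c.interval, n_markers=c.n_markers, peak_lod=c.peak_lod) for c in crit
        ],
        funnel={
            "n_private_hom": len(private),
            "n_in_critical_interval": len(in_interval),
            **funnel,
        },
        candidates=table.to_dict(orient="records"),
        segregation=seg_result,
        versions=_versions(),
    )
    if out is not None:
        report.to_json(out / "report.json")
    return report


def run_pipeline_files(
    fam_path,
    ped_path,
    map_path,
    case_vcf,
    controls_vcf,
    gff3_path,
    fasta_path,
    pedigree_vcf,
    case_id: str | None = None,
    params: PipelineParams | None = None,
    out_dir=None,
) -> RunReport:
    """File-based front end: load the standard formats, then run the pipeline."""
    import pyfaidx

    from .genotypes import read_ped_map
    from .pedigree import read_fam
    from .variants import control_carrier_index, read_gff3, read_vcf

    ped = read_fam(fam_path)
    _, gm = read_ped_map(ped_path, map_path)
    case_variants = read_vcf(case_vcf)
    if case_id is None:
        samples = set().union(*(v.genotypes.keys() for v in case_variants))
        if len(samples) != 1:
            raise PipelineError(f"variants: case VCF must be single-sample, got {sorted(samples)}")
        case_id = samples.pop()
    control_index = control_carrier_index(controls_vcf)
    transcripts = read_gff3(gff3_path)
    fasta = pyfaidx.Fasta(str(fasta_path))
    genome = {name: str(fasta[name][:]) for name in fasta.keys()}
    cohort_genotypes = {
        v.key: v.genotypes for v in read_vcf(pedigree_vcf)
    }
    return run_pipeline(
        ped,
        gm,
        case_variants,
        control_index,
        transcripts,
        genome,
        cohort_genotypes,
        case_id,
        params=params,
        out_dir=out_dir,
    )


def run_on_dataset(dataset, params: PipelineParams | None = None, out_dir=None) -> RunReport:
    """Run the pipeline directly on a SimulatedDataset (no file round-trip)."""
    return run_pipeline(
        dataset.pedigree,
        dataset.gm,
        dataset.case_variants(),
        dataset.control_index(),
        dataset.transcripts,
        dataset.genome,
        {v.key: v.genotypes for v in dataset.variants},
        dataset.case_id,
        params=params,
        out_dir=out_dir,
    )
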