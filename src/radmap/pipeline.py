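"""End-to-end pipeline: genotypes -> filters -> tags -> groups -> three maps.

Stages (each surfacing its errors under its own name):

1. ``filter``      Mendelian / missingness filters on 1:1 SNPs.
2. ``tags``        RAD-tag selection (intra < 1 kb, inter >= 100 kb).
3. ``grouping``    LOD clustering of the female-informative SNPs; tags
                   inherit their female SNP's group.
4. ``mapping``     Per group: order the female matrix, harmonize phases
                   along that order for both meioses, merge into the 2N-row
                   pseudo-backcross, order the merged matrix (integrated
                   order) and the male matrix, fit interval r by EM and
                   convert to Kosambi cM.
5. ``compare``     Multipoint log10-likelihood of the three orders per LG on
                   the merged data.
6. ``concordance`` Discordant regions of each flavor's order against the
                   reference coordinates.

Default thresholds and filters are the standard values for this design:
chi-square alpha 0.01, missing ceiling 20%, LOD scan 5..17, r̂ guard 0.45.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .concord import DiscordanceReport, count_discordant, read_reference_order, write_discordance_table
from .geno import FilterReport, SnpRecord, filter_markers, read_genotype_tsv, read_vcf
from .grouping import GroupingResult, scan_thresholds, write_group_table
from .mapping import (
    LinkageMapSet,
    build_group,
    build_maps,
    compare_orders,
    order_markers,
    write_map_summary,
    write_map_tsv,
)
from .phasemerge import FEMALE, MALE, bc_matrix_from_records, harmonize_phases, merge_datasets, write_bc_matrix
from .tags import RadTag, natural_chrom_key, select_tags, write_tag_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_genotypes"]

FLAVORS = ("INTEGRATED", "FEMALE", "MALE")


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults follow the reference protocol."""

    alpha: float = 0.01
    missing_max: float = 0.20
    intra_max: int = 1000
    inter_min: int = 100_000
    lod_thresholds: Sequence[float] = tuple(range(5, 18))
    r_max: float = 0.45
    seed: int = 0
    expected_groups: int | None = None
    estimate_error: bool = True  # fit a per-group miscall rate in the multipoint EM
    genotypes: str | None = None
    female: str = "female"
    male: str = "male"
    reference_order: str | None = None
    out_dir: str | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_reports: list[FilterReport]
    tags: list[RadTag]
    grouping: GroupingResult
    lg_tags: list[list[str]]  # tag ids per LG, LG index order
    maps: dict[str, LinkageMapSet]
    comparison: pd.DataFrame  # per-LG log10L of the three orders on merged data
    discordance: dict[str, dict[int, DiscordanceReport]]
    merged_matrices: list = field(default_factory=list, repr=False)


def load_genotypes(path: str, female: str = "female", male: str = "male") -> list[SnpRecord]:
    """Read genotypes from VCF (by extension) or the TSV dialect."""
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return read_vcf(path, female=female, male=male)
    return read_genotype_tsv(path)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(
    config: PipelineConfig, records: Sequence[SnpRecord] | None = None
) -> PipelineResult:
    """Run the full mapping pipeline; see the module docstring for the stages."""
    out = config.out_dir
    if out:
        os.makedirs(out, exist_ok=True)
    manifest: dict = {"status": "incomplete", "stage": None, "version": __version__}

    def _write_manifest():
        if out:
            with open(os.path.join(out, "MANIFEST.json"), "w") as fh:
                json.dump(manifest, fh, indent=2)

    try:
        with _stage("input"):
            manifest["stage"] = "input"
            if records is None:
                if config.genotypes is None:
                    raise ValueError("no genotype records and no input path configured")
                records = load_genotypes(config.genotypes, config.female, config.male)
            records = list(records)
            if not records:
                raise ValueError("empty genotype input")

        with _stage("filter"):
            manifest["stage"] = "filter"
            kept, reports = filter_markers(records, alpha=config.alpha, missing_max=config.missing_max)
            if len(kept) < 2:
                raise ValueError(f"fewer than 2 informative markers survive the filters ({len(kept)})")

        with _stage("tags"):
            manifest["stage"] = "tags"
            tag_list = select_tags(kept, intra_max=config.intra_max, inter_min=config.inter_min)
            if len(tag_list) < 2:
                raise ValueError(f"fewer than 2 RAD tags selected ({len(tag_list)})")
            by_id = {r.marker_id: r for r in kept}
            tag_by_f = {t.snp_f: t for t in tag_list}

        with _stage("grouping"):
            manifest["stage"] = "grouping"
            female_records = [by_id[t.snp_f] for t in tag_list]
            # With a target group count (e.g. the karyotype) scan the threshold
            # band for it; otherwise raising the threshold can only fragment
            # true chromosomes, so use the most inclusive (smallest) threshold.
            res = scan_thresholds(
                female_records,
                config.lod_thresholds,
                expected_groups=config.expected_groups,
                r_max=config.r_max,
            )
            grouping = res if isinstance(res, GroupingResult) else res[0]
            # tags inherit their female SNP's group; order LGs genomically
            lg_members: list[list[RadTag]] = []
            for group in grouping.groups:
                members = [tag_by_f[m] for m in group]
                members.sort(key=lambda t: (natural_chrom_key(t.chrom), t.anchor_pos))
                lg_members.append(members)
            lg_members.sort(key=lambda ms: (natural_chrom_key(ms[0].chrom), ms[0].anchor_pos))

        with _stage("mapping"):
            manifest["stage"] = "mapping"
            flavor_groups: dict[str, list] = {f: [] for f in FLAVORS}
            comparison_rows = []
            lg_tags: list[list[str]] = []
            merged_matrices = []
            for lg_index, members in enumerate(lg_members, start=1):
                tag_ids = [t.tag_id for t in members]
                lg_tags.append(tag_ids)
                f_recs = [by_id[t.snp_f] for t in members]
                m_recs = [by_id[t.snp_m] for t in members]
                f_mat = bc_matrix_from_records(f_recs, FEMALE, marker_ids=tag_ids)
                m_mat = bc_matrix_from_records(m_recs, MALE, marker_ids=tag_ids)
                female_order = order_markers(f_mat, seed=config.seed)
                male_order = order_markers(m_mat, seed=config.seed)
                # transform both meioses along the female-map tag order, then merge
                f_h = harmonize_phases(f_mat, female_order)
                m_h = harmonize_phases(m_mat, female_order)
                merged = merge_datasets(f_h, m_h)
                integrated_order = order_markers(merged, seed=config.seed)
                merged_matrices.append(merged)
                orders = {
                    "INTEGRATED": integrated_order,
                    "FEMALE": female_order,
                    "MALE": male_order,
                }
                flavor_groups["INTEGRATED"].append(
                    build_group(merged, integrated_order, "INTEGRATED", estimate_error=config.estimate_error)
                )
                flavor_groups["FEMALE"].append(
                    build_group(f_h, female_order, "FEMALE", estimate_error=config.estimate_error)
                )
                flavor_groups["MALE"].append(
                    build_group(
                        harmonize_phases(m_mat, male_order), male_order, "MALE",
                        estimate_error=config.estimate_error,
                    )
                )
                lls = compare_orders(merged, orders, estimate_error=config.estimate_error)
                comparison_rows.append({"LG": lg_index, **{k: round(v, 2) for k, v in lls.items()}})
            maps = {f: build_maps(flavor_groups[f], f) for f in FLAVORS}
            comparison = pd.DataFrame(comparison_rows)

        with _stage("concordance"):
            manifest["stage"] = "concordance"
            if config.reference_order:
                genome_pos = read_reference_order(config.reference_order)
            else:
                genome_pos = {t.tag_id: (t.chrom, t.anchor_pos) for t in tag_list}
            discordance: dict[str, dict[int, DiscordanceReport]] = {f: {} for f in FLAVORS}
            for f in FLAVORS:
                for lg_index, g in enumerate(maps[f].groups, start=1):
                    discordance[f][lg_index] = count_discordant(g, genome_pos)
    except _StageError:
        _write_manifest()
        raise

    result = PipelineResult(
        config=config,
        filter_reports=reports,
        tags=tag_list,
        grouping=grouping,
        lg_tags=lg_tags,
        maps=maps,
        comparison=comparison,
        discordance=discordance,
        merged_matrices=merged_matrices,
    )
    if out:
        _write_outputs(result, out)
        manifest.update({"status": "complete", "stage": "done"})
        _write_manifest()
    return result


def _write_outputs(result: PipelineResult, out: str) -> None:
    cfg = result.config
    write_tag_table(result.tags, os.path.join(out, "tags.tsv"))
    write_group_table(result.grouping, os.path.join(out, "groups.tsv"))
    write_map_tsv(result.maps, os.path.join(out, "maps.tsv"))
    write_map_summary(result.maps, os.path.join(out, "map_summary.tsv"))
    result.comparison.to_csv(os.path.join(out, "order_likelihoods.tsv"), sep="\t", index=False)
    write_discordance_table(result.discordance, os.path.join(out, "discordance.tsv"))
    for i, merged in enumerate(result.merged_matrices, start=1):
        write_bc_matrix(merged, os.path.join(out, f"merged_LG{i:02d}.tsv"))
    pd.DataFrame(
        [
            (r.marker_id, f"{r.chi2:.4f}", f"{r.p_value:.6g}", f"{r.missing_fraction:.4f}",
             r.kept, r.reason.value)
            for r in result.filter_reports
        ],
        columns=["marker_id", "chi2", "p_value", "missing_fraction", "kept", "reason"],
    ).to_csv(os.path.join(out, "filter_report.tsv"), sep="\t", index=False)
    log = {
        "radmap_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "missing_max": cfg.missing_max,
        "intra_max": cfg.intra_max,
        "inter_min": cfg.inter_min,
        "lod_thresholds": list(cfg.lod_thresholds),
        "lod_threshold_used": result.grouping.lod_threshold_used,
        "r_max": cfg.r_max,
        "estimate_error": cfg.estimate_error,
        "n_markers_kept": int(sum(r.kept for r in result.filter_reports)),
        "n_markers_removed": int(sum(not r.kept for r in result.filter_reports)),
        "n_tags": len(result.tags),
        "n_linkage_groups": len(result.lg_tags),
        "n_singleton_markers": len(result.grouping.singletons),
        "total_cM": {f: round(m.total_cM, 2) for f, m in result.maps.items()},
        "mean_adjacent_cM": {f: round(m.mean_adjacent_cM, 2) for f, m in result.maps.items()},
    }
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
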