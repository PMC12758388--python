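"""Stage orchestration: run the analysis end to end on disk.

Each stage reads the previous stages' files from the run directory,
writes versioned TSV/BED/JSON outputs, and drops a JSON provenance
sidecar (inputs, parameters, seed, record counts) next to each product.
Stage order: simulate -> call-blocks -> {scan-longreads, junctions, spi,
order, sites, stats}.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from . import __version__
from .block_caller import (
    SignificanceThresholds,
    adjacency_summary,
    call_blocks_all_genes,
    pair_exons,
    summarize_blocks,
    write_blocks_tsv,
)
from .cohort_stats import (
    paired_dpsi_correlation,
    permutation_gene_enrichment,
    random_pairing_control,
)
from .core_model import categorize_exons
from .io_formats import (
    read_alignments,
    read_diff_table,
    read_gene_models,
    read_sj_tab,
    write_blocks_bed12,
    write_diff_table,
    write_sj_tab,
)
from .read_ops import (
    call_block_skip,
    count_junction_reads,
    detection_summary,
    reconstruct_geometry,
    write_block_skip_tsv,
)
from .splice_sites import (
    compare_categories,
    extract_site_sequences,
    scan_recursive_5ss,
    score_site,
    train_pwm_model,
)
from .splicing_metrics import categorize_introns, compute_fupfi, compute_spi, differential_spi
from .synthetic import (
    SimConfig,
    generate_annotation,
    generate_diff_table,
    simulate_long_reads,
    simulate_nascent_reads,
    write_annotation,
    write_sam,
)

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "call-blocks", "scan-longreads", "junctions",
    "spi", "order", "sites", "stats",
]

_DEPENDENCIES = {
    "call-blocks": ["simulate"],
    "scan-longreads": ["call-blocks"],
    "junctions": ["call-blocks"],
    "spi": ["call-blocks"],
    "order": ["call-blocks"],
    "sites": ["call-blocks"],
    "stats": ["call-blocks"],
}

_STAGE_MARKERS = {
    "simulate": "sim/diff_table.tsv",
    "call-blocks": "blocks/blocks.tsv",
}


@dataclass
class RunConfig:
    """Paths, thresholds, tolerances, and seeds for one pipeline run."""

    outdir: str = "run"
    thresholds: SignificanceThresholds = field(default_factory=SignificanceThresholds)
    sim: SimConfig = field(default_factory=SimConfig)
    min_gap: int = 20
    junction_tolerance_nt: int = 8
    spi_min_cov: int = 10
    fupfi_min_informative: int = 5
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "thresholds" in raw:
            kwargs["thresholds"] = SignificanceThresholds(**raw.pop("thresholds"))
        if "sim" in raw:
            sim = raw.pop("sim")
            for key in ("exons_per_gene", "exon_len", "intron_len_other",
                        "intron_len_flanking", "block_size_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimConfig(**sim)
        kwargs.update(raw)
        return cls(**kwargs)


def _provenance(path: Path, stage: str, config: RunConfig, **extra) -> None:
    payload = {
        "stage": stage,
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        **extra,
    }
    path.with_suffix(path.suffix + ".prov.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=str)
    )


def _require(config: RunConfig, stage: str) -> None:
    for dep in _DEPENDENCIES.get(stage, []):
        marker = Path(config.outdir) / _STAGE_MARKERS.get(dep, "")
        if not marker.exists():
            raise FileNotFoundError(
                f"stage '{stage}' needs output of stage '{dep}' "
                f"(missing {marker}); run '{dep}' first"
            )


def _geometry(sam_path: Path, min_gap: int):
    return [
        reconstruct_geometry(rec, min_gap=min_gap)
        for rec in read_alignments(sam_path)
    ]


def _load_blocks(config: RunConfig):
    """Re-derive blocks/singles from the written diff table (deterministic)."""
    out = Path(config.outdir)
    models = read_gene_models(out / "sim" / "annotation.gtf")
    records = read_diff_table(out / "sim" / "diff_table.tsv")
    from .block_caller import filter_significant

    significant = filter_significant(records, config.thresholds)
    blocks, singles = call_blocks_all_genes(significant, models, config.thresholds)
    return models, records, significant, blocks, singles


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: RunConfig) -> None:
    out = Path(config.outdir) / "sim"
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_annotation(config.sim)
    write_annotation(bundle, out)
    records = generate_diff_table(config.sim, bundle)
    write_diff_table(records, out / "diff_table.tsv")
    chrom_lengths = {c: len(s) for c, s in bundle.genome.items()}
    for condition in ("ctrl", "treat"):
        reads = simulate_long_reads(config.sim, bundle, condition)
        write_sam(reads, chrom_lengths, out / f"longreads_{condition}.sam")
        for rep in range(config.sim.replicates):
            spi_reads, order_reads, sj = simulate_nascent_reads(
                config.sim, bundle, condition, rep
            )
            write_sam(
                spi_reads + order_reads, chrom_lengths,
                out / f"nascent_{condition}_rep{rep}.sam",
            )
            write_sj_tab(sj, out / f"sj_{condition}_rep{rep}.tab",
                         sample=f"{condition}_rep{rep}")
    _provenance(out / "diff_table.tsv", "simulate", config,
                sim=asdict(config.sim), n_records=len(records))
    logger.info("simulate: wrote %s", out)


def stage_call_blocks(config: RunConfig) -> None:
    _require(config, "call-blocks")
    out = Path(config.outdir) / "blocks"
    out.mkdir(parents=True, exist_ok=True)
    models, records, significant, blocks, singles = _load_blocks(config)
    write_blocks_tsv(blocks, out / "blocks.tsv")
    write_blocks_bed12(blocks, models, out / "blocks.bed12")
    summary = summarize_blocks(blocks, singles, models)
    pairs = [
        p
        for gid, model in models.items()
        for p in pair_exons(significant, model, config.thresholds)
    ]
    (out / "summary.json").write_text(
        json.dumps(
            {"blocks": asdict(summary), "adjacency": adjacency_summary(pairs)},
            indent=1, sort_keys=True, default=float,
        )
    )
    _provenance(out / "blocks.tsv", "call-blocks", config,
                n_blocks=len(blocks), n_singles=len(singles))


def stage_scan_longreads(config: RunConfig) -> None:
    _require(config, "scan-longreads")
    out = Path(config.outdir) / "longread_scan"
    out.mkdir(parents=True, exist_ok=True)
    models, _, _, blocks, _ = _load_blocks(config)
    sim = Path(config.outdir) / "sim"
    for condition in ("ctrl", "treat"):
        reads = _geometry(sim / f"longreads_{condition}.sam", config.min_gap)
        calls = [
            call_block_skip(reads, b, models[b.gene_id],
                            tolerance_nt=config.junction_tolerance_nt)
            for b in blocks
            if b.skip_junction is not None
        ]
        dest = out / f"block_skip_{condition}.tsv"
        write_block_skip_tsv(calls, dest)
        _provenance(dest, "scan-longreads", config, condition=condition,
                    n_blocks=len(calls))


def stage_junctions(config: RunConfig) -> None:
    _require(config, "junctions")
    out = Path(config.outdir) / "junctions"
    out.mkdir(parents=True, exist_ok=True)
    _, _, _, blocks, _ = _load_blocks(config)
    junctions = [b.skip_junction for b in blocks if b.skip_junction is not None]
    sim = Path(config.outdir) / "sim"
    per_condition = {}
    totals = {}
    for condition in ("ctrl", "treat"):
        merged = {}
        for rep in range(config.sim.replicates):
            sample = f"{condition}_rep{rep}"
            sj = read_sj_tab(sim / f"sj_{condition}_rep{rep}.tab", sample=sample)
            counted = count_junction_reads(junctions, sj, sample=sample)
            totals[sample] = max(
                sum(sum(r.counts.values()) for r in sj), 1
            )
            for rec in counted:
                key = (rec.interval.chrom, rec.interval.start, rec.interval.end)
                merged.setdefault(key, {"interval": rec.interval, "counts": {}})[
                    "counts"
                ].update(rec.counts)
        from .io_formats import JunctionCountRecord

        per_condition[condition] = [
            JunctionCountRecord(interval=v["interval"], counts=v["counts"])
            for v in merged.values()
        ]
    summary = detection_summary(per_condition, total_mapped=totals)
    dest = out / "detection.json"
    dest.write_text(json.dumps(summary, indent=1, sort_keys=True))
    _provenance(dest, "junctions", config, n_junctions=len(junctions))


def stage_spi(config: RunConfig) -> None:
    _require(config, "spi")
    out = Path(config.outdir) / "spi"
    out.mkdir(parents=True, exist_ok=True)
    models, _, _, blocks, _ = _load_blocks(config)
    categories = categorize_introns(blocks, models)
    sim = Path(config.outdir) / "sim"
    per_intron: dict[tuple[str, int], dict[str, list]] = {}
    for condition in ("ctrl", "treat"):
        for rep in range(config.sim.replicates):
            reads = _geometry(
                sim / f"nascent_{condition}_rep{rep}.sam", config.min_gap
            )
            for gid, model in models.items():
                for i, intron in enumerate(model.introns):
                    if intron is None:
                        continue
                    rec = compute_spi(
                        intron, reads, min_cov=config.spi_min_cov,
                        condition=condition, replicate=str(rep),
                    )
                    per_intron.setdefault((gid, i), {"ctrl": [], "treat": []})[
                        condition
                    ].append(rec)
    rows = []
    for (gid, i), groups in sorted(per_intron.items()):
        diff = differential_spi(groups["ctrl"], groups["treat"]) if (
            groups["ctrl"] and groups["treat"]
            and not any(r.low_coverage for r in groups["ctrl"] + groups["treat"])
        ) else None
        if diff is None:
            continue
        rows.append(
            (gid, i, categories[(gid, i)], diff.spi_ctrl, diff.spi_treat,
             diff.delta_spi, diff.p_value, int(diff.significant))
        )
    dest = out / "differential_spi.tsv"
    with open(dest, "w") as fh:
        fh.write(
            "gene_id\tintron_index\tcategory\tspi_ctrl\tspi_treat\t"
            "delta_spi\tp_value\tsignificant\n"
        )
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    _provenance(dest, "spi", config, n_introns=len(rows))


def stage_order(config: RunConfig) -> None:
    _require(config, "order")
    out = Path(config.outdir) / "order"
    out.mkdir(parents=True, exist_ok=True)
    models, _, _, blocks, _ = _load_blocks(config)
    sim = Path(config.outdir) / "sim"
    reads = _geometry(sim / "nascent_ctrl_rep0.sam", config.min_gap)
    exon_labels = {}
    for b in blocks:
        exon_labels[(b.gene_id, b.member_indices[0])] = "first_block"
        exon_labels[(b.gene_id, b.member_indices[-1])] = "last_block"
    dest = out / "fupfi.tsv"
    n = 0
    with open(dest, "w") as fh:
        fh.write("gene_id\texon_index\tlabel\tn_up_first\tn_down_first\tf_upfi\n")
        for gid, model in sorted(models.items()):
            for i in range(1, model.n_exons - 1):
                if model.introns[i - 1] is None or model.introns[i] is None:
                    continue
                rec = compute_fupfi(
                    i, reads, model,
                    min_informative=config.fupfi_min_informative,
                )
                label = exon_labels.get((gid, i), "other")
                fh.write(
                    f"{gid}\t{i}\t{label}\t{rec.n_up_first}\t"
                    f"{rec.n_down_first}\t"
                    f"{'NA' if rec.f_upfi is None else f'{rec.f_upfi:.4f}'}\n"
                )
                n += 1
    _provenance(dest, "order", config, n_exons=n)


def stage_sites(config: RunConfig) -> None:
    _require(config, "sites")
    out = Path(config.outdir) / "sites"
    out.mkdir(parents=True, exist_ok=True)
    models, records, significant, blocks, singles = _load_blocks(config)
    import pyfaidx

    genome = pyfaidx.Fasta(str(Path(config.outdir) / "sim" / "genome.fa"))
    donor_seqs, acceptor_seqs = [], []
    per_exon: dict[tuple[str, int], dict[str, str]] = {}
    for gid, model in models.items():
        for i, seq in extract_site_sequences(model, genome, "donor"):
            donor_seqs.append(seq)
            per_exon.setdefault((gid, i), {})["donor"] = seq
        for i, seq in extract_site_sequences(model, genome, "acceptor"):
            acceptor_seqs.append(seq)
            per_exon.setdefault((gid, i), {})["acceptor"] = seq
    splice_model = train_pwm_model(donor_seqs, acceptor_seqs)
    blocks_by_gene: dict[str, list] = {}
    for b in blocks:
        blocks_by_gene.setdefault(b.gene_id, []).append(b)
    category_values: dict[str, dict[str, list[float]]] = {
        "donor": {}, "acceptor": {},
    }
    dest = out / "site_scores.tsv"
    with open(dest, "w") as fh:
        fh.write("gene_id\texon_index\tcategory\tside\tsequence\tscore\n")
        for gid, model in sorted(models.items()):
            labels = categorize_exons(
                blocks_by_gene.get(gid, []),
                [r for r in significant if r.gene_id == gid],
                model,
            )
            for (g, i), sides in sorted(per_exon.items()):
                if g != gid:
                    continue
                cat = labels[i].value
                for side, seq in sides.items():
                    score = score_site(seq, side, splice_model)
                    if score is None:
                        continue
                    category_values[side].setdefault(cat, []).append(score)
                    fh.write(f"{g}\t{i}\t{cat}\t{side}\t{seq}\t{score:.4f}\n")
    comparison = {
        side: compare_categories(vals)
        for side, vals in category_values.items()
        if "non_regulated" in vals
    }
    (out / "category_comparison.json").write_text(
        json.dumps(comparison, indent=1, sort_keys=True)
    )
    _provenance(dest, "sites", config, n_exons=len(per_exon))


def stage_stats(config: RunConfig) -> None:
    _require(config, "stats")
    out = Path(config.outdir) / "stats"
    out.mkdir(parents=True, exist_ok=True)
    models, records, significant, blocks, singles = _load_blocks(config)
    pairs = [
        p
        for gid, model in sorted(models.items())
        for p in pair_exons(significant, model, config.thresholds)
    ]
    result: dict = {}
    if len(pairs) >= 2:
        try:
            result["paired_dpsi_r"] = paired_dpsi_correlation(pairs)
        except ValueError:
            result["paired_dpsi_r"] = None
    pool = [r.delta_psi for r in significant]
    if len(pool) >= 2:
        try:
            result["random_pairing_r"] = random_pairing_control(
                pool, n_pairs=min(10000, 5 * len(pool)), seed=config.seed
            )
        except ValueError:
            result["random_pairing_r"] = None
    perm = permutation_gene_enrichment(
        n_events=len(significant),
        gene_ids=sorted(models),
        observed_multi_gene_count=sum(
            1
            for gid in models
            if sum(1 for r in significant if r.gene_id == gid) >= 2
        ),
        n_perm=1000,
        seed=config.seed,
    )
    result["permutation_p"] = perm.p_value
    result["observed_multi_event_genes"] = perm.observed_multi_gene_count
    dest = out / "stats.json"
    dest.write_text(json.dumps(result, indent=1, sort_keys=True))
    _provenance(dest, "stats", config, n_pairs=len(pairs))


_STAGE_FN = {
    "simulate": stage_simulate,
    "call-blocks": stage_call_blocks,
    "scan-longreads": stage_scan_longreads,
    "junctions": stage_junctions,
    "spi": stage_spi,
    "order": stage_order,
    "sites": stage_sites,
    "stats": stage_stats,
}


def run_stage(name: str, config: RunConfig) -> None:
    """Run one stage (or 'all' for the whole chain) against a run directory."""
    if name == "all":
        for stage in STAGES:
            _STAGE_FN[stage](config)
        return
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES + ['all']}")
    _STAGE_FN[name](config)
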