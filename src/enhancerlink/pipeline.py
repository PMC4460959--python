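"""End-to-end orchestration: select -> diff -> link -> cluster -> scan -> enrich -> tf-rank.

Each cohort (cancer type) is processed independently. All outputs are
TSVs with commented headers carrying the package version, the seed,
and a hash of the configuration, so identical inputs + config
reproduce byte-identical outputs. Stage failures abort with a
stage-named error; outputs of completed stages are retained under a
``failed/`` directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io as elio
from .config import PipelineConfig
from .diffmeth import call_diff_probes
from .motifs import motif_enrichment, scan_windows
from .pairing import cluster_probes, find_pairs
from .probes import DEFAULT_ENHANCER_STATES, ProbeUniverse, build_universe
from .tf import motif_profile, rank_tfs, resolve_family

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineInputs:
    """File paths for one cohort. Motif-stage inputs are optional: when
    genome or motifs are missing the pipeline stops cleanly after pairing."""

    manifest: str
    genes: str
    beta: str
    expr: str
    sheet: str
    enhancer_beds: list = field(default_factory=list)
    states: tuple = DEFAULT_ENHANCER_STATES
    erna_beds: list = field(default_factory=list)
    genome: str | None = None
    motifs: str | None = None
    tf_list: str | None = None
    family_map: str | None = None


@dataclass
class PipelineResult:
    universe: ProbeUniverse
    sample_ids: list
    diff_calls: dict      # direction -> DataFrame
    pairs: dict           # direction -> DataFrame
    clusters: dict        # direction -> list[EnhancerCluster]
    hits: pd.DataFrame | None
    enrichment: dict      # direction -> DataFrame
    tf_assocs: dict       # direction -> DataFrame
    tf_report: dict       # direction -> per-motif report
    manifest: dict


def read_family_map(path) -> dict[str, set]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.motif_id, set()).add(row.gene_id)
    return out


def _header_lines(cfg: PipelineConfig) -> list[str]:
    return [
        f"# enhancerlink {__version__}",
        f"# seed={cfg.seed}",
        f"# config_hash={cfg.hash()}",
    ]


def write_table(df: pd.DataFrame, path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(cfg):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(
    cfg: PipelineConfig,
    inputs: PipelineInputs,
    direction: str = "hypo",
    outdir=None,
) -> PipelineResult:
    """Run the whole workflow for one cohort; see module docstring."""
    directions = ["hypo", "hyper"] if direction == "both" else [direction]
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, df: pd.DataFrame) -> None:
        if outdir is not None:
            path = outdir / name
            write_table(df, path, cfg)
            written.append(path)

    stage = "select-probes"
    try:
        probes = elio.read_probe_manifest(inputs.manifest)
        genes = elio.read_gene_models(inputs.genes)
        regions = []
        for bed in inputs.enhancer_beds:
            regions.extend(elio.read_state_bed(bed, keep_labels=set(inputs.states)))
        for bed in inputs.erna_beds:
            regions.extend(elio.read_state_bed(bed, keep_labels=None))
        universe = build_universe(probes, genes, regions,
                                  min_tss_dist=cfg.tss_min_dist)
        emit("universe.tsv", pd.DataFrame(
            sorted(universe.classes().items()), columns=["probe_id", "class"]
        ))

        stage = "match-cohort"
        beta = elio.read_matrix(inputs.beta, kind="beta")
        expr = elio.read_matrix(inputs.expr, kind="expression")
        sheet = elio.read_sample_sheet(inputs.sheet)
        sample_ids, beta, expr, sheet = elio.match_cohort(beta, expr, sheet)
        logger.info("matched cohort of %d samples", len(sample_ids))
        enh_ids = sorted(universe.distal_enhancer & set(beta.feature_ids))
        beta_enh = beta.subset_features(enh_ids)

        diff_calls, pairs, clusters = {}, {}, {}
        enrichment, tf_assocs, tf_report = {}, {}, {}
        probe_map = universe.probe_by_id()
        for d in directions:
            stage = f"diff-meth[{d}]"
            calls = call_diff_probes(
                beta_enh, sheet, d,
                fraction=cfg.extreme_fraction, p_adj_max=cfg.padj_max,
                delta_min=cfg.delta_min, pooled_var=cfg.pooled_var,
            )
            diff_calls[d] = calls
            emit(f"diff_calls_{d}.tsv", calls)

            stage = f"link[{d}]"
            pairs[d] = find_pairs(
                calls, universe, beta, expr, genes, sheet,
                fraction=cfg.extreme_fraction, pe_max=cfg.pe_max,
                nperm=cfg.nperm, seed=cfg.seed, perm_scope=cfg.perm_scope,
                n_per_side=cfg.n_adjacent_per_side,
                variability_min_frac=cfg.variability_min_frac,
                variability_beta=cfg.variability_beta,
            )
            emit(f"pairs_{d}.tsv", pairs[d])

            stage = f"cluster[{d}]"
            called_probes = [probe_map[p] for p in calls["probe_id"]]
            clusters[d] = cluster_probes(called_probes, gap=cfg.cluster_gap)
            emit(f"clusters_{d}.tsv", pd.DataFrame(
                [(c.cluster_id, c.chrom, c.span[0], c.span[1],
                  ",".join(c.probe_ids)) for c in clusters[d]],
                columns=["cluster_id", "chrom", "span_lo", "span_hi", "probe_ids"],
            ))

        hits = None
        if inputs.genome is None or inputs.motifs is None:
            logger.warning(
                "genome or motif inputs missing: stopping after pairing "
                "(motif and TF stages skipped)"
            )
        else:
            stage = "scan"
            import pyfaidx

            genome = pyfaidx.Fasta(inputs.genome)
            pwms = elio.read_meme_motifs(inputs.motifs)
            enh_probes = [probe_map[p] for p in enh_ids]
            hits = scan_windows(enh_probes, genome, pwms,
                                window=cfg.scan_window, p_max=cfg.scan_pmax)
            emit("hits.tsv", hits)

            tf_ids = elio.read_id_list(inputs.tf_list) if inputs.tf_list else []
            family_map = (read_family_map(inputs.family_map)
                          if inputs.family_map else {})
            for d in directions:
                stage = f"enrich[{d}]"
                paired_ids = sorted(set(pairs[d]["probe_id"]))
                enrichment[d] = motif_enrichment(
                    paired_ids, enh_ids, hits,
                    or_floor=cfg.or_floor, min_occurrences=cfg.min_occurrences,
                    z=cfg.ci_z,
                )
                emit(f"enrichment_{d}.tsv", enrichment[d])

                stage = f"tf-rank[{d}]"
                assoc_frames = []
                report = {}
                if tf_ids:
                    enriched = enrichment[d][enrichment[d]["enriched"]]
                    for motif_id in enriched["motif_id"]:
                        profile = motif_profile(motif_id, hits, paired_ids, beta)
                        assoc_frames.append(rank_tfs(
                            profile, expr, tf_ids,
                            fraction=cfg.extreme_fraction, top=cfg.tf_top,
                        ))
                    if assoc_frames:
                        tf_assocs[d] = pd.concat(assoc_frames, ignore_index=True)
                        report = resolve_family(tf_assocs[d], family_map)
                tf_assocs.setdefault(d, pd.DataFrame(
                    columns=["motif_id", "tf_gene_id", "p_r", "neg_log10_p",
                             "rank", "in_top"]))
                tf_report[d] = report
                emit(f"tf_ranks_{d}.tsv", tf_assocs[d])
                if outdir is not None:
                    with open(outdir / f"tf_report_{d}.json", "w") as fh:
                        json.dump(report, fh, indent=2, default=str)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.hash(),
            "directions": directions,
            "n_samples": len(sample_ids),
            "n_enhancer_probes": len(enh_ids),
            "stages_completed": "full" if hits is not None else "through-pairing",
        }
        if outdir is not None:
            with open(outdir / "run_manifest.json", "w") as fh:
                json.dump(manifest, fh, indent=2)
    except Exception as exc:
        if outdir is not None and written:
            faildir = outdir / "failed"
            faildir.mkdir(exist_ok=True)
            for path in written:
                path.rename(faildir / path.name)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    return PipelineResult(
        universe=universe, sample_ids=sample_ids, diff_calls=diff_calls,
        pairs=pairs, clusters=clusters, hits=hits, enrichment=enrichment,
        tf_assocs=tf_assocs, tf_report=tf_report, manifest=manifest,
    )


def compare_cohorts(pair_files: dict[str, str]) -> pd.DataFrame:
    """Tabulate probe-gene pairs, probes and genes shared across cohorts.

    ``pair_files`` maps cohort code -> pairs TSV path. Returns a long
    table (entity_type, entity, n_cohorts, cohorts).
    """
    rows = []
    per_cohort = {}
    for cohort, path in pair_files.items():
        df = pd.read_csv(path, sep="\t", comment="#")
        per_cohort[cohort] = df
    for kind, key in (("pair", None), ("probe", "probe_id"), ("gene", "gene_id")):
        seen: dict[str, set] = {}
        for cohort, df in per_cohort.items():
            if kind == "pair":
                items = set(df["probe_id"] + "|" + df["gene_id"])
            else:
                items = set(df[key])
            for item in items:
                seen.setdefault(item, set()).add(cohort)
        for item, cohorts in sorted(seen.items()):
            rows.append((kind, item, len(cohorts), ",".join(sorted(cohorts))))
    return pd.DataFrame(rows, columns=["entity_type", "entity", "n_cohorts", "cohorts"])
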