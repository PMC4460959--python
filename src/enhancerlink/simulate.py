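"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a tumor/normal methylation-expression cohort in
which a molecular subtype of the tumors carries the planted events:

* driver probes are highly methylated in normals (Beta-distributed
  around ``normal_beta_mean``) and shifted down by ``delta_planted``
  in subtype tumors only;
* each driver probe's planted target gene (at a configurable
  candidate rank, default 3 — deliberately not the nearest gene) has
  expression ``baseline + link_effect * (1 - beta) + noise``;
* a consensus motif is embedded in driver-probe windows at a high
  rate and elsewhere at a low background rate;
* a driver TF's expression anti-correlates with the mean driver-probe
  methylation, among independent decoy TFs.

Geometry: probes sit every ``probe_spacing`` bp (far above twice the
scan window, so motif windows never overlap) on synthetic chromosomes
of ``probes_per_chrom`` probes; gene TSSs sit asymmetrically between
consecutive probes so every probe is distal (>2 kb from all TSSs) and
candidate ranks are well defined. TF genes live on a probe-free
contig so they can never be linking candidates themselves.

Everything is reproducible bit-for-bit from ``cfg.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as elio
from .pairing import adjacent_genes
from .probes import ProbeUniverse, build_universe
from .types import (
    PWM,
    BetaMatrix,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Probe,
    SampleSheet,
)

PLANTED_MOTIF_CONSENSUS = "TGACGTCATG"
DECOY_MOTIF_CONSENSUSES = {"MOTIF_DECOY1": "CATTGTTCAC", "MOTIF_DECOY2": "GGGACCTTAG"}
PLANTED_MOTIF_ID = "MOTIF_PLANTED"
DRIVER_TF = "TF_DRIVER"

_COMP = str.maketrans("ACGT", "TGCA")


class ConfigError(ValueError):
    """Simulation configuration is infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_tumor: int = 100
    n_normal: int = 20
    subtype_fraction: float = 0.4
    n_probes: int = 2000
    n_driver_probes: int = 50
    delta_planted: float = 0.45
    link_effect: float = 20.0
    noise_sd: float = 2.0
    motif_embed_rate: float = 0.9
    background_rate: float = 0.05
    n_decoy_tfs: int = 200
    tf_effect: float = 20.0
    tf_noise_sd: float = 2.0
    # geometry / nuisance parameters
    normal_beta_mean: float = 0.8
    beta_concentration: float = 50.0
    probe_spacing: int = 6000
    probes_per_chrom: int = 1000
    enhancer_every: int = 4
    driver_stride: int = 40
    window: int = 100
    target_rank: int = 3
    cohort_code: str = "SYN"

    def __post_init__(self) -> None:
        if not (0 < self.subtype_fraction <= 1):
            raise ConfigError("subtype_fraction must be in (0, 1]")
        if self.n_driver_probes > self.n_probes:
            raise ConfigError("n_driver_probes cannot exceed n_probes")
        if self.probe_spacing < 2 * self.window:
            raise ConfigError("probe_spacing must be at least twice the scan window")
        if self.n_driver_probes * self.driver_stride > self.n_probes:
            raise ConfigError(
                "driver probes at the configured stride do not fit: need "
                f"{self.n_driver_probes * self.driver_stride} slots, have {self.n_probes}"
            )
        if not (0 <= self.delta_planted <= self.normal_beta_mean):
            raise ConfigError("delta_planted must be within [0, normal_beta_mean]")


@dataclass
class TruthTable:
    """Ground truth of planted events, consistent with the emitted matrices."""

    hypo_probes: set = field(default_factory=set)
    hyper_probes: set = field(default_factory=set)
    links: list = field(default_factory=list)  # (probe_id, gene_id)
    motif_id: str | None = None
    driver_tf: str | None = None
    family: set = field(default_factory=set)
    subtype_samples: set = field(default_factory=set)


@dataclass
class SyntheticCohort:
    cfg: SimConfig
    probes: list
    genes: list
    enhancer_regions: list
    genome: dict
    beta: BetaMatrix
    expr: ExpressionMatrix
    sheet: SampleSheet
    pwms: list
    tf_ids: list
    family_map: dict
    truth: TruthTable
    universe: ProbeUniverse

    def write(self, outdir) -> dict:
        """Write all standard-format files plus truth tables; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "manifest": outdir / "probes.tsv",
            "states_bed": outdir / "enhancer_states.bed",
            "genome": outdir / "genome.fa",
            "beta": outdir / "beta.tsv",
            "expr": outdir / "expression.tsv",
            "sheet": outdir / "samples.tsv",
            "genes": outdir / "genes.tsv",
            "motifs": outdir / "motifs.meme",
            "tf_list": outdir / "tf_list.txt",
            "family_map": outdir / "family_map.tsv",
            "truth_probes": outdir / "truth_probes.tsv",
            "truth_links": outdir / "truth_links.tsv",
            "truth_tfs": outdir / "truth_tfs.tsv",
        }
        elio.write_probe_manifest(self.probes, paths["manifest"])
        elio.write_bed(self.enhancer_regions, paths["states_bed"])
        elio.write_fasta(self.genome, paths["genome"])
        elio.write_matrix(self.beta, paths["beta"])
        elio.write_matrix(self.expr, paths["expr"])
        elio.write_sample_sheet(self.sheet, paths["sheet"])
        elio.write_gene_models(self.genes, paths["genes"])
        elio.write_meme_motifs(self.pwms, paths["motifs"])
        elio.write_id_list(self.tf_ids, paths["tf_list"])
        with open(paths["family_map"], "w") as fh:
            fh.write("motif_id\tgene_id\n")
            for motif_id, members in sorted(self.family_map.items()):
                for g in sorted(members):
                    fh.write(f"{motif_id}\t{g}\n")
        with open(paths["truth_probes"], "w") as fh:
            fh.write("probe_id\tdirection\n")
            for pid in sorted(self.truth.hypo_probes):
                fh.write(f"{pid}\thypo\n")
            for pid in sorted(self.truth.hyper_probes):
                fh.write(f"{pid}\thyper\n")
        with open(paths["truth_links"], "w") as fh:
            fh.write("probe_id\tgene_id\n")
            for pid, gid in sorted(self.truth.links):
                fh.write(f"{pid}\t{gid}\n")
        with open(paths["truth_tfs"], "w") as fh:
            fh.write("role\tid\n")
            if self.truth.motif_id:
                fh.write(f"motif\t{self.truth.motif_id}\n")
            if self.truth.driver_tf:
                fh.write(f"driver_tf\t{self.truth.driver_tf}\n")
            for s in sorted(self.truth.subtype_samples):
                fh.write(f"subtype_sample\t{s}\n")
        return paths


def _consensus_pwm(motif_id: str, consensus: str, strength: float = 0.97,
                   nsites: int = 100) -> PWM:
    probs = np.full((len(consensus), 4), (1 - strength) / 3)
    for i, base in enumerate(consensus):
        probs[i, "ACGT".index(base)] = strength
    return PWM(motif_id=motif_id, probs=probs, nsites=nsites)


def generate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate the full cohort bundle for ``cfg`` (see module docstring)."""
    rng = np.random.default_rng(cfg.seed)

    # --- samples -----------------------------------------------------------
    tumors = [f"T{i:03d}" for i in range(1, cfg.n_tumor + 1)]
    normals = [f"N{i:03d}" for i in range(1, cfg.n_normal + 1)]
    n_subtype = int(round(cfg.subtype_fraction * cfg.n_tumor))
    subtype = set(rng.choice(tumors, size=n_subtype, replace=False))
    planted_active = cfg.delta_planted > 0 or cfg.link_effect > 0 or cfg.tf_effect > 0
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": tumors + normals,
        "group": ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal,
        "cohort": cfg.cohort_code,
        "subtype": [
            ("planted" if s in subtype else "other") if planted_active else ""
            for s in tumors
        ] + [""] * cfg.n_normal,
    }))
    samples = tumors + normals
    n_samples = len(samples)

    # --- probe / gene geometry --------------------------------------------
    n_chroms = int(np.ceil(cfg.n_probes / cfg.probes_per_chrom))
    margin = 5000
    probes, genes, regions = [], [], []
    states = ("EnhA1", "EnhA2", "EnhG1", "EnhG2")
    chrom_len = margin + cfg.probes_per_chrom * cfg.probe_spacing + margin
    enhancer_local = []  # parallel flags
    for i in range(cfg.n_probes):
        c, j = divmod(i, cfg.probes_per_chrom)
        chrom = f"chr{c + 1}"
        pos = margin + j * cfg.probe_spacing  # 1-based CpG coordinate
        probes.append(Probe(id=f"cg{i:05d}", chrom=chrom, pos=pos))
        is_enh = (j % cfg.enhancer_every) == 0
        enhancer_local.append(is_enh)
        if is_enh:
            regions.append(GenomicInterval(chrom, pos - 1 - 50, pos - 1 + 50,
                                           states[i % 4]))
        # one gene TSS in each inter-probe gap, asymmetric so ranks are unique
        genes.append(GeneModel(f"G{i:05d}", chrom, "+" if i % 2 == 0 else "-",
                               pos + 2600))

    # driver probes: enhancer probes spaced driver_stride slots apart so one
    # driver's target gene never enters another driver's candidate window
    driver_idx = []
    k = 0
    j0 = cfg.driver_stride // 2
    while len(driver_idx) < cfg.n_driver_probes:
        idx = j0 + k * cfg.driver_stride
        if idx >= cfg.n_probes:
            raise ConfigError("cannot place all driver probes; reduce stride or count")
        local = idx % cfg.probes_per_chrom
        if (local % cfg.enhancer_every) == 0 and 0 < local < cfg.probes_per_chrom - 1:
            driver_idx.append(idx)
        k += 1
    driver_ids = [probes[i].id for i in driver_idx]

    # TF gene contig (no probes -> never a linking candidate)
    tf_ids = [DRIVER_TF] + [f"TF{i:03d}" for i in range(1, cfg.n_decoy_tfs + 1)]
    for t, tf in enumerate(tf_ids):
        genes.append(GeneModel(tf, "chrTF", "+", 10_000 + t * 10_000))

    # --- beta values -------------------------------------------------------
    base_mean = rng.uniform(0.1, 0.9, size=cfg.n_probes)
    base_mean[driver_idx] = cfg.normal_beta_mean
    mean = np.tile(base_mean[:, None], (1, n_samples))
    subtype_cols = np.array([s in subtype for s in samples])
    if cfg.delta_planted > 0:
        mean[np.ix_(driver_idx, np.flatnonzero(subtype_cols))] -= cfg.delta_planted
    mean = np.clip(mean, 0.02, 0.98)
    kappa = cfg.beta_concentration
    beta_vals = rng.beta(mean * kappa, (1 - mean) * kappa)
    beta = BetaMatrix(pd.DataFrame(beta_vals, index=[p.id for p in probes],
                                   columns=samples))

    # --- planted probe-gene links -----------------------------------------
    probe_by_id = {p.id: p for p in probes}
    links = []
    if cfg.link_effect > 0 or cfg.delta_planted > 0:
        for pid in driver_ids:
            cands = adjacent_genes(probe_by_id[pid], genes)
            row = cands[cands["rank"] == cfg.target_rank]
            if len(row) == 0:
                raise ConfigError(f"driver probe {pid} has no rank-{cfg.target_rank} candidate")
            links.append((pid, row.iloc[0]["gene_id"]))

    # --- expression --------------------------------------------------------
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.uniform(50, 500, size=len(gene_ids))
    expr_vals = baseline[:, None] + rng.normal(0.0, cfg.noise_sd,
                                               size=(len(gene_ids), n_samples))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    if cfg.link_effect > 0:
        for pid, gid in links:
            b = beta.df.loc[pid].to_numpy()
            expr_vals[gene_pos[gid]] = (
                baseline[gene_pos[gid]]
                + cfg.link_effect * (1 - b)
                + rng.normal(0.0, cfg.noise_sd, size=n_samples)
            )
    # driver TF anti-correlates with mean driver-probe methylation
    driver_profile = beta.df.loc[driver_ids].mean(axis=0).to_numpy()
    if cfg.tf_effect > 0:
        expr_vals[gene_pos[DRIVER_TF]] = (
            10.0
            + cfg.tf_effect * (1 - driver_profile)
            + rng.normal(0.0, cfg.tf_noise_sd, size=n_samples)
        )
    expr_vals = np.clip(expr_vals, 0.0, None)
    expr = ExpressionMatrix(pd.DataFrame(expr_vals, index=gene_ids, columns=samples))

    # --- genome & motif embedding -----------------------------------------
    pwms = [_consensus_pwm(PLANTED_MOTIF_ID, PLANTED_MOTIF_CONSENSUS)]
    for mid, cons in DECOY_MOTIF_CONSENSUSES.items():
        pwms.append(_consensus_pwm(mid, cons))
    genome_codes = {
        f"chr{c + 1}": rng.integers(0, 4, size=chrom_len, dtype=np.int8)
        for c in range(n_chroms)
    }
    genome_codes["chrTF"] = rng.integers(
        0, 4, size=10_000 + (len(tf_ids) + 1) * 10_000, dtype=np.int8
    )
    cons_codes = np.array(["ACGT".index(b) for b in PLANTED_MOTIF_CONSENSUS],
                          dtype=np.int8)
    rc_codes = (3 - cons_codes)[::-1]
    driver_set = set(driver_idx)
    width = len(cons_codes)
    for i, probe in enumerate(probes):
        rate = cfg.motif_embed_rate if i in driver_set else cfg.background_rate
        if rng.random() >= rate:
            continue
        lo = probe.pos - 1 - cfg.window
        span = 2 * cfg.window + 1 - width
        off = lo + int(rng.integers(0, span))
        ins = cons_codes if rng.random() < 0.5 else rc_codes
        genome_codes[probe.chrom][off : off + width] = ins
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {c: bytes(lut[v]).decode("ascii") for c, v in genome_codes.items()}

    universe = build_universe(probes, genes, regions)
    driver_truth = set(driver_ids) if cfg.delta_planted > 0 else set()
    truth = TruthTable(
        hypo_probes=driver_truth,
        hyper_probes=set(),
        links=links if cfg.link_effect > 0 else [],
        motif_id=PLANTED_MOTIF_ID if cfg.motif_embed_rate > cfg.background_rate else None,
        driver_tf=DRIVER_TF if cfg.tf_effect > 0 else None,
        family={DRIVER_TF, "TF001", "TF002", "TF003"} if cfg.tf_effect > 0 else set(),
        subtype_samples=subtype if planted_active else set(),
    )
    family_map = {PLANTED_MOTIF_ID: {DRIVER_TF, "TF001", "TF002", "TF003"}}
    return SyntheticCohort(
        cfg=cfg, probes=probes, genes=genes, enhancer_regions=regions,
        genome=genome, beta=beta, expr=expr, sheet=sheet, pwms=pwms,
        tf_ids=tf_ids, family_map=family_map, truth=truth, universe=universe,
    )


def generate_null_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Same bundle with every planted effect zeroed (type-I error surface)."""
    null_cfg = replace(
        cfg,
        delta_planted=0.0,
        link_effect=0.0,
        tf_effect=0.0,
        motif_embed_rate=cfg.background_rate,
    )
    return generate_cohort(null_cfg)


def config_to_yaml(cfg: SimConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def config_from_yaml(path) -> SimConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig(**data)
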