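"""Link differentially methylated probes to target genes.

For each called probe, the 10 nearest genes on each side are candidate
targets. Samples are split into the M group (20% highest methylation at
the probe) and U group (20% lowest); a one-sided Mann-Whitney U test
asks whether expression in M is lower than in U (anti-correlation,
i.e. the probe behaves like an active enhancer of the gene). The raw
p-value is calibrated against a permutation null built from random
distal non-enhancer probes paired with the same gene, giving an
empirical p-value

    p_e = (num(P_p <= P_r) + 1) / (nperm + 1)

Pairs with p_e below threshold (default 0.001) are reported. The module
also provides probe clustering into enhancer regions, distance/rank
characterization against randomized pair sets, and loop-overlap
enrichment against chromatin-interaction anchor pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .probes import ProbeUniverse
from .types import BetaMatrix, ExpressionMatrix, GeneModel, Probe, SampleSheet

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["probe_id", "gene_id", "distance", "gene_rank", "p_r", "p_e"]


# ---------------------------------------------------------------------------
# candidate genes
# ---------------------------------------------------------------------------

def adjacent_genes(probe: Probe, genes: list[GeneModel], n_per_side: int = 10) -> pd.DataFrame:
    """Up to ``n_per_side`` nearest TSSs on each side of the probe.

    Signed distance = tss - probe position (negative = upstream of the
    probe). Ranks 1..m order candidates by absolute distance, ties
    broken by gene id. Returns an empty frame (with a warning) when the
    probe's chromosome has no annotated genes.
    """
    same = [g for g in genes if g.chrom == probe.chrom]
    if not same:
        logger.warning("probe %s: chromosome %s absent from gene annotation",
                       probe.id, probe.chrom)
        return pd.DataFrame(columns=["probe_id", "gene_id", "distance", "rank", "side"])
    rows = []
    for g in same:
        dist = g.tss - probe.pos
        side = "upstream" if dist < 0 else "downstream"
        rows.append((g.gene_id, dist, side))
    df = pd.DataFrame(rows, columns=["gene_id", "distance", "side"])
    df["absdist"] = df["distance"].abs()
    kept = (
        df.sort_values(["absdist", "gene_id"], kind="stable")
        .groupby("side", group_keys=False)
        .head(n_per_side)
        .sort_values(["absdist", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )
    kept["rank"] = np.arange(1, len(kept) + 1)
    kept["probe_id"] = probe.id
    return kept[["probe_id", "gene_id", "distance", "rank", "side"]]


def variability_filter(
    probe_betas,
    min_frac: float = 0.05,
    beta_thresh: float = 0.3,
    direction: str = "hypo",
) -> bool:
    """Require headroom for a methylation change before testing a probe.

    hypo: at least ``min_frac`` of samples must have beta above
    ``beta_thresh`` (there is methylation to lose); hyper uses the
    mirrored rule (beta below the threshold — room to gain). Boundary
    inclusive; missing betas excluded from the denominator.
    """
    vals = np.asarray(probe_betas, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all betas missing")
    if direction == "hypo":
        prop = float((vals > beta_thresh).mean())
    elif direction == "hyper":
        prop = float((vals < beta_thresh).mean())
    else:
        raise ValueError(f"direction must be hypo|hyper, got {direction!r}")
    return prop >= min_frac


# ---------------------------------------------------------------------------
# Mann-Whitney machinery
# ---------------------------------------------------------------------------

def pair_utest(probe_betas, gene_expr, fraction: float = 0.2, sample_ids=None) -> float:
    """One-sided Mann-Whitney p for expression(M) < expression(U).

    M/U are the highest/lowest-beta ``fraction`` of samples at the
    probe (ties broken by sample id). Samples with missing expression
    are dropped from the groups. Exact enumeration when the combined
    group size is <= 12 with no ties; otherwise normal approximation
    with midranks, tie correction, and continuity correction.
    """
    from .diffmeth import extreme_indices

    probe_betas = np.asarray(probe_betas, dtype=float)
    gene_expr = np.asarray(gene_expr, dtype=float)
    m_idx = extreme_indices(probe_betas, fraction, "high", ids=sample_ids)
    u_idx = extreme_indices(probe_betas, fraction, "low", ids=sample_ids)
    x_m = gene_expr[m_idx]
    x_u = gene_expr[u_idx]
    x_m = x_m[~np.isnan(x_m)]
    x_u = x_u[~np.isnan(x_u)]
    if len(x_m) < 2 or len(x_u) < 2:
        raise ValueError(
            f"degenerate M/U groups ({len(x_m)}, {len(x_u)} non-missing samples)"
        )
    combined = np.concatenate([x_m, x_u])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x_m, x_u, alternative="less", method=method)
    return float(res.pvalue)


def _batch_mwu_less(x_m: np.ndarray, x_u: np.ndarray) -> np.ndarray:
    """Vectorized one-sided (M < U) Mann-Whitney over rows.

    ``x_m`` has shape (R, kM), ``x_u`` (R, kU). Normal approximation
    with midranks, tie correction and continuity correction — the same
    conventions as the scalar asymptotic path, checked against scipy in
    the test suite. Rows where every value ties give p = 1.
    """
    r, k_m = x_m.shape
    k_u = x_u.shape[1]
    n = k_m + k_u
    combined = np.concatenate([x_m, x_u], axis=1)
    ranks = stats.rankdata(combined, axis=1)
    u_m = ranks[:, :k_m].sum(axis=1) - k_m * (k_m + 1) / 2.0
    mean = k_m * k_u / 2.0

    # per-row tie term sum(t^3 - t) via run lengths of the sorted rows
    s = np.sort(combined, axis=1)
    starts = np.ones_like(s, dtype=bool)
    starts[:, 1:] = s[:, 1:] != s[:, :-1]
    flat = starts.ravel()
    run_id = np.cumsum(flat) - 1
    counts = np.bincount(run_id)
    start_pos = np.flatnonzero(flat)
    row_of_run = start_pos // n
    tie_term = np.bincount(row_of_run, weights=counts.astype(float) ** 3 - counts,
                           minlength=r)

    var = k_m * k_u / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u_m - mean + 0.5) / sd
    p = stats.norm.cdf(z)
    p[sd == 0] = 1.0
    return p


class PermutationEngine:
    """Precomputed M/U sample groupings for a pool of null probes.

    The pool is the distal non-enhancer probe set; each pool probe's
    extreme-methylation sample groups depend only on that probe, so
    they are computed once per cohort and reused across all pairs.
    """

    def __init__(self, pool_beta: pd.DataFrame, fraction: float = 0.2):
        from .diffmeth import extreme_indices

        if pool_beta.shape[0] == 0:
            raise ValueError("empty permutation pool")
        self.pool_ids = list(pool_beta.index)
        self.fraction = fraction
        sample_ids = list(pool_beta.columns)
        vals = pool_beta.to_numpy()
        if np.isnan(vals).any():
            # generic (slower) path: per-row index lists of ragged length
            self._m_idx = [
                np.asarray(extreme_indices(row, fraction, "high", ids=sample_ids))
                for row in vals
            ]
            self._u_idx = [
                np.asarray(extreme_indices(row, fraction, "low", ids=sample_ids))
                for row in vals
            ]
            self._ragged = True
        else:
            k = max(1, int(math.floor(fraction * vals.shape[1])))
            # lexicographic sample-id tie-break, matching extreme_indices
            id_order = np.argsort(np.asarray(sample_ids, dtype=object), kind="stable")
            reordered = vals[:, id_order]
            order_asc = np.argsort(reordered, axis=1, kind="stable")
            order_desc = np.argsort(-reordered, axis=1, kind="stable")
            self._u_idx = id_order[order_asc[:, :k]]
            self._m_idx = id_order[order_desc[:, :k]]
            self._ragged = False

    def sample_rows(self, nperm: int, rng: np.random.Generator) -> np.ndarray:
        n = len(self.pool_ids)
        if n >= nperm:
            return rng.choice(n, size=nperm, replace=False)
        logger.warning(
            "permutation pool (%d) smaller than nperm (%d): sampling with replacement",
            n, nperm,
        )
        return rng.choice(n, size=nperm, replace=True)

    def null_pvalues(self, gene_expr: np.ndarray, rows: np.ndarray) -> np.ndarray:
        gene_expr = np.asarray(gene_expr, dtype=float)
        if self._ragged or np.isnan(gene_expr).any():
            out = np.empty(len(rows))
            for i, row in enumerate(rows):
                x_m = gene_expr[self._m_idx[row]]
                x_u = gene_expr[self._u_idx[row]]
                x_m, x_u = x_m[~np.isnan(x_m)], x_u[~np.isnan(x_u)]
                out[i] = _batch_mwu_less(x_m[None, :], x_u[None, :])[0]
            return out
        return _batch_mwu_less(gene_expr[self._m_idx[rows]], gene_expr[self._u_idx[rows]])


def empirical_pvalue(
    p_r: float,
    gene_expr,
    engine: PermutationEngine,
    nperm: int = 10000,
    rng: np.random.Generator | None = None,
    rows: np.ndarray | None = None,
) -> float:
    """Empirical p from the permutation null: (num(P_p <= P_r) + 1) / (nperm + 1).

    ``rows`` allows reusing one drawn permutation set across the genes
    of a probe; by default a fresh set is drawn per call.
    """
    if rows is None:
        if rng is None:
            raise ValueError("need rng when permutation rows are not supplied")
        rows = engine.sample_rows(nperm, rng)
    p_p = engine.null_pvalues(gene_expr, rows)
    count = int((p_p <= p_r).sum())
    return (count + 1) / (len(rows) + 1)


# ---------------------------------------------------------------------------
# the linking driver
# ---------------------------------------------------------------------------

def find_pairs(
    diff_calls: pd.DataFrame,
    universe: ProbeUniverse,
    beta: BetaMatrix,
    expr: ExpressionMatrix,
    genes: list[GeneModel],
    sheet: SampleSheet,
    fraction: float = 0.2,
    pe_max: float = 0.001,
    nperm: int = 10000,
    seed: int | None = None,
    perm_scope: str = "pair",
    n_per_side: int = 10,
    variability_min_frac: float = 0.05,
    variability_beta: float = 0.3,
    return_all: bool = False,
) -> pd.DataFrame:
    """Probe-gene pairs with empirical p below ``pe_max``.

    ``beta`` and ``expr`` must already be sample-matched (identical
    column sets and order). Each called probe first passes the
    variability filter for its direction, then each of its candidate
    genes is tested; permutation probes come from the distal
    non-enhancer pool. ``perm_scope`` is "pair" (fresh permutation set
    per pair, the default) or "probe" (the genes of one probe share a
    set). Output is sorted by (probe_id, p_e, gene_id).
    """
    if list(beta.sample_ids) != list(expr.sample_ids):
        raise ValueError("beta and expr are not sample-matched; run match_cohort first")
    if perm_scope not in ("pair", "probe"):
        raise ValueError(f"perm_scope must be pair|probe, got {perm_scope!r}")
    sample_ids = beta.sample_ids
    rng = np.random.default_rng(seed)
    pool_ids = sorted(universe.distal_nonenhancer & set(beta.feature_ids))
    if not pool_ids:
        raise ValueError("no distal non-enhancer probes available as permutation pool")
    engine = PermutationEngine(beta.df.loc[pool_ids], fraction=fraction)
    probe_map = universe.probe_by_id()
    expr_index = set(expr.feature_ids)

    rows_out = []
    for call in diff_calls.itertuples(index=False):
        pid = call.probe_id
        if pid not in probe_map or pid not in beta:
            logger.info("called probe %s missing from manifest or beta matrix", pid)
            continue
        betas_p = beta.row(pid).to_numpy()
        if not variability_filter(betas_p, variability_min_frac, variability_beta,
                                  direction=call.direction):
            continue
        cands = adjacent_genes(probe_map[pid], genes, n_per_side=n_per_side)
        shared_rows = engine.sample_rows(nperm, rng) if perm_scope == "probe" else None
        for cand in cands.itertuples(index=False):
            if cand.gene_id not in expr_index:
                logger.info("candidate gene %s absent from expression matrix", cand.gene_id)
                continue
            e = expr.row(cand.gene_id).to_numpy()
            try:
                p_r = pair_utest(betas_p, e, fraction=fraction, sample_ids=sample_ids)
            except ValueError as exc:
                logger.info("pair %s-%s skipped: %s", pid, cand.gene_id, exc)
                continue
            rows = shared_rows if shared_rows is not None else engine.sample_rows(nperm, rng)
            p_e = empirical_pvalue(p_r, e, engine, nperm=nperm, rows=rows)
            rows_out.append((pid, cand.gene_id, cand.distance, cand.rank, p_r, p_e))

    df = pd.DataFrame(rows_out, columns=PAIR_COLUMNS)
    df = df.sort_values(["probe_id", "p_e", "gene_id"], kind="stable").reset_index(drop=True)
    if return_all:
        return df
    return df[df["p_e"] < pe_max].reset_index(drop=True)


# ---------------------------------------------------------------------------
# clustering & characterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnhancerCluster:
    cluster_id: str
    chrom: str
    probe_ids: tuple
    span: tuple  # (min pos, max pos), 1-based inclusive


def cluster_probes(probes: list[Probe], gap: int = 500) -> list[EnhancerCluster]:
    """Single-linkage chaining of probes within ``gap`` bp on a chromosome.

    Consecutive sorted positions at most ``gap`` apart join one
    cluster; gap=0 yields singletons (at distinct positions).
    """
    by_chrom: dict[str, list[Probe]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    clusters = []
    n = 0
    for chrom in sorted(by_chrom):
        members: list[Probe] = []
        for p in sorted(by_chrom[chrom], key=lambda p: (p.pos, p.id)):
            if members and p.pos - members[-1].pos > gap:
                clusters.append(_mk_cluster(n, chrom, members))
                n += 1
                members = []
            members.append(p)
        if members:
            clusters.append(_mk_cluster(n, chrom, members))
            n += 1
    return clusters


def _mk_cluster(n: int, chrom: str, members: list[Probe]) -> EnhancerCluster:
    return EnhancerCluster(
        cluster_id=f"cluster_{n:05d}",
        chrom=chrom,
        probe_ids=tuple(p.id for p in members),
        span=(members[0].pos, members[-1].pos),
    )


def _candidate_distance_table(
    probe_ids, probe_map, genes, n_per_side=10
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Padded |distance| matrix of candidates per probe, for randomization."""
    dists, counts, kept = [], [], []
    width = 2 * n_per_side
    for pid in probe_ids:
        cands = adjacent_genes(probe_map[pid], genes, n_per_side=n_per_side)
        if len(cands) == 0:
            continue
        d = np.abs(cands["distance"].to_numpy())
        row = np.full(width, np.nan)
        row[: len(d)] = d
        dists.append(row)
        counts.append(len(d))
        kept.append(pid)
    return np.array(dists), np.array(counts), kept


def distance_null_histogram(
    pairs: pd.DataFrame,
    distal_ids: set[str],
    universe: ProbeUniverse,
    genes: list[GeneModel],
    bin_widths=(50_000, 200_000),
    n_bins: int = 10,
    n_datasets: int = 1000,
    n_probes: int = 1000,
    seed: int | None = None,
    n_per_side: int = 10,
) -> dict[int, pd.DataFrame]:
    """Observed probe-gene distance histogram vs a randomized-pair null.

    Each null dataset draws ``n_probes`` random distal probes and pairs
    each with one of its candidate genes, uniformly. Per bin width the
    returned frame has the observed proportion, the null mean and SD,
    and the mean +/- 1.96*SD band over ``n_datasets`` datasets.
    Proportions include a final open-ended bin so they sum to 1.
    """
    if len(pairs) == 0:
        raise ValueError("no pairs to characterize")
    rng = np.random.default_rng(seed)
    probe_map = universe.probe_by_id()
    pool = sorted(pid for pid in distal_ids if pid in probe_map)
    dist_pad, counts, kept = _candidate_distance_table(pool, probe_map, genes, n_per_side)
    if len(kept) == 0:
        raise ValueError("no distal probes with candidate genes")

    obs = np.abs(pairs["distance"].to_numpy(dtype=float))
    out = {}
    for width in bin_widths:
        edges = np.arange(0, (n_bins + 1) * width, width, dtype=float)
        full_edges = np.concatenate([edges, [np.inf]])
        obs_counts, _ = np.histogram(obs, bins=full_edges)
        obs_prop = obs_counts / obs_counts.sum()

        replace = len(kept) < n_probes
        null_props = np.empty((n_datasets, len(full_edges) - 1))
        for d in range(n_datasets):
            pi = rng.choice(len(kept), size=n_probes, replace=replace)
            ci = np.floor(rng.random(n_probes) * counts[pi]).astype(int)
            dd = dist_pad[pi, ci]
            c, _ = np.histogram(dd, bins=full_edges)
            null_props[d] = c / c.sum()
        mean = null_props.mean(axis=0)
        sd = null_props.std(axis=0, ddof=1)
        out[width] = pd.DataFrame({
            "bin_lo": full_edges[:-1],
            "bin_hi": full_edges[1:],
            "observed": obs_prop,
            "null_mean": mean,
            "null_sd": sd,
            "ci_lo": mean - 1.96 * sd,
            "ci_hi": mean + 1.96 * sd,
        })
    return out


def nearest_rank_profile(pairs: pd.DataFrame, n_ranks: int = 20) -> pd.Series:
    """Proportion of one-to-one pairs linking to each gene-distance rank.

    Probes linked to more than one gene, and genes linked by more than
    one probe, are omitted before tabulating.
    """
    probe_counts = pairs["probe_id"].value_counts()
    gene_counts = pairs["gene_id"].value_counts()
    keep = pairs[
        pairs["probe_id"].map(probe_counts).eq(1)
        & pairs["gene_id"].map(gene_counts).eq(1)
    ]
    profile = pd.Series(0.0, index=pd.RangeIndex(1, n_ranks + 1, name="gene_rank"))
    if len(keep) == 0:
        return profile
    counts = keep["gene_rank"].value_counts()
    for rank, c in counts.items():
        if 1 <= rank <= n_ranks:
            profile.loc[rank] = c / len(keep)
    return profile


def _pos_in(iv, chrom: str, pos_1based: int) -> bool:
    return iv.chrom == chrom and iv.contains_pos(pos_1based)


def _pair_hits_loop(loops, p_chrom, p_pos, g_chrom, g_tss) -> bool:
    for a, b in loops:
        if (_pos_in(a, p_chrom, p_pos) and _pos_in(b, g_chrom, g_tss)) or (
            _pos_in(b, p_chrom, p_pos) and _pos_in(a, g_chrom, g_tss)
        ):
            return True
    return False


def loop_overlap_enrichment(
    pairs: pd.DataFrame,
    loops,
    universe: ProbeUniverse,
    genes: list[GeneModel],
    n_random: int = 100,
    seed: int | None = None,
    n_per_side: int = 10,
) -> dict:
    """Overlap of pairs with looped anchor pairs vs link-structure-preserving random sets.

    A pair overlaps a loop when the probe position falls in one anchor
    and the linked gene's TSS in the other (either orientation). Each
    of the ``n_random`` random datasets draws the same number of probes
    from the distal enhancer set and gives each random probe exactly as
    many gene links (among its candidates) as the corresponding true
    probe. Returns observed count, random mean/SD, fold enrichment, and
    the mean +/- 1.96*SD interval.
    """
    rng = np.random.default_rng(seed)
    tss = {g.gene_id: (g.chrom, g.tss) for g in genes}
    probe_map = universe.probe_by_id()

    def count_overlaps(pair_iter) -> int:
        c = 0
        for pid, gid in pair_iter:
            p = probe_map[pid]
            g_chrom, g_tss = tss[gid]
            if _pair_hits_loop(loops, p.chrom, p.pos, g_chrom, g_tss):
                c += 1
        return c

    true_pairs = [(r.probe_id, r.gene_id) for r in pairs.itertuples(index=False)
                  if r.probe_id in probe_map and r.gene_id in tss]
    observed = count_overlaps(true_pairs)
    if not loops:
        return {"observed": 0, "random_mean": math.nan, "random_sd": math.nan,
                "fold": math.nan, "ci": (math.nan, math.nan), "random_counts": [],
                "note": "empty loop set: enrichment not applicable"}

    link_counts = pd.Series([p for p, _ in true_pairs]).value_counts().to_numpy()
    enh_pool = sorted(universe.distal_enhancer)
    # candidate gene lists per enhancer probe, computed once
    cand_genes = {}
    for pid in enh_pool:
        cg = adjacent_genes(probe_map[pid], genes, n_per_side=n_per_side)
        cand_genes[pid] = [g for g in cg["gene_id"] if g in tss]

    random_counts = []
    for _ in range(n_random):
        rand_pairs = []
        for c in link_counts:
            while True:
                pid = enh_pool[rng.integers(len(enh_pool))]
                cg = cand_genes[pid]
                if len(cg) >= c:
                    break
            chosen = rng.choice(len(cg), size=c, replace=False)
            rand_pairs.extend((pid, cg[j]) for j in chosen)
        random_counts.append(count_overlaps(rand_pairs))
    random_counts = np.asarray(random_counts, dtype=float)
    mean = float(random_counts.mean())
    sd = float(random_counts.std(ddof=1)) if n_random > 1 else math.nan
    fold = observed / mean if mean > 0 else math.nan
    return {
        "observed": observed,
        "random_mean": mean,
        "random_sd": sd,
        "fold": fold,
        "ci": (mean - 1.96 * sd, mean + 1.96 * sd),
        "random_counts": random_counts.tolist(),
    }
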