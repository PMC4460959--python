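"""Rank candidate upstream transcription factors per enriched motif.

For each enriched motif, the per-sample average methylation over the
expression-linked (paired) probes carrying the motif summarizes the
activity of that motif's enhancers. Samples are split into the 20%
most (M) and least (U) methylated at that profile, and each TF in a
supplied census is tested for lower expression in M than in U
(one-sided Mann-Whitney). TFs are ranked by -log10(p); the top 5%
are candidate upstream regulators, and the best-ranked member of the
motif's cognate DNA-binding family, when it makes the top set, is
flagged as the putative driver.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .diffmeth import extreme_indices
from .types import BetaMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

TF_COLUMNS = ["motif_id", "tf_gene_id", "p_r", "neg_log10_p", "rank", "in_top"]


def motif_profile(
    motif_id: str,
    hits: pd.DataFrame,
    paired_probe_ids,
    beta: BetaMatrix,
) -> pd.Series:
    """Per-sample mean beta over the paired probes carrying the motif.

    Only paired probes with at least one scan hit for ``motif_id``
    contribute; missing betas are excluded per sample (missing-aware
    mean). Raises when no paired probe carries the motif.
    """
    with_hit = set(hits.loc[hits["motif_id"] == motif_id, "probe_id"])
    used = sorted(with_hit & set(paired_probe_ids) & set(beta.feature_ids))
    if not used:
        raise ValueError(f"motif {motif_id}: no paired probe carries a hit")
    profile = beta.df.loc[used].mean(axis=0, skipna=True)
    profile.name = motif_id
    return profile


def rank_tfs(
    profile: pd.Series,
    expr: ExpressionMatrix,
    tf_ids,
    fraction: float = 0.2,
    top: float = 0.05,
) -> pd.DataFrame:
    """Test every TF for anti-correlation with the motif methylation profile.

    The M/U groups are the ``fraction`` most/least methylated samples
    of the profile; the one-sided U test alternative is
    expression(M) < expression(U). TFs absent from the expression
    matrix are logged and skipped; the top set holds the
    ceil(top * n_tested) best ranks. Ranking is by -log10(p), ties
    broken by gene id.
    """
    from .pairing import _batch_mwu_less

    sample_ids = list(profile.index)
    if list(expr.sample_ids) != sample_ids:
        expr = expr.subset_samples(sample_ids)
    vals = profile.to_numpy(dtype=float)
    m_idx = extreme_indices(vals, fraction, "high", ids=sample_ids)
    u_idx = extreme_indices(vals, fraction, "low", ids=sample_ids)
    if len(m_idx) < 2 or len(u_idx) < 2:
        raise ValueError("degenerate M/U groups for the motif profile")

    tested = [t for t in tf_ids if t in expr]
    missing = [t for t in tf_ids if t not in expr]
    if missing:
        logger.info("%d TFs absent from the expression matrix (e.g. %s)",
                    len(missing), missing[:3])
    if not tested:
        raise ValueError("no TF from the census is present in the expression matrix")

    emat = expr.df.loc[tested].to_numpy()
    if np.isnan(emat).any():
        pvals = []
        for row in emat:
            x_m, x_u = row[m_idx], row[u_idx]
            x_m, x_u = x_m[~np.isnan(x_m)], x_u[~np.isnan(x_u)]
            pvals.append(
                _batch_mwu_less(x_m[None, :], x_u[None, :])[0]
                if len(x_m) >= 2 and len(x_u) >= 2 else 1.0
            )
        pvals = np.asarray(pvals)
    else:
        pvals = _batch_mwu_less(emat[:, m_idx], emat[:, u_idx])

    df = pd.DataFrame({
        "motif_id": profile.name,
        "tf_gene_id": tested,
        "p_r": pvals,
    })
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_r"])
    df = df.sort_values(["neg_log10_p", "tf_gene_id"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    n_top = math.ceil(top * len(df))
    df["in_top"] = df["rank"] <= n_top
    return df


def resolve_family(assocs: pd.DataFrame, family_map: dict[str, set]) -> dict:
    """Per-motif report: top-3 TFs, all family member ranks, flagged driver.

    ``family_map`` maps motif id -> set of TF gene ids in the cognate
    binding family. The best-ranked family member is flagged as the
    putative upstream regulator iff it lands in the motif's top 5%
    set. Motifs absent from the map get an empty family section.
    """
    report = {}
    for motif_id, sub in assocs.groupby("motif_id", sort=True):
        sub = sub.sort_values("rank")
        top3 = sub.head(3)[["tf_gene_id", "rank", "p_r"]].to_dict("records")
        family = sorted(family_map.get(motif_id, set()))
        fam_rows = sub[sub["tf_gene_id"].isin(family)]
        members = fam_rows[["tf_gene_id", "rank", "p_r", "in_top"]].to_dict("records")
        flagged = None
        if len(fam_rows):
            best = fam_rows.iloc[0]
            if bool(best["in_top"]):
                flagged = str(best["tf_gene_id"])
        report[motif_id] = {
            "top3": top3,
            "family_members": members,
            "flagged_regulator": flagged,
        }
    return report
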