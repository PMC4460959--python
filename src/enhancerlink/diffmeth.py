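"""Extreme-quintile differential methylation calls.

For each enhancer probe, the 20% least methylated tumor samples are
compared against the 20% least methylated normal samples (hypo
direction; the hyper direction uses the most methylated 20% on each
side and the opposite tail) with an unpaired one-tailed t-test.
Comparing extremes rather than full groups allows detection of
methylation changes confined to a molecular subtype present in only a
fraction of tumors. Raw p-values are Benjamini-Hochberg adjusted per
cohort and direction, and calls additionally require an absolute mean
beta difference above ``delta_min``.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, CohortError, SampleSheet

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "probe_id", "direction", "mu_tumor", "mu_normal", "delta", "p_raw", "p_adj",
]


def extreme_indices(values, fraction: float, side: str, ids=None) -> list[int]:
    """Indices of the k most extreme non-missing values.

    k = max(1, floor(fraction * n_nonmissing)). ``side`` is "low" for
    the smallest values, "high" for the largest. Ties are broken by the
    lexicographic order of ``ids`` (positional index when absent), so
    the selection is deterministic.
    """
    if side not in ("low", "high"):
        raise ValueError(f"side must be low|high, got {side!r}")
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(len(values))]
    ids = list(map(str, ids))
    nonmissing = [i for i in range(len(values)) if not math.isnan(values[i])]
    if not nonmissing:
        raise ValueError("all values missing")
    k = max(1, int(math.floor(fraction * len(nonmissing))))
    sign = 1.0 if side == "low" else -1.0
    order = sorted(nonmissing, key=lambda i: (sign * values[i], ids[i]))
    return order[:k]


def quintile_ttest(
    tumor_betas,
    normal_betas,
    direction: str,
    fraction: float = 0.2,
    tumor_ids=None,
    normal_ids=None,
    pooled_var: bool = False,
):
    """One-tailed t-test between tumor and normal extreme groups.

    hypo: compares the lowest-beta fractions with alternative
    mu_tumor < mu_normal; hyper: the highest-beta fractions with
    alternative mu_tumor > mu_normal. Welch (unequal variance) by
    default. Returns (p_raw, mu_tumor, mu_normal, delta) with
    delta = mu_normal - mu_tumor. Two identical constant groups give
    p = 0.5 by convention.
    """
    if direction not in ("hypo", "hyper"):
        raise ValueError(f"direction must be hypo|hyper, got {direction!r}")
    side = "low" if direction == "hypo" else "high"
    tumor_betas = np.asarray(tumor_betas, dtype=float)
    normal_betas = np.asarray(normal_betas, dtype=float)
    t_idx = extreme_indices(tumor_betas, fraction, side, ids=tumor_ids)
    n_idx = extreme_indices(normal_betas, fraction, side, ids=normal_ids)
    tq, nq = tumor_betas[t_idx], normal_betas[n_idx]
    if len(tq) < 2 or len(nq) < 2:
        raise ValueError(
            f"extreme groups too small for a t-test ({len(tq)} tumor, {len(nq)} normal)"
        )
    mu_t, mu_n = float(tq.mean()), float(nq.mean())
    delta = mu_n - mu_t
    alternative = "less" if direction == "hypo" else "greater"
    if np.ptp(tq) == 0 and np.ptp(nq) == 0 and mu_t == mu_n:
        return 0.5, mu_t, mu_n, delta
    res = stats.ttest_ind(tq, nq, equal_var=pooled_var, alternative=alternative)
    p = float(res.pvalue)
    if math.isnan(p):  # zero variance in both groups but different means
        p = 0.0 if ((mu_t < mu_n) == (direction == "hypo")) else 1.0
    return p, mu_t, mu_n, delta


def brute_force_bh(p_raw) -> np.ndarray:
    """Step-up BH adjustment from its textbook definition (sort, cummin of n*p/i)."""
    p = np.asarray(p_raw, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def call_diff_probes(
    beta: BetaMatrix,
    sheet: SampleSheet,
    direction: str,
    fraction: float = 0.2,
    p_adj_max: float = 0.01,
    delta_min: float = 0.3,
    pooled_var: bool = False,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call differentially methylated probes for one direction.

    ``beta`` should already be restricted to the enhancer probe set; BH
    runs across exactly the probes tested here. Returns calls passing
    both ``p_adj < p_adj_max`` and ``|delta| > delta_min`` (hypo calls
    have delta > 0, hyper delta < 0), sorted by (p_adj, probe_id).
    With ``return_all`` the full tested table is returned with a
    boolean ``called`` column.
    """
    if direction == "both":
        parts = [
            call_diff_probes(beta, sheet, d, fraction, p_adj_max, delta_min,
                             pooled_var, return_all)
            for d in ("hypo", "hyper")
        ]
        return pd.concat(parts, ignore_index=True)

    tumors = [s for s in sheet.tumors() if s in beta.sample_ids]
    normals = [s for s in sheet.normals() if s in beta.sample_ids]
    if not tumors or not normals:
        raise CohortError(
            f"need both tumor and normal samples ({len(tumors)} tumor, "
            f"{len(normals)} normal found); supply reference normals if the "
            "cohort has none"
        )
    tmat = beta.df[tumors]
    nmat = beta.df[normals]

    rows = []
    for probe_id in beta.feature_ids:
        try:
            p_raw, mu_t, mu_n, delta = quintile_ttest(
                tmat.loc[probe_id].to_numpy(),
                nmat.loc[probe_id].to_numpy(),
                direction,
                fraction=fraction,
                tumor_ids=tumors,
                normal_ids=normals,
                pooled_var=pooled_var,
            )
        except ValueError as exc:
            logger.info("probe %s skipped: %s", probe_id, exc)
            continue
        rows.append((probe_id, direction, mu_t, mu_n, delta, p_raw))
    if not rows:
        return pd.DataFrame(columns=CALL_COLUMNS)
    df = pd.DataFrame(rows, columns=CALL_COLUMNS[:-1])
    df["p_adj"] = multipletests(df["p_raw"].to_numpy(), method="fdr_bh")[1]
    sign_ok = df["delta"] > 0 if direction == "hypo" else df["delta"] < 0
    df["called"] = (
        (df["p_adj"] < p_adj_max) & (df["delta"].abs() > delta_min) & sign_ok
    )
    df = df.sort_values(["p_adj", "probe_id"], kind="stable").reset_index(drop=True)
    if return_all:
        return df
    return df[df["called"]].drop(columns="called").reset_index(drop=True)
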