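"""PWM scanning of probe windows and motif enrichment.

Scanning follows the FIMO convention: a position probability matrix is
converted to a log2-odds matrix against a 0-order background, windows
of +/- ``window`` bp around each probe are scored on both strands, and
a match p-value — the probability of an equal-or-better score for an
i.i.d. background sequence — is computed exactly by dynamic
programming over quantized scores. Positions scoring p < 1e-4 count as
motif occurrences.

Enrichment of a paired-probe set against the full enhancer-probe
background uses a per-probe binarized 2x2 table:

    a/b = paired probes with / without >= 1 occurrence
    c/d = background probes with / without >= 1 occurrence
    OR  = (p/(1-p)) / (P/(1-P)),  p = a/(a+b),  P = c/(c+d)
    SD  = sqrt(1/a + 1/b + 1/c + 1/d)
    lower CI = exp(ln(OR) - z*SD)

A motif is flagged enriched when the lower CI exceeds ``or_floor``
(default 1.1) and it occurs in at least ``min_occurrences`` paired
probes. ``z`` defaults to 1.96 (Wald 95% lower bound); ``z=1.0``
reproduces the alternative convention of subtracting one SD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import PWM, Probe

logger = logging.getLogger(__name__)

HIT_COLUMNS = ["probe_id", "motif_id", "offset", "strand", "score", "p_match"]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

DEFAULT_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_NSITES = 20


def log_odds_matrix(
    pwm: PWM,
    background=DEFAULT_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Log2-odds scoring matrix for a PWM against a 0-order background.

    Probabilities are smoothed with a background-proportional
    pseudocount before the ratio:
    p' = (p * nsites + pseudocount * bg) / (nsites + pseudocount),
    with nsites defaulting to 20 when the motif does not record it.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (4,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("background must be a 4-vector summing to 1")
    if (background <= 0).any():
        raise ValueError("background components must all be positive")
    n = pwm.nsites if pwm.nsites else DEFAULT_NSITES
    adjusted = (pwm.probs * n + pseudocount * background) / (n + pseudocount)
    return np.log2(adjusted / background)


@dataclass
class ScoreDistribution:
    """Exact null distribution of window scores on a quantized grid.

    ``pvalue(s)`` returns P(score >= s) for an i.i.d. background
    sequence; non-increasing in s, and 1 at the minimum achievable
    score. Quantization step is 1/1000 of the total score range.
    """

    qmatrix: np.ndarray      # (L, 4) integer scores, row minima shifted to >= 0
    step: float              # real score units per integer unit
    offset: float            # real score of integer 0
    pmf: np.ndarray          # probability mass over integer totals 0..max
    tail: np.ndarray         # P(int score >= i)

    def quantized_pvalue(self, qscore: int) -> float:
        qscore = max(0, min(qscore, len(self.tail) - 1))
        return float(self.tail[qscore])

    def pvalue(self, score: float) -> float:
        q = int(round((score - self.offset) / self.step)) if self.step > 0 else 0
        if q < 0:
            return 1.0
        if q >= len(self.tail):
            return float(self.tail[-1])
        return float(self.tail[q])

    def threshold_qscore(self, p_max: float) -> int:
        """Smallest integer score with tail probability < p_max (len(tail) if none)."""
        below = np.flatnonzero(self.tail < p_max)
        return int(below[0]) if len(below) else len(self.tail)


def score_pvalue_table(
    lom: np.ndarray,
    background=DEFAULT_BACKGROUND,
    n_steps: int = 1000,
) -> ScoreDistribution:
    """Exact p-values of PWM window scores by DP over quantized scores."""
    lom = np.asarray(lom, dtype=float)
    background = np.asarray(background, dtype=float)
    lo = lom.min(axis=1).sum()
    hi = lom.max(axis=1).sum()
    rng = hi - lo
    step = rng / n_steps if rng > 0 else 1.0
    shifted = lom - lom.min(axis=1, keepdims=True)
    q = np.rint(shifted / step).astype(np.int64)
    offset = lo  # integer 0 corresponds to every position at its row minimum

    max_total = int(q.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    for i in range(q.shape[0]):
        nxt = np.zeros_like(pmf)
        for b in range(4):
            qv = q[i, b]
            nxt[qv:] += background[b] * pmf[: len(pmf) - qv]
        pmf = nxt
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(qmatrix=q, step=step, offset=offset, pmf=pmf, tail=tail)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = np.where(codes >= 0, 3 - codes, codes)
    return out[::-1]


def _scan_codes(codes: np.ndarray, q: np.ndarray, dist: ScoreDistribution,
                p_max: float):
    """Yield (offset, qscore, p) for hits on an encoded forward sequence."""
    L = q.shape[0]
    n = len(codes)
    if n < L:
        return
    thresh = dist.threshold_qscore(p_max)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return
    idx = np.flatnonzero(valid)
    scores = q[np.arange(L)[None, :], windows[idx]].sum(axis=1)
    for i, s in zip(idx, scores):
        if s >= thresh:
            yield int(i), int(s), dist.quantized_pvalue(int(s))


def scan_windows(
    probes: list[Probe],
    genome,
    pwms: list[PWM],
    window: int = 100,
    p_max: float = 1e-4,
    background=DEFAULT_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Scan +/-``window`` bp around each probe with every PWM, both strands.

    ``genome`` is a mapping chrom -> sequence string (e.g. a
    ``pyfaidx.Fasta`` opened on an indexed FASTA, or a plain dict).
    Windows are truncated at contig ends; positions containing N are
    unscorable and skipped. Hits are positions with match p < p_max;
    offsets are relative to the (possibly truncated) window start on
    the forward strand. Probes on contigs absent from the genome are
    skipped with a warning.
    """
    background = np.asarray(background, dtype=float)
    prepped = []
    for pwm in pwms:
        lom = log_odds_matrix(pwm, background, pseudocount)
        dist = score_pvalue_table(lom, background)
        prepped.append((pwm, dist))

    rows = []
    for probe in probes:
        try:
            contig = genome[probe.chrom]
        except KeyError:
            logger.warning("probe %s: contig %s not in genome; skipped",
                           probe.id, probe.chrom)
            continue
        start0 = max(0, probe.pos - 1 - window)
        end0 = min(len(contig), probe.pos - 1 + window + 1)
        seq = str(contig[start0:end0])
        codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        rc = _revcomp_codes(codes)
        win_len = len(codes)
        for pwm, dist in prepped:
            q = dist.qmatrix
            for off, s, p in _scan_codes(codes, q, dist, p_max):
                rows.append((probe.id, pwm.motif_id, off, "+",
                             s * dist.step + dist.offset, p))
            for off, s, p in _scan_codes(rc, q, dist, p_max):
                fwd_off = win_len - pwm.width - off
                rows.append((probe.id, pwm.motif_id, fwd_off, "-",
                             s * dist.step + dist.offset, p))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


ENRICH_COLUMNS = [
    "motif_id", "a", "b", "c", "d", "p_sel", "p_bg",
    "odds_ratio", "sd", "lower_ci", "evaluable", "enriched",
]


def enrichment_stats(a: int, b: int, c: int, d: int, z: float = 1.96) -> dict:
    """OR, SD and lower CI bound from the 2x2 per-probe motif table."""
    p_sel = a / (a + b) if a + b else math.nan
    p_bg = c / (c + d) if c + d else math.nan
    if min(a, b, c, d) > 0:
        odds_ratio = (p_sel / (1 - p_sel)) / (p_bg / (1 - p_bg))
        sd = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lower_ci = math.exp(math.log(odds_ratio) - z * sd)
        evaluable = True
    else:
        odds_ratio = sd = lower_ci = math.nan
        evaluable = False
    return {"p_sel": p_sel, "p_bg": p_bg, "odds_ratio": odds_ratio,
            "sd": sd, "lower_ci": lower_ci, "evaluable": evaluable}


def motif_enrichment(
    paired_probe_ids,
    background_probe_ids,
    hits: pd.DataFrame,
    or_floor: float = 1.1,
    min_occurrences: int = 10,
    z: float = 1.96,
) -> pd.DataFrame:
    """Per-motif enrichment of the paired set against the enhancer background.

    The paired set must be a subset of the background. A probe counts
    once per motif regardless of how many occurrences its window
    holds. Motifs with a zero cell are reported unevaluable. Results
    are ranked by odds ratio (descending, unevaluable last).
    """
    paired = set(paired_probe_ids)
    background = set(background_probe_ids)
    if not paired <= background:
        raise ValueError("paired probe set must be a subset of the background set")
    n_sel, n_bg = len(paired), len(background)

    rows = []
    motif_ids = sorted(hits["motif_id"].unique()) if len(hits) else []
    for motif_id in motif_ids:
        with_hit = set(hits.loc[hits["motif_id"] == motif_id, "probe_id"])
        a = len(with_hit & paired)
        b = n_sel - a
        c = len(with_hit & background)
        d = n_bg - c
        st = enrichment_stats(a, b, c, d, z=z)
        enriched = bool(
            st["evaluable"] and st["lower_ci"] > or_floor and a >= min_occurrences
        )
        rows.append({"motif_id": motif_id, "a": a, "b": b, "c": c, "d": d,
                     **st, "enriched": enriched})
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["odds_ratio", "motif_id"], ascending=[False, True],
            kind="stable", na_position="last",
        ).reset_index(drop=True)
    return df
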