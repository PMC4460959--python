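"""Build the distal-enhancer probe universe.

A probe is *distal* if its CpG lies more than ``min_dist`` bp (default
2 kb) from every annotated TSS, and an *enhancer* probe if it is distal
and falls inside a merged enhancer region (chromatin-state segments
labeled as active enhancers, plus eRNA regions). Distal non-enhancer
probes form the pool from which permutation null probes are drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import GeneModel, GenomicInterval, Probe

logger = logging.getLogger(__name__)

DEFAULT_ENHANCER_STATES = ("EnhG1", "EnhG2", "EnhA1", "EnhA2")


@dataclass
class ProbeUniverse:
    """Partition of a probe manifest into distal enhancer / non-enhancer sets.

    Invariant: ``distal_enhancer`` is a subset of ``distal``, and
    ``distal_nonenhancer == distal - distal_enhancer``.
    """

    all_probes: list[Probe]
    distal: set[str]
    distal_enhancer: set[str]

    def __post_init__(self) -> None:
        all_ids = {p.id for p in self.all_probes}
        if not self.distal <= all_ids:
            raise ValueError("distal ids not all in the manifest")
        if not self.distal_enhancer <= self.distal:
            raise ValueError("enhancer ids must be a subset of distal ids")

    @property
    def distal_nonenhancer(self) -> set[str]:
        return self.distal - self.distal_enhancer

    def probe_by_id(self) -> dict[str, Probe]:
        return {p.id: p for p in self.all_probes}

    def classes(self) -> dict[str, str]:
        """Map probe id -> {proximal, distal_enhancer, distal_nonenhancer}."""
        out = {}
        for p in self.all_probes:
            if p.id in self.distal_enhancer:
                out[p.id] = "distal_enhancer"
            elif p.id in self.distal:
                out[p.id] = "distal_nonenhancer"
            else:
                out[p.id] = "proximal"
        return out


def merge_regions(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping or touching intervals per chromosome.

    Returns intervals sorted by (chrom, start); touching intervals
    (end == next start) are merged. Idempotent.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or touch
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, "merged"))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, "merged"))
    return merged


def select_distal(
    probes: list[Probe], genes: list[GeneModel], min_dist: int = 2000
) -> set[str]:
    """Ids of probes whose CpG is strictly more than ``min_dist`` bp from every TSS.

    Probes on chromosomes with no annotated TSS are retained. Distance
    is unstranded absolute bp between the CpG position and the TSS.
    """
    if min_dist < 0:
        raise ValueError("min_dist must be non-negative")
    if not genes:
        logger.warning("empty gene annotation: retaining all %d probes", len(probes))
        return {p.id for p in probes}
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    keep = set()
    for p in probes:
        tss = tss_by_chrom.get(p.chrom)
        if tss is None:
            keep.add(p.id)
            continue
        i = np.searchsorted(tss, p.pos)
        nearest = min(
            (abs(p.pos - tss[j]) for j in (i - 1, i) if 0 <= j < len(tss)),
        )
        if nearest > min_dist:
            keep.add(p.id)
    return keep


def select_enhancer(
    distal_ids: set[str], probes: list[Probe], enhancers: list[GenomicInterval]
) -> set[str]:
    """Distal probe ids whose CpG position falls within a merged enhancer region.

    Membership uses the single 1-based CpG coordinate converted to
    0-based against half-open ``[start, end)`` intervals.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in enhancers:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in by_chrom.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        starts[chrom] = np.array([iv.start for iv in ivs])
        ends[chrom] = np.array([iv.end for iv in ivs])

    hit = set()
    for p in probes:
        if p.id not in distal_ids or p.chrom not in starts:
            continue
        pos0 = p.pos - 1
        i = np.searchsorted(starts[p.chrom], pos0, side="right") - 1
        if i >= 0 and pos0 < ends[p.chrom][i]:
            hit.add(p.id)
    return hit


def build_universe(
    probes: list[Probe],
    genes: list[GeneModel],
    enhancer_regions: list[GenomicInterval],
    min_tss_dist: int = 2000,
    exclude_masked: bool = True,
) -> ProbeUniverse:
    """Full universe construction: mask -> distal filter -> enhancer overlap."""
    usable = [p for p in probes if not (exclude_masked and "masked" in p.flags)]
    merged = merge_regions(enhancer_regions) if enhancer_regions else []
    distal = select_distal(usable, genes, min_dist=min_tss_dist)
    enhancer = select_enhancer(distal, usable, merged)
    return ProbeUniverse(all_probes=usable, distal=distal, distal_enhancer=enhancer)
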