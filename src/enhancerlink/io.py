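"""Readers and writers for the external formats the pipeline consumes.

Matrices are TSV/CSV with row ids in the first column and sample ids in
the header. Region sets are BED4+. Gene models are either a 4-column TSV
(gene_id, chrom, strand, tss) or GTF. Motifs use MEME minimal format.
Every reader is total on the corresponding writer's output.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    PWM,
    BetaMatrix,
    CohortError,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    GenomicInterval,
    Probe,
    SampleSheet,
)

logger = logging.getLogger(__name__)

_NA_TOKENS = {"", "NA", "NaN", "nan", "N/A", "null", "NULL"}


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# probes / regions / genes
# ---------------------------------------------------------------------------

def read_probe_manifest(path) -> list[Probe]:
    """Read a probe manifest TSV with columns id, chrom, pos (+ optional masked)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    for col in ("id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"probe manifest {path}: missing column {col!r}")
    probes = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise FormatError(
                f"probe manifest {path}: non-integer pos {row.pos!r} in row {i + 1} "
                f"(probe {row.id!r})"
            ) from None
        flags = set()
        if "masked" in df.columns:
            masked = getattr(row, "masked")
            if isinstance(masked, str) and masked.strip().lower() in {"1", "true", "yes"}:
                flags.add("masked")
        probes.append(Probe(id=row.id, chrom=row.chrom, pos=pos, flags=frozenset(flags)))
    ids = pd.Series([p.id for p in probes])
    if ids.duplicated().any():
        dups = sorted(set(ids[ids.duplicated()]))
        raise FormatError(f"probe manifest {path}: duplicate probe ids {dups}")
    return probes


def write_probe_manifest(probes: list[Probe], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\tmasked\n")
        for p in probes:
            fh.write(f"{p.id}\t{p.chrom}\t{p.pos}\t{int('masked' in p.flags)}\n")


def read_state_bed(path, keep_labels=None) -> list[GenomicInterval]:
    """Read BED4+ intervals, keeping rows whose state label is in ``keep_labels``.

    ``keep_labels=None`` keeps everything. BED coordinates (0-based,
    half-open) are preserved as-is.
    """
    keep = set(keep_labels) if keep_labels is not None else None
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
            chrom, start_s, end_s, label = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            if keep is None or label in keep:
                out.append(GenomicInterval(chrom, start, end, label))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read gene TSSs from a 4-column TSV (gene_id, chrom, strand, tss) or GTF."""
    if str(path).endswith((".gtf", ".gtf.gz")):
        return _read_gene_models_gtf(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#")
    for col in ("gene_id", "chrom", "strand", "tss"):
        if col not in df.columns:
            raise FormatError(f"gene model file {path}: missing column {col!r}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            tss = int(row.tss)
        except (TypeError, ValueError):
            raise FormatError(
                f"gene model file {path}: non-integer tss {row.tss!r} in row {i + 1}"
            ) from None
        genes.append(GeneModel(row.gene_id, row.chrom, row.strand, tss))
    return genes


def _read_gene_models_gtf(path) -> list[GeneModel]:
    genes = []
    gene_id_re = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            m = gene_id_re.search(parts[8])
            if not m:
                raise FormatError(f"{path}: gene record without gene_id attribute")
            chrom, start, end, strand = parts[0], int(parts[3]), int(parts[4]), parts[6]
            tss = start if strand == "+" else end
            genes.append(GeneModel(m.group(1), chrom, strand, tss))
    return genes


def write_gene_models(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


# ---------------------------------------------------------------------------
# matrices and sample sheets
# ---------------------------------------------------------------------------

def read_matrix(path, kind: str = "beta") -> BetaMatrix | ExpressionMatrix:
    """Read a features-x-samples TSV/CSV matrix.

    ``kind`` selects validation: "beta" enforces values in [0, 1],
    "expression" enforces non-negativity. Empty cells and NA tokens map
    to missing.
    """
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=list(_NA_TOKENS),
        keep_default_na=False,
        comment="#",
    )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"matrix {path}: duplicate row ids {dup}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"matrix {path}: non-numeric cell ({exc})") from None
    if kind == "beta":
        return BetaMatrix(df)
    if kind == "expression":
        return ExpressionMatrix(df)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix, path, float_format: str = "%.6g") -> None:
    matrix.df.to_csv(path, sep=_sep_for(path), float_format=float_format, na_rep="NA")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, comment="#").fillna("")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def match_cohort(beta: BetaMatrix, expr: ExpressionMatrix, sheet: SampleSheet):
    """Restrict all three inputs to their shared samples.

    Returns ``(sample_ids, beta, expr, sheet)`` where ``sample_ids`` is
    the lexicographically sorted intersection; both matrices are
    column-subset to it in that order. The result is therefore invariant
    to the column order of the inputs.
    """
    shared = sorted(
        set(beta.sample_ids) & set(expr.sample_ids) & set(sheet.sample_ids)
    )
    if not shared:
        raise CohortError(
            "no samples shared by methylation, expression and the sample sheet"
        )
    return shared, beta.subset_samples(shared), expr.subset_samples(shared), sheet.subset(shared)


# ---------------------------------------------------------------------------
# MEME motifs
# ---------------------------------------------------------------------------

def read_meme_motifs(path) -> list[PWM]:
    """Parse MEME minimal motif format (ACGT alphabet) into PWMs.

    Rows whose sum deviates from 1 by <= 1e-3 are renormalized; larger
    deviations are a format error.
    """
    pwms = []
    motif_id = None
    rows: list[list[float]] = []
    nsites = None
    expecting = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if stripped.upper().startswith("ALPHABET=") and "ACGT" not in stripped.upper().replace(" ", ""):
                raise FormatError(f"{path}:{lineno}: unsupported alphabet {stripped!r}")
            if stripped.startswith("MOTIF"):
                if motif_id is not None:
                    pwms.append(_finish_motif(motif_id, rows, nsites, path))
                motif_id = stripped.split()[1]
                rows, nsites, expecting = [], None, 0
            elif stripped.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", stripped)
                expecting = int(m.group(1)) if m else -1
                m = re.search(r"nsites=\s*(\d+)", stripped)
                nsites = int(m.group(1)) if m else None
            elif motif_id is not None and stripped and stripped[0] in "0123456789.":
                vals = [float(v) for v in stripped.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 probabilities")
                s = sum(vals)
                if abs(s - 1.0) > 1e-3:
                    raise FormatError(
                        f"{path}:{lineno}: probability row sums to {s:.4g}, "
                        "deviating from 1 by more than 1e-3"
                    )
                rows.append([v / s for v in vals])
    if motif_id is not None:
        pwms.append(_finish_motif(motif_id, rows, nsites, path))
    return pwms


def _finish_motif(motif_id, rows, nsites, path) -> PWM:
    if not rows:
        raise FormatError(f"{path}: motif {motif_id!r} has no probability matrix")
    return PWM(motif_id=motif_id, probs=np.array(rows, dtype=float), nsites=nsites)


def write_meme_motifs(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            nsites = pwm.nsites if pwm.nsites is not None else 20
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= {nsites} E= 0\n"
            )
            for row in pwm.probs:
                fh.write(" ".join(f"{v:.9f}" for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA / loops / misc lists
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_loops(path) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """Read a loop set as 6-column TSV: chromA startA endA chromB startB endB."""
    loops = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: loop rows need 6 columns")
            a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]), "anchorA")
            b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]), "anchorB")
            loops.append((a, b))
    return loops


def write_loops(loops, path) -> None:
    with open(path, "w") as fh:
        for a, b in loops:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


def read_id_list(path) -> list[str]:
    """One id per line; '#' comments and blank lines ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split("\t")[0])
    return out


def write_id_list(ids, path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
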