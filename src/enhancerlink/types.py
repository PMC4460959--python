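"""Core domain types for methylation/expression enhancer analysis.

Coordinate conventions
----------------------
CpG probes are single 1-based genomic positions (array-manifest style).
All interval annotations (chromatin-state segmentations, eRNA regions,
loop anchors) are BED-style: 0-based, half-open ``[start, end)``.
Conversion between the two happens only inside overlap operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CohortError",
    "GenomicInterval",
    "Probe",
    "GeneModel",
    "PWM",
    "SampleSheet",
    "BetaMatrix",
    "ExpressionMatrix",
]


class FormatError(ValueError):
    """An input file violates its format contract."""


class CohortError(ValueError):
    """Samples across modalities cannot be assembled into a cohort."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)``, 0-based."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    def contains_pos(self, pos_1based: int) -> bool:
        """Whether a 1-based point position falls inside the interval."""
        return self.start <= pos_1based - 1 < self.end


@dataclass(frozen=True)
class Probe:
    """A single-CpG methylation array probe.

    ``pos`` is the 1-based coordinate of the interrogated CpG. ``flags``
    may contain ``distal``, ``enhancer`` and ``masked`` (probes masked
    upstream for assay failure / SNPs / repeats).
    """

    id: str
    chrom: str
    pos: int
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its strand-aware transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1, got {self.tss}")


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A, C, G, T.

    ``probs`` has shape (L, 4); each row sums to 1. ``nsites`` is the
    number of binding sites the matrix was estimated from, used for
    pseudocount weighting during log-odds conversion.
    """

    motif_id: str
    probs: np.ndarray
    nsites: int | None = None

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError("PWM probs must have shape (L, 4)")
        if (probs < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        sums = probs.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("PWM rows must sum to 1 within 1e-6")
        object.__setattr__(self, "probs", probs)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


class SampleSheet:
    """Sample annotations: tumor/normal label, cohort code, optional subtype."""

    REQUIRED = ("sample_id", "group")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise FormatError(f"sample sheet missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in sheet: {dups}")
        bad = set(df["group"]) - {"tumor", "normal"}
        if bad:
            raise FormatError(f"group must be tumor|normal, got {sorted(bad)}")
        if "cohort" not in df.columns:
            df["cohort"] = ""
        if "subtype" not in df.columns:
            df["subtype"] = ""
        self.df = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def group_of(self, sample_id: str) -> str:
        return self.df.loc[sample_id, "group"]

    def tumors(self) -> list[str]:
        return list(self.df.loc[self.df["group"] == "tumor", "sample_id"])

    def normals(self) -> list[str]:
        return list(self.df.loc[self.df["group"] == "normal", "sample_id"])

    def subset(self, sample_ids) -> "SampleSheet":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return SampleSheet(self.df.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)


class _FeatureMatrix:
    """Features x samples matrix backed by a pandas DataFrame (float, NaN = missing)."""

    def __init__(self, df: pd.DataFrame):
        if df.index.duplicated().any():
            raise FormatError(
                f"duplicate row ids: {df.index[df.index.duplicated()].tolist()}"
            )
        if df.columns.duplicated().any():
            raise FormatError(
                f"duplicate sample ids: {df.columns[df.columns.duplicated()].tolist()}"
            )
        self.df = df.astype(float)
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        pass

    @property
    def feature_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def row(self, feature_id: str) -> pd.Series:
        return self.df.loc[feature_id]

    def subset_samples(self, sample_ids):
        return type(self)(self.df[list(sample_ids)])

    def subset_features(self, feature_ids):
        return type(self)(self.df.loc[list(feature_ids)])

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.df.index

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape


class BetaMatrix(_FeatureMatrix):
    """Probes x samples methylation beta values, M/(M+U), each in [0, 1] or missing.

    The [0, 1] invariant is enforced here, at construction, and nowhere
    downstream.
    """

    def _validate(self) -> None:
        vals = self.df.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if np.nansum(bad):
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"beta value out of [0,1]: {vals[i, j]} at "
                f"probe {self.df.index[i]!r}, sample {self.df.columns[j]!r}"
            )


class ExpressionMatrix(_FeatureMatrix):
    """Genes x samples non-negative normalized expression (RSEM-like).

    Stored untransformed; rank-based downstream tests are invariant to
    monotone transforms, so no log is ever applied to the data itself.
    """

    def _validate(self) -> None:
        vals = self.df.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = vals < 0
        if np.nansum(bad):
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"negative expression value {vals[i, j]} at "
                f"gene {self.df.index[i]!r}, sample {self.df.columns[j]!r}"
            )
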