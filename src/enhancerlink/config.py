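"""Pipeline configuration: every threshold in one place.

Defaults are the method's canonical operating point: 2 kb distal
filter, extreme quintiles (20%), BH-adjusted p < 0.01 with |delta| >
0.3 for methylation calls, the 5%-of-samples > 0.3 variability filter,
10 candidate genes per side, 10,000 permutations with empirical
p < 0.001 for pairs, +/-100 bp motif scans at p < 1e-4, odds-ratio
lower 95% CI > 1.1 with >= 10 occurrences for enrichment, top 5% for
TF ranking, and 500 bp probe clustering.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    tss_min_dist: int = 2000
    extreme_fraction: float = 0.2
    padj_max: float = 0.01
    delta_min: float = 0.3
    variability_min_frac: float = 0.05
    variability_beta: float = 0.3
    n_adjacent_per_side: int = 10
    nperm: int = 10000
    pe_max: float = 0.001
    scan_window: int = 100
    scan_pmax: float = 1e-4
    or_floor: float = 1.1
    min_occurrences: int = 10
    ci_z: float = 1.96
    tf_top: float = 0.05
    cluster_gap: int = 500
    perm_scope: str = "pair"
    pooled_var: bool = False

    def __post_init__(self) -> None:
        checks = [
            (0 < self.extreme_fraction <= 0.5, "extreme_fraction in (0, 0.5]"),
            (0 < self.padj_max <= 1, "padj_max in (0, 1]"),
            (0 <= self.delta_min < 1, "delta_min in [0, 1)"),
            (0 <= self.variability_min_frac <= 1, "variability_min_frac in [0, 1]"),
            (self.n_adjacent_per_side >= 1, "n_adjacent_per_side >= 1"),
            (self.nperm >= 1, "nperm >= 1"),
            (0 < self.pe_max <= 1, "pe_max in (0, 1]"),
            (self.scan_window >= 1, "scan_window >= 1"),
            (0 < self.scan_pmax <= 1, "scan_pmax in (0, 1]"),
            (0 < self.tf_top <= 1, "tf_top in (0, 1]"),
            (self.cluster_gap >= 0, "cluster_gap >= 0"),
            (self.perm_scope in ("pair", "probe"), "perm_scope pair|probe"),
            (self.tss_min_dist >= 0, "tss_min_dist >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: expected {msg}")

    def hash(self) -> str:
        """Stable short hash over all thresholds; changes iff any field changes."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
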