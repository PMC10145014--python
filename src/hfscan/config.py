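"""Run configuration shared by the CLI subcommands.

Defaults follow the pipeline's published-style thresholds where those are
defined (E-value cutoff 1e-5, 10 bp virus-side merge gap, 100 kb windows,
adjusted p < 0.05 for scaffolds, raw p < 0.01 for windows, p < 0.05 for
regions); extents the method leaves open (promoter/downstream flanks,
distance bins, window step) are explicit, marked "assumed", and echoed into
every output file header.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

ASSUMED_KEYS = {"promoter_len", "downstream_len", "distance_bins", "step"}


@dataclass
class RunConfig:
    evalue_cutoff: float = 1e-5
    merge_gap: int = 10
    promoter_len: int = 2000
    downstream_len: int = 1000
    window: int = 100_000
    step: int | None = None  # None = window (disjoint tiles)
    distance_bins: tuple[int, ...] = (0, 1_000, 10_000, 100_000)
    n_sim: int = 1000
    seed: int = 0
    alpha_scaffold: float = 0.05  # Bonferroni-adjusted
    alpha_window: float = 0.01  # raw
    alpha_region: float = 0.05  # raw
    alpha_distance: float = 0.01  # raw
    overlap_policy: str = "reciprocal"
    min_reciprocal_overlap: float = 0.8
    orientation: str = "virus-as-query"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("evalue_cutoff", "window", "n_sim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.merge_gap < 0 or self.promoter_len < 0 or self.downstream_len < 0:
            raise ValueError("lengths must be >= 0")
        if self.orientation not in ("virus-as-query", "host-as-query"):
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def header(self) -> str:
        """Key=value lines echoed at the top of every output file."""
        lines = []
        for f in fields(self):
            if f.name == "extras":
                continue
            val = getattr(self, f.name)
            mark = " (assumed)" if f.name in ASSUMED_KEYS else ""
            lines.append(f"{f.name} = {val}{mark}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distance_bins"] = list(self.distance_bins)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat key-value config file (YAML subset); unknown keys rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "distance_bins" in data:
            data["distance_bins"] = tuple(data["distance_bins"])
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (CLI flags win)."""
        d = self.to_dict()
        d["distance_bins"] = tuple(d["distance_bins"])
        for k, v in overrides.items():
            if v is not None:
                d[k] = v
        return RunConfig(**d)
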