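"""Run configuration with documented defaults, YAML loading, and echoing.

Every knob that the pipeline consults lives here so that each output JSON can
embed the exact configuration that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .align import DEFAULT_SCHEMES, ScoringScheme


@dataclass
class AlignConfig:
    #: (match, mismatch, gap_open, gap_extend) tuples, one per battery entry.
    schemes: list[tuple[int, int, int, int]] = field(
        default_factory=lambda: [s.as_tuple() for s in DEFAULT_SCHEMES]
    )
    #: Guard against accidental whole-chromosome targets.
    max_region_len: int = 1_000_000

    def scheme_objects(self) -> list[ScoringScheme]:
        return [ScoringScheme(*t) for t in self.schemes]


@dataclass
class ExonConfig:
    #: Identity floor (percent) below which the best placement of an exon is
    #: declared absent. The floor must clear the spurious-fit null: under the
    #: battery's most permissive scheme, an unrelated ~100 nt sequence fitted
    #: into a ~1 kb region reaches 45-55% identity by chance, while genuinely
    #: present (even heavily mutated) exons align well above 80%.
    min_identity: float = 65.0


@dataclass
class SpliceConfig:
    #: Accept GC as a (minor, U12-like) donor in addition to GT.
    allow_gc_donor: bool = False


@dataclass
class CallerConfig:
    #: Premature stops within max(terminal_frac * CDS, terminal_nt) of the
    #: terminal stop are recorded but flagged non-disruptive: slightly early
    #: termination is commonly tolerated.
    terminal_frac: float = 0.05
    terminal_nt: int = 30
    #: Whether a lost start codon counts as disruptive (downstream in-frame
    #: ATGs often rescue translation, so the default is conservative).
    start_loss_disruptive: bool = False


@dataclass
class PseudoIndexConfig:
    #: (upper_edge, index) pairs binning the disrupted fraction; a target with
    #: no disruptive event is always index 0 regardless of the bins.
    bins: list[tuple[float, int]] = field(
        default_factory=lambda: [(0.05, 1), (0.20, 2), (0.50, 3), (0.85, 4), (1.0, 5)]
    )


@dataclass
class TreeConfig:
    #: +/- slack (nt) when deciding two targets share "the same" mutation;
    #: 0 demands exact CDS coordinates (conservative homology claim).
    pos_tolerance: int = 0


@dataclass
class RunConfig:
    align: AlignConfig = field(default_factory=AlignConfig)
    exon: ExonConfig = field(default_factory=ExonConfig)
    splice: SpliceConfig = field(default_factory=SpliceConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    pseudoindex: PseudoIndexConfig = field(default_factory=PseudoIndexConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    jobs: int = 1
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        """Analysis parameters only: execution knobs (jobs, log level) are
        excluded so outputs are byte-identical across worker counts."""
        d = asdict(self)
        d["align"]["schemes"] = [list(t) for t in d["align"]["schemes"]]
        d["pseudoindex"]["bins"] = [list(t) for t in d["pseudoindex"]["bins"]]
        del d["jobs"], d["log_level"]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        for section in ("align", "exon", "splice", "caller", "pseudoindex", "tree"):
            sub = data.get(section, {})
            target = getattr(cfg, section)
            for key, value in sub.items():
                if not hasattr(target, key):
                    raise ValueError(f"unknown config key {section}.{key}")
                if key in ("schemes", "bins"):
                    value = [tuple(v) for v in value]
                setattr(target, key, value)
        for key in ("jobs", "log_level"):
            if key in data:
                setattr(cfg, key, data[key])
        if cfg.jobs < 1:
            raise ValueError("jobs must be a positive integer")
        cfg.align.scheme_objects()  # validate scheme tuples eagerly
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
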