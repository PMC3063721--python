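"""Analysis configuration shared by the command-line entry points."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class AnalysisConfig:
    """Settings of one end-to-end causality analysis.

    Durations are seconds.  ``candidate_orders`` is the AIC search range for
    the per-neuron history order; ``orders`` (when set) bypasses selection.
    """

    delta: float = 0.001
    W: float = 0.002
    candidate_orders: list = field(default_factory=lambda: list(range(1, 11)))
    orders: list | None = None
    fdr_q: float = 0.05
    seed: int | None = None
    collapse_duplicates: bool = False

    def __post_init__(self):
        if self.delta <= 0 or self.W <= 0:
            raise ValueError("durations must be positive")
        ratio = self.W / self.delta
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("W must be an integer multiple of delta")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if not self.candidate_orders and self.orders is None:
            raise ValueError("need candidate_orders or explicit orders")

    @classmethod
    def from_file(cls, path):
        """Load from a JSON or YAML file (decided by extension)."""
        with open(path) as fh:
            if str(path).endswith((".yml", ".yaml")):
                import yaml

                doc = yaml.safe_load(fh)
            else:
                doc = json.load(fh)
        return cls(**doc)

    def to_dict(self):
        return asdict(self)

    def digest(self):
        """Short stable hash of the configuration, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
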