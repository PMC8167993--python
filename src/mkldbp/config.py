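"""Run configuration shared by the pipeline drivers and the CLI."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from .kernels import DEFAULT_GAMMAS, KERNEL_ORDER

SEQUENCE_FEATURES = ("GE", "MCD", "NMBAC")
PSSM_FEATURES = ("PSSM-AB", "PSSM-DWT", "PsePSSM")


@dataclasses.dataclass
class RunConfig:
    """All tunables of the pipeline with their benchmark-tuned defaults.

    ``strategy`` selects how the six per-feature kernels are combined:
    ``"cka"`` (alignment-optimized weights), ``"mean"`` (uniform 1/m) or
    ``"single:<feature>"`` (one kernel alone).  ``sequence_only`` restricts
    the pipeline to the three profile-free features for datasets without
    PSI-BLAST profiles.
    """

    lg_max: int = 30          # NMBAC autocorrelation depth
    lag_max: int = 10         # PsePSSM lag depth
    n_blocks: int = 20        # PSSM-AB block count
    wavelet: str = "db4"      # PSSM-DWT mother wavelet
    levels: int = 4           # PSSM-DWT decomposition depth
    gammas: dict = dataclasses.field(default_factory=lambda: dict(DEFAULT_GAMMAS))
    lam: float = 0.8          # Laplacian smoothing strength
    C: float = 2.0            # SVM margin/misclassification trade-off
    strategy: str = "cka"
    sequence_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for field in ("lg_max", "lag_max", "n_blocks", "levels", "C"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if not (
            self.strategy in ("cka", "mean")
            or (self.strategy.startswith("single:")
                and self.strategy.split(":", 1)[1] in self.feature_names())
        ):
            raise ValueError(f"invalid strategy {self.strategy!r}")

    def feature_names(self) -> tuple[str, ...]:
        if self.sequence_only:
            return SEQUENCE_FEATURES
        return KERNEL_ORDER

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
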