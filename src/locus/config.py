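"""Pipeline configuration.

Defaults reproduce the study design: 160 trials per subject, all seven
models, prior variance 1/8 on every unconstrained parameter, 16 synthetic
subjects in the recovery analysis.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .laplace_opts import FitOptions


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 16
    trials_per_subject: int = 160
    model_ids: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    generating_model_id: int = 7
    prior_variance: float = 1.0 / 8.0
    fit_options: FitOptions = field(default_factory=FitOptions)

    def __post_init__(self) -> None:
        if self.trials_per_subject % 4 != 0:
            raise ValueError("trials_per_subject must be divisible by 4")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be positive")
        bad = set(self.model_ids) - set(range(1, 8))
        if bad:
            raise ValueError(f"unknown model ids: {sorted(bad)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_ids"] = list(self.model_ids)
        return d

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        opts = raw.pop("fit_options", None)
        if "model_ids" in raw:
            raw["model_ids"] = tuple(raw["model_ids"])
        cfg = cls(**raw) if opts is None else cls(
            **raw, fit_options=FitOptions(**opts))
        return cfg
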