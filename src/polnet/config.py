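"""Analysis configuration shared by the whole pipeline.

All thresholds of the inference procedure live here so that every result
object can be serialized together with the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class AnalysisConfig:
    """Tunable parameters of the cross-tissue inference pipeline.

    Attributes
    ----------
    corr_threshold : float
        Minimum absolute Spearman correlation for an edge of the
        normal-tumour (NT) network (strict inequality is applied).
    fdr_max : float
        Benjamini-Hochberg FDR ceiling for edge selection (strict ``<``).
    n_bootstrap : int
        Number of pairing-destroyed resamples used to draw the null
        distribution of the correlation coefficient.
    epsilon : float
        Stabilising constant of the polarization index
        ``pol = (f - b) / (f + b + epsilon)``.
    min_diff : int
        The polarization index is forced to 0 when ``|f - b| < min_diff``,
        so that a handful of connections cannot produce extreme values.
    pol_threshold : float
        ``|pol|`` above which a gene is called polarized (strict).
    min_module_size : int
        Modules smaller than this are flagged as too small for
        composition/enrichment analysis.
    top_hub_k : int
        Number of highest-degree nodes used by the hub composition test.
    seed : int
        Base seed for every stochastic step.
    """

    corr_threshold: float = 0.75
    fdr_max: float = 0.01
    n_bootstrap: int = 100
    epsilon: float = 1.0
    min_diff: int = 20
    pol_threshold: float = 0.75
    min_module_size: int = 20
    top_hub_k: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must be in [0, 1]")
        if not 0.0 <= self.fdr_max <= 1.0:
            raise ValueError("fdr_max must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_diff < 0:
            raise ValueError("min_diff must be non-negative")
        if not 0.0 <= self.pol_threshold <= 1.0:
            raise ValueError("pol_threshold must be in [0, 1]")

    # -- flat key:value (de)serialization ---------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{field.name}: {getattr(self, field.name)}"
            for field in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        casts = {"int": int, "float": float}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value'")
            key, _, value = line.partition(":")
            key = key.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            kwargs[key] = casts[str(types[key])](value.strip())
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
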