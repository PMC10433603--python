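"""Run configuration with the method's default parameters.

k=31 canonical k-mers; clustering cutoff H=0.95 (Jaccard); leaf prevalence
alpha=90%; sequencing error rate e=1% and binomial significance beta=0.05;
abundance fraction floor 0.1; path acceptance cutoff F=0.4; iterative
detection stop threshold 31*40=1240 k-mers; dereplication at 0.99 complete
linkage; weak-node augmentation floor 1000 k-mers.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .errors import ParameterError


@dataclass
class RunConfig:
    k: int = 31
    H: float = 0.95
    alpha: float = 90.0
    e: float = 0.01
    beta: float = 0.05
    frac_floor: float = 0.1
    F_cutoff: float = 0.4
    stop_kmers: int = 1240
    derep_threshold: float = 0.99
    min_kmers: int = 1000
    single_strain_cap: int = 20000
    annotate_patterns: bool = True
    seed: int = 0

    def validate(self) -> "RunConfig":
        if self.k % 2 == 0 or not (1 <= self.k <= 63):
            raise ParameterError(f"k must be odd in [1, 63], got {self.k}")
        for name, lo, hi in (
            ("H", 0.0, 1.0),
            ("alpha", 0.0, 100.0),
            ("e", 0.0, 1.0),
            ("beta", 0.0, 1.0),
            ("derep_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ParameterError(f"{name} must be in ({lo}, {hi}], got {v}")
        for name in ("frac_floor", "F_cutoff"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must be in [0, 1), got {v}")
        if self.stop_kmers < 1 or self.min_kmers < 0:
            raise ParameterError("stop_kmers must be >= 1 and min_kmers >= 0")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known}).validate()
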