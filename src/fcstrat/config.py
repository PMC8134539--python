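"""Pipeline configuration with the study's printed defaults.

The defaults encode the published analysis settings: Spearman screening at
P < 0.005 keeping ~100 edges for 260 subjects, 10,000-iteration whole-pipeline
permutation, BH-FDR at q = 0.05, 10-fold SVM prediction capped at 20 features,
and inclusion bounds IQ >= 70, mean FD <= 0.5 mm, age 6-30 years, ADOS total
> 7, and sites with at least 3 ASD subjects.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    screening_p_threshold: float = 0.005
    screening_k: int = 100
    n_permutations: int = 10_000
    rng_seed: int = 0
    fdr_q: float = 0.05
    cutoff_range: tuple[int, int] = (9, 17)
    n_folds: int = 10
    prediction_feature_cap: int = 20
    fd_threshold: float = 0.5
    age_range: tuple[float, float] = (6.0, 30.0)
    iq_min: float = 70.0
    ados_min_exclusive: int = 7
    min_asd_per_site: int = 3
    svm_mode: str = "classification"
    standardize_mode: str = "within_subject"
    cca_on_residualized: bool = True
    validation_site_disjoint: bool = True
    cutoff_rule: str = "ge"
    min_screened_edges: int = 3

    def validate(self) -> "PipelineConfig":
        positive = {
            "screening_p_threshold": self.screening_p_threshold,
            "screening_k": self.screening_k,
            "n_permutations": self.n_permutations,
            "fdr_q": self.fdr_q,
            "n_folds": self.n_folds,
            "prediction_feature_cap": self.prediction_feature_cap,
            "fd_threshold": self.fd_threshold,
            "iq_min": self.iq_min,
            "min_asd_per_site": self.min_asd_per_site,
            "min_screened_edges": self.min_screened_edges,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.ados_min_exclusive < 0:
            raise ValueError("ados_min_exclusive must be non-negative")
        lo, hi = self.cutoff_range
        if int(lo) != lo or int(hi) != hi or lo > hi:
            raise ValueError("cutoff_range must be a contiguous integer interval")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.svm_mode not in ("classification", "regression"):
            raise ValueError("svm_mode must be 'classification' or 'regression'")
        if self.standardize_mode not in ("within_subject", "per_edge"):
            raise ValueError("unknown standardize_mode")
        if self.cutoff_rule not in ("ge", "gt"):
            raise ValueError("cutoff_rule must be 'ge' or 'gt'")
        return self

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["cutoff_range"] = list(self.cutoff_range)
        d["age_range"] = list(self.age_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("cutoff_range", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d).validate()
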