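"""Run configuration: a single structured YAML document plus a master seed
reproduces every artifact of a pipeline run.

Every randomized stage derives its own seed deterministically from the master
seed and the stage name, so stages can be re-run independently.
"""
from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError


def seed_for(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class TraitConfig:
    """Causal architecture of one simulated trait."""

    n_causal_genes: int = 0
    effect_model: str = "maf_linked"
    effect_scale: float = 1.0
    architecture: tuple[float, float, float] | None = None


@dataclass
class RunConfig:
    out_dir: str = "raregene_run"
    # cohort / exome scale
    n: int = 697
    m: int = 5000
    R: int = 20
    n_populations: int = 7
    rare_fraction_target: float = 21355 / 24487
    # causal architectures; Q1-like MAF-independent effects, Q2-like
    # MAF-linked effects, a polygenic binary trait, and a genotype-free Q4
    traits: dict[str, TraitConfig] = field(default_factory=lambda: {
        "q1": TraitConfig(n_causal_genes=9, effect_model="maf_independent"),
        "q2": TraitConfig(n_causal_genes=13, effect_model="maf_linked"),
        "q4": TraitConfig(n_causal_genes=0),
        "affected": TraitConfig(n_causal_genes=36, effect_model="maf_linked"),
    })
    n_twins: int = 0
    prevalence: float = 0.30
    # testing
    methods: tuple[str, ...] = ("collapse", "proportion", "wsum", "cmc",
                                "kernel", "wkernel")
    maf_threshold: float = 0.05
    nonsyn_only: bool = False
    test_traits: tuple[str, ...] = ("q1", "q2")
    # MCMC
    mcmc_iterations: int = 10_000
    mcmc_burn_in: int = 2_000
    mcmc_thin: int = 5
    # evaluation
    alpha: float = 0.05
    master_seed: int = 0

    def validate(self) -> None:
        if self.n < 2 or self.m < 1 or self.R < 1:
            raise ParameterError("need n >= 2, m >= 1, R >= 1")
        bad = set(self.methods) - {"collapse", "proportion", "wsum", "cmc",
                                   "kernel", "wkernel"}
        if bad:
            raise ParameterError(f"unknown methods: {sorted(bad)}")
        for t in self.test_traits:
            if t not in self.traits:
                raise ParameterError(f"test trait {t!r} has no trait config")

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["traits"] = {k: asdict(v) for k, v in self.traits.items()}
        d["methods"] = list(self.methods)
        d["test_traits"] = list(self.test_traits)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        traits = d.pop("traits", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if traits is not None:
            cfg.traits = {}
            for name, td in traits.items():
                td = dict(td)
                if td.get("architecture") is not None:
                    td["architecture"] = tuple(td["architecture"])
                cfg.traits[name] = TraitConfig(**td)
        cfg.methods = tuple(d.get("methods", cfg.methods))
        cfg.test_traits = tuple(d.get("test_traits", cfg.test_traits))
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        return f"{zlib.crc32(self.to_yaml().encode()):08x}"


__all__ = ["RunConfig", "TraitConfig", "seed_for"]
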