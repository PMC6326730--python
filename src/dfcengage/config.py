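"""Run configuration: every stage's tunables with the study's default values
(window length 30 TRs, k = 4 clusters, 1,000 k-means iterations, 500 Louvain
repetitions, band-pass 0.0222-0.18 Hz, 4-TR hemodynamic shift, FDR q = 0.01).
Serializes round-trip to YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class ParadigmConfig:
    block_tr: int = 120
    instruction_tr: int = 8
    tr_seconds: float = 1.5
    n_repeats: int = 2
    tail_tr: int = 4


@dataclass
class PrepConfig:
    low_hz: float = 0.0222
    high_hz: float = 0.18
    order: int = 6
    regress_motion: bool = True
    bandpass: bool = True


@dataclass
class WindowConfig:
    wl_tr: int = 30
    shift_tr: int = 4


@dataclass
class ClusterConfig:
    k: int = 4
    max_iter: int = 1000
    n_init: int = 100
    qc_threshold_r: float = 0.95


@dataclass
class GraphConfig:
    n_reps: int = 500
    gamma: float = 1.0
    tau: float = 0.5


@dataclass
class StatsConfig:
    fdr_q: float = 0.01
    alpha: float = 0.05


@dataclass
class SynthConfig:
    n_subjects: int = 24
    n_components: int = 61
    n_modules: int = 4
    within_r: float = 0.6
    between_r: float = 0.35
    rest_between_r: float = 0.0
    delay_tr: int = 4
    noise_sd: float = 0.0
    ar_rho: float = 0.0


@dataclass
class RunConfig:
    seed: int = 0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    prep: PrepConfig = field(default_factory=PrepConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    graph: GraphConfig = field(default_factory=GraphConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        section_cls = {
            "paradigm": ParadigmConfig, "prep": PrepConfig,
            "window": WindowConfig, "cluster": ClusterConfig,
            "graph": GraphConfig, "stats": StatsConfig, "synth": SynthConfig,
        }
        kwargs: dict = {}
        for name, value in d.items():
            if name == "seed":
                kwargs[name] = int(value)
            elif name in section_cls:
                sub_cls = section_cls[name]
                known = {fl.name for fl in dataclasses.fields(sub_cls)}
                unknown = set(value) - known
                if unknown:
                    raise ValueError(f"unknown keys in {name}: {sorted(unknown)}")
                kwargs[name] = sub_cls(**value)
            else:
                raise ValueError(f"unknown config section {name!r}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
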