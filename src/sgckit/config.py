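"""Run configuration: defaults, (de)serialization, and simulation-spec parsing.

Defaults match the reference analysis protocol: model order 10, 5-90 Hz
analysis band, 5-30 Hz aperiodic fit band, 1000 bootstrap resamples, 1000
null permutations, two-tailed p < 0.001 asymmetry test, SVM cost 1 with 200
exemplars and 5000 repeats. Configs round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from sgckit.synth import ConditionPairSpec, Coupling, NetworkSpec

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    # input: either a container path or an inline simulation spec
    input_path: str | None = None
    simulation: dict | None = None

    order: int = 10
    order_scan: list[int] = field(default_factory=lambda: list(range(5, 16)))
    band: list[float] = field(default_factory=lambda: [5.0, 90.0])
    freq_step: float = 1.0
    fit_band: list[float] = field(default_factory=lambda: [5.0, 30.0])

    B: int = 1000
    n_null: int = 1000
    alpha_asymmetry: float = 0.001
    alpha_peaks: float = 0.05
    alpha_trtest: float = 0.05
    target_freq: float = 16.0

    B_exemplars: int = 200
    repeats: int = 5000
    cost: float = 1.0
    control_freq_range: list[float] = field(default_factory=lambda: [5.0, 50.0])

    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.input_path is None and self.simulation is None:
            raise ValueError("config needs input_path or a simulation spec")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.B < 2 or self.n_null < 1:
            raise ValueError("B must be >= 2 and n_null >= 1")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = CONFIG_SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- simulation spec ----------------------------------------------------
    def build_simulation_spec(self) -> ConditionPairSpec:
        if self.simulation is None:
            raise ValueError("config has no simulation spec")
        return spec_from_dict(self.simulation, default_seed=self.seed)


def spec_from_dict(d: dict, default_seed: int = 0) -> ConditionPairSpec:
    """Build a :class:`ConditionPairSpec` from plain-data (YAML/JSON) form.

    Couplings are ``[source, target, coeff, lag]`` lists; condition deltas
    map condition names to ``{"SOURCE->TARGET": factor}``.
    """
    d = dict(d)
    coupling = tuple(
        Coupling(str(s), str(t), float(c), int(lag))
        for s, t, c, lag in d.get("coupling", [])
    )
    net = NetworkSpec(
        n_lower=int(d.get("n_lower", 3)),
        n_higher=int(d.get("n_higher", 2)),
        osc_freq=float(d.get("osc_freq", 16.0)),
        osc_damping=float(d.get("osc_damping", 0.9)),
        coupling=coupling,
        pink_noise_gain=float(d.get("pink_noise_gain", 0.0)),
        sampling_rate=float(d.get("sampling_rate", 200.0)),
    )
    deltas = None
    if d.get("condition_deltas"):
        deltas = {
            cond: {
                tuple(edge.split("->")): float(f) for edge, f in edges.items()
            }
            for cond, edges in d["condition_deltas"].items()
        }
    return ConditionPairSpec(
        base=net,
        condition_deltas=deltas,
        trials_per_condition=int(d.get("trials_per_condition", 1000)),
        samples_per_trial=int(d.get("samples_per_trial", 17)),
        seed=int(d.get("seed", default_seed)),
        burn_in=int(d.get("burn_in", 200)),
    )
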