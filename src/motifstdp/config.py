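"""Run configuration: nested, strictly validated, YAML round-trippable."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict, fields

import yaml

from .params import (
    EIFParams, NoiseParams, SimConfig, DegreeDistConfig, STDPRule,
    hebbian_rule, TAU_S_DEFAULT,
)

__all__ = ["RunConfig", "STDPConfig", "NetworkConfig",
           "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class STDPConfig:
    """Serializable description of the plasticity rule.

    ``balance`` picks a preset relation between the depression and
    potentiation areas (see :func:`motifstdp.params.hebbian_rule`);
    amplitudes are on the unscaled weight scale and multiplied by
    epsilon = 1/(N p0) when the rule is attached to a network.
    """

    f_plus: float = 0.1
    tau_plus: float = 20.0
    tau_minus: float = 40.0
    wmax: float = 5.0
    balance: str = "depression"
    delta: float = 0.1

    def rule(self, epsilon: float = 1.0) -> STDPRule:
        base = hebbian_rule(
            f_plus=self.f_plus, tau_plus=self.tau_plus,
            tau_minus=self.tau_minus, wmax=self.wmax,
            balance=self.balance, delta=self.delta, epsilon=epsilon,
        )
        return base.scaled(epsilon)


@dataclass(frozen=True)
class NetworkConfig:
    N: int = 1000
    p0: float = 0.15
    wmax: float = 5.0
    kind: str = "erdos_renyi"        # or "degree_correlated"
    fill_fraction: float = 0.5
    degree: DegreeDistConfig = field(default_factory=DegreeDistConfig)

    def build(self, seed: int):
        from .network import make_erdos_renyi, make_degree_correlated, \
            uniform_weights

        if self.kind == "erdos_renyi":
            W0 = make_erdos_renyi(self.N, self.p0, seed)
        elif self.kind == "degree_correlated":
            cfg = dataclasses.replace(self.degree,
                                      mean_degree=self.N * self.p0)
            W0 = make_degree_correlated(self.N, cfg, seed)
        else:
            raise ConfigError(f"unknown network kind {self.kind!r}")
        return uniform_weights(W0, p0=self.p0, wmax=self.wmax,
                               fill_fraction=self.fill_fraction)


@dataclass(frozen=True)
class RunConfig:
    eif: EIFParams = field(default_factory=EIFParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    tauS: float = TAU_S_DEFAULT
    seed: int = 0


_SECTIONS = {f.name: f.type for f in fields(RunConfig)}


def _from_dict(cls, data, path=""):
    if not dataclasses.is_dataclass(cls):
        return data
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {path + key!r}")
    kwargs = {}
    for name, val in data.items():
        f = known[name]
        sub = f.default_factory() if f.default_factory is not dataclasses.MISSING else None  # type: ignore
        sub_cls = type(sub) if dataclasses.is_dataclass(sub) else None
        if sub_cls is not None:
            kwargs[name] = _from_dict(sub_cls, val, path=f"{path}{name}.")
        else:
            kwargs[name] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data)


def save_config(cfg: RunConfig, path) -> None:
    """Dump a configuration; load_config(save_config(c)) == c exactly
    (floats are written with full precision)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False,
                       default_flow_style=False)
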