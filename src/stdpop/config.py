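"""Run configuration, plasticity-rule presets, and YAML loading.

Units convention used throughout the package and in every file this module
touches: times in ms, rates in Hz, weights/voltages in mV, drifts in mV/s.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .neuron import NeuronParams
from .rules import (
    BoundsPolicy,
    NmdarParams,
    PairParams,
    PlasticityRule,
    SuppressionParams,
    TripletParams,
)

__all__ = ["RunConfig", "load_config", "RULE_PRESETS", "get_rule_preset"]


# ---------------------------------------------------------------------------
# rule presets
#
# The *_sweep presets take the swept quantity as an argument with the
# example-panel value as default.


def _pair_dep_dominant() -> PairParams:
    return PairParams(a_plus=0.005, a_minus=1.01 * 0.005, tau_plus=20.0, tau_minus=20.0)


def _pair_pot_dominant() -> PairParams:
    return PairParams(a_plus=1.01 * 0.005, a_minus=0.005, tau_plus=20.0, tau_minus=20.0)


def _triplet_hippocampal() -> TripletParams:
    # original triplet fit to hippocampal culture data; the presynaptic
    # depression increment is zero there, so tau_pre is inert
    return TripletParams(
        pair=PairParams(a_plus=5.3e-3, a_minus=3.5e-3, tau_plus=16.8, tau_minus=33.7),
        a_pre=0.0, a_post=8.0e-3, tau_pre=40.0, tau_post=40.0,
    )


def _suppression_original() -> SuppressionParams:
    return SuppressionParams(
        pair=PairParams(a_plus=1.3e-2, a_minus=5.1e-3, tau_plus=13.3, tau_minus=34.5),
        tau_pre=28.0, tau_post=88.0,
    )


def _nmdar_original() -> NmdarParams:
    return NmdarParams(
        a_plus=1.0e-3, a_minus=1.0e-3,
        a_f_up=1.0, a_f_dn=0.5, a_m_up=0.7, a_m_dn=0.7,
        tau_f_up=300.0, tau_f_dn=300.0, tau_m_up=600.0, tau_m_dn=600.0,
        theta_up=0.7, theta_dn=0.35,
    )


def _triplet_sweep(a_post_over_a_pre: float = 0.2, pot_dominant: bool = False) -> TripletParams:
    pair = _pair_pot_dominant() if pot_dominant else _pair_dep_dominant()
    a_pre = 1.0e-3
    return TripletParams(
        pair=pair, a_pre=a_pre, a_post=a_post_over_a_pre * a_pre,
        tau_pre=40.0, tau_post=40.0,
    )


def _suppression_sweep(tau_ratio: float = 1.0) -> SuppressionParams:
    tau_minus = 20.0
    return SuppressionParams(
        pair=PairParams(
            a_plus=0.005, a_minus=0.005,
            tau_plus=tau_ratio * tau_minus, tau_minus=tau_minus,
        ),
        tau_pre=28.0, tau_post=88.0,
    )


def _nmdar_sweep(amp_ratio: float = 0.03) -> NmdarParams:
    # equal kinetic coefficients, original time constants, asymmetric
    # messenger thresholds (depression thresholded at 0.2, potentiation
    # unthresholded); A_- fixed, A_+ = ratio * A_-
    a_minus = 1.0e-3
    return NmdarParams(
        a_plus=amp_ratio * a_minus, a_minus=a_minus,
        a_f_up=0.1, a_f_dn=0.1, a_m_up=0.1, a_m_dn=0.1,
        tau_f_up=300.0, tau_f_dn=300.0, tau_m_up=600.0, tau_m_dn=600.0,
        theta_up=0.0, theta_dn=0.2,
    )


RULE_PRESETS = {
    "fig1_pair_dep_dominant": _pair_dep_dominant,
    "fig1_pair_pot_dominant": _pair_pot_dominant,
    "table2_triplet_hippocampal": _triplet_hippocampal,
    "table2_suppression": _suppression_original,
    "table2_nmdar": _nmdar_original,
    "fig3_triplet_sweep": _triplet_sweep,
    "fig5_suppression_sweep": _suppression_sweep,
    "fig8_nmdar_sweep": _nmdar_sweep,
}


def get_rule_preset(name: str, **kwargs) -> PlasticityRule:
    """Resolve a named rule preset; sweep presets accept the swept value."""
    try:
        factory = RULE_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown rule preset {name!r}; valid presets: {sorted(RULE_PRESETS)}"
        ) from None
    return factory(**kwargs)


_RULE_CLASSES = {
    "pair": PairParams,
    "triplet": TripletParams,
    "suppression": SuppressionParams,
    "nmdar": NmdarParams,
}


def _rule_from_dict(d: dict) -> PlasticityRule:
    d = dict(d)
    kind = d.pop("kind", None)
    if kind not in _RULE_CLASSES:
        raise ValueError(f"rule kind must be one of {sorted(_RULE_CLASSES)}, got {kind!r}")
    if kind in ("triplet", "suppression"):
        pair_d = dict(d.pop("pair", {}))
        pair_d.setdefault("pairing", "all_to_all")
        d["pair"] = PairParams(**pair_d)
    return _RULE_CLASSES[kind](**d)


def _rule_to_dict(rule: PlasticityRule) -> dict:
    d = asdict(rule)
    d["kind"] = rule.kind
    return d


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class InputSpec:
    n_ex: int = 1000
    n_in: int = 250
    r_pre: float = 10.0
    r_in: float = 10.0
    c: float = 0.0
    frac_correlated: float = 0.5


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    rule_preset: str | None = "fig1_pair_dep_dominant"
    rule: dict | None = None          # explicit parameters override the preset
    neuron: NeuronParams = field(default_factory=NeuronParams)
    inputs: InputSpec = field(default_factory=InputSpec)
    bounds: BoundsPolicy = field(default_factory=BoundsPolicy)
    duration_s: float = 2000.0
    sim_seconds: float = 200.0        # frozen-weight drift estimation length
    dt: float = 0.1
    record_every_ms: float = 1000.0
    chunk_seconds: float = 100.0
    init_low: float = 0.3
    init_high: float = 0.7
    seed: int = 0
    out_dir: str = "stdpop_out"

    def resolve_rule(self, **preset_kwargs) -> PlasticityRule:
        if self.rule is not None:
            return _rule_from_dict(self.rule)
        return get_rule_preset(self.rule_preset, **preset_kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "neuron" in d and isinstance(d["neuron"], dict):
            _check_keys(d["neuron"], NeuronParams.__dataclass_fields__, "neuron")
            d["neuron"] = NeuronParams(**d["neuron"])
        if "inputs" in d and isinstance(d["inputs"], dict):
            _check_keys(d["inputs"], InputSpec.__dataclass_fields__, "inputs")
            d["inputs"] = InputSpec(**d["inputs"])
        if "bounds" in d and isinstance(d["bounds"], dict):
            _check_keys(d["bounds"], BoundsPolicy.__dataclass_fields__, "bounds")
            d["bounds"] = BoundsPolicy(**d["bounds"])
        cfg = cls(**d)
        if cfg.rule is None and cfg.rule_preset not in RULE_PRESETS:
            raise ValueError(
                f"unknown rule preset {cfg.rule_preset!r}; "
                f"valid presets: {sorted(RULE_PRESETS)}"
            )
        if cfg.rule is not None:
            _rule_from_dict(cfg.rule)  # validate eagerly
        return cfg

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _check_keys(d: dict, fields, section: str) -> None:
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in config section {section!r}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty file yields all defaults (the standard operating point:
    tau_m = 20 ms, V_th = -40 mV, V_r = -60 mV, tau_s = 5 ms, N_ex = 1000,
    N_in = 250, w_in = 1 mV, 10 Hz input rates).  Unknown keys raise a
    descriptive error.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.from_dict(data)
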