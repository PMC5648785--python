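"""Parameter schema and loader for the four-population thalamocortical model.

The model lumps cortex (pyramidal PY, interneuron IN) and thalamus
(thalamocortical relay TC, reticular RE) into four mean-field populations.
All parameters carry explicit units: time in seconds, potentials in mV,
firing densities in pulses per second (pps), capacitance in uF and
conductance in mS (so g/C has units 1/s).

Validation is key-level: a bad entry in a parameter file raises a
``ParameterError`` naming the offending key and the violated constraint.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

__all__ = [
    "ParameterError",
    "PopulationParams",
    "SynapseParams",
    "GababActivationParams",
    "BurstParams",
    "NetworkParams",
    "Coupling",
    "ModelParameters",
    "load_parameters",
    "default_parameters",
    "default_parameter_path",
]

POPULATIONS = ("PY", "IN", "TC", "RE")
SYN_TYPES = ("AMPA", "GABA_A", "GABA_B")

#: every (target population, synapse type) pair that carries a conductance
#: filter in the model, in canonical state-vector order.
FILTER_SLOTS = (
    ("PY", "AMPA"),
    ("PY", "GABA_A"),
    ("PY", "GABA_B"),
    ("IN", "AMPA"),
    ("TC", "AMPA"),
    ("TC", "GABA_A"),
    ("TC", "GABA_B"),
    ("RE", "AMPA"),
    ("RE", "GABA_A"),
)

#: admissible presynaptic sources: the four populations plus the three
#: external drives.
SOURCES = POPULATIONS + ("sensory", "cortical", "reticular")


class ParameterError(ValueError):
    """Invalid model parameter; message names the offending key."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class PopulationParams(_Strict):
    """Membrane and tonic-firing constants of one population.

    ``C_m`` membrane capacitance (uF); ``g_leak`` leak conductance (mS);
    ``V_leak`` leak reversal (mV); ``G_F`` maximal tonic firing rate (pps);
    ``theta_F`` sigmoid threshold (mV); ``nu_F`` sigmoid slope (1/mV,
    negative for firing that grows with depolarisation).
    """

    C_m: float
    g_leak: float
    V_leak: float
    G_F: float
    theta_F: float
    nu_F: float

    @model_validator(mode="after")
    def _check(self):
        if not self.C_m > 0:
            raise ValueError("C_m must be > 0")
        if self.g_leak < 0:
            raise ValueError("g_leak must be >= 0")
        if not self.G_F > 0:
            raise ValueError("G_F must be > 0")
        return self


class SynapseParams(_Strict):
    """Bi-exponential synaptic kernel h(t) = A [exp(-a1 t) - exp(-a2 t)].

    ``A`` amplitude (mS/pps scaled); ``a1`` decay rate, ``a2`` rise rate
    (1/s) with the order constraint a2 > a1 > 0; ``V_rev`` reversal
    potential (mV); ``syn_type`` one of AMPA / GABA_A / GABA_B.
    """

    A: float
    a1: float
    a2: float
    V_rev: float
    syn_type: Literal["AMPA", "GABA_A", "GABA_B"]

    @model_validator(mode="after")
    def _check(self):
        if not self.a1 > 0:
            raise ValueError("a1 must be > 0")
        if not self.a2 > self.a1:
            raise ValueError("kernel order constraint violated: requires a2 > a1")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        return self


class GababActivationParams(_Strict):
    """Sigmoidal recruitment of the slow GABA_B conductance.

    B(F) = 1 / (1 + exp(nu_B (F - theta_B))) with presynaptic rate F in
    pps; ``nu_B`` < 0 makes recruitment grow with presynaptic firing.
    """

    theta_B: float
    nu_B: float


class BurstParams(_Strict):
    """Low-threshold burst firing of a thalamic population.

    F_B(V) = G_B * m_inf(V) * [h_n * n_inf(V)](t) where h_n is a unit-area
    bi-exponential kernel with decay ``n1`` and rise ``n2`` (1/s, n2 > n1).
    m_inf gates the burst at depolarised potentials (nu_m < 0), n_inf
    de-inactivates with hyperpolarisation (nu_n > 0).
    """

    G_B: float
    n1: float
    n2: float
    theta_m: float
    nu_m: float
    theta_n: float
    nu_n: float

    @model_validator(mode="after")
    def _check(self):
        if not self.n1 > 0:
            raise ValueError("n1 must be > 0")
        if not self.n2 > self.n1:
            raise ValueError("burst kernel order constraint violated: requires n2 > n1")
        if not self.G_B > 0:
            raise ValueError("G_B must be > 0")
        return self


class Coupling(_Strict):
    """One directed pathway: ``source`` firing density (or external drive)
    feeding the ``target``/``syn_type`` conductance filter with mean
    synaptic-contact count ``value`` (dimensionless, >= 0).
    ``delayed`` marks the inter-module conduction-delayed pathways.
    """

    source: str
    target: str
    syn_type: Literal["AMPA", "GABA_A", "GABA_B"]
    value: float
    delayed: bool = False

    @model_validator(mode="after")
    def _check(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.target not in POPULATIONS:
            raise ValueError(f"unknown target {self.target!r}")
        if (self.target, self.syn_type) not in FILTER_SLOTS:
            raise ValueError(
                f"no conductance filter for {self.target}.{self.syn_type}"
            )
        if self.value < 0:
            raise ValueError("coupling value must be >= 0")
        return self


class NetworkParams(_Strict):
    """Inter-module conduction delays (s, >= 0)."""

    delay_cortex_to_thalamus: float = 0.0
    delay_thalamus_to_cortex: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.delay_cortex_to_thalamus < 0 or self.delay_thalamus_to_cortex < 0:
            raise ValueError("delays must be >= 0")
        return self


class ModelParameters(_Strict):
    """Complete parameter set of the thalamocortical model."""

    name: str = "unnamed"
    populations: dict[str, PopulationParams]
    synapses: dict[str, SynapseParams]  # keyed "TARGET.SYNTYPE"
    couplings: dict[str, Coupling]  # keyed c1 ... c13 (any names accepted)
    gabab_activation: dict[str, GababActivationParams]  # keyed by target pop
    burst: dict[str, BurstParams]  # keyed TC / RE
    network: NetworkParams = NetworkParams()

    @model_validator(mode="after")
    def _check(self):
        missing = [p for p in POPULATIONS if p not in self.populations]
        if missing:
            raise ValueError(f"populations missing entries for {missing}")
        for key, syn in self.synapses.items():
            try:
                target, syn_type = key.split(".")
            except ValueError:
                raise ValueError(f"synapses key {key!r} must be 'TARGET.SYNTYPE'")
            if (target, syn_type) not in FILTER_SLOTS:
                raise ValueError(f"synapses key {key!r} is not a model filter slot")
            if syn.syn_type != syn_type:
                raise ValueError(f"synapses[{key!r}].syn_type inconsistent with key")
        for name, c in self.couplings.items():
            slot = f"{c.target}.{c.syn_type}"
            if slot not in self.synapses:
                raise ValueError(
                    f"couplings[{name!r}] targets {slot} which has no synapse entry"
                )
        for pop in self.gabab_activation:
            if pop not in POPULATIONS:
                raise ValueError(f"gabab_activation key {pop!r} is not a population")
        # every GABA_B filter slot that is wired must have an activation entry
        for name, c in self.couplings.items():
            if c.syn_type == "GABA_B" and c.target not in self.gabab_activation:
                raise ValueError(
                    f"couplings[{name!r}] drives {c.target}.GABA_B but "
                    f"gabab_activation has no entry for {c.target}"
                )
        for pop in self.burst:
            if pop not in ("TC", "RE"):
                raise ValueError("burst entries are only defined for TC and RE")
        return self

    @property
    def max_delay(self) -> float:
        return max(
            self.network.delay_cortex_to_thalamus,
            self.network.delay_thalamus_to_cortex,
        )

    def digest(self) -> str:
        """Stable content hash of the parameter set."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace_coupling(self, name: str, value: float) -> "ModelParameters":
        data = self.model_dump()
        data["couplings"][name]["value"] = value
        return ModelParameters(**data)


def _format_validation_error(err: ValidationError, context: str) -> str:
    lines = [f"invalid parameters in {context}:"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        lines.append(f"  key '{loc}': {e['msg']}")
    return "\n".join(lines)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and validate a YAML parameter file.

    Raises ``ParameterError`` naming the offending key on any violated
    invariant (e.g. a synaptic kernel with a2 <= a1).
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: parameter file must be a mapping")
    raw.pop("units", None)
    raw.pop("notes", None)
    raw.pop("version", None)
    try:
        return ModelParameters(**raw)
    except ValidationError as err:
        raise ParameterError(_format_validation_error(err, str(path))) from None


def default_parameter_path() -> Path:
    return Path(
        resources.files("thalamodyn").joinpath("data/thalamocortical_default.yaml")  # type: ignore[arg-type]
    )


def default_parameters() -> ModelParameters:
    """The packaged default thalamocortical parameter set."""
    return load_parameters(default_parameter_path())
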