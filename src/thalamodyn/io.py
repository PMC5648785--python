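"""Run configuration, result serialisation and provenance manifests.

A run is described by a YAML config with exactly one experiment block
(simulate / scan-bias / scan-frequency / sweep / transitions / mle).
Outputs are delimited tabular text plus a JSON manifest recording config
and parameter digests and per-file checksums, so a run can be
reproduced and verified byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .integrate import IntegrationSettings, integrate
from .metrics import max_lyapunov
from .model import build_system, equilibrium_state, settled_equilibrium
from .params import ModelParameters, default_parameters, load_parameters
from .scan import (
    FrequencyResponse,
    ScanResult,
    ScanSpec,
    bias_scan_bidirectional,
    detect_jumps,
    hysteresis_region,
    model_scan_problem,
    run_scan,
    sweep_frequency_response,
    transition_protocol,
)
from .stimuli import FrequencySchedule, StimulusSet, StimulusSpec

__all__ = [
    "RunConfig",
    "RunManifest",
    "load_config",
    "run_experiment",
    "shipped_reproduction_configs",
    "trajectory_frame",
    "scan_frame",
]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StimulusBlock(_Strict):
    sensory: dict = Field(default_factory=dict)
    cortical: dict = Field(default_factory=dict)
    reticular_bias: float = 0.0
    schedule: list[tuple[float, float]] | None = None
    schedule_channel: Literal["sensory", "cortical"] | None = None

    def build(self) -> StimulusSet:
        return StimulusSet(
            sensory=StimulusSpec(**self.sensory),
            cortical=StimulusSpec(**self.cortical),
            reticular_bias=self.reticular_bias,
            schedule=FrequencySchedule(self.schedule) if self.schedule else None,
            schedule_channel=self.schedule_channel,
        )


class IntegrationBlock(_Strict):
    rtol: float = 1e-6
    atol: float = 1e-8
    sample_dt: float = 1e-3
    max_step: float = float("inf")

    def build(self) -> IntegrationSettings:
        return IntegrationSettings(
            rtol=self.rtol, atol=self.atol,
            sample_dt=self.sample_dt, max_step=self.max_step,
        )


class SimulateBlock(_Strict):
    kind: Literal["simulate"]
    duration: float = 30.0
    initial: Literal["equilibrium", "leak"] = "equilibrium"


class ScanBiasBlock(_Strict):
    kind: Literal["scan-bias"]
    channel: Literal["cortical", "sensory", "reticular"]
    start: float
    stop: float
    step: float = 0.1
    duration: float = 20.0
    probe: bool = False


class ScanFrequencyBlock(_Strict):
    kind: Literal["scan-frequency"]
    channel: Literal["cortical", "sensory"]
    start: float
    stop: float
    step: float = 0.1
    duration: float = 20.0
    compute_mle: bool = True
    mle_horizon: float = 24.0


class SweepBlock(_Strict):
    kind: Literal["sweep"]
    channel: Literal["cortical", "sensory"]
    start: float
    stop: float
    step: float = 0.1
    duration: float = 20.0
    directions: list[Literal["forward", "backward"]] = Field(
        default_factory=lambda: ["forward", "backward"]
    )


class TransitionsBlock(_Strict):
    kind: Literal["transitions"]
    duration: float = 60.0
    segment_transient: float = 5.0


class MleBlock(_Strict):
    kind: Literal["mle"]
    horizon: float = 60.0
    renorm_interval: float = 0.5
    transient: float = 10.0
    d0: float = 1e-6


_EXPERIMENT_TYPES = {
    "simulate": SimulateBlock,
    "scan-bias": ScanBiasBlock,
    "scan-frequency": ScanFrequencyBlock,
    "sweep": SweepBlock,
    "transitions": TransitionsBlock,
    "mle": MleBlock,
}


class RunConfig(_Strict):
    """One reproducible run: model parameters, stimuli, integration
    settings, exactly one experiment block, output directory and seed."""

    parameters: str = "default"  # path to a parameter file or "default"
    stimuli: StimulusBlock = Field(default_factory=StimulusBlock)
    integration: IntegrationBlock = Field(default_factory=IntegrationBlock)
    experiment: dict
    output_dir: str = "runs"
    seed: int = 0

    def load_parameters(self) -> ModelParameters:
        if self.parameters == "default":
            return default_parameters()
        return load_parameters(self.parameters)

    def experiment_block(self):
        kind = self.experiment.get("kind")
        if kind not in _EXPERIMENT_TYPES:
            raise ConfigError(
                f"unknown experiment kind {kind!r}; valid kinds: "
                f"{sorted(_EXPERIMENT_TYPES)}"
            )
        try:
            return _EXPERIMENT_TYPES[kind](**self.experiment)
        except ValidationError as err:
            raise ConfigError(_fmt_validation(err, f"experiment ({kind})")) from None

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class RunManifest(BaseModel):
    config_digest: str
    params_digest: str
    software_version: str
    created: str
    seed: int
    outputs: dict[str, str]  # filename -> sha256


def _fmt_validation(err: ValidationError, context: str) -> str:
    lines = [f"invalid config in {context}:"]
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"])
        lines.append(f"  key '{loc}': {e['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; errors name the offending key."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as err:
        raise ConfigError(_fmt_validation(err, str(path))) from None
    cfg.experiment_block()  # validate the experiment block eagerly
    if cfg.parameters != "default" and not Path(cfg.parameters).exists():
        raise ConfigError(f"parameter file not found: {cfg.parameters}")
    return cfg


# ---------------------------------------------------------------------------
# tabular serialisation
# ---------------------------------------------------------------------------


def trajectory_frame(traj) -> pd.DataFrame:
    cols = {"time": traj.t}
    if traj.y.shape[1] >= 4:
        for i, name in enumerate(("V_PY", "V_IN", "V_TC", "V_RE")):
            cols[name] = traj.y[:, i]
    else:
        cols["output"] = traj.output
    cols["V_c_derivative"] = traj.d_output
    return pd.DataFrame(cols)


def scan_frame(result: ScanResult) -> pd.DataFrame:
    rows = []
    for r in result.records:
        rows.append(
            {
                "value": r.value,
                "amplitude": r.amplitude,
                "extrema": ";".join(
                    f"{v:.6g}" for v in r.extrema.cluster_representatives()
                ),
                "mle": r.mle if r.mle is not None else np.nan,
                "label": str(r.label),
            }
        )
    return pd.DataFrame(rows)


def response_frame(resp: FrequencyResponse) -> pd.DataFrame:
    return pd.DataFrame(
        {"frequency": resp.frequencies, "amplitude": resp.amplitudes,
         "direction": resp.direction}
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    # full double precision so re-runs diff cleanly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step))
    return tuple(np.round(start + step * np.arange(n + 1), 10))


def run_experiment(config: RunConfig, output_dir: str | Path | None = None) -> RunManifest:
    """Execute the config's experiment; write tables + manifest.

    Deterministic: re-running the same config reproduces byte-identical
    numeric tables.
    """
    from . import __version__

    params = config.load_parameters()
    stimuli = config.stimuli.build()
    settings = config.integration.build()
    block = config.experiment_block()
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}
    extra: dict = {}

    if isinstance(block, SimulateBlock):
        system = build_system(params, stimuli)
        y0 = (
            settled_equilibrium(params, stimuli)
            if block.initial == "equilibrium"
            else equilibrium_state(params)
        )
        traj = integrate(system, y0, (0.0, block.duration), settings)
        outputs["trajectory.tsv"] = trajectory_frame(traj)

    elif isinstance(block, ScanBiasBlock):
        grid = _grid(block.start, block.stop, block.step)
        fwd, bwd, rmap = bias_scan_bidirectional(
            params, stimuli, f"{block.channel}.bias", grid,
            settings=settings, probe=block.probe,
            min_duration=block.duration, seed=config.seed,
        )
        outputs["scan_forward.tsv"] = scan_frame(fwd)
        outputs["scan_backward.tsv"] = scan_frame(bwd)
        extra["regime_map"] = [
            {"lo": lo, "hi": hi, "class": cls} for lo, hi, cls in rmap.intervals
        ]

    elif isinstance(block, ScanFrequencyBlock):
        problem = model_scan_problem(
            params, stimuli, f"{block.channel}.frequency", settings
        )
        spec = ScanSpec(
            f"{block.channel}.frequency",
            _grid(block.start, block.stop, block.step),
            compute_mle=block.compute_mle,
            min_duration=block.duration,
            mle_horizon=block.mle_horizon,
            seed=config.seed,
        )
        result = run_scan(problem, spec)
        outputs["bifurcation_scan.tsv"] = scan_frame(result)

    elif isinstance(block, SweepBlock):
        problem = model_scan_problem(
            params, stimuli, f"{block.channel}.frequency", settings
        )
        grid = _grid(block.start, block.stop, block.step)
        responses = {}
        for direction in block.directions:
            resp = sweep_frequency_response(
                problem, grid, direction,
                min_duration=block.duration, seed=config.seed,
            )
            responses[direction] = resp
            outputs[f"response_{direction}.tsv"] = response_frame(resp)
            extra[f"jumps_{direction}"] = [
                {"frequency": j.frequency, "direction": j.direction,
                 "ratio": j.ratio}
                for j in detect_jumps(resp)
            ]
        if {"forward", "backward"} <= set(responses):
            extra["hysteresis_intervals"] = hysteresis_region(
                responses["forward"], responses["backward"]
            )

    elif isinstance(block, TransitionsBlock):
        traj, reports = transition_protocol(
            params, stimuli, block.duration,
            segment_transient=block.segment_transient, settings=settings,
        )
        outputs["trajectory.tsv"] = trajectory_frame(traj)
        outputs["segments.tsv"] = pd.DataFrame(
            [
                {
                    "t_start": r.t_start, "t_end": r.t_end,
                    "frequency": r.frequency, "label": str(r.label),
                    "amplitude": r.amplitude if r.amplitude is not None else np.nan,
                }
                for r in reports
            ]
        )

    elif isinstance(block, MleBlock):
        system = build_system(params, stimuli)
        y0 = settled_equilibrium(params, stimuli)
        lam = max_lyapunov(
            system, y0, horizon=block.horizon,
            renorm_interval=block.renorm_interval, d0=block.d0,
            seed=config.seed, transient=block.transient, settings=settings,
        )
        extra["max_lyapunov"] = lam

    file_hashes: dict[str, str] = {}
    for name, df in outputs.items():
        path = outdir / name
        _write(df, path)
        file_hashes[name] = _sha256(path)
    if extra:
        path = outdir / "results.json"
        path.write_text(json.dumps(extra, indent=2, default=float))
        file_hashes["results.json"] = _sha256(path)

    manifest = RunManifest(
        config_digest=config.digest(),
        params_digest=params.digest(),
        software_version=__version__,
        created=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        seed=config.seed,
        outputs=file_hashes,
    )
    (outdir / "manifest.json").write_text(manifest.model_dump_json(indent=2))
    return manifest


# ---------------------------------------------------------------------------
# shipped reproduction configs
# ---------------------------------------------------------------------------


def shipped_reproduction_configs() -> dict[str, RunConfig]:
    """Named configs for the model's canonical experiments.

    Constants: the driven-scan operating point uses biases (cortical,
    sensory, reticular) = (13.5, 11, 12) pps; the transition protocols
    run with zero sensory amplitude; the sensory sweeps sit at cortical
    bias 12 pps with zero cortical amplitude; all grids step 0.1 (pps or
    Hz).
    """
    operating = dict(
        sensory={"bias": 11.0}, cortical={"bias": 13.5}, reticular_bias=12.0
    )
    configs = {
        "bias-scans": RunConfig(
            stimuli=StimulusBlock(**operating),
            experiment={
                "kind": "scan-bias", "channel": "cortical",
                "start": 10.0, "stop": 18.0, "step": 0.1,
            },
        ),
        "frequency-bifurcations": RunConfig(
            stimuli=StimulusBlock(
                sensory={"bias": 11.0},
                cortical={"bias": 13.5, "amplitude": 1.0, "frequency": 5.0},
                reticular_bias=12.0,
            ),
            experiment={
                "kind": "scan-frequency", "channel": "cortical",
                "start": 5.0, "stop": 15.0, "step": 0.1,
            },
        ),
        "frequency-transitions": RunConfig(
            stimuli=StimulusBlock(
                sensory={"bias": 11.0},
                cortical={"bias": 13.5, "amplitude": 1.0, "frequency": 11.0},
                reticular_bias=12.0,
                schedule=[(0.0, 11.0), (20.0, 9.0), (40.0, 11.0)],
                schedule_channel="cortical",
            ),
            experiment={"kind": "transitions", "duration": 60.0},
        ),
        "frequency-sweeps": RunConfig(
            stimuli=StimulusBlock(
                sensory={"bias": 11.0, "amplitude": 0.3, "frequency": 5.0},
                cortical={"bias": 12.0},
                reticular_bias=12.0,
            ),
            experiment={
                "kind": "sweep", "channel": "sensory",
                "start": 5.0, "stop": 15.0, "step": 0.1,
            },
        ),
    }
    return configs
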