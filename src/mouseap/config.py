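"""Run configuration, serialization and provenance.

A :class:`RunConfig` fully determines a simulation (the pipeline contains
no randomness), so re-running a serialized config reproduces its outputs.
``run`` executes the configured protocol and writes a summary CSV, optional
trace CSVs, and a provenance JSON recording parameter-file hashes and
solver settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cell, protocols
from .drugs import DrugSpec, MECHANISMS

_PROTOCOLS = ("clamp", "pace", "bcl_scan", "s1s2", "dose_response")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """A fully serializable simulation request."""

    protocol: str
    variant: str = "endocardial"
    drug: str | None = None          # "C" | "O" | None
    dose_mM: float = 0.0
    channel: str = "iktof"           # clamp protocols only
    segments: tuple = protocols.BLOCK_CLAMP
    bcl: float = 1000.0
    bcls: tuple = protocols.BCL_SET
    s1_bcl: float = 1000.0
    s2_intervals: tuple = protocols.S2_SET
    doses: tuple = protocols.DOSE_GRID
    metric: str = "area"             # dose_response: area | peak | apd50_prolongation
    n_beats: int = 1000
    fast: bool = False               # reduced pre-pacing with convergence flag
    rtol: float = 1e-6
    atol: float = 1e-8
    write_traces: bool = False
    outdir: str = "results"

    def __post_init__(self):
        if self.protocol not in _PROTOCOLS:
            raise ConfigError(
                f"field 'protocol': unknown value {self.protocol!r}; "
                f"expected one of {_PROTOCOLS}"
            )
        if self.variant not in cell.VARIANTS:
            raise ConfigError(f"field 'variant': unknown value {self.variant!r}")
        if self.drug is not None and self.drug.upper() not in ("C", "O"):
            raise ConfigError(
                f"field 'drug': unknown mechanism {self.drug!r}; expected C, O or null"
            )
        if self.dose_mM < 0:
            raise ConfigError("field 'dose_mM': must be >= 0")
        if self.n_beats < 1:
            raise ConfigError("field 'n_beats': must be >= 1")

    @property
    def effective_beats(self) -> int:
        return min(self.n_beats, 100) if self.fast else self.n_beats

    def drug_spec(self) -> DrugSpec | None:
        if self.drug is None or self.dose_mM == 0:
            return None
        return DrugSpec.from_name(self.drug, self.dose_mM)

    def solver(self) -> cell.Solver:
        return cell.Solver(rtol=self.rtol, atol=self.atol)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["segments"] = [[float(x) for x in s] for s in self.segments]
        for k in ("bcls", "s2_intervals", "doses"):
            d[k] = [float(x) for x in d[k]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "segments" in d:
            d["segments"] = tuple(tuple(s) for s in d["segments"])
        for k in ("bcls", "s2_intervals", "doses"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def parameter_hashes() -> dict[str, str]:
    out = {}
    root = resources.files("mouseap.params")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            out[entry.name] = hashlib.sha256(entry.read_bytes()).hexdigest()[:16]
    return out


def provenance_block(config: RunConfig) -> dict:
    from . import __version__

    return {
        "package_version": __version__,
        "parameter_file_sha256_16": parameter_hashes(),
        "solver": {"rtol": config.rtol, "atol": config.atol,
                   "method": "adaptive Dormand-Prince 4(5)"},
        "n_beats": config.effective_beats,
        "fast_mode": config.fast,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }


def run(config: RunConfig) -> dict:
    """Execute a configured protocol; write summary CSV + provenance JSON.

    Returns ``{"summary": DataFrame, "paths": {...}}``. Partial outputs are
    removed if the run fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    drug = config.drug_spec()
    solver = config.solver()
    try:
        if config.protocol == "clamp":
            tr = protocols.clamp_channel(
                config.channel, config.segments, variant=config.variant, drug=drug
            )
            summary = tr.to_frame()
        elif config.protocol == "pace":
            res = cell.run_to_steady_pacing(
                config.variant, bcl=config.bcl, n_beats=config.effective_beats,
                drug=drug, solver=solver,
            )
            summary = res.trace.to_frame()
            summary.attrs["converged"] = res.converged
        elif config.protocol == "bcl_scan":
            summary = protocols.bcl_scan(
                config.variant, drug=drug, bcls=config.bcls,
                n_beats=config.effective_beats, solver=solver,
            )
        elif config.protocol == "s1s2":
            summary = protocols.s1s2_restitution(
                config.variant, drug=drug, s1_bcl=config.s1_bcl,
                s2_intervals=config.s2_intervals,
                n_beats=config.effective_beats, solver=solver,
            )
        else:  # dose_response
            if config.drug is None:
                raise ConfigError("dose_response requires field 'drug' (C or O)")
            dr = protocols.dose_scan(
                config.variant, config.drug, doses=config.doses,
                metric=config.metric,
                **({"n_beats": config.effective_beats, "solver": solver}
                   if config.metric == "apd50_prolongation" else {}),
            )
            summary = pd.DataFrame({"dose_mM": dr.doses, "response": dr.responses})
            summary.attrs["half_max_dose_mM"] = dr.half_max_dose

        csv_path = outdir / f"{config.protocol}_summary.csv"
        summary.to_csv(csv_path, index=False)
        written.append(csv_path)
        prov = provenance_block(config)
        for key, value in summary.attrs.items():
            prov[key] = value
        prov_path = outdir / f"{config.protocol}_provenance.json"
        prov_path.write_text(json.dumps(prov, indent=2, default=float))
        written.append(prov_path)
        return {"summary": summary, "paths": {p.name: p for p in written}}
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
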