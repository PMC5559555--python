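"""Configuration, file I/O and the end-to-end regression pipeline.

Run configurations serialise to flat ``key = value`` text so that any
result can be reproduced from its config file alone; every report embeds
the configuration hash.  The pipeline executes the main workflow stages
in order (fixtures -> channel presets -> conductance calibration ->
single cells -> strand ECG) and writes a machine-readable JSON report
plus CSV tables, comparing the recomputed quantities against the
packaged regression references with data-driven tolerances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .fixtures import FixtureConfig, FixtureSet, generate_fixtures

__all__ = [
    "RunConfig",
    "load_config",
    "generate_fixtures",
    "run_pipeline",
    "REGRESSION_REFERENCE",
]

#: regression reference values recomputed by the pipeline (package's own
#: frozen outputs, ms unless noted) with absolute tolerances
REGRESSION_REFERENCE: Dict[str, Dict[str, float]] = {
    "apd90.EPI.WT": {"value": 325.6, "tol": 2.0},
    "apd90.EPI.WT-V307L": {"value": 233.9, "tol": 2.0},
    "apd90.EPI.V307L": {"value": 192.0, "tol": 2.0},
    "apd90.MIDDLE.WT": {"value": 435.4, "tol": 2.0},
    "apd90.MIDDLE.WT-V307L": {"value": 362.0, "tol": 2.0},
    "apd90.MIDDLE.V307L": {"value": 312.8, "tol": 2.0},
    "apd90.ENDO.WT": {"value": 326.0, "tol": 2.0},
    "apd90.ENDO.WT-V307L": {"value": 231.8, "tol": 2.0},
    "apd90.ENDO.V307L": {"value": 187.9, "tol": 2.0},
    "qt.WT": {"value": 382.0, "tol": 4.0},
    "qt.WT-V307L": {"value": 294.0, "tol": 4.0},
    "qt.V307L": {"value": 250.0, "tol": 4.0},
}


@dataclass
class RunConfig:
    """Reproducible description of one pipeline run."""

    module: str = "pipeline"
    genotype: str = "WT"
    cell_type: str = "EPI"
    bcl: float = 1000.0
    n_beats: int = 50
    dt: float = 0.02
    dx: float = 0.2
    seed: int = 0
    out_dir: str = "results"
    fixture: FixtureConfig = field(default_factory=FixtureConfig)

    def to_text(self) -> str:
        lines = []
        for k, v in asdict(self).items():
            if isinstance(v, dict):
                for kk, vv in v.items():
                    lines.append(f"fixture.{kk} = {vv}")
            else:
                lines.append(f"{k} = {v}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    def hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    if value in ("True", "False"):
        return value == "True"
    if value == "None":
        return None
    return value


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file."""
    fields: Dict[str, object] = {}
    fixture: Dict[str, object] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key.startswith("fixture."):
            fixture[key[len("fixture."):]] = _coerce(value)
        else:
            fields[key] = _coerce(value)
    cfg = RunConfig(**fields)  # type: ignore[arg-type]
    if fixture:
        cfg.fixture = FixtureConfig(**fixture)  # type: ignore[arg-type]
    return cfg


def run_pipeline(config: Optional[RunConfig] = None,
                 with_strand: bool = True,
                 verbose: bool = True) -> Dict[str, object]:
    """Execute fixtures -> calibration -> cells (-> strand) and report.

    Returns the report dict (also written to ``<out_dir>/report.json``
    with CSV tables); ``report["passed"]`` reflects the regression
    comparison against :data:`REGRESSION_REFERENCE`.
    """
    from .calibrate import calibrated_constants
    from .tnnp2006 import PacingSpec
    from .ventricle_cell import pace, apd90
    from .strand_ecg import StrandSpec, simulate_strand, pseudo_ecg, \
        ecg_metrics

    config = config or RunConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: Dict[str, object] = {"config_hash": config.hash(),
                                 "values": {}, "failures": []}
    values: Dict[str, float] = report["values"]  # type: ignore[assignment]

    def log(msg: str) -> None:
        if verbose:
            print(msg)

    log("stage: fixtures")
    fixtures = generate_fixtures(config.fixture)
    fixtures.write(out / "fixtures")

    log("stage: calibration constants")
    constants = calibrated_constants()
    values.update({f"constant.{k}": float(v) for k, v in constants.items()})

    log("stage: single-cell APDs")
    rows = []
    for ct in ("EPI", "MIDDLE", "ENDO"):
        for gt in ("WT", "WT-V307L", "V307L"):
            tr = pace(ct, gt, PacingSpec(config.bcl, config.n_beats))
            a = apd90(tr)
            values[f"apd90.{ct}.{gt}"] = round(float(a), 1)
            rows.append({"cell_type": ct, "genotype": gt, "apd90_ms": a})
            log(f"  {ct:7s} {gt:9s} APD90 = {a:6.1f} ms")
    pd.DataFrame(rows).to_csv(out / "apd90.csv", index=False)

    if with_strand:
        log("stage: strand pseudo-ECG")
        rows = []
        for gt in ("WT", "WT-V307L", "V307L"):
            met = ecg_metrics(pseudo_ecg(simulate_strand(
                StrandSpec(dx=config.dx), gt)))
            values[f"qt.{gt}"] = round(float(met.qt), 1)
            values[f"t_width.{gt}"] = round(float(met.t_width), 1)
            values[f"t_amplitude.{gt}"] = float(met.t_amplitude)
            rows.append({"genotype": gt, "qt_ms": met.qt,
                         "t_width_ms": met.t_width,
                         "t_amplitude": met.t_amplitude})
            log(f"  {gt:9s} QT = {met.qt:5.1f} ms, "
                f"Tpeak-Tend = {met.t_width:4.1f} ms")
        pd.DataFrame(rows).to_csv(out / "ecg_metrics.csv", index=False)

    for key, ref in REGRESSION_REFERENCE.items():
        if key not in values:
            continue
        if abs(values[key] - ref["value"]) > ref["tol"]:
            report["failures"].append(  # type: ignore[union-attr]
                f"{key}: {values[key]} vs reference {ref['value']} "
                f"(tol {ref['tol']})")
    report["passed"] = not report["failures"]
    (out / "report.json").write_text(json.dumps(report, indent=1))
    log(f"report: {out / 'report.json'} (passed={report['passed']})")
    return report
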