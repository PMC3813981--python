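"""Config parsing, trial-summary serialisation and the bundled example.

Trial summaries travel either as a JSON/YAML config block::

    design: {k: 3, n1: 71, n2: 71, sigma: 6.0, b: 0.0}
    stage1_means: [-0.082, 0.413, 1.766, 1.567]
    stage2_means: {control: 0.049, selected: 1.451}

or as a flat CSV with columns (arm, stage, mean, n); ``arm`` 0 is the
control.  Omitting ``b`` means "no futility gate" (-inf) and is logged
prominently.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from importlib import resources
from pathlib import Path

import yaml

from .design import DesignConfig, ParameterVector, TrialData

__all__ = [
    "load_example",
    "example_truth",
    "parse_design",
    "parse_trial_config",
    "load_trial",
    "trial_to_csv",
    "trial_from_csv",
    "trial_to_config",
]

log = logging.getLogger("seamest")

_DESIGN_KEYS = {"k", "n1", "n2", "sigma", "b"}


def parse_design(block: dict) -> DesignConfig:
    """Validate and build a :class:`DesignConfig` from a mapping."""
    if not isinstance(block, dict):
        raise ValueError("design block must be a mapping")
    unknown = set(block) - _DESIGN_KEYS
    if unknown:
        raise ValueError(f"unknown design key(s): {sorted(unknown)}")
    missing = {"k", "n1", "n2", "sigma"} - set(block)
    if missing:
        raise ValueError(f"missing design key(s): {sorted(missing)}")
    b = block.get("b", None)
    if b is None:
        log.warning("futility boundary 'b' omitted: defaulting to -inf (no gate)")
        b = -math.inf
    elif isinstance(b, str):
        b = float(b)
    return DesignConfig(k=int(block["k"]), n1=int(block["n1"]), n2=int(block["n2"]),
                        sigma=float(block["sigma"]), b=float(b))


def parse_trial_config(cfg: dict) -> TrialData:
    """Build a :class:`TrialData` from a parsed JSON/YAML mapping."""
    allowed = {"design", "stage1_means", "stage2_means", "comment", "true_means"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    design = parse_design(cfg.get("design", {}))
    x = cfg.get("stage1_means")
    if x is None:
        raise ValueError("missing key: stage1_means")
    s2 = cfg.get("stage2_means")
    y0 = yS = None
    if s2 is not None:
        unknown2 = set(s2) - {"control", "selected"}
        if unknown2:
            raise ValueError(f"unknown stage2_means key(s): {sorted(unknown2)}")
        y0, yS = float(s2["control"]), float(s2["selected"])
    return TrialData(design=design, x=[float(v) for v in x], y0=y0, yS=yS)


def load_trial(path: str | Path) -> TrialData:
    """Load a trial config from a .json/.yaml/.yml file."""
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_trial_config(cfg)


def trial_to_config(trial: TrialData) -> dict:
    d = trial.design
    cfg = {
        "design": {"k": d.k, "n1": d.n1, "n2": d.n2, "sigma": d.sigma,
                   "b": d.b if math.isfinite(d.b) else None},
        "stage1_means": [float(v) for v in trial.x],
    }
    if cfg["design"]["b"] is None:
        del cfg["design"]["b"]
    if trial.continued:
        cfg["stage2_means"] = {"control": trial.y0, "selected": trial.yS}
    return cfg


def trial_to_csv(trial: TrialData, path: str | Path) -> None:
    """Flat CSV with columns (arm, stage, mean, n); arm 0 is the control."""
    d = trial.design
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "stage", "mean", "n"])
        for arm, mean in enumerate(trial.x):
            w.writerow([arm, 1, repr(float(mean)), d.n1])
        if trial.continued:
            w.writerow([0, 2, repr(float(trial.y0)), d.n2])
            w.writerow([trial.S, 2, repr(float(trial.yS)), d.n2])


def trial_from_csv(path: str | Path, sigma: float, b: float = -math.inf) -> TrialData:
    """Rebuild a trial from the flat CSV representation.

    The CSV carries means and sample sizes; the known outcome SD and the
    futility boundary are design inputs supplied separately.
    """
    stage1: dict[int, float] = {}
    stage2: dict[int, float] = {}
    n1 = n2 = None
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            arm, stage, mean, n = (int(row["arm"]), int(row["stage"]),
                                   float(row["mean"]), int(row["n"]))
            if stage == 1:
                stage1[arm] = mean
                n1 = n if n1 is None else n1
                if n != n1:
                    raise ValueError("unequal stage-1 allocation across arms is not supported")
            else:
                stage2[arm] = mean
                n2 = n if n2 is None else n2
                if n != n2:
                    raise ValueError("unequal stage-2 allocation across arms is not supported")
    k = len(stage1) - 1
    design = DesignConfig(k=k, n1=n1, n2=n2 if n2 is not None else 1, sigma=sigma, b=b)
    x = [stage1[a] for a in range(k + 1)]
    if stage2:
        sel = [a for a in stage2 if a != 0]
        return TrialData(design=design, x=x, y0=stage2[0], yS=stage2[sel[0]])
    return TrialData(design=design, x=x)


def _example_config() -> dict:
    text = resources.files("seamest").joinpath("data/anxiety_example.json").read_text()
    return json.loads(text)


def load_example() -> TrialData:
    """The bundled anxiety-trial worked example (see data/anxiety_example.json)."""
    return parse_trial_config(
        {k: v for k, v in _example_config().items() if k != "true_means"}
    )


def example_truth() -> ParameterVector:
    """True means used to construct the bundled example (for simulation demos)."""
    tm = _example_config()["true_means"]
    return ParameterVector(mu0=float(tm["control"]), mu=tm["experimental"])
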