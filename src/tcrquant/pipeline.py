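"""End-to-end workflow orchestration.

A :class:`RunConfig` (plain key-value mapping, usually loaded from YAML)
drives the packaged workflow: simulate a WT/mutant kinetic-proofreading
dose-response pair, fit it jointly under the shared-kp null and the
per-condition-kp alternative, run the extra-sum-of-squares F-test, and
write every intermediate table plus a machine-readable summary. All
defaults are materialised into the echoed config, so a report is fully
reproducible from its config echo alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .nested_inference import ess_f_test
from .proofreading import kp_sharing_fits
from .synthetic_data import GroundTruth, default_dose_grid, simulate_dose_response

__all__ = ["RunConfig", "run_pipeline", "write_report"]

log = logging.getLogger("tcrquant")

_DEFAULTS: dict[str, Any] = {
    "workflow": "kpr_compare",
    "seed": 1,
    "out_dir": "tcrquant_run",
    "dose_top_nm": 600.0,
    "n_doses": 10,
    "n_reps": 3,
    "noise_cv": 0.1,
    "kd_nm": 30.0,
    "koff_s": 0.85,
    "n_steps": 2.7,
    "scale": 430000.0,
    "kp_wt_s": 0.1,
    "kp_mut_s": 0.5,
    "weighted": True,
    "share_kd": True,
    "share_scale": True,
}

_NUMERIC_KEYS = (
    "seed", "dose_top_nm", "n_doses", "n_reps", "noise_cv", "kd_nm",
    "koff_s", "n_steps", "scale", "kp_wt_s", "kp_mut_s",
)


@dataclass
class RunConfig:
    """Validated, fully materialised run configuration."""

    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = {**_DEFAULTS, **self.values}
        if merged["workflow"] != "kpr_compare":
            raise ValueError(f"unknown workflow {merged['workflow']!r}")
        for key in _NUMERIC_KEYS:
            try:
                merged[key] = float(merged[key])
            except (TypeError, ValueError):
                raise ValueError(f"config key {key!r} must be numeric, got {merged[key]!r}") from None
        for key in ("seed", "n_doses", "n_reps"):
            merged[key] = int(merged[key])
        if merged["noise_cv"] < 0 or merged["koff_s"] <= 0 or merged["kd_nm"] <= 0:
            raise ValueError("noise_cv must be >= 0 and koff_s, kd_nm positive")
        self.values = merged

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a key-value mapping")
        return cls(values=data)

    def echo(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({**self.values, "version": __version__}, sort_keys=True))


def write_report(values: Mapping[str, Any], path: str | Path) -> None:
    """Write a flat key-value report, one ``key = value`` line each."""
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def _file_fingerprint(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig | Mapping[str, Any]) -> dict[str, Any]:
    """Execute the configured workflow and write its report bundle.

    Returns the summary dict (also written as JSON and key-value text in the
    output directory). Raises on any stage failure; the CLI converts that to
    a nonzero exit status.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(values=dict(config))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out / "config_echo.yaml")

    seed = config["seed"]
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=2)
    doses = default_dose_grid(config["dose_top_nm"], config["n_doses"])

    log.info("simulating WT and mutant KPR dose-response (seed=%d)", seed)
    datasets = {}
    for label, kp, sub_seed in (("WT", config["kp_wt_s"], seeds[0]), ("mut", config["kp_mut_s"], seeds[1])):
        truth = GroundTruth(
            "kpr",
            {
                "kd": config["kd_nm"],
                "kp": kp,
                "koff": config["koff_s"],
                "n_steps": config["n_steps"],
                "scale": config["scale"],
            },
            noise_cv=config["noise_cv"],
            seed=int(sub_seed),
        )
        ds = simulate_dose_response(truth, doses, n_reps=config["n_reps"], condition_label=label)
        ds.to_csv(out / f"dose_response_{label}.csv")
        datasets[label] = ds

    log.info("fitting shared-kp null and per-condition-kp alternative")
    null, alt = kp_sharing_fits(
        datasets["WT"],
        datasets["mut"],
        koff_fixed=config["koff_s"],
        n_fixed=config["n_steps"],
        share_kd=config["share_kd"],
        share_scale=config["share_scale"],
        weighted=config["weighted"],
    )
    for name, fit in (("null_shared_kp", null), ("alt_free_kp", alt)):
        report = {
            "ss_resid": fit.ss_resid,
            "df": fit.df,
            "converged": fit.converged,
            "identifiable": fit.identifiable,
            "fingerprint": fit.data_fingerprint,
            "sharing": fit.sharing_spec,
        }
        for lab, p in fit.params.items():
            report[f"kd_{lab}"] = p.kd
            report[f"kp_{lab}"] = p.kp
            report[f"scale_{lab}"] = p.scale
        write_report(report, out / f"fit_{name}.txt")

    ftest = ess_f_test(null, alt, null_label="shared kp", alt_label="per-condition kp")
    log.info("F-test: %s", ftest)

    summary = {
        "workflow": config["workflow"],
        "seed": seed,
        "f_stat": ftest.f_stat,
        "df_num": ftest.df_num,
        "df_den": ftest.df_den,
        "p_value": ftest.p_value,
        "ss_null": null.ss_resid,
        "ss_alt": alt.ss_resid,
        "input_fingerprints": {
            lab: _file_fingerprint(out / f"dose_response_{lab}.csv") for lab in datasets
        },
        "version": __version__,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    write_report(
        {k: v for k, v in summary.items() if not isinstance(v, dict)}, out / "summary.txt"
    )
    return summary
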