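"""Synthetic-data generators with known ground truth.

Every input class the analysis modules consume can be generated here with
its generating parameters recorded in the output metadata, so each
fitter/quantifier can be validated by round-trip: generate at known truth,
analyse, compare. Generators are pure functions of (truth, seed) — there is
no hidden global random state.

Noise model for intensity-like readouts (MFI, band signal): multiplicative
Gaussian parameterised by a coefficient of variation and truncated at zero,
reflecting the approximately signal-proportional spread of fluorescence
intensities; a log-normal option (same CV, mean-one) is available via
``noise_model="lognormal"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .binding_models import logistic_response, one_phase_decay, specific_binding
from .datasets import DoseResponseDataset, TimeCourseDataset
from .dsa_quant import SCHEMES, BandTable
from .localization_stats import LocalizationTable, RegionMask
from .proofreading import KPRParams, kpr_signal

__all__ = [
    "GroundTruth",
    "PointPatternTruth",
    "default_dose_grid",
    "simulate_dose_response",
    "simulate_dissociation",
    "simulate_band_table",
    "simulate_localizations",
]

_MODEL_KINDS = ("binding", "kpr", "logistic", "decay")


@dataclass(frozen=True)
class GroundTruth:
    """Generating model and parameters for a dose-response or decay dataset.

    ``params`` uses natural scales: Bmax/top/bottom/scale in response units,
    Kd/EC50 in nM, kp/koff in s^-1, N (steps) real >= 0, Hill slope
    unitless. ``noise_cv`` is the coefficient of variation of the
    multiplicative measurement noise.
    """

    model_kind: str
    params: Mapping[str, float]
    noise_cv: float = 0.1
    seed: int = 0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.model_kind not in _MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}; choose from {_MODEL_KINDS}")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError("noise_model must be 'gaussian' or 'lognormal'")
        for key in ("kd", "ec50", "koff"):
            if key in self.params and self.params[key] <= 0:
                raise ValueError(f"{key} must be positive")
        for key in ("kp", "n_steps"):
            if key in self.params and self.params[key] < 0:
                raise ValueError(f"{key} must be >= 0")

    def mean_response(self, x: np.ndarray) -> np.ndarray:
        p = dict(self.params)
        if self.model_kind == "binding":
            return specific_binding(x, p["bmax"], p["kd"], p.get("h", 1.0))
        if self.model_kind == "kpr":
            kpr = KPRParams(kd=p["kd"], kp=p["kp"], koff=p["koff"], n_steps=p["n_steps"], scale=p.get("scale", 1.0))
            return kpr_signal(x, kpr)
        if self.model_kind == "logistic":
            return logistic_response(x, p.get("bottom", 0.0), p["top"], p["ec50"], p.get("hill", 1.0))
        if self.model_kind == "decay":
            return one_phase_decay(x, p["plateau"], p["span"], p["koff"])
        raise AssertionError(self.model_kind)


def default_dose_grid(top_nm: float = 600.0, n_doses: int = 10, dilution: float = 2.0) -> np.ndarray:
    """1:2 dilution series starting at 600 nM, 10 doses (highest first)."""
    return top_nm / dilution ** np.arange(n_doses)


def _apply_noise(mean: np.ndarray, truth: GroundTruth, rng: np.random.Generator) -> np.ndarray:
    if truth.noise_cv == 0:
        return mean.copy()
    if truth.noise_model == "gaussian":
        out = mean * (1.0 + rng.normal(0.0, truth.noise_cv, size=mean.shape))
        return np.clip(out, 0.0, None)
    sigma = math.sqrt(math.log1p(truth.noise_cv**2))
    return mean * rng.lognormal(-0.5 * sigma**2, sigma, size=mean.shape)


def simulate_dose_response(
    truth: GroundTruth,
    doses: Sequence[float] | None = None,
    n_reps: int = 3,
    condition_label: str = "sim",
) -> DoseResponseDataset:
    """Simulate an MFI-like dose-response table from the generating model.

    Each record is the model mean at that dose times a multiplicative noise
    factor (see module docstring). The same ``truth`` (including seed)
    always reproduces the identical dataset; truth and seed are embedded in
    the dataset metadata.
    """
    if truth.model_kind == "decay":
        raise ValueError("use simulate_dissociation for decay time courses")
    doses = default_dose_grid() if doses is None else np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(truth.seed)
    conc = np.repeat(doses, n_reps)
    mean = truth.mean_response(conc)
    resp = _apply_noise(np.asarray(mean, dtype=float), truth, rng)
    records = pd.DataFrame(
        {
            "concentration_nm": conc,
            "response": resp,
            "replicate_id": np.tile(np.arange(n_reps), len(doses)),
        }
    )
    meta = {"model_kind": truth.model_kind, "noise_cv": truth.noise_cv, "seed": truth.seed, **dict(truth.params)}
    return DoseResponseDataset(condition_label=condition_label, records=records, metadata=meta)


def simulate_dissociation(
    truth: GroundTruth,
    times: Sequence[float],
    n_reps: int = 3,
    condition_label: str = "sim",
) -> TimeCourseDataset:
    """Simulate a one-phase dissociation time course."""
    if truth.model_kind != "decay":
        raise ValueError("simulate_dissociation requires a decay ground truth")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    rng = np.random.default_rng(truth.seed)
    t = np.repeat(times, n_reps)
    mean = truth.mean_response(t)
    resp = _apply_noise(np.asarray(mean, dtype=float), truth, rng)
    records = pd.DataFrame(
        {"time_s": t, "response": resp, "replicate_id": np.tile(np.arange(n_reps), len(times))}
    )
    meta = {"model_kind": "decay", "noise_cv": truth.noise_cv, "seed": truth.seed, **dict(truth.params)}
    return TimeCourseDataset(condition_label=condition_label, records=records, metadata=meta)


# ---------------------------------------------------------------------------
# Immunoblot band tables
# ---------------------------------------------------------------------------

#: relative abundance of the three β glycoform bands within total β
_BETA_SPLIT = {"beta1": 0.25, "beta2": 0.55, "beta3": 0.20}
_BAND_BASE_SIGNAL = 1000.0  # signal units per unit abundance at lane factor 1


def simulate_band_table(
    true_ratios: Mapping[str, float],
    n_lanes: int = 5,
    lane_scale_sd: float = 0.2,
    background_level: float = 50.0,
    seed: int = 0,
    condition_label: str = "sim",
    band_noise_cv: float = 0.0,
    blot_id: str | None = None,
) -> BandTable:
    """Simulate an immunoblot band table with known true subunit ratios.

    Subunit abundances are derived from ``true_ratios`` (keys are scheme
    names, e.g. ``{"zeta_over_beta2": 0.2}``) on top of a fixed β-glycoform
    split with β_T = 1. Each lane gets a shared loading factor
    (1 + N(0, lane_scale_sd), truncated at 0.05) applied to every band, so
    ratios are loading-invariant by construction; ``band_noise_cv`` adds
    independent multiplicative noise per band. The recorded
    ``local_background`` is exact, so at zero band noise the ratio pipeline
    recovers ``true_ratios`` exactly.
    """
    if n_lanes < 1:
        raise ValueError("n_lanes must be >= 1")
    if lane_scale_sd < 0 or band_noise_cv < 0:
        raise ValueError("noise parameters must be >= 0")
    for name, r in true_ratios.items():
        if name not in SCHEMES:
            raise ValueError(f"unknown ratio scheme {name!r}")
        if r <= 0:
            raise ValueError(f"true ratio {name} must be positive, got {r}")

    abundance: dict[str, float] = {**_BETA_SPLIT, "beta_T": 1.0, "actin": 1.0}
    pending = dict(true_ratios)
    for _ in range(len(pending) + 1):
        resolved = []
        for name, r in pending.items():
            num, den = SCHEMES[name]
            if den in abundance:
                abundance[num] = r * abundance[den]
                resolved.append(name)
        for name in resolved:
            del pending[name]
        if not pending:
            break
    if pending:
        raise ValueError(f"could not resolve ratio schemes {sorted(pending)}: denominators undefined")
    abundance.pop("beta_T")

    rng = np.random.default_rng(seed)
    rows = []
    for lane in range(n_lanes):
        factor = max(1.0 + rng.normal(0.0, lane_scale_sd), 0.05) if lane_scale_sd > 0 else 1.0
        for band, ab in abundance.items():
            signal = factor * ab * _BAND_BASE_SIGNAL
            if band_noise_cv > 0:
                signal = max(signal * (1.0 + rng.normal(0.0, band_noise_cv)), 0.0)
            row = {
                "condition": condition_label,
                "replicate_id": lane,
                "band": band,
                "median_signal": background_level + signal,
                "local_background": background_level,
            }
            if blot_id is not None:
                row["blot_id"] = blot_id
            rows.append(row)
    meta = {"true_ratios": dict(true_ratios), "seed": seed, "lane_scale_sd": lane_scale_sd,
            "band_noise_cv": band_noise_cv}
    return BandTable(records=pd.DataFrame(rows), metadata=meta)


# ---------------------------------------------------------------------------
# Clustered localization patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointPatternTruth:
    """Ground truth for a clustered 2D molecular point pattern.

    Molecules are placed as a parent-offspring cluster process (isotropic
    Gaussian clusters of width ``cluster_sigma``) plus a uniform background,
    all inside ``mask``. Each molecule emits a geometric number of
    localizations (mean ``blink_mean``) in consecutive frames starting at a
    uniform random frame, each jittered by the localization precision;
    photon counts are log-normal. Units: nm and molecules/μm².
    """

    n_clusters: int = 20
    molecules_per_cluster_mean: float = 15.0
    cluster_sigma: float = 15.0
    background_density: float = 5.0  # molecules per μm²
    blink_mean: float = 2.0
    loc_precision_sigma: float = 10.0
    mask: RegionMask = field(default_factory=lambda: RegionMask.from_rect(5000.0, 5000.0))
    frame_count: int = 5000
    pixel_size_nm: float = 107.0
    photon_median: float = 1000.0
    photon_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 0 or self.background_density < 0:
            raise ValueError("counts and densities must be >= 0")
        for name in ("cluster_sigma", "blink_mean", "loc_precision_sigma", "pixel_size_nm"):
            if getattr(self, name) <= 0 and not (name == "loc_precision_sigma" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.blink_mean < 1:
            raise ValueError("blink_mean must be >= 1 (every molecule localises at least once)")
        if self.mask is None or not self.mask.array.any():
            raise ValueError("mask must be provided and non-empty")


def _uniform_in_mask(rng: np.random.Generator, mask: RegionMask, n: int) -> np.ndarray:
    """Rejection-sample n points uniformly inside the mask."""
    w, h = mask.extent_nm
    ox, oy = mask.origin_nm
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        x = ox + rng.uniform(0, w, m)
        y = oy + rng.uniform(0, h, m)
        ok = mask.contains(x, y)
        out = np.vstack([out, np.column_stack([x[ok], y[ok]])])
    return out[:n]


def simulate_localizations(truth: PointPatternTruth) -> LocalizationTable:
    """Simulate a dSTORM localization table from a clustered point pattern.

    Ground-truth molecule positions and cluster labels (-1 = background) are
    retained in the table metadata.
    """
    rng = np.random.default_rng(truth.seed)
    mask = truth.mask

    # molecules: cluster offspring + uniform background
    mol_xy: list[np.ndarray] = []
    mol_label: list[np.ndarray] = []
    parents = _uniform_in_mask(rng, mask, truth.n_clusters)
    for ci, (px, py) in enumerate(parents):
        n_mol = rng.poisson(truth.molecules_per_cluster_mean)
        pts = np.empty((0, 2))
        while len(pts) < n_mol:  # redraw offspring falling outside the mask
            cand = np.column_stack(
                [
                    rng.normal(px, truth.cluster_sigma, n_mol),
                    rng.normal(py, truth.cluster_sigma, n_mol),
                ]
            )
            ok = mask.contains(cand[:, 0], cand[:, 1])
            pts = np.vstack([pts, cand[ok]])
        mol_xy.append(pts[:n_mol])
        mol_label.append(np.full(n_mol, ci))
    n_bg = rng.poisson(truth.background_density * mask.area_nm2 / 1e6)
    if n_bg:
        mol_xy.append(_uniform_in_mask(rng, mask, n_bg))
        mol_label.append(np.full(n_bg, -1))
    if not mol_xy:
        raise ValueError("pattern is empty: no clusters and zero background density")
    molecules = np.vstack(mol_xy)
    labels = np.concatenate(mol_label)
    n_mol = len(molecules)

    # blinking: geometric number of localizations in consecutive frames
    if truth.blink_mean == 1.0:
        blinks = np.ones(n_mol, dtype=int)
    else:
        blinks = rng.geometric(1.0 / truth.blink_mean, size=n_mol)
    start = rng.integers(0, np.maximum(truth.frame_count - blinks, 1))

    rows_x, rows_y, rows_f = [], [], []
    for k in range(n_mol):
        b = int(blinks[k])
        jit = rng.normal(0.0, truth.loc_precision_sigma, size=(b, 2)) if truth.loc_precision_sigma > 0 else np.zeros((b, 2))
        rows_x.append(molecules[k, 0] + jit[:, 0])
        rows_y.append(molecules[k, 1] + jit[:, 1])
        rows_f.append(start[k] + np.arange(b))
    x = np.concatenate(rows_x)
    y = np.concatenate(rows_y)
    frame = np.concatenate(rows_f)
    photons = np.round(truth.photon_median * rng.lognormal(0.0, truth.photon_sigma, size=len(x)))

    records = pd.DataFrame({"x_nm": x, "y_nm": y, "frame": frame.astype(int), "photons": photons})
    records = records.sort_values(["frame", "x_nm", "y_nm"], kind="mergesort").reset_index(drop=True)
    meta = {
        "seed": truth.seed,
        "n_molecules": n_mol,
        "molecule_x_nm": molecules[:, 0].tolist(),
        "molecule_y_nm": molecules[:, 1].tolist(),
        "molecule_cluster": labels.astype(int).tolist(),
    }
    return LocalizationTable(records=records, pixel_size_nm=truth.pixel_size_nm, mask=mask, metadata=meta)
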