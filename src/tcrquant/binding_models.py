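"""Closed-form binding, decay and logistic response models and their fitters.

The regression families mirror those used for ligand-binding flow cytometry:

``one_site``
    One-site specific binding, ``Bmax * C / (Kd + C)``.
``hill``
    Specific binding with Hill slope, ``Bmax * C**h / (Kd**h + C**h)``.
``decay``
    One-phase exponential dissociation, ``plateau + span * exp(-koff * t)``.
``logistic3`` / ``logistic4``
    [Agonist] versus response, three parameters (Hill slope fixed at 1) or
    variable slope (four parameters).

:func:`fit_binding` minimises the total residual sum of squares jointly over
one or more datasets, with an arbitrary subset of parameters shared across
datasets and another subset fixed — the structure needed for the nested
model comparisons in :mod:`tcrquant.nested_inference` (e.g. shared-Kd versus
per-condition Kd).

Positive parameters (Kd, EC50, koff, Hill slope) are optimised on a log10
scale with generous bounds; optimisation is multi-start from data-driven
heuristics (Kd start = dose nearest half-maximal response) plus seeded
jitter, so the fitter is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .datasets import DoseResponseDataset, TimeCourseDataset

__all__ = [
    "occupancy",
    "specific_binding",
    "one_phase_decay",
    "logistic_response",
    "BindingFit",
    "fit_binding",
    "ec50_from_fit",
    "FAMILIES",
]

_LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# Response functions
# ---------------------------------------------------------------------------

def occupancy(conc: float | np.ndarray, kd: float) -> float | np.ndarray:
    """Equilibrium receptor occupancy under an effective 1:1 binding model.

    Parameters
    ----------
    conc
        Ligand concentration in nM, >= 0.
    kd
        Effective dissociation constant in nM, > 0.

    Returns
    -------
    Fraction of receptors bound, ``conc / (kd + conc)``, in [0, 1).
    """
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd}")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    out = conc / (kd + conc)
    return float(out) if out.ndim == 0 else out


def specific_binding(
    conc: float | np.ndarray, bmax: float, kd: float, h: float = 1.0
) -> float | np.ndarray:
    """Specific binding with Hill slope: ``bmax * conc**h / (kd**h + conc**h)``.

    With ``h = 1`` this is one-site specific binding,
    ``bmax * occupancy(conc, kd)``.
    """
    if kd <= 0 or h <= 0:
        raise ValueError(f"kd and h must be positive, got kd={kd}, h={h}")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    ch = conc**h
    out = bmax * ch / (kd**h + ch)
    return float(out) if out.ndim == 0 else out


def one_phase_decay(
    t: float | np.ndarray, plateau: float, span: float, koff: float
) -> float | np.ndarray:
    """One-phase exponential dissociation, ``plateau + span * exp(-koff * t)``."""
    if koff <= 0:
        raise ValueError(f"koff must be positive, got {koff}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = plateau + span * np.exp(-koff * t)
    return float(out) if out.ndim == 0 else out


def logistic_response(
    conc: float | np.ndarray, bottom: float, top: float, ec50: float, hill: float = 1.0
) -> float | np.ndarray:
    """Agonist-versus-response logistic curve.

    ``bottom + (top - bottom) / (1 + (ec50 / conc)**hill)``; ``hill = 1``
    gives the three-parameter form.
    """
    if ec50 <= 0 or hill <= 0:
        raise ValueError(f"ec50 and hill must be positive, got ec50={ec50}, hill={hill}")
    conc = np.asarray(conc, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentration must be strictly positive for logistic fits")
    out = bottom + (top - bottom) / (1.0 + (ec50 / conc) ** hill)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Family registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Family:
    name: str
    param_names: tuple[str, ...]
    log_params: frozenset[str]  # optimised as log10
    fn: Callable[..., np.ndarray]
    x_is_time: bool = False

    def starts(self, x: np.ndarray, y: np.ndarray) -> dict[str, float]:
        lo, hi = float(np.min(y)), float(np.max(y))
        half = 0.5 * (lo + hi)
        x_half = float(x[np.argmin(np.abs(y - half))])
        x_half = max(x_half, 1e-9)
        s: dict[str, float] = {}
        if self.name in ("one_site", "hill"):
            s = {"bmax": hi if hi > 0 else 1.0, "kd": x_half, "h": 1.0}
        elif self.name == "decay":
            s = {"plateau": lo, "span": max(hi - lo, 1e-9), "koff": math.log(2.0) / x_half}
        elif self.name in ("logistic3", "logistic4"):
            s = {"bottom": lo, "top": hi, "ec50": x_half, "hill": 1.0}
        return {k: v for k, v in s.items() if k in self.param_names}


def _one_site(x, bmax, kd):
    return bmax * x / (kd + x)


def _hill(x, bmax, kd, h):
    xh = x**h
    return bmax * xh / (kd**h + xh)


def _decay(x, plateau, span, koff):
    return plateau + span * np.exp(-koff * x)


def _logistic3(x, bottom, top, ec50):
    return bottom + (top - bottom) / (1.0 + ec50 / x)


def _logistic4(x, bottom, top, ec50, hill):
    return bottom + (top - bottom) / (1.0 + (ec50 / x) ** hill)


FAMILIES: dict[str, _Family] = {
    "one_site": _Family("one_site", ("bmax", "kd"), frozenset({"kd"}), _one_site),
    "hill": _Family("hill", ("bmax", "kd", "h"), frozenset({"kd", "h"}), _hill),
    "decay": _Family("decay", ("plateau", "span", "koff"), frozenset({"koff"}), _decay, x_is_time=True),
    "logistic3": _Family("logistic3", ("bottom", "top", "ec50"), frozenset({"ec50"}), _logistic3),
    "logistic4": _Family("logistic4", ("bottom", "top", "ec50", "hill"), frozenset({"ec50", "hill"}), _logistic4),
}

# log10 bounds for positive parameters
_LOG_BOUNDS: dict[str, tuple[float, float]] = {
    "kd": (-6.0, 9.0),
    "ec50": (-6.0, 9.0),
    "koff": (-6.0, 6.0),
    "h": (-2.0, 2.0),
    "hill": (-2.0, 2.0),
}

_N_STARTS_DEFAULT = 8


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class BindingFit:
    """Joint least-squares fit over one or more datasets.

    ``params[label][name]`` holds the estimate for every parameter of the
    family for every dataset; shared parameters appear with the same value
    under every label, fixed parameters with their fixed value. ``param_se``
    carries asymptotic standard errors on the natural scale (NaN for fixed
    parameters).
    """

    family: str
    condition_labels: tuple[str, ...]
    params: dict[str, dict[str, float]]
    param_se: dict[str, dict[str, float]]
    shared: frozenset[str]
    fixed: dict[str, float]
    ss_resid: float
    df: int
    n_points: int
    cov: np.ndarray | None
    converged: bool
    identifiable: bool
    n_starts_used: int
    data_fingerprint: str
    notes: tuple[str, ...] = ()
    free_param_index: tuple[tuple[str, str | None], ...] = ()

    @property
    def n_free_params(self) -> int:
        return self.n_points - self.df

    def __getitem__(self, label: str) -> dict[str, float]:
        return self.params[label]


# ---------------------------------------------------------------------------
# Joint fitting engine
# ---------------------------------------------------------------------------

def _as_xy(ds, family: _Family) -> tuple[np.ndarray, np.ndarray, str]:
    if family.x_is_time:
        if isinstance(ds, TimeCourseDataset):
            return ds.times, ds.responses, ds.condition_label
        raise TypeError("decay family requires TimeCourseDataset inputs")
    if isinstance(ds, DoseResponseDataset):
        if ds.n_distinct_doses < 4:
            raise ValueError(
                f"dataset {ds.condition_label!r} has {ds.n_distinct_doses} distinct "
                "concentrations; >= 4 are required for a fit"
            )
        return ds.concentrations, ds.responses, ds.condition_label
    raise TypeError(f"unsupported dataset type {type(ds).__name__} for family {family.name}")


def _build_layout(
    family: _Family,
    labels: Sequence[str],
    share: frozenset[str],
    fixed: Mapping[str, float],
) -> list[tuple[str, str | None]]:
    """Free-parameter layout: (name, condition label) — label None if shared."""
    layout: list[tuple[str, str | None]] = []
    for name in family.param_names:
        if name in fixed:
            continue
        if name in share:
            layout.append((name, None))
        else:
            layout.extend((name, lab) for lab in labels)
    return layout


def _theta_bounds(layout, family: _Family) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name, _ in layout:
        if name in family.log_params:
            b = _LOG_BOUNDS[name]
            lo.append(b[0])
            hi.append(b[1])
        else:
            lo.append(-np.inf)
            hi.append(np.inf)
    return np.array(lo), np.array(hi)


def _theta_to_params(theta, layout, family, labels, fixed):
    per: dict[str, dict[str, float]] = {lab: dict(fixed) for lab in labels}
    for val, (name, lab) in zip(theta, layout):
        nat = 10.0**val if name in family.log_params else val
        targets = labels if lab is None else (lab,)
        for t in targets:
            per[t][name] = nat
    return per


def _params_to_theta(start: Mapping[str, float], layout, family) -> np.ndarray:
    theta = []
    for name, _ in layout:
        v = start[name]
        theta.append(math.log10(v) if name in family.log_params else v)
    return np.array(theta, dtype=float)


def fit_binding(
    datasets: Any,
    family: str,
    share: set[str] | frozenset[str] = frozenset(),
    fixed: Mapping[str, float] | None = None,
    weighted: bool = False,
    n_starts: int = _N_STARTS_DEFAULT,
    extra_starts: Sequence[Mapping[str, float]] = (),
) -> BindingFit:
    """Fit one or more datasets jointly by ordinary least squares.

    Parameters
    ----------
    datasets
        A single dataset or sequence of datasets (``DoseResponseDataset``,
        or ``TimeCourseDataset`` for the ``decay`` family).
    family
        One of ``one_site``, ``hill``, ``decay``, ``logistic3``, ``logistic4``.
    share
        Parameter names estimated as a single value across all datasets.
    fixed
        Parameter names fixed to given values (applied to every dataset).
    weighted
        If True, weight residuals by 1/|fitted value| (relative residuals);
        the default is ordinary (unweighted) least squares.
    n_starts
        Number of multi-start optimisations; the first start is the data
        heuristic, the rest are seeded log-scale jitters of it.
    extra_starts
        Additional full parameter dicts to use as warm starts (e.g. the
        optimum of a nested null fit).
    """
    if isinstance(datasets, (DoseResponseDataset, TimeCourseDataset)):
        datasets = [datasets]
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    fam = FAMILIES[family]
    fixed = dict(fixed or {})
    share = frozenset(share)
    bad = (share | set(fixed)) - set(fam.param_names)
    if bad:
        raise ValueError(f"parameters {sorted(bad)} not in family {family!r}")
    if share & set(fixed):
        raise ValueError("a parameter cannot be both shared and fixed")

    xs, ys, labels = [], [], []
    for ds in datasets:
        x, y, lab = _as_xy(ds, fam)
        xs.append(x)
        ys.append(y)
        labels.append(lab)
    if len(set(labels)) != len(labels):
        raise ValueError("condition labels must be unique across datasets")
    n_points = int(sum(y.size for y in ys))
    fp = _joint_fingerprint(datasets)

    layout = _build_layout(fam, labels, share, fixed)
    df = n_points - len(layout)
    if df <= 0:
        raise ValueError(f"under-determined fit: {n_points} points, {len(layout)} free parameters")

    # Degenerate data: every response identical -> scale parameters are that
    # value, location parameters (Kd, EC50, koff) are unidentifiable.
    if all(np.ptp(y) == 0 for y in ys) and len({float(y[0]) for y in ys}) == 1:
        return _degenerate_fit(fam, labels, fixed, share, float(ys[0][0]), n_points, df, fp, layout)

    def residuals(theta: np.ndarray) -> np.ndarray:
        per = _theta_to_params(theta, layout, fam, labels, fixed)
        out = []
        for x, y, lab in zip(xs, ys, labels):
            pred = fam.fn(x, **{k: per[lab][k] for k in fam.param_names})
            r = pred - y
            if weighted:
                r = r / np.maximum(np.abs(pred), 1e-12)
            out.append(r)
        return np.concatenate(out)

    lo, hi = _theta_bounds(layout, fam)
    starts = _make_starts(fam, xs, ys, labels, layout, fixed, n_starts, extra_starts)

    best = None
    used = 0
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        used += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all optimisation starts failed")

    ss = float(2.0 * best.cost)
    converged = bool(best.status > 0)
    per = _theta_to_params(best.x, layout, fam, labels, fixed)

    cov_nat, se_map, identifiable, notes = _covariance(best, layout, fam, ss, df)
    per_se = {lab: {n: float("nan") for n in fam.param_names} for lab in labels}
    for (name, lab), se in zip(layout, se_map):
        for t in labels if lab is None else (lab,):
            per_se[t][name] = se

    return BindingFit(
        family=family,
        condition_labels=tuple(labels),
        params=per,
        param_se=per_se,
        shared=share,
        fixed=fixed,
        ss_resid=ss,
        df=df,
        n_points=n_points,
        cov=cov_nat,
        converged=converged,
        identifiable=identifiable,
        n_starts_used=used,
        data_fingerprint=fp,
        notes=tuple(notes),
        free_param_index=tuple(layout),
    )


def _joint_fingerprint(datasets) -> str:
    from .datasets import data_fingerprint as _dfp

    arrays = []
    for ds in datasets:
        if isinstance(ds, TimeCourseDataset):
            arrays.extend([ds.times, ds.responses])
        else:
            arrays.extend([ds.concentrations, ds.responses])
    return _dfp(*arrays)


def _make_starts(fam, xs, ys, labels, layout, fixed, n_starts, extra_starts):
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    base = fam.starts(x_all, y_all)
    base.update({k: v for k, v in fixed.items() if k in base})
    rng = np.random.default_rng(0)  # fixed: multi-start jitter is part of the algorithm
    starts = [
        _params_to_theta({**base, **dict(fixed)}, layout, fam)
    ]
    for s in extra_starts:
        starts.append(_params_to_theta({**base, **s}, layout, fam))
    while len(starts) < n_starts + len(extra_starts):
        theta = starts[0].copy()
        for i, (name, _) in enumerate(layout):
            if name in fam.log_params:
                theta[i] += rng.normal(0.0, 0.7)
            else:
                theta[i] *= 1.0 + rng.normal(0.0, 0.3)
        starts.append(theta)
    return starts


def _covariance(sol, layout, fam, ss, df):
    """Asymptotic covariance from the Jacobian at the optimum (natural scale)."""
    notes: list[str] = []
    J = sol.jac
    JTJ = J.T @ J
    identifiable = True
    try:
        cond = np.linalg.cond(JTJ)
        if not np.isfinite(cond) or cond > 1e12:
            identifiable = False
            notes.append("Jacobian nearly rank-deficient: some parameters are structurally confounded")
        cov_theta = float(ss / df) * np.linalg.pinv(JTJ)
    except np.linalg.LinAlgError:
        identifiable = False
        notes.append("covariance unavailable (singular Jacobian)")
        return None, [float("nan")] * len(layout), identifiable, notes
    # delta method: d(natural)/d(theta) = ln(10)*value for log10 parameters
    scale = np.array(
        [_LN10 * 10.0 ** sol.x[i] if name in fam.log_params else 1.0 for i, (name, _) in enumerate(layout)]
    )
    cov_nat = cov_theta * np.outer(scale, scale)
    se = list(np.sqrt(np.maximum(np.diag(cov_nat), 0.0)))
    return cov_nat, se, identifiable, notes


def _degenerate_fit(fam, labels, fixed, share, value, n_points, df, fp, layout):
    scale_names = {"one_site": "bmax", "hill": "bmax", "decay": "plateau"}
    per: dict[str, dict[str, float]] = {}
    for lab in labels:
        p = {n: float("nan") for n in fam.param_names}
        p.update(fixed)
        if fam.name in scale_names:
            p[scale_names[fam.name]] = value
            if fam.name == "decay":
                p["span"] = 0.0
        else:  # logistic families
            p["bottom"] = value
            p["top"] = value
        per[lab] = p
    se = {lab: {n: float("nan") for n in fam.param_names} for lab in labels}
    return BindingFit(
        family=fam.name,
        condition_labels=tuple(labels),
        params=per,
        param_se=se,
        shared=share,
        fixed=dict(fixed),
        ss_resid=0.0,
        df=df,
        n_points=n_points,
        cov=None,
        converged=True,
        identifiable=False,
        n_starts_used=0,
        data_fingerprint=fp,
        notes=("all responses identical: location parameters unidentifiable",),
        free_param_index=tuple(layout),
    )


def ec50_from_fit(fit: BindingFit, condition: str | None = None) -> tuple[float, float]:
    """Fitted EC50 (nM) and its asymptotic standard error from a logistic fit.

    For a multi-condition fit with a per-condition EC50, ``condition``
    selects which estimate to return.
    """
    if fit.family not in ("logistic3", "logistic4"):
        raise ValueError(f"ec50 requires a logistic fit, got family {fit.family!r}")
    if not fit.converged:
        raise ValueError("fit did not converge; EC50 estimate unavailable")
    if condition is None:
        if len(fit.condition_labels) > 1 and "ec50" not in fit.shared:
            raise ValueError("multiple per-condition EC50s: specify condition=")
        condition = fit.condition_labels[0]
    return fit.params[condition]["ec50"], fit.param_se[condition]["ec50"]
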