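"""Detergent-stability-assay (DSA) immunoblot quantitation.

Quantitative near-infrared immunoblots of DDM-solubilised, pulled-down
TCR-CD3 complexes report how tightly the CD3 dimers (γε, δε, ζζ) remain
associated with the ligand-binding αβ heterodimer. Band signal is computed
as ``median - local background``; the β chain resolves into three glycoform
bands (β1, β2, β3) whose sum is total β (β_T), with β2 the mature,
ζζ-associated surface form. Subunit ratios (e.g. ζ/β2, ε/β_T) are computed
per lane, then normalised so the reference condition (typically WT) has mean
ratio 1 — a normalised ζ/β2 of 0.2 means the mutant retains 20% of the
ζζ recovered per intact receptor relative to WT.

Lane-to-lane loading differences cancel in the ratios, so no loading
normalisation is required before ratio computation; an ``x_over_actin``
loading scheme is available for input-lysate panels when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .nested_inference import TTestResult, t_test

__all__ = [
    "BAND_NAMES",
    "SCHEMES",
    "BandTable",
    "RatioResult",
    "band_signal",
    "beta_total",
    "subunit_ratios",
    "compare_dsa",
]

BAND_NAMES = ("beta1", "beta2", "beta3", "eps", "zeta", "gamma", "delta", "actin")

#: ratio schemes: name -> (numerator, denominator); "beta_T" = beta1+beta2+beta3
SCHEMES: dict[str, tuple[str, str]] = {
    "zeta_over_beta2": ("zeta", "beta2"),
    "eps_over_betaT": ("eps", "beta_T"),
    "gamma_over_betaT": ("gamma", "beta_T"),
    "delta_over_betaT": ("delta", "beta_T"),
    "beta_over_eps": ("beta_T", "eps"),
    "zeta_over_eps": ("zeta", "eps"),
    # loading-control schemes for input-lysate panels
    "beta_over_actin": ("beta_T", "actin"),
    "zeta_over_actin": ("zeta", "actin"),
    "eps_over_actin": ("eps", "actin"),
}


def band_signal(median_signal: float, local_background: float) -> float:
    """Band signal as median minus local background.

    Negative or zero results are physically meaningless abundances and are
    flagged (and excluded) downstream, but the arithmetic value is returned.
    """
    if not (np.isfinite(median_signal) and np.isfinite(local_background)):
        raise ValueError("band signals must be finite")
    return float(median_signal) - float(local_background)


@dataclass
class BandTable:
    """Long-form immunoblot band table.

    One row per band per lane with columns ``condition``, ``replicate_id``,
    ``band``, ``median_signal``, ``local_background`` and optionally
    ``blot_id`` (membrane identity, enabling per-blot normalisation).
    """

    records: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"condition", "replicate_id", "band", "median_signal", "local_background"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        vals = self.records[["median_signal", "local_background"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("band signals must be finite")
        unknown = set(self.records["band"]) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown band names: {sorted(unknown)}; expected among {BAND_NAMES}")

    @property
    def has_blot_id(self) -> bool:
        return "blot_id" in self.records.columns

    def lanes(self) -> pd.DataFrame:
        """Wide per-lane table of background-subtracted band signals."""
        rec = self.records.copy()
        rec["signal"] = rec["median_signal"].astype(float) - rec["local_background"].astype(float)
        keys = ["condition", "replicate_id"] + (["blot_id"] if self.has_blot_id else [])
        wide = rec.pivot_table(index=keys, columns="band", values="signal", aggfunc="first")
        return wide.reset_index()

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BandTable":
        return cls(pd.read_csv(path))


def beta_total(lane: pd.Series | dict) -> float:
    """Total β signal: β1 + β2 + β3 (background-subtracted)."""
    try:
        vals = [float(lane[b]) for b in ("beta1", "beta2", "beta3")]
    except KeyError as e:
        raise ValueError(f"lane is missing band {e.args[0]!r} required for beta_T") from None
    if any(not np.isfinite(v) for v in vals):
        raise ValueError("lane is missing a beta isoform band required for beta_T")
    return float(sum(vals))


@dataclass
class RatioResult:
    """Reference-normalised subunit ratios with replicate statistics.

    ``per_replicate`` has one row per accepted lane (raw and normalised
    ratio); ``summary`` has mean, SD and n of the normalised ratio per
    condition. ``exclusions`` lists lanes rejected for non-positive band
    signals.
    """

    scheme: str
    reference_condition: str
    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    exclusions: tuple[str, ...] = ()

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def normalized(self, condition: str) -> np.ndarray:
        sel = self.per_replicate["condition"] == condition
        return self.per_replicate.loc[sel, "normalized_ratio"].to_numpy(dtype=float)

    def mean(self, condition: str) -> float:
        row = self.summary[self.summary["condition"] == condition]
        if row.empty:
            raise KeyError(condition)
        return float(row["mean"].iloc[0])


def _lane_value(lane: pd.Series, token: str) -> float:
    if token == "beta_T":
        return beta_total(lane)
    if token not in lane or not np.isfinite(lane[token]):
        raise ValueError(f"lane is missing band {token!r}")
    return float(lane[token])


def subunit_ratios(table: BandTable, scheme: str, reference_condition: str) -> RatioResult:
    """Per-lane subunit ratios normalised to a reference condition.

    For each lane the ratio numerator/denominator of the scheme is computed
    from background-subtracted signals; lanes with a non-positive numerator
    or denominator are excluded with a message. Ratios are then divided by
    the reference condition's mean raw ratio — per blot when the table
    carries a ``blot_id`` column (normalisation within experiments), else
    globally — so the reference condition's normalised mean is 1.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    num_token, den_token = SCHEMES[scheme]
    lanes = table.lanes()
    if reference_condition not in set(lanes["condition"]):
        raise ValueError(f"reference condition {reference_condition!r} not present in the table")

    rows = []
    exclusions: list[str] = []
    for _, lane in lanes.iterrows():
        lane_id = f"{lane['condition']}/{lane['replicate_id']}"
        try:
            num = _lane_value(lane, num_token)
            den = _lane_value(lane, den_token)
        except ValueError as e:
            exclusions.append(f"{lane_id}: {e}")
            continue
        if den <= 0:
            exclusions.append(f"{lane_id}: non-positive denominator signal ({den_token} = {den:.4g})")
            continue
        if num <= 0:
            exclusions.append(f"{lane_id}: non-positive numerator signal ({num_token} = {num:.4g})")
            continue
        rows.append(
            {
                "condition": lane["condition"],
                "replicate_id": lane["replicate_id"],
                "blot_id": lane.get("blot_id", None),
                "raw_ratio": num / den,
            }
        )
    if not rows:
        raise ValueError("no usable lanes after exclusions")
    per = pd.DataFrame(rows)

    ref = per[per["condition"] == reference_condition]
    if ref.empty:
        raise ValueError(f"all reference-condition lanes were excluded for scheme {scheme!r}")

    if table.has_blot_id and per["blot_id"].notna().all():
        ref_means = ref.groupby("blot_id")["raw_ratio"].mean()
        divisor = per["blot_id"].map(ref_means)
        if divisor.isna().any():
            # blots without a reference lane fall back to the global reference mean
            divisor = divisor.fillna(float(ref["raw_ratio"].mean()))
    else:
        divisor = float(ref["raw_ratio"].mean())
    per["normalized_ratio"] = per["raw_ratio"] / divisor

    summary = (
        per.groupby("condition", sort=False)["normalized_ratio"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return RatioResult(
        scheme=scheme,
        reference_condition=reference_condition,
        per_replicate=per,
        summary=summary,
        exclusions=tuple(exclusions),
    )


def compare_dsa(
    result_a: RatioResult,
    result_b: RatioResult | None = None,
    condition_a: str | None = None,
    condition_b: str | None = None,
    paired: bool = False,
) -> TTestResult:
    """t-test between two conditions' normalised subunit ratios.

    Typical call: ``compare_dsa(r, condition_a="WT", condition_b="mut")``
    on a single :class:`RatioResult`, or two results (e.g. the same scheme
    computed on two tables).
    """
    result_b = result_b or result_a
    conds_a = list(result_a.summary["condition"])
    conds_b = list(result_b.summary["condition"])
    if condition_a is None or condition_b is None:
        if result_b is result_a and len(conds_a) == 2:
            condition_a, condition_b = conds_a
        elif len(conds_a) == 1 and len(conds_b) == 1:
            condition_a, condition_b = conds_a[0], conds_b[0]
        else:
            raise ValueError("ambiguous conditions: pass condition_a and condition_b explicitly")
    a = result_a.normalized(condition_a)
    b = result_b.normalized(condition_b)
    return t_test(a, b, paired=paired)
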