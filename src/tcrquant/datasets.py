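"""Shared data containers: dose-response and time-course tables.

Both containers wrap a tidy :class:`pandas.DataFrame` and carry a metadata
dict (generating ground truth, seed) plus a content fingerprint used by
:func:`tcrquant.nested_inference.ess_f_test` to refuse comparisons between
fits made on different data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["DoseResponseDataset", "TimeCourseDataset", "data_fingerprint"]


def data_fingerprint(*arrays: np.ndarray) -> str:
    """SHA-256 fingerprint of numeric arrays, stable across runs.

    Values are rounded to 12 significant decimals before hashing so that
    round-tripping through CSV (written with ``repr`` precision) preserves
    the fingerprint.
    """
    h = hashlib.sha256()
    for a in arrays:
        a = np.asarray(a, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(a == 0, 1.0, 10.0 ** (11 - np.floor(np.log10(np.abs(a)))))
        rounded = np.round(a * scale) / scale
        h.update(np.ascontiguousarray(rounded).tobytes())
    return h.hexdigest()[:16]


def _write_sidecar(path: Path, metadata: Mapping[str, Any]) -> None:
    side = path.with_suffix(path.suffix + ".meta.json")
    side.write_text(json.dumps(dict(metadata), indent=2, default=float) + "\n")


def _read_sidecar(path: Path) -> dict[str, Any]:
    side = path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        return json.loads(side.read_text())
    return {}


@dataclass
class DoseResponseDataset:
    """Per-condition table of ligand concentrations and replicate responses.

    Parameters
    ----------
    condition_label
        Free-text condition name (e.g. ``"WT"`` or ``"betaA291"``).
    records
        DataFrame with columns ``concentration_nm``, ``response``,
        ``replicate_id``. Responses are background-subtracted MFI-like
        values in arbitrary units.
    metadata
        Generating ground truth and seed, if the dataset is synthetic.
    """

    condition_label: str
    records: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"concentration_nm", "response", "replicate_id"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        conc = np.asarray(self.records["concentration_nm"], dtype=float)
        resp = np.asarray(self.records["response"], dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if not np.all(np.isfinite(resp)):
            raise ValueError("responses must be finite")

    @property
    def concentrations(self) -> np.ndarray:
        return np.asarray(self.records["concentration_nm"], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.asarray(self.records["response"], dtype=float)

    @property
    def n_distinct_doses(self) -> int:
        return int(np.unique(self.concentrations).size)

    def fingerprint(self) -> str:
        return data_fingerprint(self.concentrations, self.responses)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.records.to_csv(path, index=False)
        _write_sidecar(path, {"condition_label": self.condition_label, **self.metadata})

    @classmethod
    def from_csv(cls, path: str | Path, condition_label: str | None = None) -> "DoseResponseDataset":
        path = Path(path)
        records = pd.read_csv(path)
        meta = _read_sidecar(path)
        label = condition_label or meta.pop("condition_label", path.stem)
        meta.pop("condition_label", None)
        return cls(condition_label=label, records=records, metadata=meta)


@dataclass
class TimeCourseDataset:
    """Dissociation time course: response versus time per replicate."""

    condition_label: str
    records: pd.DataFrame  # columns: time_s, response, replicate_id
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"time_s", "response", "replicate_id"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        t = np.asarray(self.records["time_s"], dtype=float)
        if np.any(t < 0):
            raise ValueError("times must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.records["time_s"], dtype=float)

    @property
    def responses(self) -> np.ndarray:
        return np.asarray(self.records["response"], dtype=float)

    def fingerprint(self) -> str:
        return data_fingerprint(self.times, self.responses)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.records.to_csv(path, index=False)
        _write_sidecar(path, {"condition_label": self.condition_label, **self.metadata})

    @classmethod
    def from_csv(cls, path: str | Path, condition_label: str | None = None) -> "TimeCourseDataset":
        path = Path(path)
        records = pd.read_csv(path)
        meta = _read_sidecar(path)
        label = condition_label or meta.pop("condition_label", path.stem)
        meta.pop("condition_label", None)
        return cls(condition_label=label, records=records, metadata=meta)
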