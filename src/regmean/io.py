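"""CSV/JSON input and output.

Participant samples travel as plain comma-separated UTF-8 files with a
required ``id,x,y`` header; optional columns (``y1,y2`` split halves,
``s,e_x,e_y`` latents, ``subpop`` labels) are detected from the header.
Model specs travel as JSON documents with a ``model`` discriminator
(see :func:`regmean.models.spec_from_dict`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .models import BivariateSample, spec_from_dict, spec_to_dict

__all__ = [
    "read_participant_csv",
    "write_participant_csv",
    "read_spec_json",
    "write_spec_json",
    "RunConfig",
]

# canonical column order for writing
_COLUMN_ORDER = ["id", "x", "y", "y1", "y2", "s", "s_x", "s_y", "e_x", "e_y",
                 "subpop"]
_NUMERIC = {"x", "y", "y1", "y2", "s", "s_x", "s_y", "e_x", "e_y"}


def read_participant_csv(path) -> BivariateSample:
    """Read a participant-level CSV into a :class:`BivariateSample`.

    Requires a header with at least ``id,x,y``.  Unknown columns are an
    error, as is a lone ``y1`` without ``y2`` (or vice versa).  Malformed
    numeric cells are rejected with the offending data row number
    (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in ("id", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) "
                         f"{', '.join(missing)}")
    unknown = [c for c in df.columns if c not in _COLUMN_ORDER]
    if unknown:
        raise ValueError(f"{path.name}: unknown column(s) {', '.join(unknown)}")
    for col in df.columns:
        if col not in _NUMERIC:
            continue
        probe = pd.to_numeric(df[col], errors="coerce")
        bad = (probe.isna() & df[col].notna()) | df[col].isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(f"{path.name}: non-numeric or missing value in "
                             f"column {col!r} at data row {row}")
        # numpy's strtod is correctly rounded, so written files re-read exactly
        df[col] = df[col].to_numpy(dtype=str).astype(float)
    return BivariateSample(df)


def write_participant_csv(sample: BivariateSample, path) -> None:
    """Write a sample as canonical CSV (fixed column order, no quoting).

    Reading a canonical file and writing it again is byte-identical.
    """
    cols = [c for c in _COLUMN_ORDER if c in sample.data.columns]
    sample.data[cols].to_csv(path, index=False)


def read_spec_json(path):
    """Load a model spec from a JSON file with a ``model`` discriminator."""
    with open(path, encoding="utf-8") as fh:
        return spec_from_dict(json.load(fh))


def write_spec_json(spec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(spec_to_dict(spec), fh, indent=2)
        fh.write("\n")


@dataclass
class RunConfig:
    """A simulate-then-diagnose run: model spec, sample size, seed, and
    the selection rule to audit."""

    spec: object
    n: int = 200
    seed: Optional[int] = None
    cutoff: float = 0.0
    direction: str = "at-or-below"
    retest: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.direction not in ("at-or-below", "above"):
            raise ValueError(f"unknown direction: {self.direction!r}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if "spec" not in doc:
            raise ValueError("config must contain a 'spec' object")
        spec = spec_from_dict(doc["spec"])
        kwargs = {k: doc[k] for k in ("n", "seed", "cutoff", "direction",
                                      "retest") if k in doc}
        cfg = cls(spec=spec, **kwargs)
        if cfg.seed is None:
            raise ValueError("config must set a seed for simulation")
        return cfg
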