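"""Core in-memory containers shared across the pipeline.

A screen is represented by three aligned tables:

* a feature x sample matrix of read counts (or normalized activities),
* a *design* table describing each sample (condition, replicate, timepoint),
* a *feature* annotation table (gene, calibrator flag).

Normalized matrices additionally carry a *provenance* tuple recording the
chain of operations applied, which downstream operations use to enforce
the fixed normalization order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# design conditions used throughout
COND_TTX = "TTX"
COND_BIC = "BIC"
COND_REF = "reference"


def make_design(
    samples: list[tuple[str, str, str, float | None]],
) -> pd.DataFrame:
    """Build a design table from (sample_id, condition, replicate, timepoint) rows."""
    df = pd.DataFrame(samples, columns=["sample_id", "condition", "replicate", "timepoint"])
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    return df.set_index("sample_id")


def screen_design(n_ttx: int, n_bic: int) -> pd.DataFrame:
    """Standard two-condition screen design: silenced (TTX) vs stimulated (BIC)."""
    rows = [(f"TTX_r{i + 1}", COND_TTX, f"r{i + 1}", None) for i in range(n_ttx)]
    rows += [(f"BIC_r{i + 1}", COND_BIC, f"r{i + 1}", 4.0) for i in range(n_bic)]
    return make_design(rows)


@dataclass
class CountMatrix:
    """Integer reads per feature per sample with attached design and annotations.

    ``counts``: DataFrame, features x samples, non-negative integers.
    ``design``: DataFrame indexed by sample_id with condition/replicate/timepoint.
    ``features``: DataFrame indexed by feature id; typical columns are
    ``gene`` and ``is_calibrator``.
    ``level``: what a feature is ("barcode", "shrna", "sensor").
    """

    counts: pd.DataFrame
    design: pd.DataFrame
    features: pd.DataFrame
    level: str = "barcode"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str, timepoint: float | None = None) -> list[str]:
        d = self.design.loc[self.counts.columns]
        mask = d["condition"] == condition
        if timepoint is not None:
            mask &= d["timepoint"] == timepoint
        return list(d.index[mask])

    def to_tsv(self, path: str) -> None:
        write_matrix_tsv(path, self.counts, ("counts", f"level={self.level}"))

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.design.copy(), self.features.copy(), self.level)


@dataclass
class NormMatrix:
    """Non-negative real matrix plus the provenance chain that produced it."""

    values: pd.DataFrame
    design: pd.DataFrame
    features: pd.DataFrame
    level: str = "barcode"
    provenance: tuple[str, ...] = field(default_factory=tuple)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str, timepoint: float | None = None) -> list[str]:
        d = self.design.loc[self.values.columns]
        mask = d["condition"] == condition
        if timepoint is not None:
            mask &= d["timepoint"] == timepoint
        return list(d.index[mask])

    def with_values(self, values: pd.DataFrame, tag: str, **kw) -> "NormMatrix":
        out = replace(self, values=values, provenance=self.provenance + (tag,))
        for k, v in kw.items():
            setattr(out, k, v)
        return out

    def to_tsv(self, path: str) -> None:
        write_matrix_tsv(path, self.values, self.provenance)


def write_matrix_tsv(path: str, df: pd.DataFrame, provenance: tuple[str, ...]) -> None:
    """TSV with a leading '#provenance:' header line."""
    with open(path, "w") as fh:
        fh.write("#provenance:" + ";".join(provenance) + "\n")
        df.to_csv(fh, sep="\t", index_label="feature")


def read_matrix_tsv(path: str) -> tuple[pd.DataFrame, tuple[str, ...]]:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#provenance:"):
            raise ValueError(f"{path}: missing provenance header")
        provenance = tuple(t for t in first[len("#provenance:"):].strip().split(";") if t)
        df = pd.read_csv(io.StringIO(fh.read()), sep="\t", index_col="feature")
    return df, provenance


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage RNG stream derived from one master seed.

    Stages are identified by name so adding a stage never perturbs the
    streams of existing ones.
    """
    import zlib

    child = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(child,)))
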