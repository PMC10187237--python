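"""Synthetic experimental-style datasets and tabular I/O.

No numerical experimental dataset accompanies the growth-rate and binding
measurements this package models, so recovery tests and examples run on
synthetic tables generated here.  Each generator evaluates a stated truth
model (the minus-end growth law, the quench isotherm, or the competition
model), attaches Gaussian noise of a stated coefficient of variation to the
per-condition *mean* (standard deviation = CV * mean / sqrt(n), i.e. the
SEM of n hypothetical replicates), and embeds the truth parameters, seed
and generator version in a ``#``-prefixed metadata header so any file can
be re-generated and its parameters re-fit with no other inputs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding import competition_model, minus_growth_prediction, quench_isotherm

__all__ = [
    "FixtureSpec",
    "generate_growth_dataset",
    "generate_binding_dataset",
    "write_table",
    "read_table",
]

GENERATOR_VERSION = "1"

#: default per-condition replicate counts emulating per-condition sample
#: sizes of tens of growth events per condition
DEFAULT_N_PER_CONDITION = 50


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic dataset.

    ``kind`` selects the truth model: ``growth_series`` (minus-end growth
    law versus free GDP), ``isotherm`` (6-Thio-GTP quench) or
    ``competition`` (unquenching by a competitor).  ``truth`` holds the
    generating parameters; ``cv`` the relative noise per replicate;
    ``n_per_condition`` the hypothetical replicate count behind each mean.
    """

    kind: str
    truth: dict
    cv: float = 0.05
    n_per_condition: int = DEFAULT_N_PER_CONDITION
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.kind not in ("growth_series", "isotherm", "competition"):
            raise ValueError(f"unknown generator kind {self.kind!r}")


def _noisy_table(x, model_values, spec: FixtureSpec, floor: float = 1e-6) -> pd.DataFrame:
    rng = np.random.default_rng(spec.rng_seed)
    model_values = np.asarray(model_values, float)
    scale = np.maximum(np.abs(model_values), floor)
    sem = spec.cv * scale / np.sqrt(spec.n_per_condition)
    y = model_values + rng.normal(0.0, sem) if spec.cv > 0 else model_values.copy()
    return pd.DataFrame(
        {"x_uM": np.asarray(x, float), "y": y,
         "sem": np.where(sem > 0, sem, floor), "n": spec.n_per_condition}
    )


def generate_growth_dataset(
    spec: FixtureSpec, gdp_concentrations: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Synthetic minus-end growth rates versus free GDP concentration.

    Truth keys: ``tubulin_uM``, ``affinity_ratio``, optional ``slope`` /
    ``intercept`` of the growth law.  ``x_uM`` in the output is free GDP.
    """
    if spec.kind != "growth_series":
        raise ValueError("spec.kind must be 'growth_series'")
    if gdp_concentrations is None:
        gdp_concentrations = [0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0]
    t = spec.truth
    model = [
        minus_growth_prediction(
            t["tubulin_uM"], g, t["affinity_ratio"],
            slope=t.get("slope", 0.9), intercept=t.get("intercept", -0.05),
        )
        for g in gdp_concentrations
    ]
    df = _noisy_table(gdp_concentrations, model, spec)
    df.attrs["metadata"] = _metadata(spec)
    return df


def generate_binding_dataset(
    spec: FixtureSpec, concentrations: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Synthetic fluorescence assay table.

    ``isotherm`` truth keys: ``amp_A``, ``base_B``, ``kd_6t``; ``x_uM`` is
    6-Thio-GTP.  ``competition`` truth keys add ``kd_nuc``, ``floor_C`` and
    ``six_thio`` (the fixed reporter concentration, 3 uM by default);
    ``x_uM`` is the unlabelled competitor.
    """
    t = spec.truth
    if spec.kind == "isotherm":
        if concentrations is None:
            concentrations = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0, 20.0, 40.0]
        model = quench_isotherm(concentrations, t["amp_A"], t["base_B"], t["kd_6t"])
    elif spec.kind == "competition":
        if concentrations is None:
            concentrations = [0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]
        model = competition_model(
            concentrations, t.get("six_thio", 3.0), t["amp_A"], t["floor_C"],
            t["kd_nuc"], t["kd_6t"],
        )
    else:
        raise ValueError("spec.kind must be 'isotherm' or 'competition'")
    df = _noisy_table(concentrations, model, spec)
    df.attrs["metadata"] = _metadata(spec)
    return df


def _metadata(spec: FixtureSpec) -> dict:
    return {
        "generator": spec.kind,
        "generator_version": GENERATOR_VERSION,
        "truth": dict(spec.truth),
        "cv": spec.cv,
        "n_per_condition": spec.n_per_condition,
        "rng_seed": spec.rng_seed,
    }


def write_table(df: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a CSV with a ``#``-prefixed JSON metadata header."""
    meta = metadata if metadata is not None else df.attrs.get("metadata", {})
    with open(path, "w") as fh:
        if meta:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`; metadata lands in
    ``df.attrs['metadata']``."""
    meta = {}
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines(keepends=True)
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            meta = json.loads(line.lstrip("# ").strip() or "{}")
            body_start += 1
        else:
            break
    df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    df.attrs["metadata"] = meta
    return df
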