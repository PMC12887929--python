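"""Batch generation of power lookup tables over (series length x effect) grids.

Each table fixes the AR(1) autocorrelation and innovation SD, places the
intervention at the midpoint of the series, sets the intercept to zero and
simulates no covariate and no baseline trend — except for change-in-trend
tables, where a zero-slope deterministic baseline trend is included and
modelled as a time regressor, so the analysis adjusts for a baseline slope
just as a practitioner would when testing a slope change.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .dgp import (
    CovariateSpec,
    ErrorModelSpec,
    InterventionSpec,
    ScenarioConfig,
    TrendSpec,
)
from .power import PowerEstimate, derive_seed, estimate_power

__all__ = [
    "LookupGrid",
    "LookupTable",
    "generate_lookup_table",
    "write_lookup_csv",
    "read_lookup_csv",
    "write_wide_csv",
]

FORMAT_VERSION = 1
MIN_TIMEPOINTS = 20


@dataclass(frozen=True)
class LookupGrid:
    """Grid of series lengths and effect sizes at fixed error settings."""

    times: tuple[int, ...]
    effects: tuple[float, ...]
    intervention_kind: str = "step"
    ar1: float = 0.5
    noise_sd: float = 1.0
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(int(t) for t in self.times))
        object.__setattr__(self, "effects", tuple(float(e) for e in self.effects))
        if not self.times or not self.effects:
            raise ValueError("lookup grid must have at least one time and one effect")
        if min(self.times) < MIN_TIMEPOINTS:
            raise ValueError(
                f"series lengths below {MIN_TIMEPOINTS} are unreliable "
                "(autoregressive estimates become unstable); "
                f"got min(times) = {min(self.times)}"
            )
        if np.any(np.diff(self.times) <= 0) or np.any(np.diff(self.effects) <= 0):
            raise ValueError("times and effects must be strictly increasing")

    def cell_config(self, t: int, effect: float) -> ScenarioConfig:
        """Scenario for one cell: midpoint intervention, zero intercept."""
        if self.intervention_kind == "trend_change":
            trend = TrendSpec(
                kind="deterministic", magnitude=0.0, include_in_dgp=True, model_method="xreg"
            )
        else:
            trend = TrendSpec(include_in_dgp=False)
        return ScenarioConfig(
            t=t,
            k=t // 2,
            b0=0.0,
            intervention=InterventionSpec(
                kind=self.intervention_kind, effect_size=effect, pulse_duration=1
            ),
            covariate=CovariateSpec(include_in_dgp=False),
            trend=trend,
            error_model=ErrorModelSpec(ar_coefs=(self.ar1,), noise_sd=self.noise_sd),
            n_sims=self.n_sims,
            seed=derive_seed(self.seed, t, int(round(effect * 10**6))),
        )


@dataclass(frozen=True)
class LookupTable:
    """Power estimates over a LookupGrid; ``power[i][j]`` is (times[i], effects[j])."""

    grid: LookupGrid
    power: tuple[tuple[PowerEstimate, ...], ...] = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format tidy frame, one row per grid cell."""
        rows = []
        for i, t in enumerate(self.grid.times):
            for j, effect in enumerate(self.grid.effects):
                est = self.power[i][j]
                rows.append(
                    {
                        "time": t,
                        "effect": effect,
                        "power": est.power,
                        "n_effective": est.n_effective,
                        "n_requested": est.n_requested,
                        "n_failed": est.n_failed,
                        "alpha": est.alpha,
                        "seed": est.seed,
                    }
                )
        return pd.DataFrame(rows)

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide layout: one row per series length, one column per effect size."""
        values = [[est.power for est in row] for row in self.power]
        return pd.DataFrame(
            values,
            index=pd.Index(self.grid.times, name="time"),
            columns=[f"{e:g}" for e in self.grid.effects],
        )

    def monotonicity_violations(self, z: float = 3.0) -> list[tuple[int, float]]:
        """Cells where power drops along time or effect by more than z * mc_se.

        Sampling noise makes small decreases expected; flagged cells are
        those whose decrease exceeds ``z`` combined standard errors.
        """
        flagged = []
        for i, t in enumerate(self.grid.times):
            for j, effect in enumerate(self.grid.effects):
                est = self.power[i][j]
                for prev in ([self.power[i][j - 1]] if j else []) + (
                    [self.power[i - 1][j]] if i else []
                ):
                    se = np.hypot(est.mc_se, prev.mc_se)
                    if est.power < prev.power - z * se:
                        flagged.append((t, effect))
        return sorted(set(flagged))


def generate_lookup_table(grid: LookupGrid, progress: bool = False) -> LookupTable:
    """Estimate power for every cell of the grid.

    Cells are simulated independently with per-cell seeds derived from the
    grid seed and cell coordinates, so regeneration of any subset of cells
    reproduces the full-table values.
    """
    rows = []
    for t in grid.times:
        row = []
        for effect in grid.effects:
            row.append(estimate_power(grid.cell_config(t, effect)))
            if progress:
                print(f"t={t} effect={effect:g} power={row[-1].power:.3f}", flush=True)
        rows.append(tuple(row))
    return LookupTable(grid=grid, power=tuple(rows))


def _header_lines(grid: LookupGrid) -> list[str]:
    return [
        f"# itspower-lookup-table v{FORMAT_VERSION}",
        f"# intervention_kind: {grid.intervention_kind}",
        f"# ar1: {grid.ar1!r}",
        f"# noise_sd: {grid.noise_sd!r}",
        f"# n_sims: {grid.n_sims}",
        f"# seed: {grid.seed}",
    ]


def write_lookup_csv(table: LookupTable, path) -> None:
    """Write the table losslessly: metadata header plus long-format rows."""
    with open(path, "w") as fh:
        for line in _header_lines(table.grid):
            fh.write(line + "\n")
        table.to_frame().to_csv(fh, index=False)


def write_wide_csv(table: LookupTable, path) -> None:
    """Write the printed-table layout: rows by time, columns by effect, 2 dp."""
    with open(path, "w") as fh:
        for line in _header_lines(table.grid):
            fh.write(line + "\n")
        table.to_wide_frame().to_csv(fh, float_format="%.2f")


class LookupFormatError(ValueError):
    """A lookup-table file does not match the expected format."""


def read_lookup_csv(path) -> LookupTable:
    """Read a table written by :func:`write_lookup_csv` (lossless round-trip)."""
    with open(path) as fh:
        lines = fh.readlines()

    meta: dict[str, str] = {}
    body_start = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            body_start = lineno - 1
            break
        if lineno == 1:
            if not line.strip().startswith("# itspower-lookup-table v"):
                raise LookupFormatError(
                    f"line 1: missing 'itspower-lookup-table' version stamp"
                )
            continue
        try:
            key, value = line[1:].split(":", 1)
        except ValueError:
            raise LookupFormatError(f"line {lineno}: malformed header {line.strip()!r}")
        meta[key.strip()] = value.strip()
    else:
        raise LookupFormatError("file contains no data rows")

    try:
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    except Exception as exc:
        raise LookupFormatError(f"line {body_start + 1}: unparseable data ({exc})")
    required = {"time", "effect", "power", "n_effective", "n_requested", "n_failed", "alpha", "seed"}
    if missing := required - set(df.columns):
        raise LookupFormatError(
            f"line {body_start + 1}: missing column(s) {sorted(missing)}"
        )

    grid = LookupGrid(
        times=tuple(sorted(df["time"].unique())),
        effects=tuple(sorted(df["effect"].unique())),
        intervention_kind=meta["intervention_kind"],
        ar1=float(meta["ar1"]),
        noise_sd=float(meta["noise_sd"]),
        n_sims=int(meta["n_sims"]),
        seed=int(meta["seed"]),
    )
    lookup = {
        (int(r.time), float(r.effect)): PowerEstimate(
            power=float(r.power),
            n_effective=int(r.n_effective),
            n_requested=int(r.n_requested),
            n_failed=int(r.n_failed),
            alpha=float(r.alpha),
            seed=int(r.seed),
        )
        for r in df.itertuples()
    }
    try:
        power = tuple(
            tuple(lookup[(t, e)] for e in grid.effects) for t in grid.times
        )
    except KeyError as exc:
        raise LookupFormatError(f"incomplete grid: missing cell {exc.args[0]}")
    return LookupTable(grid=grid, power=power)
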