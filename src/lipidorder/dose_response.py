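"""Dose–response assembly of per-concentration deconvolution results.

One membrane system (a liposome preparation or a cell line, at one
temperature) is titrated with increasing peptide concentrations; each
concentration yields one deconvolved spectrum.  This module assembles those
results into a :class:`DoseSeries`, computes differences from the
untreated control (:class:`DeltaSeries`), and ranks the spectral
parameters (GP, ΔS_r, R_S) by how well their delta curves separate
different membrane systems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .deconvolution import DeconvolutionResult
from .exceptions import SeriesError

#: Spectral parameters tracked along a titration.
PARAMETERS = ("gp", "delta_s_r", "r_s", "s_b")


@dataclass(frozen=True)
class SampleLabel:
    """Parsed sample identity: membrane system, temperature, peptide dose."""

    system: str
    temperature_c: float
    melittin_um: float

    @classmethod
    def parse(cls, text: str) -> "SampleLabel":
        """Parse ``"system;temperature_C;melittin_uM"`` (``|`` also accepted)."""
        parts = [p.strip() for p in text.replace("|", ";").split(";")]
        if len(parts) != 3:
            raise SeriesError(
                f"label {text!r} does not parse as 'system;temperature_C;melittin_uM'"
            )
        try:
            return cls(parts[0], float(parts[1]), float(parts[2]))
        except ValueError as exc:
            raise SeriesError(f"label {text!r}: {exc}") from None


@dataclass(frozen=True)
class DoseSeries:
    """Per-concentration spectral parameters for one system and temperature.

    ``table`` is indexed by melittin concentration (µM, ascending, first
    entry 0 = control) with one column per entry of :data:`PARAMETERS`
    plus the fitted band positions.
    """

    system: str
    temperature_c: float
    table: pd.DataFrame

    @property
    def concentrations(self) -> np.ndarray:
        return self.table.index.to_numpy()


@dataclass(frozen=True)
class DeltaSeries:
    """Differences of each parameter from its 0 µM control value."""

    system: str
    temperature_c: float
    table: pd.DataFrame

    @property
    def concentrations(self) -> np.ndarray:
        return self.table.index.to_numpy()


def build_series(
    results: Iterable[tuple[SampleLabel | str, DeconvolutionResult]],
) -> DoseSeries:
    """Assemble labelled deconvolution results into a sorted dose series.

    All labels must share one system and temperature; concentrations must
    be unique and include the 0 µM control.  Input order is irrelevant.
    """
    rows = []
    for label, res in results:
        if isinstance(label, str):
            label = SampleLabel.parse(label)
        rows.append((label, res))
    if not rows:
        raise SeriesError("no results to assemble")
    systems = {(lab.system, lab.temperature_c) for lab, _ in rows}
    if len(systems) > 1:
        raise SeriesError(f"mixed systems/temperatures in one series: {sorted(systems)}")
    concs = [lab.melittin_um for lab, _ in rows]
    if len(set(concs)) != len(concs):
        dup = sorted({c for c in concs if concs.count(c) > 1})
        raise SeriesError(f"duplicate concentrations {dup}")
    if 0.0 not in concs:
        raise SeriesError("missing 0 µM control")
    rows.sort(key=lambda item: item[0].melittin_um)
    table = pd.DataFrame(
        {
            "gp": [r.gp for _, r in rows],
            "delta_s_r": [r.delta_s_r for _, r in rows],
            "r_s": [r.r_s for _, r in rows],
            "s_b": [r.s_b for _, r in rows],
            "blue_position": [r.blue.position for _, r in rows],
            "green_position": [r.green.position for _, r in rows],
        },
        index=pd.Index([lab.melittin_um for lab, _ in rows], name="melittin_uM"),
    )
    lab = rows[0][0]
    return DoseSeries(system=lab.system, temperature_c=lab.temperature_c, table=table)


def compute_deltas(series: DoseSeries) -> DeltaSeries:
    """Subtract the 0 µM control value from each parameter at each dose."""
    control = series.table.loc[0.0]
    return DeltaSeries(
        system=series.system,
        temperature_c=series.temperature_c,
        table=series.table - control,
    )


@dataclass(frozen=True)
class SensitivityRanking:
    """Cross-system comparison of parameter sensitivity.

    ``max_abs_delta`` holds, per system and parameter, the largest absolute
    change from control over the titration.  ``separation`` holds one score
    per parameter: the minimum pairwise distance between the systems' delta
    curves (mean absolute difference over shared concentrations) normalized
    by the parameter's pooled delta range — large when every pair of
    systems stays distinguishable along the whole titration.  ``ranking``
    lists parameters by decreasing separation; with fewer than two systems
    no separation is defined and ``applicable`` is False.
    """

    max_abs_delta: pd.DataFrame
    separation: pd.Series
    ranking: tuple[str, ...]
    applicable: bool


def sensitivity_rank(
    deltas: Sequence[DeltaSeries],
    parameters: Sequence[str] = ("gp", "delta_s_r", "r_s"),
) -> SensitivityRanking:
    """Rank spectral parameters by cross-system separation of delta curves."""
    if not deltas:
        raise SeriesError("sensitivity ranking needs at least one delta series")
    max_abs = pd.DataFrame(
        {p: [d.table[p].abs().max() for d in deltas] for p in parameters},
        index=pd.Index([d.system for d in deltas], name="system"),
    )
    if len(deltas) < 2:
        sep = pd.Series(np.nan, index=list(parameters))
        return SensitivityRanking(max_abs, sep, tuple(parameters), applicable=False)
    scores = {}
    for p in parameters:
        pooled = np.concatenate([d.table[p].to_numpy() for d in deltas])
        rng = float(pooled.max() - pooled.min())
        pair_dists = [
            _curve_distance(a.table[p], b.table[p])
            for a, b in itertools.combinations(deltas, 2)
        ]
        scores[p] = min(pair_dists) / rng if rng > 0 else 0.0
    sep = pd.Series(scores)
    ranking = tuple(sep.sort_values(ascending=False, kind="stable").index)
    return SensitivityRanking(max_abs, sep, ranking, applicable=True)


def _curve_distance(a: pd.Series, b: pd.Series) -> float:
    """Mean absolute difference between two delta curves.

    Curves on different concentration grids are linearly interpolated onto
    the shared part of their ranges.
    """
    ca, cb = a.index.to_numpy(float), b.index.to_numpy(float)
    lo, hi = max(ca.min(), cb.min()), min(ca.max(), cb.max())
    grid = np.unique(np.concatenate([ca, cb]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0:
        raise SeriesError("delta curves share no concentration range")
    va = np.interp(grid, ca, a.to_numpy(float))
    vb = np.interp(grid, cb, b.to_numpy(float))
    return float(np.mean(np.abs(va - vb)))


def aggregate_replicates(series: Sequence[DoseSeries]) -> pd.DataFrame:
    """Mean ± SD across replicate series of one system (long format)."""
    if not series:
        raise SeriesError("no replicates")
    systems = {(s.system, s.temperature_c) for s in series}
    if len(systems) > 1:
        raise SeriesError(f"replicates mix systems: {sorted(systems)}")
    stacked = pd.concat([s.table for s in series])
    grouped = stacked.groupby(level=0)
    out = grouped.agg(["mean", "std"])
    out.columns = [f"{p}_{stat}" for p, stat in out.columns]
    return out


def to_long_frame(
    series: Sequence[DoseSeries], deltas: Sequence[DeltaSeries] = ()
) -> pd.DataFrame:
    """Long-format table: system, temperature_C, melittin_uM, parameter, value[, delta]."""
    records = []
    delta_lookup = {(d.system, d.temperature_c): d for d in deltas}
    for s in series:
        d = delta_lookup.get((s.system, s.temperature_c))
        for conc, row in s.table.iterrows():
            for p in s.table.columns:
                rec = {
                    "system": s.system,
                    "temperature_C": s.temperature_c,
                    "melittin_uM": conc,
                    "parameter": p,
                    "value": row[p],
                }
                if d is not None and p in d.table.columns:
                    rec["delta"] = d.table.loc[conc, p]
                records.append(rec)
    return pd.DataFrame.from_records(records)
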