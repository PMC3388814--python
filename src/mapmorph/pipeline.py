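"""The morphing iteration loop: search -> smooth -> apply -> regularize.

Each cycle runs the per-residue translation search against the (fixed) target
map from the model's current coordinates, smooths the shifts within chain
segments, translates each residue by its smoothed shift, and optionally
regularizes the backbone geometry with a density bias.  Shift magnitudes
normally drop sharply after the first cycle; iteration stops after
``n_cycles`` (default six) or earlier once the mean applied shift falls below
a small threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import MapGrid, calc_model_map, map_correlation
from .metrics import compare_structures
from .model_io import Structure
from .morph_engine import MorphConfig, residue_shift_search
from .regularize import GeometryRestraints, regularize
from .smoothing import apply_shifts, mean_shift_magnitude, shifts_table, smooth_all

__all__ = ["CycleRecord", "morph_cycle", "morph"]


@dataclass
class CycleRecord:
    """Summary of one morphing cycle."""

    cycle: int
    mean_shift: float           # A, mean |dx_smooth| over residues
    fraction_included: float    # residues passing the cc_min filter
    map_cc: float               # model-map vs target correlation after the cycle
    rmsd_vs_truth: float | None = None
    spread_vs_truth: float | None = None


def morph_cycle(model: Structure, target: MapGrid, config: MorphConfig,
                cycle_index: int = 1, truth: Structure | None = None,
                restraints: GeometryRestraints | None = None,
                ) -> tuple[Structure, CycleRecord]:
    """Run one full morphing cycle and summarize it."""
    shifts = residue_shift_search(model, target, config)
    if not shifts:
        raise ValueError("no searchable residues (no centre atoms)")
    n_inc = sum(1 for s in shifts if s.included)
    if n_inc == 0:
        warnings.warn("no residue passed the local-correlation filter; "
                      "applying regularization only", stacklevel=2)
        new = regularize(model, restraints, target) if config.regularize else model.copy()
        mean_shift = 0.0
    else:
        smoothed = smooth_all(shifts, config)
        new = apply_shifts(model, smoothed)
        mean_shift = mean_shift_magnitude(smoothed)
        if config.regularize:
            new = regularize(new, restraints, target)

    model_map = calc_model_map(new, d_min=config.d_min, dims=target.dims)
    try:
        map_cc = map_correlation(model_map, target)
    except ValueError:  # constant (e.g. empty) target map
        map_cc = float("nan")
    record = CycleRecord(
        cycle=cycle_index,
        mean_shift=mean_shift,
        fraction_included=n_inc / len(shifts),
        map_cc=map_cc,
    )
    if truth is not None:
        cmp = compare_structures(new, truth)
        record.rmsd_vs_truth = cmp.rmsd
        record.spread_vs_truth = cmp.spread
    record._shifts = shifts  # noqa: SLF001 -- kept for CSV export
    return new, record


def morph(model: Structure, target: MapGrid, config: MorphConfig | None = None,
          truth: Structure | None = None,
          restraints: GeometryRestraints | None = None,
          early_stop: bool = True) -> tuple[Structure, list[CycleRecord]]:
    """Iterate morphing cycles (default six, with early stop on converged shifts)."""
    config = config or MorphConfig()
    if config.n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    records: list[CycleRecord] = []
    current = model
    for i in range(1, config.n_cycles + 1):
        current, rec = morph_cycle(current, target, config, cycle_index=i,
                                   truth=truth, restraints=restraints)
        records.append(rec)
        if early_stop and rec.mean_shift < config.early_stop_shift:
            break
    return current, records


def records_table(records: list[CycleRecord]):
    """Per-cycle log as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame([{
        "cycle": r.cycle,
        "mean_shift": r.mean_shift,
        "fraction_included": r.fraction_included,
        "map_cc": r.map_cc,
        "rmsd_vs_truth": r.rmsd_vs_truth,
        "spread_vs_truth": r.spread_vs_truth,
    } for r in records])
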