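"""Windowed smoothing of per-residue shift vectors and their application.

Raw translation-search shifts are noisy and some residues are excluded
outright (low local correlation, empty neighbourhood).  Under the assumption
that the true deformation varies gradually along the chain, each Cartesian
component of the shifts is smoothed by an unweighted ordinary-least-squares
line over a window of residues (default 11), fitted to the included residues
only and evaluated at the centre residue.  A regression (rather than a
weighted mean) is used precisely because points may be missing from the
window.  Windows never cross a gap in residue numbering: chains are split
into maximal consecutively-numbered segments first.

Excluded residues still receive a smoothed shift from their neighbours.  The
smoothed shift is applied as a single translation to every atom of the
residue, preserving intra-residue geometry and side-chain orientation at the
cost of distorting inter-residue links (which regularization later repairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_io import Structure
from .morph_engine import MorphConfig, ResidueShift

__all__ = [
    "SmoothedShift",
    "smooth_segment",
    "smooth_all",
    "apply_shifts",
    "mean_shift_magnitude",
    "shifts_table",
]


@dataclass
class SmoothedShift:
    chain_id: str
    seq_id: int
    dx_smooth: np.ndarray = field(default_factory=lambda: np.zeros(3))
    n_support: int = 0
    fallback: bool = False


def _ols_at(seq_ids: np.ndarray, vecs: np.ndarray, at: float) -> np.ndarray:
    """Least-squares line per component through (seq_id, vec), evaluated at ``at``."""
    x = seq_ids.astype(float)
    design = np.stack([np.ones_like(x), x], axis=1)
    coef, *_ = np.linalg.lstsq(design, vecs, rcond=None)
    return coef[0] + coef[1] * at


def smooth_segment(shifts: list[ResidueShift], window: int, cc_min: float) -> list[SmoothedShift]:
    """Smooth one contiguous segment of per-residue shifts.

    ``shifts`` must come from a single chain segment with strictly
    consecutive seq_ids.  ``cc_min`` is accepted for explicitness but
    exclusion is read from each shift's ``included`` flag (set by the search
    from the same threshold).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    seq = np.array([s.seq_id for s in shifts])
    if len(seq) > 1 and not np.all(np.diff(seq) == 1):
        raise ValueError("smooth_segment requires consecutive seq_ids")
    half = (window - 1) // 2

    inc_mask = np.array([s.included for s in shifts])
    vectors = np.array([s.dx_cent if s.included else np.zeros(3) for s in shifts])

    out: list[SmoothedShift] = []
    for i, s in enumerate(shifts):
        lo = max(0, i - half)
        hi = min(len(shifts), i + half + 1)
        sel = np.arange(lo, hi)[inc_mask[lo:hi]]
        n_support = len(sel)
        if n_support >= 2:
            dx = _ols_at(seq[sel], vectors[sel], s.seq_id)
            fallback = False
        elif n_support == 1:
            dx = vectors[sel[0]].copy()
            fallback = True
        else:
            dx = s.dx_cent.copy() if s.included else np.zeros(3)
            fallback = True
        out.append(SmoothedShift(s.chain_id, s.seq_id, np.asarray(dx, dtype=float),
                                 n_support, fallback))
    return out


def _set_smoothing_vector(shifts: list[ResidueShift], which: str) -> list[ResidueShift]:
    if which == "dx_cent":
        return shifts
    remapped = []
    for s in shifts:
        r = ResidueShift(s.chain_id, s.seq_id, s.dx_max.copy(), s.dx_max.copy(),
                         s.cc_local, s.included, s.no_peak)
        remapped.append(r)
    return remapped


def smooth_all(shifts: list[ResidueShift], config: MorphConfig) -> list[SmoothedShift]:
    """Smooth shifts chain by chain, segment by segment.

    Segments are maximal runs of consecutive seq_ids within one chain; each
    is smoothed independently so windows never span a numbering gap.  The
    vector smoothed is chosen by ``config.smooth_on`` (peak centroid by
    default, argmax grid point as the alternative).
    """
    by_chain: dict[str, list[ResidueShift]] = {}
    for s in shifts:
        by_chain.setdefault(s.chain_id, []).append(s)
    out: list[SmoothedShift] = []
    for chain_shifts in by_chain.values():
        chain_shifts = sorted(chain_shifts, key=lambda s: s.seq_id)
        chain_shifts = _set_smoothing_vector(chain_shifts, config.smooth_on)
        seg: list[ResidueShift] = []
        for s in chain_shifts:
            if seg and s.seq_id != seg[-1].seq_id + 1:
                out.extend(smooth_segment(seg, config.window, config.cc_min))
                seg = []
            seg.append(s)
        if seg:
            out.extend(smooth_segment(seg, config.window, config.cc_min))
    return out


def apply_shifts(structure: Structure, smoothed: list[SmoothedShift]) -> Structure:
    """Translate every atom of each residue by that residue's smoothed shift.

    Residues without a smoothed shift are left untouched.  Returns a new
    structure; the input is not modified.
    """
    table: dict[tuple[str, int], np.ndarray] = {}
    for s in smoothed:
        key = (s.chain_id, s.seq_id)
        if key in table:
            raise ValueError(f"duplicate smoothed shift for residue {key}")
        table[key] = s.dx_smooth
    new = structure.copy()
    for chain, res in new.residues():
        dx = table.get((chain.chain_id, res.seq_id))
        if dx is None:
            continue
        for atom in res.atoms:
            atom.xyz = atom.xyz + dx
    return new


def mean_shift_magnitude(smoothed: list[SmoothedShift]) -> float:
    """Arithmetic mean of |dx_smooth| over all residues with a shift."""
    if not smoothed:
        raise ValueError("no smoothed shifts")
    return float(np.mean([np.linalg.norm(s.dx_smooth) for s in smoothed]))


def shifts_table(raw: list[ResidueShift], smoothed: list[SmoothedShift]):
    """Per-residue raw and smoothed shifts as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    sm = {(s.chain_id, s.seq_id): s for s in smoothed}
    rows = []
    for s in raw:
        m = sm.get((s.chain_id, s.seq_id))
        rows.append({
            "chain": s.chain_id,
            "seq_id": s.seq_id,
            "dx_max_x": s.dx_max[0], "dx_max_y": s.dx_max[1], "dx_max_z": s.dx_max[2],
            "dx_cent_x": s.dx_cent[0], "dx_cent_y": s.dx_cent[1], "dx_cent_z": s.dx_cent[2],
            "cc_local": s.cc_local,
            "included": s.included,
            "dx_smooth_x": m.dx_smooth[0] if m else np.nan,
            "dx_smooth_y": m.dx_smooth[1] if m else np.nan,
            "dx_smooth_z": m.dx_smooth[2] if m else np.nan,
        })
    return pd.DataFrame(rows)
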