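"""Peak detection, local-mode assignment and reference reconciliation.

Peaks of a simulated vibrational DOS are assigned local-mode character by
measuring how much unit-area spectral mass each local-mode spectrum carries
within a window around the peak, listing contributors in descending order.
Assignment tables at two coverages give label-matched frequency-shift
tables (positive = blue shift), and calculated peak lists are reconciled
against experimental (e.g. RAIRS) reference lists through rms discrepancy
statistics, absolute (cm⁻¹) and relative (%).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import signal

from .errors import PreconditionError
from .spectra import Spectrum

__all__ = [
    "Peak",
    "AssignmentTable",
    "DiscrepancyStats",
    "detect_peaks",
    "assign_peaks",
    "peak_shifts",
    "rms_discrepancy",
    "load_assignment_table",
    "load_reference_pairs",
    "bundled_path",
]


@dataclass
class Peak:
    """A detected spectral peak (frequencies in cm⁻¹)."""

    frequency: float
    height: float
    prominence: float
    width: float

    def rounded(self, to: float = 5.0) -> float:
        """Frequency rounded for reporting (default: nearest 5 cm⁻¹)."""
        return float(to * round(self.frequency / to))


@dataclass
class AssignmentTable:
    """Rows of (peak frequency, contributors) sorted by frequency descending.

    Each contributor list holds ``(label, fraction)`` pairs in descending
    order of contribution; loaded literature tables carry ``None`` fractions
    but preserve the printed ordering.
    """

    rows: list[tuple[float, list[tuple[str, float | None]]]]

    def dominant(self) -> list[tuple[str, float]]:
        """(dominant label, frequency) per row, frequency-descending."""
        return [(labels[0][0], f) for f, labels in self.rows if labels]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(f, ";".join(lab for lab, _ in labels),
              ";".join("" if c is None else f"{c:.3f}" for _, c in labels))
             for f, labels in self.rows],
            columns=["frequency_cm1", "assignment", "contributions"])


@dataclass
class DiscrepancyStats:
    """Rms agreement between reference and calculated frequencies.

    ``rms_abs``/``rms_rel`` are exact; the paper-style rounded values
    (nearest cm⁻¹, nearest 0.1 %) are exposed as properties.
    """

    pairs: list[tuple[float, float]]       # (reference, calculated) cm⁻¹
    rms_abs: float                         # cm⁻¹
    rms_rel: float                         # percent
    excluded_labels: list[str] = field(default_factory=list)

    @property
    def rms_abs_rounded(self) -> float:
        return float(round(self.rms_abs))

    @property
    def rms_rel_rounded(self) -> float:
        return float(round(self.rms_rel, 1))


def detect_peaks(spec: Spectrum,
                 min_prominence: float = 0.01,
                 min_separation: float = 10.0) -> list[Peak]:
    """Local maxima with prominence ≥ ``min_prominence``·max(intensity),
    separated by at least ``min_separation`` cm⁻¹.  May return an empty list.
    """
    y = spec.intensity
    if y.size < 3:
        raise PreconditionError("spectrum too short for peak detection")
    top = float(y.max())
    if top <= 0:
        return []
    dist = max(1, int(np.ceil(min_separation / spec.resolution)))
    idx, props = signal.find_peaks(y, prominence=min_prominence * top,
                                   distance=dist)
    widths = signal.peak_widths(y, idx, rel_height=0.5)[0] * spec.resolution
    return [Peak(frequency=float(spec.wavenumbers[i]),
                 height=float(y[i]),
                 prominence=float(props["prominences"][k]),
                 width=float(widths[k]))
            for k, i in enumerate(idx)]


def assign_peaks(peaks: list[Peak],
                 local_spectra: dict[str, Spectrum],
                 window_halfwidth: float = 25.0,
                 floor: float = 0.10) -> AssignmentTable:
    """Assign local-mode character to peaks by windowed unit-area mass.

    For each peak, a mode's contribution is the integral of its unit-area
    spectrum within ±``window_halfwidth`` of the peak frequency.  Modes
    below ``floor`` × the top contributor are omitted; ties are broken
    alphabetically; a peak with no contributor is reported unassigned
    (empty list).
    """
    grids = [sp.wavenumbers for sp in local_spectra.values()]
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g, grids[0]):
            raise PreconditionError("local spectra must share a common grid")
    for name, sp in local_spectra.items():
        if sp.normalization != "unit_area":
            raise PreconditionError(f"local spectrum {name} is not unit-area")
    rows = []
    for pk in sorted(peaks, key=lambda p: -p.frequency):
        contrib = []
        for name, sp in sorted(local_spectra.items()):
            w = sp.wavenumbers
            m = (w >= pk.frequency - window_halfwidth) & \
                (w <= pk.frequency + window_halfwidth)
            mass = float(np.trapezoid(sp.intensity[m], w[m])) if m.sum() > 1 else 0.0
            contrib.append((name, mass))
        top = max(c for _, c in contrib)
        if top <= 0:
            rows.append((pk.frequency, []))
            continue
        kept = [(n, c) for n, c in contrib if c >= floor * top]
        kept.sort(key=lambda nc: (-nc[1], nc[0]))
        rows.append((pk.frequency, kept))
    return AssignmentTable(rows=rows)


def peak_shifts(table_low: AssignmentTable,
                table_high: AssignmentTable) -> pd.DataFrame:
    """Label-matched frequency shifts between two coverages (cm⁻¹).

    Rows are matched on the dominant label; a label occurring several times
    in a table (e.g. a main peak and a satellite) is paired by descending
    frequency rank.  Positive shift = blue shift (high − low).  Unmatched
    rows appear with ``matched = False`` and no shift.
    """
    def ranked(table):
        out: dict[str, list[float]] = {}
        for lab, f in table.dominant():
            out.setdefault(lab, []).append(f)
        return out

    lo, hi = ranked(table_low), ranked(table_high)
    rows = []
    for lab in sorted(set(lo) | set(hi)):
        flo = lo.get(lab, [])
        fhi = hi.get(lab, [])
        for k in range(max(len(flo), len(fhi))):
            has = k < len(flo) and k < len(fhi)
            rows.append({
                "label": lab, "rank": k,
                "low_cm1": flo[k] if k < len(flo) else np.nan,
                "high_cm1": fhi[k] if k < len(fhi) else np.nan,
                "shift_cm1": fhi[k] - flo[k] if has else np.nan,
                "matched": has,
            })
    return pd.DataFrame(rows)


def rms_discrepancy(pairs: list[tuple[str, float, float]],
                    exclude: set[str] | None = None) -> DiscrepancyStats:
    """Rms discrepancy between labelled (reference, calculated) pairs.

    ``pairs`` rows are ``(label, reference, calculated)``; labels in
    ``exclude`` are dropped before computing

        rms_abs = √(Σ(calc − ref)²/n),
        rms_rel = √(Σ((calc − ref)/ref)²/n) × 100.
    """
    exclude = exclude or set()
    kept = [(lab, r, c) for lab, r, c in pairs if lab not in exclude]
    if not kept:
        raise PreconditionError("no pairs left after exclusion")
    ref = np.array([r for _, r, _ in kept], dtype=float)
    calc = np.array([c for _, _, c in kept], dtype=float)
    d = calc - ref
    return DiscrepancyStats(
        pairs=[(float(r), float(c)) for _, r, c in kept],
        rms_abs=float(np.sqrt(np.mean(d ** 2))),
        rms_rel=float(100.0 * np.sqrt(np.mean((d / ref) ** 2))),
        excluded_labels=sorted(exclude))


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------

def bundled_path(name: str):
    """Filesystem path of a bundled data file (context-manager-free)."""
    return resources.files("advib.data").joinpath(name)


def load_assignment_table(path=None, column: str = "freq_third_ml",
                          ) -> AssignmentTable:
    """Load a literature-style assignment table from CSV.

    The CSV has one or more frequency columns plus an ``assignment`` column
    with semicolon-separated labels in descending order of contribution;
    blank frequencies (peaks absent at that coverage) are skipped.
    """
    src = bundled_path("table1_assignments.csv") if path is None else path
    df = pd.read_csv(src)
    rows = []
    for _, rec in df.iterrows():
        if pd.isna(rec[column]):
            continue
        labels = [(lab.strip(), None) for lab in str(rec["assignment"]).split(";")]
        rows.append((float(rec[column]), labels))
    rows.sort(key=lambda r: -r[0])
    return AssignmentTable(rows=rows)


def load_reference_pairs(path=None) -> list[tuple[str, float, float]]:
    """Load labelled (reference, calculated) pairs from CSV.

    Columns: ``label``, ``rairs`` (reference cm⁻¹), ``md`` (calculated
    cm⁻¹); defaults to the bundled experimental/MD reconciliation list.
    """
    src = bundled_path("table2_rairs_md.csv") if path is None else path
    df = pd.read_csv(src)
    return [(str(r["label"]), float(r["rairs"]), float(r["md"]))
            for _, r in df.iterrows()]
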