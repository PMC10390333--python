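"""FTICR-MS peak filtering, formula selection and van Krevelen classification.

Ultra-high-resolution mass spectra of soil water-extractable organic matter
yield peak lists with candidate molecular formulas (CHONSP only).  Peaks are
retained when S/N > 7 with at least one candidate under 1 ppm mass error; a
formula is selected per peak (lowest |error|, ties to fewest heteroatoms,
phosphorus only with at least four oxygens); compounds are then binned into
biochemical classes from their O:C and H:C elemental ratios on the van
Krevelen plane, and per-sample class profiles are reported as count-based
relative abundances.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics.mass import Composition

__all__ = [
    "CLASS_NAMES",
    "ALLOWED_ELEMENTS",
    "parse_formula",
    "filter_peaks",
    "select_formula",
    "classify",
    "class_profile",
    "process_peaks",
]

ALLOWED_ELEMENTS = frozenset({"C", "H", "O", "N", "S", "P"})

SN_THRESHOLD = 7.0  # strict: S/N must exceed 7
ERROR_PPM_LIMIT = 1.0  # strict: |mass error| must be below 1 ppm
MIN_O_PER_P = 4  # at least four oxygens per assigned phosphorus


@dataclass(frozen=True)
class _Box:
    """One van Krevelen class box; bounds may be open or closed."""

    name: str
    oc_lo: float
    oc_lo_open: bool
    oc_hi: float
    oc_hi_open: bool
    hc_lo: float
    hc_lo_open: bool
    hc_hi: float
    hc_hi_open: bool

    def contains(self, oc: float, hc: float) -> bool:
        lo_oc = oc > self.oc_lo if self.oc_lo_open else oc >= self.oc_lo
        hi_oc = oc < self.oc_hi if self.oc_hi_open else oc <= self.oc_hi
        lo_hc = hc > self.hc_lo if self.hc_lo_open else hc >= self.hc_lo
        hi_hc = hc < self.hc_hi if self.hc_hi_open else hc <= self.hc_hi
        return lo_oc and hi_oc and lo_hc and hi_hc


# Boxes in their conventional listing order; overlapping regions (e.g. the
# low-O:C, high-H:C corner shared by lipids and unsaturated hydrocarbons)
# are resolved first-match-wins in this order.  The condensed-hydrocarbon
# upper O:C bound is 0.95 (the stray factor sometimes printed with it is a
# typesetting artefact).
_BOXES: tuple[_Box, ...] = (
    _Box("lipid", 0.0, True, 0.3, False, 1.5, False, 2.5, False),
    _Box("unsaturated_hydrocarbon", 0.0, False, 0.125, False, 0.8, False, 2.5, True),
    _Box("protein", 0.3, True, 0.55, False, 1.5, False, 2.3, False),
    _Box("amino_sugar", 0.55, True, 0.7, False, 1.5, False, 2.2, False),
    _Box("lignin", 0.125, True, 0.65, False, 0.8, False, 1.5, True),
    _Box("tannin", 0.65, True, 1.1, False, 0.8, False, 1.5, True),
    _Box("condensed_hydrocarbon", 0.0, False, 0.95, False, 0.2, False, 0.8, True),
)

CLASS_NAMES = tuple(b.name for b in _BOXES) + ("unclassified",)

_FORMULA_RE = re.compile(r"^(?:[A-Z][a-z]?\d*)+$")


def parse_formula(formula: str) -> dict[str, int]:
    """Element counts of a molecular formula string (e.g. 'C10H14O3N1')."""
    if not _FORMULA_RE.match(formula.strip()):
        raise ValueError(f"malformed formula: {formula!r}")
    return {el: int(n) for el, n in Composition(formula=formula.strip()).items()}


def _heteroatoms(counts: dict[str, int]) -> int:
    return counts.get("N", 0) + counts.get("S", 0) + counts.get("P", 0)


def _candidate_ok(counts: dict[str, int]) -> bool:
    if set(counts) - ALLOWED_ELEMENTS:
        return False
    if counts.get("P", 0) > 0 and counts.get("O", 0) < MIN_O_PER_P * counts["P"]:
        return False
    return True


def filter_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Retain peaks passing the assignment filters.

    A peak (grouped by ``peak_id``) is kept when its S/N strictly exceeds 7
    and at least one CHONSP candidate has |mass error| < 1 ppm.  Candidate
    rows with other elements or with errors >= 1 ppm are dropped from the
    retained peaks.
    """
    if peaks.empty:
        return peaks.copy()
    df = peaks.copy()
    counts = df["candidate_formula"].map(parse_formula)
    chonsp = counts.map(lambda c: not (set(c) - ALLOWED_ELEMENTS))
    good = (df["sn"] > SN_THRESHOLD) & chonsp & (df["error_ppm"].abs() < ERROR_PPM_LIMIT)
    return df[good.groupby(df["peak_id"]).transform("any") & good].reset_index(drop=True)


def select_formula(candidates: pd.DataFrame) -> tuple[dict | None, bool]:
    """Assign one formula among a peak's candidate rows.

    Candidates containing phosphorus without at least four oxygens per P are
    discarded; among the survivors the lowest |mass error| wins, ties broken
    by fewest heteroatoms (N+S+P), remaining ties by formula string for
    determinism and flagged ambiguous.  Returns ``(assignment, ambiguous)``
    where ``assignment`` is None when no candidate survives.
    """
    recs = []
    for row in candidates.itertuples(index=False):
        counts = parse_formula(row.candidate_formula)
        if not _candidate_ok(counts):
            continue
        recs.append((abs(float(row.error_ppm)), _heteroatoms(counts),
                     row.candidate_formula, counts, float(row.error_ppm)))
    if not recs:
        return None, False
    recs.sort(key=lambda r: (r[0], r[1], r[2]))
    best = recs[0]
    ambiguous = len(recs) > 1 and recs[1][0] == best[0] and recs[1][1] == best[1]
    counts = best[3]
    c = counts.get("C", 0)
    if c <= 0:
        return None, False
    return (
        {
            "formula": best[2],
            "error_ppm": best[4],
            "C": c,
            "H": counts.get("H", 0),
            "O": counts.get("O", 0),
            "N": counts.get("N", 0),
            "S": counts.get("S", 0),
            "P": counts.get("P", 0),
            "O_C": counts.get("O", 0) / c,
            "H_C": counts.get("H", 0) / c,
        },
        ambiguous,
    )


def classify(o_c: float, h_c: float, order: str = "printed") -> str:
    """Biochemical compound class of a formula from its van Krevelen position.

    ``order="printed"`` evaluates the boxes in their listing order with
    first-match-wins; ``order="unsaturated_first"`` gives the unsaturated-
    hydrocarbon box precedence over lipids in their overlap region.
    """
    boxes = _BOXES
    if order == "unsaturated_first":
        boxes = (_BOXES[1], _BOXES[0]) + _BOXES[2:]
    elif order != "printed":
        raise ValueError(f"unknown precedence order: {order!r}")
    for box in boxes:
        if box.contains(o_c, h_c):
            return box.name
    return "unclassified"


def class_profile(assigned: pd.DataFrame) -> pd.DataFrame:
    """Count-based relative abundance over compound classes.

    ``assigned`` needs a ``compound_class`` column (one row per assigned
    peak).  Relative abundances are over all assigned peaks including the
    unclassified ones, so they sum to 1; an empty input yields zero counts
    with flag ``empty``.
    """
    counts = {name: 0 for name in CLASS_NAMES}
    for cls in assigned.get("compound_class", pd.Series(dtype=object)):
        counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    out = pd.DataFrame({
        "compound_class": list(counts),
        "count": list(counts.values()),
    })
    out["relative_abundance"] = out["count"] / total if total > 0 else 0.0
    out["flag"] = "ok" if total > 0 else "empty"
    return out


def process_peaks(peaks: pd.DataFrame, order: str = "printed") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, assign and classify a candidate-level peak list.

    Returns ``(assigned, profile)``: one row per retained peak with its
    selected formula, elemental ratios, class and ambiguity flag, plus the
    class relative-abundance profile.
    """
    retained = filter_peaks(peaks)
    rows = []
    if not retained.empty:
        for pid, grp in retained.groupby("peak_id", sort=True):
            assignment, ambiguous = select_formula(grp)
            if assignment is None:
                continue
            first = grp.iloc[0]
            rows.append({
                "peak_id": pid,
                "mz": float(first["mz"]),
                "intensity": float(first["intensity"]),
                "sn": float(first["sn"]),
                **assignment,
                "compound_class": classify(assignment["O_C"], assignment["H_C"], order),
                "ambiguous": ambiguous,
            })
    assigned = pd.DataFrame(rows)
    return assigned, class_profile(assigned)
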