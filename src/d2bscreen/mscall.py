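"""Green/yellow/blue hit calling of per-well direct-injection spectra.

A well is *green* (major product formation) when a peak matching the
expected product mass plus an [M+H]+, [M+Na]+ or [M+K]+ cation adduct is
the most intense peak of the spectrum, *blue* (no product) when no adduct
matches any peak, and *yellow* (medium product formation) otherwise.  The
normalized well value reported alongside the verdict is the best matched
intensity divided by the base-peak intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .plates import PlateDesign, WellAddress

__all__ = [
    "WellSpectrum",
    "AdductSet",
    "DEFAULT_ADDUCTS",
    "Verdict",
    "WellCall",
    "SuccessSummary",
    "classify_well",
    "classify_plate",
    "summarize_success",
    "render_heatmap",
    "read_peaklist_csv",
    "write_calls",
]

# Monoisotopic cation adduct mass shifts, Da (proton; Na minus e-; K minus e-).
PROTON = 1.00728
SODIUM = 22.98922
POTASSIUM = 38.96316


class NoSignalError(ValueError):
    pass


@dataclass(frozen=True)
class WellSpectrum:
    well: WellAddress
    peaks: tuple[tuple[float, float], ...]  # (m/z, intensity)

    def __post_init__(self) -> None:
        for mz, inten in self.peaks:
            if mz <= 0 or not np.isfinite(inten) or inten < 0:
                raise ValueError(f"invalid peak ({mz}, {inten}) in well {self.well}")


@dataclass(frozen=True)
class AdductSet:
    adducts: tuple[tuple[str, float], ...] = (
        ("[M+H]+", PROTON),
        ("[M+Na]+", SODIUM),
        ("[M+K]+", POTASSIUM),
    )


DEFAULT_ADDUCTS = AdductSet()

Verdict = str  # "green" | "yellow" | "blue"


@dataclass(frozen=True)
class WellCall:
    well: WellAddress
    verdict: Verdict
    matched_adduct: str | None
    normalized_value: float


def classify_well(
    spectrum: WellSpectrum,
    product_mass: float,
    adducts: AdductSet = DEFAULT_ADDUCTS,
    tol: float = 0.3,
    *,
    min_mz: float = 100.0,
) -> WellCall:
    """Classify one well spectrum against its expected neutral product mass.

    ``tol`` is the absolute m/z matching tolerance in Da (direct-injection
    unit-resolution default 0.3).  ``min_mz`` discards low-mass solvent ions
    before the base peak is determined; set to 0 to keep the full range.
    A matched peak tying the base-peak intensity counts as green.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    peaks = [(mz, i) for mz, i in spectrum.peaks if mz >= min_mz]
    if not peaks:
        if not spectrum.peaks:
            raise NoSignalError(f"well {spectrum.well}: empty spectrum")
        peaks = list(spectrum.peaks)  # only sub-cutoff peaks recorded: keep them
    base = max(i for _, i in peaks)
    best_intensity = -1.0
    best_adduct: str | None = None
    for label, delta in adducts.adducts:
        target = product_mass + delta
        for mz, inten in peaks:
            if abs(mz - target) <= tol and inten > best_intensity:
                best_intensity = inten
                best_adduct = label
    if best_adduct is None:
        return WellCall(spectrum.well, "blue", None, 0.0)
    normalized = best_intensity / base if base > 0 else 0.0
    verdict = "green" if best_intensity >= base else "yellow"
    return WellCall(spectrum.well, verdict, best_adduct, normalized)


def classify_plate(
    spectra: list[WellSpectrum],
    design: PlateDesign,
    product_masses: dict[str, float],
    adducts: AdductSet = DEFAULT_ADDUCTS,
    tol: float = 0.3,
    *,
    min_mz: float = 100.0,
) -> list[WellCall]:
    by_well = {a.well: a for a in design.assignments}
    calls = []
    for spec in spectra:
        assignment = by_well.get(spec.well)
        if assignment is None:
            raise KeyError(f"spectrum for unassigned well {spec.well}")
        mass = product_masses[assignment.product_id]
        calls.append(classify_well(spec, mass, adducts, tol, min_mz=min_mz))
    return calls


@dataclass
class SuccessSummary:
    per_scheme: pd.DataFrame
    per_block: pd.DataFrame
    overall: pd.Series

    @property
    def product_formation_fraction(self) -> float:
        """Fraction of wells with any product signal (green + yellow)."""
        return float(self.overall["green_frac"] + self.overall["yellow_frac"])


def _fractions(verdicts: pd.Series) -> pd.Series:
    n = len(verdicts)
    counts = verdicts.value_counts()
    return pd.Series(
        {
            "green_frac": counts.get("green", 0) / n,
            "yellow_frac": counts.get("yellow", 0) / n,
            "blue_frac": counts.get("blue", 0) / n,
            "n": n,
        }
    )


def summarize_success(calls: list[WellCall], design: PlateDesign) -> SuccessSummary:
    """Green/yellow/blue fractions overall, per scheme and per building block."""
    by_well = {a.well: a for a in design.assignments}
    rows = []
    for c in calls:
        a = by_well.get(c.well)
        if a is None:
            raise KeyError(f"call for well {c.well} absent from plate design")
        rows.append(
            {"well": str(c.well), "scheme": a.scheme.value, "verdict": c.verdict,
             "blocks": a.block_ids}
        )
    df = pd.DataFrame(rows)
    per_scheme = df.groupby("scheme")["verdict"].apply(_fractions).unstack()
    block_rows = df.explode("blocks")
    per_block = block_rows.groupby("blocks")["verdict"].apply(_fractions).unstack()
    overall = _fractions(df["verdict"])
    return SuccessSummary(per_scheme=per_scheme, per_block=per_block, overall=overall)


def render_heatmap(
    calls: list[WellCall],
    csv_path: str | Path | None = None,
    png_path: str | Path | None = None,
) -> pd.DataFrame:
    """16x24 plate grid of verdicts with normalized values.

    Returns a DataFrame indexed by row letter with columns 1..24 holding
    ``verdict:normalized`` strings (empty for unassigned wells); optionally
    writes it as CSV and/or renders a colour-coded PNG.
    """
    wells = [c.well for c in calls]
    if len(set(wells)) != len(wells):
        raise ValueError("duplicate wells among calls")
    rows = list("ABCDEFGHIJKLMNOP")
    grid = pd.DataFrame("", index=rows, columns=range(1, 25), dtype=object)
    for c in calls:
        grid.loc[c.well.row, c.well.column] = f"{c.verdict}:{c.normalized_value:.3f}"
    if csv_path is not None:
        grid.to_csv(csv_path, index_label="row")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from matplotlib import colors

        code = {"": 0, "blue": 1, "yellow": 2, "green": 3}
        z = np.array(
            [[code[v.split(":")[0]] if v else 0 for v in grid.loc[r]] for r in rows]
        )
        cmap = colors.ListedColormap(["#eeeeee", "#4575b4", "#fee090", "#1a9850"])
        fig, ax = plt.subplots(figsize=(10, 7))
        ax.imshow(z, cmap=cmap, vmin=0, vmax=3)
        ax.set_xticks(range(24), labels=[str(i) for i in range(1, 25)], fontsize=7)
        ax.set_yticks(range(16), labels=rows, fontsize=7)
        ax.set_title("Destination-plate hit calls")
        fig.savefig(png_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return grid


def parse_heatmap(grid: pd.DataFrame) -> list[WellCall]:
    """Inverse of :func:`render_heatmap` (verdict and normalized value only)."""
    calls = []
    for row in grid.index:
        for col in grid.columns:
            v = grid.loc[row, col]
            if not v:
                continue
            verdict, norm = v.split(":")
            calls.append(
                WellCall(WellAddress(str(row), int(col)), verdict, None, float(norm))
            )
    return calls


def read_peaklist_csv(path: str | Path, well: WellAddress | str) -> WellSpectrum:
    """Read a two-column (mz, intensity) CSV peak list for one well."""
    if isinstance(well, str):
        well = WellAddress.parse(well)
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "mz" not in cols or "intensity" not in cols:
        raise ValueError("peak-list CSV needs columns mz, intensity")
    return WellSpectrum(
        well=well,
        peaks=tuple(zip(df["mz"].astype(float), df["intensity"].astype(float))),
    )


def write_calls(
    calls: list[WellCall],
    product_masses: dict[WellAddress, float],
    path: str | Path,
    adducts: AdductSet = DEFAULT_ADDUCTS,
) -> None:
    rows = []
    for c in sorted(calls, key=lambda c: c.well.index):
        mass = product_masses.get(c.well, float("nan"))
        row = {
            "well": str(c.well),
            "verdict": c.verdict,
            "adduct": c.matched_adduct or "",
            "normalized_value": round(c.normalized_value, 4),
        }
        for label, delta in adducts.adducts:
            row[f"expected_{label}"] = round(mass + delta, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
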