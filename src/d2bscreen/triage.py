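"""On-plate viability normalization, inhibition triage and diverse hit picking.

Raw luminescence (CellTiterGlo-style) signals are normalized to the mean of
the plate's untreated wells.  Wells whose crude reaction product formed by MS
(green/yellow) are triaged: *strong* inhibition means viability below 0.5,
and a well ``beats_controls`` when its viability is lower than the mean
viability of both positive-control degraders (pomalidomide and lenalidomide).
A diverse resynthesis list is chosen by MaxMin (farthest-point) selection on
fingerprint Tanimoto distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import DataStructs
from rdkit.Chem.rdFingerprintGenerator import GetRDKitFPGenerator

from .mscall import WellCall
from .plates import PlateDesign, WellAddress

__all__ = [
    "Condition",
    "ViabilityRecord",
    "TriageResult",
    "HitSelection",
    "normalize_plate",
    "triage",
    "select_hits",
    "read_viability_csv",
    "write_triage",
]

CONDITIONS = ("compound", "untreated", "pomalidomide", "lenalidomide", "vehicle")
Condition = str

STRONG_THRESHOLD = 0.5


class NormalizationError(ValueError):
    pass


class CoverageError(ValueError):
    pass


@dataclass(frozen=True)
class ViabilityRecord:
    well: WellAddress
    raw_signal: float
    condition: Condition
    viability: float | None = None  # fraction of untreated mean; None pre-normalization

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class TriageResult:
    well: WellAddress
    product_id: str
    viability: float
    inhibition_class: str  # strong | moderate | weak
    beats_controls: bool


@dataclass(frozen=True)
class HitSelection:
    selected: tuple[str, ...]
    diversity_metric: float  # mean pairwise Tanimoto distance in [0, 1]
    seed: int


def normalize_plate(records: list[ViabilityRecord]) -> list[ViabilityRecord]:
    """Divide every raw signal by the mean raw signal of the untreated wells.

    Idempotent: records whose viability already equals raw/untreated-mean are
    reproduced unchanged.
    """
    untreated = [r.raw_signal for r in records if r.condition == "untreated"]
    if not untreated:
        raise NormalizationError("no untreated wells on plate")
    mean = float(np.mean(untreated))
    if mean <= 0:
        raise NormalizationError(f"nonpositive untreated mean signal {mean}")
    return [
        ViabilityRecord(r.well, r.raw_signal, r.condition, r.raw_signal / mean)
        for r in records
    ]


def _classify(viability: float) -> str:
    if viability < STRONG_THRESHOLD:
        return "strong"
    if viability < 0.8:
        return "moderate"
    return "weak"


def triage(
    records: list[ViabilityRecord],
    calls: list[WellCall],
    design: PlateDesign,
) -> list[TriageResult]:
    """Classify MS-positive wells by inhibition strength.

    Only wells called green or yellow are eligible; blue wells are excluded.
    ``strong`` requires viability strictly below 0.5.  Control comparison
    uses per-plate mean viabilities of the pomalidomide and lenalidomide
    wells; with no control wells present ``beats_controls`` is False.
    """
    viab = {r.well: r for r in records if r.condition == "compound"}
    if any(r.viability is None for r in viab.values()):
        raise NormalizationError("records must be normalized before triage")
    controls = [
        np.mean([r.viability for r in records if r.condition == cond])
        for cond in ("pomalidomide", "lenalidomide")
        if any(r.condition == cond for r in records)
    ]
    control_floor = float(min(controls)) if controls else -np.inf
    by_well = {a.well: a for a in design.assignments}
    results = []
    for call in sorted(calls, key=lambda c: c.well.index):
        if call.verdict not in ("green", "yellow"):
            continue
        rec = viab.get(call.well)
        if rec is None:
            raise CoverageError(f"eligible well {call.well} has no viability record")
        v = float(rec.viability)
        results.append(
            TriageResult(
                well=call.well,
                product_id=by_well[call.well].product_id,
                viability=v,
                inhibition_class=_classify(v),
                beats_controls=bool(v < control_floor),
            )
        )
    return results


_FPGEN = GetRDKitFPGenerator(fpSize=2048)


def _fingerprints(smiles: list[str]):
    fps = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable structure {s!r}")
        fps.append(_FPGEN.GetFingerprint(mol))
    return fps


def select_hits(
    triage_results: list[TriageResult],
    structures: dict[str, str],
    n: int,
    seed: int = 0,
) -> HitSelection:
    """MaxMin-diverse pick of ``n`` strong inhibitors for resynthesis.

    Greedy farthest-point selection on binary substructure-fingerprint
    Tanimoto distance, started at the lowest-viability strong hit
    (ties broken by product id); deterministic for fixed inputs.
    """
    pool = sorted(
        (t for t in triage_results if t.inhibition_class == "strong"),
        key=lambda t: (t.viability, t.product_id),
    )
    if n > len(pool):
        raise ValueError(f"requested {n} hits from a pool of {len(pool)}")
    ids = [t.product_id for t in pool]
    fps = _fingerprints([structures[p] for p in ids])
    m = len(ids)
    dist = np.zeros((m, m))
    for i in range(m):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps)
        dist[i] = 1.0 - np.asarray(sims)
    chosen = [0]  # lowest-viability hit seeds the selection
    while len(chosen) < n:
        remaining = [i for i in range(m) if i not in chosen]
        min_d = dist[np.ix_(remaining, chosen)].min(axis=1)
        chosen.append(remaining[int(np.argmax(min_d))])
    sel = [ids[i] for i in chosen]
    if len(chosen) > 1:
        sub = dist[np.ix_(chosen, chosen)]
        diversity = float(sub[np.triu_indices(len(chosen), k=1)].mean())
    else:
        diversity = 0.0
    return HitSelection(selected=tuple(sel), diversity_metric=diversity, seed=seed)


def read_viability_csv(path: str | Path) -> list[ViabilityRecord]:
    df = pd.read_csv(path)
    need = {"well", "raw_signal", "condition"}
    if not need.issubset(df.columns):
        raise ValueError(f"viability CSV needs columns {sorted(need)}")
    return [
        ViabilityRecord(
            WellAddress.parse(str(r.well)), float(r.raw_signal), str(r.condition)
        )
        for r in df.itertuples(index=False)
    ]


def write_triage(results: list[TriageResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "well": [str(t.well) for t in results],
            "product_id": [t.product_id for t in results],
            "viability": [round(t.viability, 4) for t in results],
            "class": [t.inhibition_class for t in results],
            "beats_controls": [t.beats_controls for t in results],
        }
    ).to_csv(path, sep="\t", index=False)
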