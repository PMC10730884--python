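"""Seeded synthetic inputs emulating the statistical structure of a
direct-to-biology molecular-glue screen.

Every generator draws from a named substream of one root seed, so a single
stage can be regenerated independently and the full simulate -> enumerate ->
call -> screen -> proteomics chain is byte-reproducible per seed.

Defaults mirror the screening campaign the pipeline targets: 28 amines,
28 oxo components and 28 carboxylic acids plus one isocyanide, formaldehyde
and the azide source (87 starting materials; 23,520-product virtual space);
per-scheme synthesis success rates of 51% (Ugi), 67% (Ugi-formaldehyde) and
61% (Ugi-tetrazole); a 73% strong-hit rate among MS-positive wells; and
4-vs-4 LFQ matrices with a handful of strongly down-regulated neo-substrate
proteins, intensity-dependent (MNAR) missingness and log-normal noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .chem import BuildingBlock, EnumeratedProduct, Role, SchemeName
from .mscall import DEFAULT_ADDUCTS, AdductSet, WellCall, WellSpectrum
from .plates import PlateDesign
from .protstats import IntensityMatrix
from .triage import ViabilityRecord

__all__ = [
    "SimConfig",
    "gen_building_blocks",
    "gen_spectra",
    "gen_viability",
    "gen_proteomics",
    "ViabilitySim",
    "ProteomicsSim",
]

# Curated fragment pools, one per variable role.  Small, drug-like, and
# covering the motif classes screened in practice: aromatic/heteroaromatic,
# alicyclic and aliphatic skeletons with halogen, CF3, hydroxyl, methyl
# ether and tertiary-amine decorations.
AMINE_POOL: tuple[str, ...] = (
    "CN", "CCN", "CCCN", "CC(C)N", "CCCCN", "NCC(C)C", "NC1CC1", "NC1CCCC1",
    "NC1CCCCC1", "NCCO", "NCCOC", "NCCc1ccccc1", "NCc1ccccc1", "Nc1ccccc1",
    "Nc1ccc(F)cc1", "Nc1ccc(Cl)cc1", "Nc1ccc(C)cc1", "Nc1ccc(OC)cc1",
    "NCc1ccco1", "NCc1cccs1", "NCc1ccncc1", "NCc1ccccn1", "NCCc1ccncc1",
    "NCCN1CCOCC1", "NCCN(C)C", "NCc1ccc(F)cc1", "NCc1ccc(C(F)(F)F)cc1",
    "NCC1CCOCC1", "NCCC1CCCCC1", "Nc1cccc(O)c1",
)
OXO_POOL: tuple[str, ...] = (
    "CC=O", "CCC=O", "CC(C)C=O", "CCCC=O", "O=CC1CC1", "O=CC1CCCC1",
    "O=CC1CCCCC1", "O=Cc1ccccc1", "O=Cc1ccc(F)cc1", "O=Cc1ccc(Cl)cc1",
    "O=Cc1ccc(C)cc1", "O=Cc1ccc(OC)cc1", "O=Cc1ccc(C(F)(F)F)cc1",
    "O=Cc1ccco1", "O=Cc1cccs1", "O=Cc1ccncc1", "O=Cc1cccnc1", "O=Cc1ccccn1",
    "CC(C)=O", "CCC(C)=O", "O=C1CCCC1", "O=C1CCCCC1", "O=C1CCOCC1",
    "CC(=O)c1ccccc1", "CC(=O)c1ccc(F)cc1", "O=CCc1ccccc1", "O=CCOC",
    "O=CC(C)(C)C", "O=Cc1cc(F)ccc1F", "CC(=O)C1CC1",
)
ACID_POOL: tuple[str, ...] = (
    "CC(=O)O", "CCC(=O)O", "CCCC(=O)O", "CC(C)C(=O)O", "CC(C)(C)C(=O)O",
    "OC(=O)C1CC1", "OC(=O)C1CCCC1", "OC(=O)C1CCCCC1", "OC(=O)c1ccccc1",
    "OC(=O)c1ccc(F)cc1", "OC(=O)c1ccc(Cl)cc1", "OC(=O)c1ccc(C)cc1",
    "OC(=O)c1ccc(OC)cc1", "OC(=O)c1ccc(C(F)(F)F)cc1", "OC(=O)c1ccco1",
    "OC(=O)c1cccs1", "OC(=O)c1ccncc1", "OC(=O)c1cccnc1", "OC(=O)Cc1ccccc1",
    "OC(=O)Cc1ccc(F)cc1", "OC(=O)COC", "OC(=O)CC1CCCCC1", "OC(=O)CCOC",
    "OC(=O)c1cc(F)ccc1F", "OC(=O)CN1CCOCC1", "OC(=O)c1ccc(O)cc1",
    "OC(=O)C1CCOCC1", "OC(=O)CCc1ccccc1", "OC(=O)c1cncnc1", "OC(=O)CC(C)C",
)

#: Synthetic stand-in for the IMiD-derived isocyanide used as the fixed
#: fourth component (a glutarimide-phthalimide head on an isocyanide tail).
DEFAULT_ISOCYANIDE_SMILES = (
    "[C-]#[N+]CCNC(=O)c1cccc2c1C(=O)N(C1CCC(=O)NC1=O)C2=O"
)

_STREAMS = {"blocks": 1, "spectra": 2, "viability": 3, "proteomics": 4, "plate": 5}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stage]])


@dataclass
class SimConfig:
    """Study conditions of the simulated screen."""

    seed: int = 0
    n_amine: int = 28
    n_oxo: int = 28
    n_acid: int = 28
    isocyanide_smiles: str = DEFAULT_ISOCYANIDE_SMILES
    # Per-scheme probability that the reaction formed product in a well.
    scheme_success_probs: dict[SchemeName, float] = field(
        default_factory=lambda: {
            SchemeName.U4CR: 0.51,
            SchemeName.UGI_FA: 0.67,
            SchemeName.UT4CR: 0.61,
        }
    )
    block_reactivity: dict[str, float] = field(default_factory=dict)
    adduct_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)  # H/Na/K Dirichlet
    base_peak_prob: float = 0.8  # P(top adduct is the base peak | product formed)
    noise_peak_rate: float = 5.0  # Poisson mean of background peaks
    # Viability model: hit probability among MS-positive wells, viability
    # ranges for hits and non-hits, and assay noise SD (viability units).
    hit_prob: float = 0.73
    hit_viab_range: tuple[float, float] = (0.05, 0.45)
    nonhit_viab_range: tuple[float, float] = (0.55, 1.1)
    viab_noise_sd: float = 0.02
    control_viability: dict[str, float] = field(
        default_factory=lambda: {
            "untreated": 1.0, "pomalidomide": 0.50, "lenalidomide": 0.55,
            "vehicle": 1.0,
        }
    )
    n_control_wells: int = 4  # per control condition
    # Proteomics model (4 vs 4 LFQ).
    n_proteins: int = 1000
    n_spiked: int = 5
    spike_effect: float = -2.0  # log2 shift of spiked proteins in treated
    within_sd: float = 0.5  # within-group log2 SD
    baseline_mean: float = 20.0  # log2 intensity location
    baseline_sd: float = 2.0
    missing_max: float = 0.6  # asymptotic missing rate at low intensity
    missing_mid: float = 16.5  # log2 intensity of half-maximal missingness
    missing_scale: float = 0.8


def gen_building_blocks(config: SimConfig) -> list[BuildingBlock]:
    """Draw the building-block set: n_amine + n_oxo + n_acid variable blocks
    plus the fixed isocyanide, formaldehyde and azide entries."""
    for n, pool, role in (
        (config.n_amine, AMINE_POOL, "amine"),
        (config.n_oxo, OXO_POOL, "oxo"),
        (config.n_acid, ACID_POOL, "acid"),
    ):
        if n > len(pool):
            raise ValueError(f"at most {len(pool)} {role} fragments available")
    rng = _rng(config.seed, "blocks")
    blocks: list[BuildingBlock] = []
    for prefix, pool, n, role in (
        ("A", AMINE_POOL, config.n_amine, Role.AMINE),
        ("O", OXO_POOL, config.n_oxo, Role.OXO),
        ("C", ACID_POOL, config.n_acid, Role.ACID),
    ):
        picks = rng.choice(len(pool), size=n, replace=False)
        for k, i in enumerate(sorted(picks), start=1):
            blocks.append(BuildingBlock.from_smiles(f"{prefix}{k}", role, pool[i]))
    blocks.append(
        BuildingBlock.from_smiles("IC1", Role.ISOCYANIDE, config.isocyanide_smiles)
    )
    blocks.append(BuildingBlock.formaldehyde("FA"))
    blocks.append(BuildingBlock.azide_source("AZ"))
    return blocks


def _well_success_prob(
    assignment_blocks: tuple[str, ...], scheme: SchemeName, config: SimConfig
) -> float:
    p = config.scheme_success_probs[scheme]
    for b in assignment_blocks:
        p *= config.block_reactivity.get(b, 1.0)
    return min(p, 1.0)


def gen_spectra(
    design: PlateDesign,
    products: list[EnumeratedProduct],
    config: SimConfig,
    adducts: AdductSet = DEFAULT_ADDUCTS,
) -> list[WellSpectrum]:
    """Per-well direct-injection peak lists.

    A well's product forms with probability scheme success x block
    reactivity.  Formed products emit the three cation adduct peaks with
    Dirichlet-weighted intensities; with probability ``base_peak_prob`` the
    strongest adduct is the spectrum's base peak, otherwise a background
    peak dominates (a yellow call).  Every well receives Poisson-count
    uniform background peaks in m/z 100-1200.
    """
    rng = _rng(config.seed, "spectra")
    mass = {p.product_id: p.mono_mass for p in products}

    def background_mz(targets: np.ndarray, size: int) -> np.ndarray:
        # background ions never coincide with the product adduct windows
        mz = rng.uniform(100.0, 1200.0, size=size)
        for _ in range(100):
            clash = np.abs(mz[:, None] - targets[None, :]).min(axis=1) < 0.5
            if not clash.any():
                break
            mz[clash] = rng.uniform(100.0, 1200.0, size=int(clash.sum()))
        return mz

    spectra = []
    for a in sorted(design.assignments, key=lambda a: a.well.index):
        targets = np.array([mass[a.product_id] + d for _, d in adducts.adducts])
        peaks: list[tuple[float, float]] = []
        formed = rng.random() < _well_success_prob(a.block_ids, a.scheme, config)
        n_noise = rng.poisson(config.noise_peak_rate)
        noise_mz = background_mz(targets, n_noise)
        noise_int = rng.uniform(10.0, 400.0, size=n_noise)
        if formed:
            weights = rng.dirichlet(np.asarray(config.adduct_mix) * 20.0)
            adduct_int = 1000.0 * weights
            for (label, delta), inten in zip(adducts.adducts, adduct_int):
                peaks.append((mass[a.product_id] + delta, float(inten)))
            top = float(adduct_int.max())
            if rng.random() < config.base_peak_prob:
                noise_int = np.minimum(noise_int, 0.9 * top)  # product dominates
            else:
                # a contaminant outcompetes the product: medium formation
                peaks.append((float(background_mz(targets, 1)[0]), top * rng.uniform(1.5, 3.0)))
        peaks.extend(zip(noise_mz.tolist(), noise_int.tolist()))
        if not peaks:  # guarantee a classifiable spectrum
            peaks.append((float(rng.uniform(100.0, 1200.0)), 50.0))
        spectra.append(WellSpectrum(well=a.well, peaks=tuple(peaks)))
    return spectra


@dataclass
class ViabilitySim:
    records: list[ViabilityRecord]
    truth: pd.DataFrame  # well, is_hit, true_viability


def gen_viability(
    design: PlateDesign,
    calls: list[WellCall],
    config: SimConfig,
    *,
    raw_scale: float = 10_000.0,
) -> ViabilitySim:
    """Raw viability plate for the MS-positive wells plus control wells.

    MS-positive (green/yellow) wells carry compounds: hits with probability
    ``hit_prob`` drawn uniformly from the hit viability range, non-hits from
    the non-hit range, plus Gaussian assay noise.  Control wells (untreated,
    pomalidomide, lenalidomide, vehicle) are placed on the screening copy in
    wells whose reaction failed (blue) and are therefore compound-free.
    """
    rng = _rng(config.seed, "viability")
    eligible = sorted(
        (c.well for c in calls if c.verdict in ("green", "yellow")),
        key=lambda w: w.index,
    )
    blue = sorted(
        (c.well for c in calls if c.verdict == "blue"), key=lambda w: w.index
    )
    conditions = ["untreated", "pomalidomide", "lenalidomide", "vehicle"]
    need = config.n_control_wells * len(conditions)
    if len(blue) < need:
        raise ValueError(f"need {need} compound-free wells for controls, have {len(blue)}")

    records: list[ViabilityRecord] = []
    truth_rows = []
    for well in eligible:
        is_hit = bool(rng.random() < config.hit_prob)
        lo, hi = config.hit_viab_range if is_hit else config.nonhit_viab_range
        true_v = float(rng.uniform(lo, hi))
        noisy = max(true_v + rng.normal(0.0, config.viab_noise_sd), 0.0) if config.viab_noise_sd > 0 else true_v
        records.append(ViabilityRecord(well, noisy * raw_scale, "compound"))
        truth_rows.append({"well": str(well), "is_hit": is_hit, "true_viability": true_v})
    for i, cond in enumerate(conditions):
        for well in blue[i * config.n_control_wells : (i + 1) * config.n_control_wells]:
            v = config.control_viability[cond]
            noisy = max(v + rng.normal(0.0, config.viab_noise_sd), 0.0) if config.viab_noise_sd > 0 else v
            records.append(ViabilityRecord(well, noisy * raw_scale, cond))
    return ViabilitySim(records=records, truth=pd.DataFrame(truth_rows))


@dataclass
class ProteomicsSim:
    matrix: IntensityMatrix
    truth: pd.DataFrame  # protein, spiked, true_log2fc


def gen_proteomics(config: SimConfig) -> ProteomicsSim:
    """4-vs-4 LFQ intensity matrix with spiked-in neo-substrate proteins.

    Baseline log2 abundances are normal(baseline_mean, baseline_sd); within-
    group replicate noise is normal(0, within_sd); the first ``n_spiked``
    proteins are shifted by ``spike_effect`` log2 units in the treated group
    (degradation: negative effect).  Missingness is intensity-dependent:
    P(missing | x) = missing_max * expit((missing_mid - x)/missing_scale),
    the missing-not-at-random censoring typical of LFQ data.
    """
    if config.n_spiked > config.n_proteins:
        raise ValueError("n_spiked exceeds n_proteins")
    rng = _rng(config.seed, "proteomics")
    n, k = config.n_proteins, config.n_spiked
    proteins = [f"SPIKE{i+1}" if i < k else f"P{i+1:05d}" for i in range(n)]
    samples = [f"ctrl_{r+1}" for r in range(4)] + [f"treat_{r+1}" for r in range(4)]
    groups = ["control"] * 4 + ["treated"] * 4
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    log2 = base[:, None] + rng.normal(0.0, config.within_sd, size=(n, 8))
    log2[:k, 4:] += config.spike_effect
    if config.missing_max > 0:
        p_miss = config.missing_max * expit(
            (config.missing_mid - log2) / config.missing_scale
        )
        mask = rng.random(size=log2.shape) < p_miss
    else:
        mask = np.zeros_like(log2, dtype=bool)
    values = np.power(2.0, log2)
    values[mask] = np.nan
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "spiked": [i < k for i in range(n)],
            "true_log2fc": [config.spike_effect if i < k else 0.0 for i in range(n)],
        }
    )
    return ProteomicsSim(
        matrix=IntensityMatrix(
            proteins=proteins, samples=samples, groups=groups, values=values
        ),
        truth=truth,
    )
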