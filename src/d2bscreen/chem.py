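"""Building blocks and isocyanide multicomponent reaction (IMCR) enumeration.

Three reaction transforms are supported, all condensations with net loss of
one water molecule:

* **U4CR** — classical Ugi four-component reaction of a primary amine, an
  aldehyde/ketone (oxo), a carboxylic acid and an isocyanide, giving an
  alpha-acylamino amide.
* **UGI_FA** — the Ugi reaction with formaldehyde as the fixed oxo component.
* **UT4CR** — the Ugi-tetrazole (azide) variant of amine, oxo, isocyanide and
  an azide source, giving a 1,5-disubstituted tetrazole.  The azide source
  (e.g. TMSN3) is accounted as delivering HN3: the trimethylsilyl group is
  lost during workup and never appears in the product.

The contract of the module is formula/exact-mass arithmetic; 2-D product
structures are generated opportunistically from reaction SMARTS and may be
absent for exotic substrates without invalidating the enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .formula import (
    HYDRAZOIC_ACID,
    WATER,
    add_formulas,
    avg_mass,
    formula_from_smiles,
    hill_formula,
    mono_mass,
    subtract_formula,
)

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Role",
    "BuildingBlock",
    "SchemeName",
    "ReactionScheme",
    "SCHEMES",
    "EnumeratedProduct",
    "SchemeViolationError",
    "EligibilityError",
    "apply_scheme",
    "enumerate_space",
    "product_formula_string",
    "read_building_blocks",
    "write_products",
]


class Role(str, Enum):
    AMINE = "amine"
    OXO = "oxo"
    ACID = "acid"
    ISOCYANIDE = "isocyanide"
    FORMALDEHYDE = "formaldehyde"
    AZIDE_SOURCE = "azide_source"


class SchemeViolationError(ValueError):
    """Blocks supplied to a scheme do not match its required roles."""


class EligibilityError(ValueError):
    """A block lacks the functional group its role requires."""


# Role-defining functional groups used for eligibility checking.
_ROLE_PATTERNS = {
    Role.AMINE: Chem.MolFromSmarts("[NX3;H2;!$(NC=[O,S,N])]"),
    Role.OXO: Chem.MolFromSmarts("[$([CX3H1](=O)[#6]),$([CX3](=O)([#6])[#6]),$([CH2]=[OX1])]"),
    Role.ACID: Chem.MolFromSmarts("[CX3](=O)[OX2H1]"),
    Role.ISOCYANIDE: Chem.MolFromSmarts("[N+]#[C-]"),
    Role.FORMALDEHYDE: Chem.MolFromSmarts("[CH2]=[OX1]"),
}


@dataclass(frozen=True)
class BuildingBlock:
    """One reagent of the combinatorial library.

    ``formula`` is an elemental map; for the azide source it is the HN3 the
    reagent delivers to the product, not the full TMSN3 reagent.
    """

    id: str
    role: Role
    structure: str | None
    formula: dict[str, int]
    mono_mass: float
    avg_mass: float
    multi_reactive: bool = False

    @classmethod
    def from_smiles(cls, block_id: str, role: Role | str, smiles: str) -> "BuildingBlock":
        role = Role(role)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"block {block_id}: unparseable SMILES {smiles!r}")
        pattern = _ROLE_PATTERNS.get(role)
        if pattern is not None and not mol.HasSubstructMatch(pattern):
            raise EligibilityError(
                f"block {block_id}: structure lacks the {role.value} functional group"
            )
        multi = pattern is not None and len(mol.GetSubstructMatches(pattern)) > 1
        f = formula_from_smiles(smiles)
        return cls(
            id=block_id,
            role=role,
            structure=Chem.MolToSmiles(mol),
            formula=f,
            mono_mass=mono_mass(f),
            avg_mass=avg_mass(f),
            multi_reactive=multi,
        )

    @classmethod
    def azide_source(cls, block_id: str = "AZ") -> "BuildingBlock":
        """The azide reagent, accounted as delivering HN3 to the product."""
        f = dict(HYDRAZOIC_ACID)
        return cls(
            id=block_id,
            role=Role.AZIDE_SOURCE,
            structure="[H]N=[N+]=[N-]",
            formula=f,
            mono_mass=mono_mass(f),
            avg_mass=avg_mass(f),
        )

    @classmethod
    def formaldehyde(cls, block_id: str = "FA") -> "BuildingBlock":
        return cls.from_smiles(block_id, Role.FORMALDEHYDE, "C=O")


class SchemeName(str, Enum):
    U4CR = "U4CR"
    UGI_FA = "UGI_FA"
    UT4CR = "UT4CR"


@dataclass(frozen=True)
class ReactionScheme:
    name: SchemeName
    required_roles: tuple[Role, ...]
    net_loss_formula: dict[str, int] = field(default_factory=lambda: dict(WATER))
    net_gain_formula: dict[str, int] = field(default_factory=dict)
    # Roles that vary across the library (the fixed reagents — isocyanide,
    # formaldehyde, azide — are shared by every well of a scheme's zone).
    variable_roles: tuple[Role, ...] = ()


SCHEMES: dict[SchemeName, ReactionScheme] = {
    SchemeName.U4CR: ReactionScheme(
        name=SchemeName.U4CR,
        required_roles=(Role.AMINE, Role.OXO, Role.ACID, Role.ISOCYANIDE),
        variable_roles=(Role.AMINE, Role.OXO, Role.ACID, Role.ISOCYANIDE),
    ),
    SchemeName.UGI_FA: ReactionScheme(
        name=SchemeName.UGI_FA,
        required_roles=(Role.AMINE, Role.FORMALDEHYDE, Role.ACID, Role.ISOCYANIDE),
        variable_roles=(Role.AMINE, Role.ACID, Role.ISOCYANIDE),
    ),
    SchemeName.UT4CR: ReactionScheme(
        name=SchemeName.UT4CR,
        required_roles=(Role.AMINE, Role.OXO, Role.ISOCYANIDE, Role.AZIDE_SOURCE),
        net_gain_formula={},  # HN3 enters through the azide block's formula
        variable_roles=(Role.AMINE, Role.OXO, Role.ISOCYANIDE),
    ),
}


@dataclass(frozen=True)
class EnumeratedProduct:
    product_id: str
    scheme: SchemeName
    parents: tuple[str, ...]
    structure: str | None
    formula: dict[str, int]
    mono_mass: float
    avg_mass: float
    flags: tuple[str, ...] = ()


# Reaction SMARTS for optional structure generation.  The mapped-atom
# bookkeeping drops the oxo oxygen and the acid hydroxyl (the net water loss)
# and wires the Ugi / Ugi-tetrazole skeletons.
_RXN_U4CR = AllChem.ReactionFromSmarts(
    "[NX3;H2:1].[CX3:2]=[OX1:3].[CX3:4](=[OX1:5])[OX2H1].[N+:6]#[C-:7]>>"
    "[N+0:1]([C:4]=[O:5])[C:2][C+0:7](=[O:3])[NH1+0:6]"
)
_RXN_UT4CR = AllChem.ReactionFromSmarts(
    "[NX3;H2:1].[CX3:2]=[OX1:3].[N+:4]#[C-:5]>>"
    "[NH1+0:1][C:2][c+0:5]1[n+0:4][n][n][n]1"
)


def _generate_structure(scheme: ReactionScheme, by_role: dict[Role, BuildingBlock]) -> str | None:
    """Best-effort 2-D product structure; None when SMARTS application fails."""
    try:
        if scheme.name in (SchemeName.U4CR, SchemeName.UGI_FA):
            rxn = _RXN_U4CR
            oxo = by_role.get(Role.OXO) or by_role[Role.FORMALDEHYDE]
            reagents = (by_role[Role.AMINE], oxo, by_role[Role.ACID], by_role[Role.ISOCYANIDE])
        else:
            rxn = _RXN_UT4CR
            reagents = (by_role[Role.AMINE], by_role[Role.OXO], by_role[Role.ISOCYANIDE])
        mols = tuple(Chem.MolFromSmiles(b.structure) for b in reagents)
        if any(m is None for m in mols):
            return None
        products = rxn.RunReactants(mols)
        if not products:
            return None
        # Multi-reactive blocks react once, at the first matching site in
        # canonical atom order — i.e. the first product set RDKit emits.
        mol = products[0][0]
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def apply_scheme(
    scheme: ReactionScheme,
    blocks: list[BuildingBlock],
    *,
    generate_structure: bool = True,
    product_id: str | None = None,
) -> EnumeratedProduct:
    """Apply one IMCR transform to a complete set of building blocks.

    Product formula = sum of parent formulas - H2O (the azide parent already
    counts as HN3).  Raises :class:`SchemeViolationError` when the supplied
    roles do not match the scheme.
    """
    roles = sorted(b.role.value for b in blocks)
    if roles != sorted(r.value for r in scheme.required_roles):
        raise SchemeViolationError(
            f"{scheme.name.value} requires roles "
            f"{sorted(r.value for r in scheme.required_roles)}, got {roles}"
        )
    by_role = {b.role: b for b in blocks}
    f = add_formulas(*(b.formula for b in blocks), scheme.net_gain_formula)
    f = subtract_formula(f, scheme.net_loss_formula)

    flags = tuple(
        f"multi_reactive:{b.id}" for b in blocks if b.multi_reactive
    )
    structure = _generate_structure(scheme, by_role) if generate_structure else None
    parents = tuple(b.id for b in blocks)
    return EnumeratedProduct(
        product_id=product_id or f"{scheme.name.value}:" + "+".join(sorted(parents)),
        scheme=scheme.name,
        parents=parents,
        structure=structure,
        formula=f,
        mono_mass=mono_mass(f),
        avg_mass=avg_mass(f),
        flags=flags,
    )


def enumerate_space(
    blocks: list[BuildingBlock],
    schemes: list[ReactionScheme] | None = None,
    *,
    generate_structures: bool = False,
) -> list[EnumeratedProduct]:
    """Full cross-product enumeration of the virtual library.

    Per scheme, every combination of one block per required role is formed,
    deduplicated on (scheme, sorted parent-id multiset).  The product count
    therefore equals the closed form
    ``n_amine*n_oxo*n_acid*n_ic + n_amine*n_acid*n_ic + n_amine*n_oxo*n_ic``
    for the three default schemes (formaldehyde and azide are fixed
    single-member roles).
    """
    if schemes is None:
        schemes = list(SCHEMES.values())
    pools: dict[Role, list[BuildingBlock]] = {r: [] for r in Role}
    for b in blocks:
        pools[b.role].append(b)

    products: list[EnumeratedProduct] = []
    seen: set[tuple[str, tuple[str, ...]]] = set()
    for scheme in schemes:
        for role in scheme.required_roles:
            if not pools[role]:
                raise SchemeViolationError(
                    f"{scheme.name.value}: no building block with role {role.value}"
                )
        for combo in itertools.product(*(pools[r] for r in scheme.required_roles)):
            key = (scheme.name.value, tuple(sorted(b.id for b in combo)))
            if key in seen:
                continue
            seen.add(key)
            products.append(
                apply_scheme(
                    scheme,
                    list(combo),
                    generate_structure=generate_structures,
                    product_id=f"{scheme.name.value}:" + "+".join(key[1]),
                )
            )
    return products


def product_formula_string(product: EnumeratedProduct) -> str:
    """Hill-order formula string of the product."""
    return hill_formula(product.formula)


def read_building_blocks(path: str | Path) -> list[BuildingBlock]:
    """Read a building-block CSV with columns ``id, role, smiles``.

    Rows with role ``azide_source`` may leave smiles empty; the block is then
    the HN3-delivering azide reagent.
    """
    df = pd.read_csv(path)
    required = {"id", "role", "smiles"}
    if not required.issubset(df.columns):
        raise ValueError(f"building-block CSV needs columns {sorted(required)}")
    blocks = []
    for row in df.itertuples(index=False):
        role = Role(row.role)
        if role is Role.AZIDE_SOURCE:
            blocks.append(BuildingBlock.azide_source(str(row.id)))
        else:
            blocks.append(BuildingBlock.from_smiles(str(row.id), role, str(row.smiles)))
    return blocks


def write_products(products: list[EnumeratedProduct], path: str | Path) -> None:
    rows = [
        {
            "product_id": p.product_id,
            "scheme": p.scheme.value,
            "parents": "+".join(p.parents),
            "formula": hill_formula(p.formula),
            "mono_mass": round(p.mono_mass, 5),
            "avg_mass": round(p.avg_mass, 4),
            "structure": p.structure or "",
            "flags": ";".join(p.flags),
        }
        for p in products
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
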