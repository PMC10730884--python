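"""Elemental-composition arithmetic with exact-mass bookkeeping.

A formula is represented as a plain ``dict[str, int]`` mapping element
symbols to (non-negative) atom counts.  Monoisotopic masses come from the
RDKit periodic table, so they agree with the masses RDKit computes for a
parsed structure to well below 1e-4 Da.
"""

from __future__ import annotations

import re
from collections import Counter
from collections.abc import Mapping

from rdkit import Chem

__all__ = [
    "WATER",
    "HYDRAZOIC_ACID",
    "formula_from_mol",
    "formula_from_smiles",
    "add_formulas",
    "subtract_formula",
    "mono_mass",
    "avg_mass",
    "hill_formula",
    "parse_formula",
]

_PT = Chem.GetPeriodicTable()

#: Net small-molecule losses/gains of the isocyanide multicomponent reactions.
WATER: dict[str, int] = {"H": 2, "O": 1}
HYDRAZOIC_ACID: dict[str, int] = {"H": 1, "N": 3}


def formula_from_mol(mol: Chem.Mol) -> dict[str, int]:
    """Elemental composition of an RDKit molecule, implicit H included."""
    counts: Counter[str] = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    return {el: n for el, n in counts.items() if n > 0}


def formula_from_smiles(smiles: str) -> dict[str, int]:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    return formula_from_mol(mol)


def add_formulas(*formulas: Mapping[str, int]) -> dict[str, int]:
    total: Counter[str] = Counter()
    for f in formulas:
        total.update(f)
    return {el: n for el, n in total.items() if n > 0}


def subtract_formula(formula: Mapping[str, int], loss: Mapping[str, int]) -> dict[str, int]:
    """``formula - loss``; raises if the loss is not contained in the formula."""
    result = dict(formula)
    for el, n in loss.items():
        have = result.get(el, 0)
        if have < n:
            raise ValueError(f"cannot remove {n} {el} from formula with {have}")
        result[el] = have - n
        if result[el] == 0:
            del result[el]
    return result


def mono_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    return sum(_PT.GetMostCommonIsotopeMass(el) * n for el, n in formula.items())


def avg_mass(formula: Mapping[str, int]) -> float:
    """Average (isotope-abundance-weighted) mass in Da."""
    return sum(_PT.GetAtomicWeight(el) * n for el, n in formula.items())


def hill_formula(formula: Mapping[str, int]) -> str:
    """Hill-order formula string: C first, H second, then alphabetical.

    Without carbon all elements (including H) sort alphabetically.
    """
    if not formula:
        raise ValueError("empty formula")
    parts: list[str] = []
    items = {el: n for el, n in formula.items() if n > 0}
    if "C" in items:
        order = ["C"] + (["H"] if "H" in items else [])
        order += sorted(el for el in items if el not in ("C", "H"))
    else:
        order = sorted(items)
    for el in order:
        n = items[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-style formula string back into an elemental map."""
    pos = 0
    counts: Counter[str] = Counter()
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r}")
        pos = m.end()
        counts[m.group(1)] += int(m.group(2) or 1)
    if pos != len(text) or not counts:
        raise ValueError(f"malformed formula {text!r}")
    return dict(counts)
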