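"""Descriptor families and pair-feature assembly.

Four descriptor blocks are computed: a 1024-bit folded Morgan (ECFP4)
fingerprint and a 30-entry constitutional block per drug, and a 20-entry
amino-acid composition (AAC) plus a 400-entry dipeptide composition (DC)
per protein. Pair feature matrices concatenate one drug block with one
protein block per recipe:

========  ==============================  =====
recipe    blocks                          width
========  ==============================  =====
FS1       Morgan ++ AAC                    1044
FS2       Morgan ++ DC                     1424
FS3       constitutional ++ AAC              50
FS4       constitutional ++ DC              430
ALL       Morgan ++ const ++ AAC ++ DC     1474
========  ==============================  =====

The RDKit dependency is confined to :func:`compute_morgan` and
:func:`compute_constitutional`; precomputed blocks can be fed straight to
:func:`build_pair_features` so the downstream pipeline runs without any
cheminformatics toolkit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from dtibalance.io_formats import AMINO_ACIDS, InteractionSet

#: Frozen dipeptide column order: lexicographic over ordered residue pairs.
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(AMINO_ACIDS, AMINO_ACIDS)
)

MORGAN_BITS = 1024
MORGAN_RADIUS = 2

#: Block widths for the five pair-feature recipes.
FEATURE_SET_WIDTHS = {"FS1": 1044, "FS2": 1424, "FS3": 50, "FS4": 430, "ALL": 1474}

_RECIPES = {
    "FS1": (("MORGAN",), ("AAC",)),
    "FS2": (("MORGAN",), ("DC",)),
    "FS3": (("CONSTITUTIONAL",), ("AAC",)),
    "FS4": (("CONSTITUTIONAL",), ("DC",)),
    "ALL": (("MORGAN", "CONSTITUTIONAL"), ("AAC", "DC")),
}

_SIMPLEX_TOL = 1e-9


class SmilesParseError(ValueError):
    """A SMILES string RDKit could not parse; carries the offending string."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


@dataclass(frozen=True)
class DrugFeatureBlock:
    kind: str  # MORGAN | CONSTITUTIONAL
    vector: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if self.kind == "MORGAN":
            if v.shape != (MORGAN_BITS,):
                raise ValueError(f"MORGAN block must have {MORGAN_BITS} entries")
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError("MORGAN block entries must be binary")
        elif self.kind == "CONSTITUTIONAL":
            if v.shape != (len(CONSTITUTIONAL_NAMES),):
                raise ValueError(
                    f"CONSTITUTIONAL block must have {len(CONSTITUTIONAL_NAMES)} entries"
                )
            if not np.isfinite(v).all():
                raise ValueError("CONSTITUTIONAL block entries must be finite")
        else:
            raise ValueError(f"unknown drug block kind {self.kind!r}")
        if len(self.feature_names) != v.shape[0]:
            raise ValueError("feature_names length mismatch")


@dataclass(frozen=True)
class ProteinFeatureBlock:
    kind: str  # AAC | DC
    vector: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        width = {"AAC": 20, "DC": 400}.get(self.kind)
        if width is None:
            raise ValueError(f"unknown protein block kind {self.kind!r}")
        if v.shape != (width,):
            raise ValueError(f"{self.kind} block must have {width} entries")
        if (v < 0).any() or abs(v.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"{self.kind} block must be a probability simplex")
        if len(self.feature_names) != width:
            raise ValueError("feature_names length mismatch")


@dataclass
class PairFeatureMatrix:
    """Pair-aligned numeric matrix for one feature-set recipe."""

    feature_set_id: str
    pair_keys: list[tuple[str, str]]
    matrix: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.feature_set_id not in FEATURE_SET_WIDTHS:
            raise ValueError(f"unknown feature set {self.feature_set_id!r}")
        expected = FEATURE_SET_WIDTHS[self.feature_set_id]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != expected:
            raise ValueError(
                f"{self.feature_set_id} matrix must have {expected} columns, "
                f"got shape {self.matrix.shape}"
            )
        if self.matrix.shape[0] != len(self.pair_keys):
            raise ValueError("row count does not match pair_keys")
        if len(self.feature_names) != expected:
            raise ValueError("feature_names length mismatch")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_keys)


AAC_NAMES: tuple[str, ...] = tuple(f"aac_{a}" for a in AMINO_ACIDS)
DC_NAMES: tuple[str, ...] = tuple(f"dc_{dp}" for dp in DIPEPTIDES)
MORGAN_NAMES: tuple[str, ...] = tuple(f"morgan_{i}" for i in range(MORGAN_BITS))


def compute_aac(sequence: str) -> ProteinFeatureBlock:
    """Amino-acid composition: per-residue count normalized by length."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.zeros(20)
    index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for ch in sequence:
        try:
            counts[index[ch]] += 1
        except KeyError:
            raise ValueError(f"unknown residue {ch!r} in sequence") from None
    return ProteinFeatureBlock("AAC", counts / len(sequence), AAC_NAMES)


def compute_dipeptide(sequence: str) -> ProteinFeatureBlock:
    """Dipeptide composition: adjacent-pair counts over the length-1 windows."""
    if len(sequence) < 2:
        raise ValueError("dipeptide composition needs a sequence of length >= 2")
    index = {dp: i for i, dp in enumerate(DIPEPTIDES)}
    counts = np.zeros(400)
    for i in range(len(sequence) - 1):
        window = sequence[i : i + 2]
        try:
            counts[index[window]] += 1
        except KeyError:
            bad = window[0] if window[0] not in AMINO_ACIDS else window[1]
            raise ValueError(f"unknown residue {bad!r} in sequence") from None
    return ProteinFeatureBlock("DC", counts / (len(sequence) - 1), DC_NAMES)


def _parse_smiles(smiles: str):
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def compute_morgan(
    smiles: str, n_bits: int = MORGAN_BITS, radius: int = MORGAN_RADIUS
) -> DrugFeatureBlock:
    """Folded binary Morgan fingerprint (radius 2 == ECFP4).

    Deterministic for a molecule regardless of how its SMILES is spelled,
    because RDKit canonicalizes the parsed structure before hashing.
    """
    from rdkit.Chem import rdFingerprintGenerator

    mol = _parse_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = gen.GetFingerprintAsNumPy(mol).astype(float)
    names = MORGAN_NAMES if n_bits == MORGAN_BITS else tuple(
        f"morgan_{i}" for i in range(n_bits)
    )
    return DrugFeatureBlock("MORGAN", bits, names)


# The 30 constitutional descriptors: composition-only quantities (weights,
# element/bond/ring counts, H-bond donors/acceptors). The list is frozen here
# because column identity must be stable across runs.
CONSTITUTIONAL_NAMES: tuple[str, ...] = (
    "mol_weight",
    "heavy_atom_mol_weight",
    "n_atoms_total",
    "n_heavy_atoms",
    "n_hydrogen",
    "n_carbon",
    "n_nitrogen",
    "n_oxygen",
    "n_sulfur",
    "n_phosphorus",
    "n_fluorine",
    "n_chlorine",
    "n_bromine",
    "n_iodine",
    "n_halogens",
    "n_heteroatoms",
    "n_bonds",
    "n_single_bonds",
    "n_double_bonds",
    "n_triple_bonds",
    "n_aromatic_bonds",
    "n_rings",
    "n_aromatic_rings",
    "n_aromatic_atoms",
    "n_rotatable_bonds",
    "n_hbond_donors",
    "n_hbond_acceptors",
    "n_radical_electrons",
    "net_formal_charge",
    "fraction_csp3",
)


def compute_constitutional(smiles: str) -> DrugFeatureBlock:
    """The 30 constitutional descriptors of :data:`CONSTITUTIONAL_NAMES`."""
    from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors
    from rdkit.Chem.rdchem import BondType

    mol = _parse_smiles(smiles)

    def count_elem(symbol: str) -> int:
        return sum(1 for a in mol.GetAtoms() if a.GetSymbol() == symbol)

    def count_bond(btype) -> int:
        return sum(1 for b in mol.GetBonds() if b.GetBondType() == btype)

    n_hydrogen = sum(a.GetTotalNumHs() for a in mol.GetAtoms()) + count_elem("H")
    n_heavy = mol.GetNumHeavyAtoms()
    values = {
        "mol_weight": Descriptors.MolWt(mol),
        "heavy_atom_mol_weight": Descriptors.HeavyAtomMolWt(mol),
        "n_atoms_total": n_heavy + n_hydrogen,
        "n_heavy_atoms": n_heavy,
        "n_hydrogen": n_hydrogen,
        "n_carbon": count_elem("C"),
        "n_nitrogen": count_elem("N"),
        "n_oxygen": count_elem("O"),
        "n_sulfur": count_elem("S"),
        "n_phosphorus": count_elem("P"),
        "n_fluorine": count_elem("F"),
        "n_chlorine": count_elem("Cl"),
        "n_bromine": count_elem("Br"),
        "n_iodine": count_elem("I"),
        "n_halogens": count_elem("F") + count_elem("Cl") + count_elem("Br") + count_elem("I"),
        "n_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms(mol),
        "n_bonds": mol.GetNumBonds(),
        "n_single_bonds": count_bond(BondType.SINGLE),
        "n_double_bonds": count_bond(BondType.DOUBLE),
        "n_triple_bonds": count_bond(BondType.TRIPLE),
        "n_aromatic_bonds": count_bond(BondType.AROMATIC),
        "n_rings": rdMolDescriptors.CalcNumRings(mol),
        "n_aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "n_aromatic_atoms": sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
        "n_rotatable_bonds": Lipinski.NumRotatableBonds(mol),
        "n_hbond_donors": Lipinski.NumHDonors(mol),
        "n_hbond_acceptors": Lipinski.NumHAcceptors(mol),
        "n_radical_electrons": Descriptors.NumRadicalElectrons(mol),
        "net_formal_charge": sum(a.GetFormalCharge() for a in mol.GetAtoms()),
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
    }
    vec = np.array([values[name] for name in CONSTITUTIONAL_NAMES], dtype=float)
    if not np.isfinite(vec).all():
        raise ValueError(f"non-finite constitutional descriptor for {smiles!r}")
    return DrugFeatureBlock("CONSTITUTIONAL", vec, CONSTITUTIONAL_NAMES)


def compute_drug_blocks(smiles_by_id: Mapping[str, str]) -> dict[str, dict[str, DrugFeatureBlock]]:
    """Morgan + constitutional blocks for every drug, keyed by id then kind."""
    return {
        did: {
            "MORGAN": compute_morgan(smi),
            "CONSTITUTIONAL": compute_constitutional(smi),
        }
        for did, smi in smiles_by_id.items()
    }


def compute_protein_blocks(
    sequence_by_id: Mapping[str, str],
) -> dict[str, dict[str, ProteinFeatureBlock]]:
    """AAC + DC blocks for every protein, keyed by id then kind."""
    return {
        pid: {"AAC": compute_aac(seq), "DC": compute_dipeptide(seq)}
        for pid, seq in sequence_by_id.items()
    }


def build_pair_features(
    pairs: InteractionSet | Sequence[tuple[str, str]],
    drug_blocks: Mapping[str, Mapping[str, DrugFeatureBlock]],
    protein_blocks: Mapping[str, Mapping[str, ProteinFeatureBlock]],
    feature_set_id: str,
) -> PairFeatureMatrix:
    """Assemble one pair-feature recipe by block concatenation.

    Row i is the concatenation of the pair's drug block(s) followed by its
    protein block(s), in the fixed recipe order. Blocks may come from the
    descriptor functions above or be precomputed.
    """
    if feature_set_id not in _RECIPES:
        raise ValueError(f"unknown feature set {feature_set_id!r}")
    drug_kinds, prot_kinds = _RECIPES[feature_set_id]
    if isinstance(pairs, InteractionSet):
        keys = pairs.keys()
    else:
        keys = [(d, p) for d, p in pairs]

    rows = []
    names: list[str] | None = None
    for drug_id, protein_id in keys:
        segments = []
        seg_names: list[str] = []
        for kind in drug_kinds:
            try:
                block = drug_blocks[drug_id][kind]
            except KeyError:
                raise KeyError(
                    f"missing {kind} block for drug {drug_id!r}"
                ) from None
            segments.append(np.asarray(block.vector, dtype=float))
            seg_names.extend(block.feature_names)
        for kind in prot_kinds:
            try:
                block = protein_blocks[protein_id][kind]
            except KeyError:
                raise KeyError(
                    f"missing {kind} block for protein {protein_id!r}"
                ) from None
            segments.append(np.asarray(block.vector, dtype=float))
            seg_names.extend(block.feature_names)
        rows.append(np.concatenate(segments))
        if names is None:
            names = seg_names
    if names is None:
        names = _recipe_names(feature_set_id)
        matrix = np.empty((0, FEATURE_SET_WIDTHS[feature_set_id]))
    else:
        matrix = np.vstack(rows)
    return PairFeatureMatrix(feature_set_id, list(keys), matrix, names)


def _recipe_names(feature_set_id: str) -> list[str]:
    parts = {
        "MORGAN": MORGAN_NAMES,
        "CONSTITUTIONAL": CONSTITUTIONAL_NAMES,
        "AAC": AAC_NAMES,
        "DC": DC_NAMES,
    }
    drug_kinds, prot_kinds = _RECIPES[feature_set_id]
    names: list[str] = []
    for kind in (*drug_kinds, *prot_kinds):
        names.extend(parts[kind])
    return names
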