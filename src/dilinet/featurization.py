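"""Chemical feature blocks: structural fingerprints, the 2D descriptor
catalogue, the 15 physicochemical parameters, and variance-threshold
selection masks fitted on a reference set."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator, rdMolDescriptors

from .chemprep import StandardizedCompound

import rdkit

CATALOGUE_VERSION = f"rdkit-{rdkit.__version__}"

MORGAN_BITS = 2048
MORGAN_RADIUS = 2
MACCS_BITS = 166
STRUCTURAL_BITS = MORGAN_BITS + MACCS_BITS  # 2214

DEFAULT_THRESHOLDS = {"morgan": 0.05, "maccs": 0.10, "descriptors": 0.10}

PHYSCHEM15_NAMES = [
    "tpsa",
    "hbond_acceptors",
    "hbond_donors",
    "fraction_csp3",
    "logp",
    "rotatable_bonds",
    "rings",
    "assembled_rings",
    "aromatic_rings",
    "heteroatoms",
    "stereocenters",
    "positive_atoms",
    "negative_atoms",
    "nhoh_count",
    "no_count",
]


class FeaturizationError(RuntimeError):
    pass


@dataclass
class FeatureBlock:
    """A named, ordered feature matrix with an optional selection mask."""

    name: str
    matrix: np.ndarray
    feature_names: list[str]
    selection_mask: np.ndarray | None = None
    threshold: float | None = None
    catalogue_version: str = CATALOGUE_VERSION
    imputed_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("column count must equal len(feature_names)")
        if self.selection_mask is not None:
            self.selection_mask = np.asarray(self.selection_mask, dtype=bool)
            if self.selection_mask.shape != (len(self.feature_names),):
                raise ValueError("selection_mask must have one entry per feature")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def validate_finite(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise FeaturizationError(f"block {self.name!r} contains non-finite values")

    def to_files(self, csv_path: str | Path, json_path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.matrix, columns=self.feature_names).to_csv(csv_path, index=False)
        meta = {
            "name": self.name,
            "feature_names": self.feature_names,
            "selection_mask": None
            if self.selection_mask is None
            else self.selection_mask.astype(int).tolist(),
            "threshold": self.threshold,
            "catalogue_version": self.catalogue_version,
        }
        Path(json_path).write_text(json.dumps(meta, indent=1))


def _mol(compound: StandardizedCompound | str) -> Chem.Mol:
    smiles = compound if isinstance(compound, str) else (
        compound.smiles_ph7 or compound.smiles_std
    )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"cannot featurize {smiles!r}")
    return mol


_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
)


def morgan_bits(compound: StandardizedCompound | str) -> np.ndarray:
    """2048-bit radius-2 circular fingerprint as a 0/1 vector."""
    fp = _morgan_gen.GetFingerprint(_mol(compound))
    arr = np.zeros(MORGAN_BITS, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def maccs_bits(compound: StandardizedCompound | str) -> np.ndarray:
    """166-bit MACCS key vector (RDKit's bit 0 placeholder dropped)."""
    fp = MACCSkeys.GenMACCSKeys(_mol(compound))
    arr = np.zeros(167, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr[1:]


def structural_bits(compound: StandardizedCompound | str) -> np.ndarray:
    """Concatenated Morgan + MACCS vector, length 2214."""
    return np.concatenate([morgan_bits(compound), maccs_bits(compound)])


def _assembled_rings(mol: Chem.Mol) -> int:
    """Number of connected ring systems (fused rings count once)."""
    ri = mol.GetRingInfo()
    rings = [set(r) for r in ri.AtomRings()]
    n_systems = 0
    while rings:
        system = rings.pop()
        changed = True
        while changed:
            changed = False
            for other in rings[:]:
                if system & other:
                    system |= other
                    rings.remove(other)
                    changed = True
        n_systems += 1
    return n_systems


def physchem15(compound: StandardizedCompound | str) -> np.ndarray:
    """The fixed panel of 15 physicochemical parameters (see PHYSCHEM15_NAMES)."""
    mol = _mol(compound)
    n_stereo = rdMolDescriptors.CalcNumAtomStereoCenters(
        mol
    ) + rdMolDescriptors.CalcNumUnspecifiedAtomStereoCenters(mol)
    vals = [
        Descriptors.TPSA(mol),
        rdMolDescriptors.CalcNumHBA(mol),
        rdMolDescriptors.CalcNumHBD(mol),
        Descriptors.FractionCSP3(mol),
        Descriptors.MolLogP(mol),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        rdMolDescriptors.CalcNumRings(mol),
        _assembled_rings(mol),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        rdMolDescriptors.CalcNumHeteroatoms(mol),
        n_stereo,
        sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() > 0),
        sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() < 0),
        Descriptors.NHOHCount(mol),
        Descriptors.NOCount(mol),
    ]
    return np.asarray(vals, dtype=float)


def _raw_descriptor_table(
    compounds: list[StandardizedCompound | str],
) -> tuple[np.ndarray, list[str]]:
    names = [n for n, _ in Descriptors.descList]
    rows = []
    for c in compounds:
        mol = _mol(c)
        d = Descriptors.CalcMolDescriptors(mol, missingVal=np.nan)
        rows.append([d[n] for n in names])
    return np.asarray(rows, dtype=float), names


def descriptor_catalogue(
    compounds: list[StandardizedCompound | str],
    reference: "DescriptorReference | None" = None,
) -> FeatureBlock:
    """Bulk 2D descriptor catalogue.

    Without a reference, columns with any non-finite value are dropped and
    the surviving names plus their medians become the fitted reference
    (attach it via :func:`fit_descriptor_reference`).  With a reference, the
    reference's columns are kept and stray non-finite values are imputed
    with the reference median (rows flagged).
    """
    matrix, names = _raw_descriptor_table(compounds)
    if reference is None:
        keep = np.all(np.isfinite(matrix), axis=0)
        block = FeatureBlock(
            name="descriptors",
            matrix=matrix[:, keep],
            feature_names=[n for n, k in zip(names, keep) if k],
        )
        block.validate_finite()
        return block
    cols = [names.index(n) for n in reference.feature_names]
    sub = matrix[:, cols]
    imputed_rows = sorted(set(np.where(~np.isfinite(sub))[0].tolist()))
    for j, med in enumerate(reference.medians):
        bad = ~np.isfinite(sub[:, j])
        sub[bad, j] = med
    block = FeatureBlock(
        name="descriptors",
        matrix=sub,
        feature_names=list(reference.feature_names),
        imputed_rows=imputed_rows,
    )
    block.validate_finite()
    return block


@dataclass
class DescriptorReference:
    """Surviving descriptor names and reference medians, fitted once."""

    feature_names: list[str]
    medians: list[float]
    catalogue_version: str = CATALOGUE_VERSION


def fit_descriptor_reference(block: FeatureBlock) -> DescriptorReference:
    return DescriptorReference(
        feature_names=list(block.feature_names),
        medians=np.median(block.matrix, axis=0).tolist(),
    )


def physchem_block(compounds: list[StandardizedCompound | str]) -> FeatureBlock:
    matrix = np.vstack([physchem15(c) for c in compounds]) if compounds else np.zeros((0, 15))
    return FeatureBlock(name="physchem15", matrix=matrix, feature_names=list(PHYSCHEM15_NAMES))


def morgan_block(compounds: list[StandardizedCompound | str]) -> FeatureBlock:
    matrix = (
        np.vstack([morgan_bits(c) for c in compounds])
        if compounds
        else np.zeros((0, MORGAN_BITS))
    )
    return FeatureBlock(
        name="morgan",
        matrix=matrix,
        feature_names=[f"morgan_{i}" for i in range(MORGAN_BITS)],
    )


def maccs_block(compounds: list[StandardizedCompound | str]) -> FeatureBlock:
    matrix = (
        np.vstack([maccs_bits(c) for c in compounds])
        if compounds
        else np.zeros((0, MACCS_BITS))
    )
    return FeatureBlock(
        name="maccs",
        matrix=matrix,
        feature_names=[f"maccs_{i + 1}" for i in range(MACCS_BITS)],
    )


def fit_variance_mask(block: FeatureBlock, threshold: float | None = None) -> np.ndarray:
    """Keep feature j iff its population (divide-by-n) variance > threshold.

    physchem15 blocks are never masked.  The mask is stored on the block.
    """
    if block.matrix.shape[0] == 0:
        raise ValueError("cannot fit a variance mask on an empty reference set")
    if block.name == "physchem15":
        mask = np.ones(block.n_features, dtype=bool)
        block.selection_mask = mask
        block.threshold = None
        return mask
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS.get(block.name, 0.10)
    var = np.var(block.matrix, axis=0)  # population variance
    mask = var > threshold  # strictly greater: var == threshold is dropped
    block.selection_mask = mask
    block.threshold = threshold
    return mask


def apply_mask(block: FeatureBlock, mask_block: FeatureBlock | np.ndarray, *,
               mask_name: str | None = None, mask_names: list[str] | None = None) -> FeatureBlock:
    """Column-subset ``block`` by a mask fitted on an identically named block."""
    if isinstance(mask_block, FeatureBlock):
        if mask_block.selection_mask is None:
            raise ValueError(f"block {mask_block.name!r} has no fitted mask")
        mask = mask_block.selection_mask
        mask_name = mask_block.name
        mask_names = mask_block.feature_names
    else:
        mask = np.asarray(mask_block, dtype=bool)
    if mask_name is not None and mask_name != block.name:
        raise ValueError(f"mask fitted on {mask_name!r} cannot apply to {block.name!r}")
    if mask_names is not None:
        for a, b in zip(block.feature_names, mask_names):
            if a != b:
                raise ValueError(f"feature name mismatch: {a!r} != {b!r}")
        if len(mask_names) != block.n_features:
            raise ValueError("feature name list length mismatch")
    if mask.shape != (block.n_features,):
        raise ValueError(
            f"mask length {mask.shape[0]} != feature count {block.n_features}"
        )
    return FeatureBlock(
        name=block.name,
        matrix=block.matrix[:, mask],
        feature_names=[n for n, m in zip(block.feature_names, mask) if m],
        catalogue_version=block.catalogue_version,
        imputed_rows=list(block.imputed_rows),
    )


@dataclass
class ChemFeaturizer:
    """Fitted featurizer: variance masks + descriptor reference, applied to
    any compound list to produce the structural and descriptor blocks."""

    morgan_ref: FeatureBlock
    maccs_ref: FeatureBlock
    descriptor_reference: DescriptorReference
    descriptor_mask: np.ndarray

    @classmethod
    def fit(
        cls,
        reference_compounds: list[StandardizedCompound | str],
        thresholds: dict[str, float] | None = None,
    ) -> "ChemFeaturizer":
        th = dict(DEFAULT_THRESHOLDS)
        if thresholds:
            th.update(thresholds)
        mo = morgan_block(reference_compounds)
        ma = maccs_block(reference_compounds)
        fit_variance_mask(mo, th["morgan"])
        fit_variance_mask(ma, th["maccs"])
        desc = descriptor_catalogue(reference_compounds)
        ref = fit_descriptor_reference(desc)
        dmask = fit_variance_mask(desc, th["descriptors"])
        return cls(
            morgan_ref=mo,
            maccs_ref=ma,
            descriptor_reference=ref,
            descriptor_mask=dmask,
        )

    @property
    def n_structural(self) -> int:
        return int(self.morgan_ref.selection_mask.sum() + self.maccs_ref.selection_mask.sum())

    @property
    def n_descriptor_features(self) -> int:
        return int(self.descriptor_mask.sum()) + len(PHYSCHEM15_NAMES)

    def structural(self, compounds: list[StandardizedCompound | str]) -> FeatureBlock:
        mo = apply_mask(morgan_block(compounds), self.morgan_ref)
        ma = apply_mask(maccs_block(compounds), self.maccs_ref)
        return FeatureBlock(
            name="structural",
            matrix=np.hstack([mo.matrix, ma.matrix]),
            feature_names=mo.feature_names + ma.feature_names,
        )

    def descriptors(self, compounds: list[StandardizedCompound | str]) -> FeatureBlock:
        """Selected catalogue descriptors plus the 15 physicochemical values."""
        desc = descriptor_catalogue(compounds, reference=self.descriptor_reference)
        desc = apply_mask(
            desc,
            self.descriptor_mask,
            mask_name="descriptors",
            mask_names=self.descriptor_reference.feature_names,
        )
        pc = physchem_block(compounds)
        block = FeatureBlock(
            name="descriptors+physchem",
            matrix=np.hstack([desc.matrix, pc.matrix]),
            feature_names=desc.feature_names + pc.feature_names,
            imputed_rows=list(desc.imputed_rows),
        )
        block.validate_finite()
        return block


__all__ = [
    "FeatureBlock",
    "FeaturizationError",
    "ChemFeaturizer",
    "DescriptorReference",
    "morgan_bits",
    "maccs_bits",
    "structural_bits",
    "physchem15",
    "descriptor_catalogue",
    "fit_descriptor_reference",
    "physchem_block",
    "morgan_block",
    "maccs_block",
    "fit_variance_mask",
    "apply_mask",
    "MORGAN_BITS",
    "MACCS_BITS",
    "STRUCTURAL_BITS",
    "PHYSCHEM15_NAMES",
    "DEFAULT_THRESHOLDS",
    "CATALOGUE_VERSION",
]
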