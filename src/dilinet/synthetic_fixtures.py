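"""Self-contained synthetic multi-endpoint panel with planted
substructure-activity signal.

A fragment grammar (scaffolds x substituents, attached through RDKit mol
editing) guarantees parseable SMILES; toxicophore substituents carry the
planted signal; salts, stereocenters and label conflicts exercise the
preparation pipeline; and a ground-truth manifest lets recovery tests check
every stage against the generator's bookkeeping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chemprep import RawRecord, StandardizedCompound, prepare
from .data_model import EndpointDataset, Panel, build_panel

DEFAULT_SCAFFOLDS = [
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "c1ccc2ccccc2c1",
    "C1CCNCC1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCOCC1",
]

DEFAULT_SUBSTITUENTS = [
    "C",
    "CC",
    "CCC",
    "O",
    "OC",
    "N",
    "F",
    "Cl",
    "C(=O)O",
    "C(C)O",
    "C#N",
    "S(=O)(=O)N",
    "C(=O)N",
    "CCO",
]

# substituent SMILES -> SMARTS that detects it after attachment
DEFAULT_TOXICOPHORES = {
    "[N+](=O)[O-]": "[N+](=O)[O-]",  # nitro
    "NN": "[NX3][NX3]",  # hydrazine
    "C(F)(F)F": "C(F)(F)F",  # trifluoromethyl
    "SC#N": "SC#N",  # thiocyanate
}


@dataclass
class GenerativeSpec:
    n_compounds: int = 300
    scaffolds: list[str] = field(default_factory=lambda: list(DEFAULT_SCAFFOLDS))
    substituents: list[str] = field(default_factory=lambda: list(DEFAULT_SUBSTITUENTS))
    toxicophores: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_TOXICOPHORES)
    )
    # endpoint name -> (list of toxicophore SMILES keys, label-flip noise rate)
    endpoint_signal_map: dict[str, tuple[list[str], float]] = field(
        default_factory=lambda: {
            "endpoint_a": (["[N+](=O)[O-]", "NN"], 0.05),
            "endpoint_b": (["[N+](=O)[O-]"], 0.05),
            "endpoint_c": (["C(F)(F)F"], 0.05),
            "endpoint_d": (["SC#N"], 0.10),
        }
    )
    # gold label: logistic over latent toxicophore indicators + direct alert
    gold_weights: dict[str, float] = field(
        default_factory=lambda: {
            "[N+](=O)[O-]": 2.5,
            "NN": 2.0,
            "C(F)(F)F": 1.5,
            "SC#N": 1.0,
        }
    )
    gold_bias: float = -1.2
    gold_noise: float = 0.05
    # weight of the standardized PK latent (a*logP + b*MW) in the gold rule;
    # routes signal through the PK columns that fingerprints encode poorly
    gold_pk_weight: float = 0.0
    toxicophore_rate: float = 0.35
    gold_fraction: float = 0.35  # fraction of the library in the gold set
    endpoint_membership: float = 0.8  # fraction of compounds in each endpoint
    overlap_fraction: float = 0.8
    conflict_rate: float = 0.0
    salt_rate: float = 0.0
    stereo_rate: float = 0.0
    cmax_coefficients: tuple[float, float] = (-0.4, 0.01)  # logP, MW
    cmax_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (toxs, noise) in self.endpoint_signal_map.items():
            if not (0.0 <= noise < 0.5):
                raise ValueError(f"noise rate for {name!r} must be in [0, 0.5)")
            for t in toxs:
                if t not in self.toxicophores:
                    raise ValueError(f"unknown toxicophore {t!r} for {name!r}")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        for smi in self.scaffolds + self.substituents + list(self.toxicophores):
            if Chem.MolFromSmiles(smi) is None:
                raise ValueError(f"grammar fragment {smi!r} is not valid SMILES")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, abs(hash_stream(stream))])


def hash_stream(name: str) -> int:
    import hashlib

    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


def _attach(core: Chem.Mol, group_smiles: str, rng: np.random.Generator) -> Chem.Mol | None:
    """Bond the first atom of ``group`` to a random H-bearing carbon of core."""
    group = Chem.MolFromSmiles(group_smiles)
    sites = [
        a.GetIdx()
        for a in core.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() == 6
    ]
    if not sites:
        return None
    site = int(rng.choice(sites))
    combo = Chem.RWMol(Chem.CombineMols(core, group))
    combo.AddBond(site, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combo.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    except Exception:
        return None


@dataclass
class LibraryEntry:
    record: RawRecord
    toxicophore_flags: dict[str, bool]
    conflict_partner: int | None = None  # index of the planted-conflict twin


def generate_library(spec: GenerativeSpec) -> list[LibraryEntry]:
    """Enumerate grammar molecules with planted toxicophores, salts, random
    stereocenters and exact-count planted label conflicts."""
    rng = spec.rng("library")
    entries: list[LibraryEntry] = []
    tox_list = list(spec.toxicophores)
    seen: set[str] = set()
    attempts = 0
    while len(entries) < spec.n_compounds and attempts < spec.n_compounds * 50:
        attempts += 1
        scaffold = Chem.MolFromSmiles(str(rng.choice(spec.scaffolds)))
        mol = scaffold
        for _ in range(int(rng.integers(1, 4))):
            nxt = _attach(mol, str(rng.choice(spec.substituents)), rng)
            if nxt is not None:
                mol = nxt
        flags = {t: False for t in tox_list}
        if rng.random() < spec.toxicophore_rate:
            tox = tox_list[int(rng.integers(len(tox_list)))]
            nxt = _attach(mol, tox, rng)
            if nxt is None:
                continue
            mol = nxt
            flags[tox] = True
        # re-derive flags by SMARTS so decorations that happen to form a
        # pattern are still counted as signal carriers
        for t, smarts in spec.toxicophores.items():
            patt = Chem.MolFromSmarts(smarts)
            flags[t] = mol.HasSubstructMatch(patt)
        smiles = Chem.MolToSmiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        out_smiles = smiles
        if rng.random() < spec.stereo_rate:
            from rdkit.Chem.EnumerateStereoisomers import EnumerateStereoisomers

            isomers = list(EnumerateStereoisomers(mol))
            if len(isomers) > 1:
                out_smiles = Chem.MolToSmiles(isomers[int(rng.integers(len(isomers)))])
        if rng.random() < spec.salt_rate:
            out_smiles = out_smiles + ".Cl"
        entries.append(
            LibraryEntry(
                record=RawRecord(smiles=out_smiles, source="synthetic"),
                toxicophore_flags=flags,
            )
        )
    if len(entries) < spec.n_compounds:
        raise RuntimeError("fragment grammar could not reach the requested size")
    return entries


def _gold_label(
    flags: dict[str, bool], spec: GenerativeSpec, rng, pk_z: float = 0.0
) -> int:
    z = (
        spec.gold_bias
        + sum(w for t, w in spec.gold_weights.items() if flags.get(t))
        + spec.gold_pk_weight * pk_z
    )
    p = 1.0 / (1.0 + math.exp(-z))
    label = int(rng.random() < p)
    if rng.random() < spec.gold_noise:
        label = 1 - label
    return label


@dataclass
class SyntheticPanel:
    panel: Panel
    manifest: dict
    raw_records: list[RawRecord]


def assign_endpoint_labels(
    entries: list[LibraryEntry], spec: GenerativeSpec, protonate: bool = True
) -> SyntheticPanel:
    """Prepare the library and assemble a full Panel with planted labels.

    Endpoint label = indicator(any mapped toxicophore) XOR Bernoulli(noise);
    Cmax targets are a linear function of logP and MW plus Gaussian noise;
    gold labels follow the logistic gold rule.  Conflicts are planted after
    labeling by duplicating records with flipped labels.
    """
    rng_labels = spec.rng("labels")
    rng_gold = spec.rng("gold")
    rng_member = spec.rng("membership")
    rng_conflict = spec.rng("conflicts")

    prepared: list[StandardizedCompound] = []
    kept_entries: list[LibraryEntry] = []
    for e in entries:
        rec = prepare(e.record, protonate=protonate)
        if not rec.rejected:
            prepared.append(rec)
            kept_entries.append(e)
    # drop duplicate structures up front so planted conflicts stay exact
    seen: set[str] = set()
    uniq_prepared, uniq_entries = [], []
    for rec, e in zip(prepared, kept_entries):
        if rec.key14 in seen:
            continue
        seen.add(rec.key14)
        uniq_prepared.append(rec)
        uniq_entries.append(e)
    prepared, kept_entries = uniq_prepared, uniq_entries
    n = len(prepared)

    latent = {
        t: [bool(e.toxicophore_flags[t]) for e in kept_entries]
        for t in spec.toxicophores
    }

    from dataclasses import replace

    # noiseless PK latent per compound; also feeds the gold rule when
    # gold_pk_weight is nonzero
    a, b = spec.cmax_coefficients
    pk_raw = []
    for rec in prepared:
        mol = Chem.MolFromSmiles(rec.smiles_std)
        pk_raw.append(a * Descriptors.MolLogP(mol) + b * Descriptors.MolWt(mol))
    pk_raw = np.asarray(pk_raw)
    pk_sd = pk_raw.std()
    pk_z = (pk_raw - pk_raw.mean()) / pk_sd if pk_sd > 0 else np.zeros(n)

    gold_labels = [
        _gold_label(e.toxicophore_flags, spec, rng_gold, pk_z=float(pk_z[i]))
        for i, e in enumerate(kept_entries)
    ]
    gold_keys = set()
    gold_members = rng_member.random(n) < spec.gold_fraction
    gold_compounds = []
    for i in range(n):
        if gold_members[i]:
            gold_compounds.append(replace(prepared[i], label=gold_labels[i]))
            gold_keys.add(prepared[i].key14)
    gold = EndpointDataset(name="DILI", compounds=gold_compounds, kind="binary")

    proxies: list[EndpointDataset] = []
    indicator_true: dict[str, list[int]] = {}
    for name, (toxs, noise) in spec.endpoint_signal_map.items():
        members = rng_member.random(n) < spec.endpoint_membership
        compounds = []
        true_indicator = []
        for i in range(n):
            ind = int(any(latent[t][i] for t in toxs))
            true_indicator.append(ind)
            if not members[i]:
                continue
            label = ind ^ int(rng_labels.random() < noise)
            compounds.append(replace(prepared[i], label=label, source=name))
        indicator_true[name] = true_indicator
        proxies.append(EndpointDataset(name=name, compounds=compounds, kind="binary"))

    # numeric PK targets: pCmax = a*logP + b*MW + noise
    rng_cmax = spec.rng("cmax")
    pk_sets = []
    for pk_name in ("cmax_unbound", "cmax_total"):
        compounds = []
        for i in range(n):
            val = pk_raw[i] + rng_cmax.normal(0, spec.cmax_noise_sd)
            compounds.append(replace(prepared[i], label=float(val), source=pk_name))
        pk_sets.append(EndpointDataset(name=pk_name, compounds=compounds, kind="numeric"))

    # plant exact-count conflicts: duplicate raw records with flipped labels
    conflict_pairs: list[str] = []
    raw_records: list[RawRecord] = []
    n_conflicts = round(spec.conflict_rate * n)
    conflict_idx = set(
        rng_conflict.choice(n, size=n_conflicts, replace=False).tolist()
    ) if n_conflicts else set()
    for i in range(n):
        lbl = gold_labels[i]
        raw_records.append(replace(kept_entries[i].record, label=lbl))
        if i in conflict_idx:
            raw_records.append(replace(kept_entries[i].record, label=1 - lbl))
            conflict_pairs.append(prepared[i].key14)

    panel = build_panel(gold, proxies, pk_sets)
    manifest = {
        "seed": spec.seed,
        "toxicophores": dict(spec.toxicophores),
        "latent_indicators": {
            t: [int(v) for v in vals] for t, vals in latent.items()
        },
        "compound_keys": [c.key14 for c in prepared],
        "endpoint_true_indicators": indicator_true,
        "cmax_coefficients": {"logp": a, "mw": b},
        "conflict_pairs": sorted(conflict_pairs),
        "gold_rule": {"weights": dict(spec.gold_weights), "bias": spec.gold_bias},
    }
    return SyntheticPanel(panel=panel, manifest=manifest, raw_records=raw_records)


def make_panel(spec: GenerativeSpec, protonate: bool = True) -> SyntheticPanel:
    return assign_endpoint_labels(generate_library(spec), spec, protonate=protonate)


def ground_truth_manifest(sp: SyntheticPanel, path: str | Path | None = None) -> dict:
    if path is not None:
        Path(path).write_text(json.dumps(sp.manifest, indent=1))
    return sp.manifest


__all__ = [
    "GenerativeSpec",
    "LibraryEntry",
    "SyntheticPanel",
    "generate_library",
    "assign_endpoint_labels",
    "make_panel",
    "ground_truth_manifest",
    "DEFAULT_SCAFFOLDS",
    "DEFAULT_SUBSTITUENTS",
    "DEFAULT_TOXICOPHORES",
]
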