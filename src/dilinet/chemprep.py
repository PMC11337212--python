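"""Compound filtering, standardization, pH-7 protonation and deduplication.

The preparation pipeline is: raw-parse filters (parse failure, metal-only,
no carbon) -> iterative standardization to a canonical-SMILES fixpoint ->
post-standardization filters (fragment ambiguity, molecular weight) ->
pH-7.0 protonation via a bundled pKa rule table -> 14-character structure
key (InChIKey hash layer) for deduplication.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field, replace

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .pka_rules import PKA_RULES, PKA_TABLE_VERSION

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

MW_LIMIT = 1500.0  # Da, inclusive: strictly greater is rejected
MAX_STANDARDIZE_ITER = 5

# Elements that are NOT metals (H + nonmetals/metalloids + noble gases).
_NONMETALS = frozenset(
    [1, 2, 5, 6, 7, 8, 9, 10, 14, 15, 16, 17, 18, 33, 34, 35, 36, 52, 53, 54, 85, 86]
)

REJECT_REASONS = (
    "no_carbon",
    "disconnected",
    "metals_only",
    "mw_over_1500",
    "parse_failure",
    "none",
)


@dataclass
class RawRecord:
    """One raw input row: SMILES plus optional label and provenance."""

    smiles: str
    label: float | int | None = None
    source: str = ""
    identifier: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.smiles, str) or not self.smiles.strip():
            raise ValueError("smiles must be non-empty text")


@dataclass
class StandardizedCompound:
    """Standardized structure record, possibly rejected with a reason."""

    smiles_std: str = ""
    smiles_ph7: str = ""
    key14: str = ""
    rejected: bool = False
    reject_reason: str = "none"
    label: float | int | None = None
    source: str = ""
    identifier: str | None = None
    smiles_in: str = ""

    def __post_init__(self) -> None:
        if self.reject_reason not in REJECT_REASONS:
            raise ValueError(f"unknown reject_reason {self.reject_reason!r}")
        if self.rejected and self.reject_reason == "none":
            raise ValueError("rejected record needs a reject_reason")


def _reject(record: RawRecord, reason: str) -> StandardizedCompound:
    return StandardizedCompound(
        rejected=True,
        reject_reason=reason,
        label=record.label,
        source=record.source,
        identifier=record.identifier,
        smiles_in=record.smiles,
    )


def _is_metal(atom: Chem.Atom) -> bool:
    return atom.GetAtomicNum() not in _NONMETALS and atom.GetAtomicNum() > 0


def _organic_fragments(mol: Chem.Mol) -> list[Chem.Mol]:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]


def _principal_fragment(mol: Chem.Mol) -> tuple[Chem.Mol | None, str]:
    """Largest organic fragment, or (None, reason) when no unambiguous choice.

    A tie in heavy-atom count between two structurally distinct organic
    fragments means the principal fragment cannot be chosen -> "disconnected".
    """
    organics = _organic_fragments(mol)
    if not organics:
        if all(_is_metal(a) for a in mol.GetAtoms()):
            return None, "metals_only"
        return None, "no_carbon"
    sized = sorted(
        ((f.GetNumHeavyAtoms(), i, f) for i, f in enumerate(organics)),
        key=lambda t: (-t[0], t[1]),
    )
    if len(sized) > 1 and sized[0][0] == sized[1][0]:
        smi0 = Chem.MolToSmiles(sized[0][2])
        smi1 = Chem.MolToSmiles(sized[1][2])
        if smi0 != smi1:
            return None, "disconnected"
    return sized[0][2], "none"


def filter_compound(record: RawRecord) -> StandardizedCompound:
    """Apply the raw-stage drop rules; never raises on bad structures.

    Rejects: unparseable SMILES; metal-only structures; structures without
    carbon; multi-fragment structures with no unambiguous principal organic
    fragment; principal fragments heavier than 1500 Da.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return _reject(record, "parse_failure")
    atoms = list(mol.GetAtoms())
    if atoms and all(_is_metal(a) for a in atoms):
        return _reject(record, "metals_only")
    if not any(a.GetAtomicNum() == 6 for a in atoms):
        return _reject(record, "no_carbon")
    # disconnect metals before fragment analysis so e.g. Na salts do not
    # count as ambiguous fragments
    try:
        mol = rdMolStandardize.MetalDisconnector().Disconnect(mol)
    except Exception:
        return _reject(record, "parse_failure")
    frag, reason = _principal_fragment(mol)
    if frag is None:
        return _reject(record, reason)
    if Descriptors.MolWt(frag) > MW_LIMIT:
        return _reject(record, "mw_over_1500")
    return StandardizedCompound(
        smiles_std=Chem.MolToSmiles(frag),
        label=record.label,
        source=record.source,
        identifier=record.identifier,
        smiles_in=record.smiles,
    )


def _strip_isotopes(mol: Chem.Mol) -> Chem.Mol:
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return mol


def _standardize_once(smiles: str, tautomers: rdMolStandardize.TautomerEnumerator) -> str | None:
    """One pass of the standardization sequence; returns canonical SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    try:
        mol = rdMolStandardize.MetalDisconnector().Disconnect(mol)
        mol = rdMolStandardize.Normalize(mol)
        mol = rdMolStandardize.Reionize(mol)
        frag, reason = _principal_fragment(mol)
        if frag is None:
            return None
        Chem.SanitizeMol(frag)
        mol = rdMolStandardize.Uncharger().uncharge(frag)
        mol = _strip_isotopes(mol)
        Chem.RemoveStereochemistry(mol)
        mol = tautomers.Canonicalize(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def standardize(record: RawRecord | StandardizedCompound) -> StandardizedCompound:
    """Standardize a filtered record.

    The sequence (metal disconnection, normalization, reionization,
    principal-fragment selection, uncharging, isotope standardization,
    stereochemistry removal, tautomer canonicalization) is applied
    iteratively up to five times or until the canonical SMILES stabilizes.
    Without a fixpoint, the most frequent SMILES among the iterates wins
    (ties -> lexicographically smallest).
    """
    if isinstance(record, RawRecord):
        record = filter_compound(record)
    if record.rejected:
        return record

    tautomers = rdMolStandardize.TautomerEnumerator()
    current = record.smiles_std
    iterates: list[str] = []
    converged = False
    for _ in range(MAX_STANDARDIZE_ITER):
        nxt = _standardize_once(current, tautomers)
        if nxt is None:
            return replace(record, rejected=True, reject_reason="parse_failure")
        iterates.append(nxt)
        if nxt == current:
            converged = True
            break
        current = nxt
    if not converged:
        counts = Counter(iterates)
        top = max(counts.values())
        current = min(s for s, c in counts.items() if c == top)
        logger.warning("standardization did not converge for %r; using %r", record.smiles_in, current)

    mol = Chem.MolFromSmiles(current)
    if mol is None:
        return replace(record, rejected=True, reject_reason="parse_failure")
    frag, reason = _principal_fragment(mol)
    if frag is None:
        return replace(record, rejected=True, reject_reason=reason)
    if Descriptors.MolWt(frag) > MW_LIMIT:
        return replace(record, rejected=True, reject_reason="mw_over_1500")
    return replace(record, smiles_std=current)


def protonate_ph7(smiles_std: str, enabled: bool = True, ph: float = 7.0) -> str:
    """Adjust ionizable groups to the dominant microstate at the given pH.

    Rule-based: each entry of the bundled pKa table either removes a proton
    (acids with pKa < pH) or adds one (bases with pKa > pH) at its matched
    site.  Deterministic; with the rule engine disabled the input is
    returned unchanged.
    """
    if not enabled:
        logger.warning("pH-7 protonation disabled; returning input unchanged")
        return smiles_std
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        logger.warning("protonate_ph7: unparseable input %r", smiles_std)
        return smiles_std
    rw = Chem.RWMol(mol)
    done: set[int] = set()
    for _name, smarts, pka, kind, site in PKA_RULES:
        if kind == "acid" and pka >= ph:
            continue
        if kind == "base" and pka <= ph:
            continue
        patt = Chem.MolFromSmarts(smarts)
        for match in rw.GetSubstructMatches(patt):
            idx = match[site]
            if idx in done:
                continue
            atom = rw.GetAtomWithIdx(idx)
            if kind == "acid":
                if atom.GetTotalNumHs() < 1 or atom.GetFormalCharge() != 0:
                    continue
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
            else:
                if atom.GetFormalCharge() != 0:
                    continue
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
            done.add(idx)
    if not done:
        return smiles_std
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        logger.warning("protonate_ph7 produced an invalid structure for %r; keeping input", smiles_std)
        return smiles_std


def key14(smiles_ph7: str) -> str:
    """First 14 characters of the InChIKey (the connectivity hash layer)."""
    mol = Chem.MolFromSmiles(smiles_ph7)
    if mol is None:
        raise ValueError(f"cannot parse {smiles_ph7!r}")
    ik = Chem.MolToInchiKey(mol)
    if not ik:
        raise ValueError(f"InChIKey generation failed for {smiles_ph7!r}")
    return ik[:14]


def prepare(record: RawRecord, protonate: bool = True) -> StandardizedCompound:
    """Full preparation: filter -> standardize -> protonate -> key14."""
    std = standardize(record)
    if std.rejected:
        return std
    ph7 = protonate_ph7(std.smiles_std, enabled=protonate)
    try:
        k = key14(ph7)
    except ValueError:
        return replace(std, rejected=True, reject_reason="parse_failure")
    return replace(std, smiles_ph7=ph7, key14=k)


def prepare_records(
    records: list[RawRecord], protonate: bool = True
) -> list[StandardizedCompound]:
    return [prepare(r, protonate=protonate) for r in records]


@dataclass
class DedupResult:
    compounds: list[StandardizedCompound]
    n_conflicts: int = 0
    merged_from: dict[str, int] = field(default_factory=dict)


def deduplicate(
    records: list[StandardizedCompound], policy: str = "prefer_active"
) -> DedupResult:
    """Collapse records sharing a key14.

    ``prefer_active``: binary labels; any conflict resolves to 1 (toxic wins).
    ``median_numeric``: numeric labels; duplicates resolve to the median.
    Order-invariant: output sorted by key14.
    """
    if policy not in ("prefer_active", "median_numeric"):
        raise ValueError(f"unknown policy {policy!r}")
    labels = [r.label for r in records if not r.rejected]
    if policy == "prefer_active" and any(
        lbl is not None and float(lbl) not in (0.0, 1.0) for lbl in labels
    ):
        raise ValueError("prefer_active policy requires binary labels")

    groups: dict[str, list[StandardizedCompound]] = {}
    for r in records:
        if r.rejected:
            continue
        if not r.key14:
            raise ValueError("deduplicate requires key14 on every record")
        groups.setdefault(r.key14, []).append(r)

    out: list[StandardizedCompound] = []
    n_conflicts = 0
    merged: dict[str, int] = {}
    for k in sorted(groups):
        grp = groups[k]
        vals = [float(g.label) for g in grp if g.label is not None]
        if len({v for v in vals}) > 1:
            n_conflicts += 1
        if policy == "prefer_active":
            label: float | int | None = int(max(vals)) if vals else None
        else:
            label = statistics.median(vals) if vals else None
        rep = replace(grp[0], label=label)
        out.append(rep)
        if len(grp) > 1:
            merged[k] = len(grp)
    return DedupResult(compounds=out, n_conflicts=n_conflicts, merged_from=merged)


__all__ = [
    "RawRecord",
    "StandardizedCompound",
    "DedupResult",
    "filter_compound",
    "standardize",
    "protonate_ph7",
    "key14",
    "prepare",
    "prepare_records",
    "deduplicate",
    "MW_LIMIT",
    "PKA_TABLE_VERSION",
]
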