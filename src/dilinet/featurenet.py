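"""Level-2 stacking: stacked feature matrices over chemistry and level-1
endpoint predictions, repeated nested cross-validation, the final model with
its calibrated threshold, structure-only prediction, and per-compound
feature attribution."""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from ._util import keyset_digest
from .attribution import forest_contributions
from .chemprep import RawRecord, StandardizedCompound, prepare
from .data_model import EndpointDataset
from .endpoint_models import EndpointModel, SearchSpace, _search, youden_threshold
from .evaluation import binary_report
from .featurization import ChemFeaturizer, FeatureBlock

COMBOS = ("structural", "descriptors", "chem-all", "proxy", "all")


class LeakError(RuntimeError):
    """An input compound appears in a level-1 model's training set."""


@dataclass
class StackedFeatures:
    combo: str
    matrix: np.ndarray
    feature_names: list[str]
    provenance: list[str]  # per-column source block

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("width mismatch")
        if len(self.provenance) != len(self.feature_names):
            raise ValueError("provenance must cover every column")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def as_block(self) -> FeatureBlock:
        return FeatureBlock(
            name=f"stacked:{self.combo}",
            matrix=self.matrix,
            feature_names=self.feature_names,
        )


@dataclass
class StackedBuilder:
    """Builds stacked matrices from a fitted chemistry featurizer and the
    trained level-1 endpoint models (insertion order fixes column order)."""

    featurizer: ChemFeaturizer
    endpoint_models: dict[str, EndpointModel]
    binarize_proxy: bool = False

    def _chem_block(self, compounds: list[StandardizedCompound]) -> FeatureBlock:
        st = self.featurizer.structural(compounds)
        de = self.featurizer.descriptors(compounds)
        return FeatureBlock(
            name="chem-all",
            matrix=np.hstack([st.matrix, de.matrix]),
            feature_names=st.feature_names + de.feature_names,
        )

    def leak_check(self, compounds: list[StandardizedCompound]) -> None:
        # PK regressors are exempt: their training sets legitimately overlap
        # the gold set (numeric exposure values carry no DILI label).
        keys = {c.key14 for c in compounds}
        for name, model in self.endpoint_models.items():
            if not model.is_classifier:
                continue
            inter = keys & model.training_keys
            if inter:
                raise LeakError(
                    f"{len(inter)} input compounds are in the training set of "
                    f"endpoint model {name!r} (e.g. {sorted(inter)[0]})"
                )

    def build(
        self,
        compounds: list[StandardizedCompound],
        combo: str = "all",
        check_leak: bool = True,
    ) -> StackedFeatures:
        if combo not in COMBOS:
            raise ValueError(f"combo must be one of {COMBOS}")
        parts: list[np.ndarray] = []
        names: list[str] = []
        prov: list[str] = []
        n = len(compounds)

        need_chem_inputs = combo in ("proxy", "all")
        chem_inputs = (
            self._chem_block(compounds) if (need_chem_inputs and n) else None
        )

        if combo in ("structural", "chem-all", "all"):
            blk = (
                self.featurizer.structural(compounds)
                if n
                else FeatureBlock(
                    name="structural",
                    matrix=np.zeros((0, self.featurizer.n_structural)),
                    feature_names=self._structural_names(),
                )
            )
            parts.append(blk.matrix)
            names += blk.feature_names
            prov += ["structural"] * len(blk.feature_names)
        if combo in ("descriptors", "chem-all", "all"):
            blk = (
                self.featurizer.descriptors(compounds)
                if n
                else FeatureBlock(
                    name="descriptors+physchem",
                    matrix=np.zeros((0, self.featurizer.n_descriptor_features)),
                    feature_names=self._descriptor_names(),
                )
            )
            parts.append(blk.matrix)
            names += blk.feature_names
            prov += ["descriptors"] * len(blk.feature_names)
        if combo in ("proxy", "all"):
            if check_leak and n:
                self.leak_check(compounds)
            for name, model in self.endpoint_models.items():
                if n == 0:
                    col = np.zeros((0, 1))
                elif model.is_classifier:
                    p = model.estimator.predict_proba(chem_inputs.matrix)[:, 1]
                    if self.binarize_proxy:
                        p = (p >= model.threshold).astype(float)
                    col = p[:, None]
                else:
                    col = model.estimator.predict(chem_inputs.matrix)[:, None]
                parts.append(col)
                tag = "proxy" if model.is_classifier else "pk"
                names.append(f"{tag}:{name}")
                prov.append(tag)

        matrix = np.hstack(parts) if parts else np.zeros((n, 0))
        return StackedFeatures(combo=combo, matrix=matrix, feature_names=names, provenance=prov)

    def _structural_names(self) -> list[str]:
        mo = self.featurizer.morgan_ref
        ma = self.featurizer.maccs_ref
        return [n for n, m in zip(mo.feature_names, mo.selection_mask) if m] + [
            n for n, m in zip(ma.feature_names, ma.selection_mask) if m
        ]

    def _descriptor_names(self) -> list[str]:
        from .featurization import PHYSCHEM15_NAMES

        kept = [
            n
            for n, m in zip(self.featurizer.descriptor_reference.feature_names,
                            self.featurizer.descriptor_mask)
            if m
        ]
        return kept + list(PHYSCHEM15_NAMES)


@dataclass
class NestedCVConfig:
    outer_folds: int = 5
    repeats: int = 10
    inner_folds: int = 4
    space: SearchSpace = field(default_factory=SearchSpace)
    seed: int = 0


@dataclass
class NestedCVReport:
    combo: str
    rows: list[dict]  # one per outer fold x repeat
    config: NestedCVConfig

    def metric(self, name: str) -> list[float]:
        return [r[name] for r in self.rows if r[name] is not None]

    def mean(self, name: str) -> float:
        vals = self.metric(name)
        return float(np.mean(vals)) if vals else float("nan")

    def repeat_means(self, name: str) -> list[float]:
        reps = sorted({r["repeat"] for r in self.rows})
        return [
            float(np.mean([r[name] for r in self.rows
                           if r["repeat"] == rep and r[name] is not None]))
            for rep in reps
        ]

    def best_repeat_params(self) -> dict:
        """Hyperparameters from the repeat with the highest mean outer AUC."""
        reps = sorted({r["repeat"] for r in self.rows})
        means = self.repeat_means("auc_roc")
        best = reps[int(np.argmax(means))]
        folds = [r for r in self.rows if r["repeat"] == best]
        folds.sort(key=lambda r: (-(r["auc_roc"] if r["auc_roc"] is not None else -1)))
        return folds[0]["params"]


def nested_cv(
    gold_train: EndpointDataset,
    stacked: StackedFeatures,
    config: NestedCVConfig | None = None,
) -> NestedCVReport:
    """Repeated nested CV: per outer fold, tune on the remaining folds with
    an inner halving search, derive the Youden threshold from inner
    out-of-fold probabilities, and evaluate the thresholded model on the
    outer fold.  Yields outer_folds x repeats evaluation rows."""
    config = config or NestedCVConfig()
    X = stacked.matrix
    y = gold_train.labels()
    if X.shape[0] != len(y):
        raise ValueError("stacked features must align with the dataset")
    if np.bincount(y, minlength=2).min() < config.outer_folds:
        raise ValueError("cannot stratify: a class has fewer members than folds")
    rows: list[dict] = []
    for rep in range(config.repeats):
        rep_seed = config.seed * 1000 + rep
        outer = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=rep_seed
        )
        for fold, (tr, va) in enumerate(outer.split(X, y)):
            base = RandomForestClassifier(random_state=rep_seed, n_jobs=1)
            est, params = _search(
                base, config.space, X[tr], y[tr], rep_seed, "roc_auc", stratified=True
            )
            inner = StratifiedKFold(
                n_splits=config.inner_folds, shuffle=True, random_state=rep_seed
            )
            oof = cross_val_predict(
                est, X[tr], y[tr], cv=inner, method="predict_proba"
            )[:, 1]
            thr = youden_threshold(oof, y[tr])
            probs = est.predict_proba(X[va])[:, 1]
            calls = (probs >= thr).astype(int)
            rep_metrics = binary_report(y[va], calls, probs)
            rows.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "threshold": thr,
                    "params": params,
                    "auc_roc": rep_metrics.auc_roc,
                    "average_precision": rep_metrics.average_precision,
                    "balanced_accuracy": rep_metrics.balanced_accuracy,
                    "mcc": rep_metrics.mcc,
                    "f1": rep_metrics.f1,
                    "sensitivity": rep_metrics.sensitivity,
                    "specificity": rep_metrics.specificity,
                }
            )
    return NestedCVReport(combo=stacked.combo, rows=rows, config=config)


@dataclass
class FinalModel:
    estimator: RandomForestClassifier
    threshold: float
    combo: str
    feature_names: list[str]
    provenance: list[str]
    builder: StackedBuilder
    endpoint_digests: dict[str, str]
    training_digest: str
    oof_probs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must be in [0, 1]")


def fit_final(
    gold_train: EndpointDataset,
    stacked: StackedFeatures,
    builder: StackedBuilder,
    params: dict,
    seed: int = 0,
    inner_folds: int = 4,
) -> FinalModel:
    """Refit the chosen configuration on all training rows; the threshold
    comes from fresh inner-fold out-of-fold probabilities (never test data)."""
    X, y = stacked.matrix, gold_train.labels()
    est = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    est.fit(X, y)
    cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    oof = cross_val_predict(est, X, y, cv=cv, method="predict_proba")[:, 1]
    thr = youden_threshold(oof, y)
    return FinalModel(
        estimator=est,
        threshold=thr,
        combo=stacked.combo,
        feature_names=list(stacked.feature_names),
        provenance=list(stacked.provenance),
        builder=builder,
        endpoint_digests={
            n: m.training_digest for n, m in builder.endpoint_models.items()
        },
        training_digest=keyset_digest(gold_train.keys()),
        oof_probs=oof,
    )


def predict_dili(
    final: FinalModel, smiles_list: list[str], protonate: bool = True
) -> dict:
    """End-to-end prediction from raw SMILES.

    Returns {"accepted": [...], "rejected": [...]}; each accepted entry has
    probability, binary call at the calibrated threshold, and the stacked
    feature vector."""
    prepared: list[StandardizedCompound] = []
    rejected: list[dict] = []
    for smi in smiles_list:
        try:
            rec = prepare(RawRecord(smiles=smi), protonate=protonate)
        except ValueError:
            rejected.append({"smiles_in": smi, "reason": "parse_failure"})
            continue
        if rec.rejected:
            rejected.append({"smiles_in": smi, "reason": rec.reject_reason})
        else:
            prepared.append(rec)
    accepted: list[dict] = []
    if prepared:
        stacked = final.builder.build(prepared, combo=final.combo, check_leak=False)
        probs = final.estimator.predict_proba(stacked.matrix)[:, 1]
        calls = (probs >= final.threshold).astype(int)
        for i, rec in enumerate(prepared):
            accepted.append(
                {
                    "smiles_in": rec.smiles_in,
                    "smiles_std": rec.smiles_std,
                    "key14": rec.key14,
                    "probability": float(probs[i]),
                    "call": int(calls[i]),
                    "features": stacked.matrix[i],
                }
            )
    return {"accepted": accepted, "rejected": rejected}


_MACCS_RE = re.compile(r"^maccs_(\d+)$")


def attribute(final: FinalModel, compound: StandardizedCompound) -> dict:
    """Per-feature additive contributions for one prediction.

    Reports the ranked contribution list, the top-3 positive and negative
    proxy/PK columns, and the positively contributing MACCS key with matched
    atoms for substructure highlighting."""
    stacked = final.builder.build([compound], combo=final.combo, check_leak=False)
    x = stacked.matrix[0]
    base, contrib = forest_contributions(final.estimator, x)
    prob = float(final.estimator.predict_proba(x[None, :])[0, 1])
    if abs(base + contrib.sum() - prob) > 1e-6:
        raise AssertionError("attribution additivity violated")

    ranked = sorted(
        zip(final.feature_names, final.provenance, contrib),
        key=lambda t: -abs(t[2]),
    )
    proxy_cols = [
        (n, c) for n, p, c in zip(final.feature_names, final.provenance, contrib)
        if p in ("proxy", "pk")
    ]
    top_pos = sorted([t for t in proxy_cols if t[1] > 0], key=lambda t: -t[1])[:3]
    top_neg = sorted([t for t in proxy_cols if t[1] < 0], key=lambda t: t[1])[:3]

    highlight = None
    mol = Chem.MolFromSmiles(compound.smiles_ph7 or compound.smiles_std)
    maccs_contribs = []
    for name, p, c in zip(final.feature_names, final.provenance, contrib):
        m = _MACCS_RE.match(name)
        if m and c > 0 and x[final.feature_names.index(name)] > 0:
            maccs_contribs.append((int(m.group(1)), c))
    if maccs_contribs and mol is not None:
        maccs_contribs.sort(key=lambda t: -t[1])
        for key_idx, c in maccs_contribs:
            smarts, _count = MACCSkeys.smartsPatts.get(key_idx, ("?", 0))
            if smarts == "?":
                continue
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                continue
            match = mol.GetSubstructMatch(patt)
            if match:
                highlight = {
                    "maccs_key": key_idx,
                    "smarts": smarts,
                    "atoms": list(match),
                    "contribution": float(c),
                }
                break
    note = None if highlight else "no positively contributing MACCS key matched"

    return {
        "probability": prob,
        "base_value": base,
        "contributions": [(n, p, float(c)) for n, p, c in ranked],
        "top_positive_proxy": [(n, float(c)) for n, c in top_pos],
        "top_negative_proxy": [(n, float(c)) for n, c in top_neg],
        "highlight": highlight,
        "note": note,
    }


def structural_feature_atoms(
    compound: StandardizedCompound, feature_name: str
) -> set[int]:
    """Atom indices responsible for a structural feature in this compound.

    Morgan bits map to atoms via the fingerprint bit trace; MACCS keys map
    via their SMARTS pattern.  Empty set when the feature is not set.
    """
    from rdkit.Chem import rdFingerprintGenerator

    from .featurization import MORGAN_BITS, MORGAN_RADIUS

    mol = Chem.MolFromSmiles(compound.smiles_ph7 or compound.smiles_std)
    if mol is None:
        return set()
    m = _MACCS_RE.match(feature_name)
    if m:
        smarts, _ = MACCSkeys.smartsPatts.get(int(m.group(1)), ("?", 0))
        if smarts == "?":
            return set()
        patt = Chem.MolFromSmarts(smarts)
        atoms: set[int] = set()
        if patt is not None:
            for match in mol.GetSubstructMatches(patt):
                atoms.update(match)
        return atoms
    if feature_name.startswith("morgan_"):
        bit = int(feature_name.split("_")[1])
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=MORGAN_RADIUS, fpSize=MORGAN_BITS
        )
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        gen.GetFingerprint(mol, additionalOutput=ao)
        info = ao.GetBitInfoMap()
        atoms = set()
        for center, radius in info.get(bit, ()):
            if radius == 0:
                atoms.add(center)
            else:
                env = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
                for b in env:
                    bond = mol.GetBondWithIdx(b)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
        return atoms
    return set()


def recovers_toxicophore(
    final: FinalModel,
    compound: StandardizedCompound,
    tox_smarts: str,
    k: int = 3,
) -> bool:
    """True when one of the k most positive structural contributors overlaps
    the atoms matched by the planted toxicophore pattern."""
    mol = Chem.MolFromSmiles(compound.smiles_ph7 or compound.smiles_std)
    patt = Chem.MolFromSmarts(tox_smarts)
    if mol is None or patt is None:
        return False
    tox_atoms: set[int] = set()
    for match in mol.GetSubstructMatches(patt):
        tox_atoms.update(match)
    if not tox_atoms:
        return False
    att = attribute(final, compound)
    for name in top_structural_features(att, k=k):
        if structural_feature_atoms(compound, name) & tox_atoms:
            return True
    return False


def top_structural_features(attribution: dict, k: int = 3) -> list[str]:
    """Names of the k most positively contributing structural columns."""
    structural = [
        (n, c) for n, p, c in attribution["contributions"] if p == "structural" and c > 0
    ]
    structural.sort(key=lambda t: -t[1])
    return [n for n, _ in structural[:k]]


__all__ = [
    "StackedFeatures",
    "StackedBuilder",
    "NestedCVConfig",
    "NestedCVReport",
    "FinalModel",
    "LeakError",
    "nested_cv",
    "fit_final",
    "predict_dili",
    "attribute",
    "top_structural_features",
    "COMBOS",
]
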