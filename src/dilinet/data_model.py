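"""Panel assembly: gold-standard dataset, proxy endpoints, leak-proof
overlap removal, and pairwise label concordance."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemprep import StandardizedCompound, deduplicate

DILIRANK_CATEGORIES = {"vMost": 1, "vLess": 1, "vNo": 0}


@dataclass
class EndpointDataset:
    """Named compound set with binary activity or numeric labels."""

    name: str
    compounds: list[StandardizedCompound]
    kind: str = "binary"  # or "numeric"

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "numeric"):
            raise ValueError(f"unknown kind {self.kind!r}")
        keys = self.keys()
        if len(keys) != len(set(keys)):
            raise ValueError(f"dataset {self.name!r} has duplicate key14 values")
        for c in self.compounds:
            if c.label is None:
                raise ValueError(f"dataset {self.name!r} has an unlabeled compound")
            if self.kind == "binary" and float(c.label) not in (0.0, 1.0):
                raise ValueError(f"non-binary label {c.label!r} in {self.name!r}")
            if self.kind == "numeric" and not math.isfinite(float(c.label)):
                raise ValueError(f"non-finite label in {self.name!r}")

    def keys(self) -> list[str]:
        return [c.key14 for c in self.compounds]

    def labels(self) -> np.ndarray:
        arr = np.asarray([float(c.label) for c in self.compounds])
        return arr.astype(int) if self.kind == "binary" else arr

    def label_by_key(self) -> dict[str, float]:
        return {c.key14: float(c.label) for c in self.compounds}

    def __len__(self) -> int:
        return len(self.compounds)


@dataclass
class Panel:
    """Gold DILI dataset + proxy endpoint datasets + PK regression targets.

    After construction no proxy compound shares a key14 with the gold set;
    PK datasets are exempt from overlap removal.
    """

    gold: EndpointDataset
    proxies: list[EndpointDataset]
    pk: list[EndpointDataset] = field(default_factory=list)
    removed_overlap: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gold_keys = set(self.gold.keys())
        for p in self.proxies:
            inter = gold_keys & set(p.keys())
            if inter:
                raise ValueError(
                    f"proxy {p.name!r} shares {len(inter)} compounds with gold; "
                    "run remove_overlap first"
                )
        for p in self.pk:
            if p.kind != "numeric":
                raise ValueError("PK datasets must be numeric")

    @property
    def endpoint_names(self) -> list[str]:
        return [p.name for p in self.proxies] + [p.name for p in self.pk]


def dataset_from_records(
    name: str, records: list[StandardizedCompound], kind: str = "binary"
) -> EndpointDataset:
    """Deduplicate prepared records into an EndpointDataset."""
    policy = "prefer_active" if kind == "binary" else "median_numeric"
    dd = deduplicate([r for r in records if not r.rejected], policy=policy)
    compounds = [c for c in dd.compounds if c.label is not None]
    return EndpointDataset(name=name, compounds=compounds, kind=kind)


def assemble_gold(
    dilist_records: list[StandardizedCompound],
    dilirank_records: list[StandardizedCompound],
) -> EndpointDataset:
    """Merge a binary-labeled source with a categorically labeled source.

    Categorical labels map vMost/vLess -> 1, vNo -> 0; Ambiguous entries are
    dropped.  Cross-source conflicts resolve to the toxic annotation.
    """
    mapped: list[StandardizedCompound] = []
    for r in dilirank_records:
        if r.rejected:
            continue
        cat = r.label
        if cat == "Ambiguous":
            continue
        if cat not in DILIRANK_CATEGORIES:
            raise ValueError(f"unknown DILIrank category {cat!r}")
        mapped.append(
            StandardizedCompound(
                smiles_std=r.smiles_std,
                smiles_ph7=r.smiles_ph7,
                key14=r.key14,
                label=DILIRANK_CATEGORIES[cat],
                source=r.source or "dilirank",
                identifier=r.identifier,
                smiles_in=r.smiles_in,
            )
        )
    binary = [r for r in dilist_records if not r.rejected]
    for r in binary:
        if r.label is None or float(r.label) not in (0.0, 1.0):
            raise ValueError(f"binary source has non-binary label {r.label!r}")
    dd = deduplicate(binary + mapped, policy="prefer_active")
    return EndpointDataset(name="DILI", compounds=dd.compounds, kind="binary")


def remove_overlap(
    proxy: EndpointDataset, gold: EndpointDataset
) -> tuple[EndpointDataset, int]:
    """Drop proxy compounds whose key14 appears in the gold set."""
    gold_keys = set(gold.keys())
    kept = [c for c in proxy.compounds if c.key14 not in gold_keys]
    removed = len(proxy.compounds) - len(kept)
    if not kept:
        import warnings

        warnings.warn(f"overlap removal emptied proxy dataset {proxy.name!r}")
    return EndpointDataset(name=proxy.name, compounds=kept, kind=proxy.kind), removed


def build_panel(
    gold: EndpointDataset,
    proxies: list[EndpointDataset],
    pk: list[EndpointDataset] | None = None,
) -> Panel:
    cleaned = []
    removed = {}
    for p in proxies:
        cp, n = remove_overlap(p, gold)
        cleaned.append(cp)
        removed[p.name] = n
    return Panel(gold=gold, proxies=cleaned, pk=list(pk or []), removed_overlap=removed)


def concordance_matrix(
    datasets: list[EndpointDataset], include_overlap: bool = True
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pairwise Cohen's kappa over shared compounds.

    Returns (kappa matrix, overlap-count matrix, names).  Entries for pairs
    with no shared compounds — or an undefined kappa — are NaN, never 0.
    The caller chooses whether the datasets passed in retain gold-overlapping
    compounds (``include_overlap`` is documentation of that choice).
    """
    from .evaluation import kappa as cohen_kappa

    for d in datasets:
        if d.kind != "binary":
            raise ValueError(f"concordance requires binary datasets, got {d.name!r}")
    n = len(datasets)
    if n < 2:
        raise ValueError("need at least two datasets")
    maps = [d.label_by_key() for d in datasets]
    kmat = np.full((n, n), np.nan)
    omat = np.zeros((n, n), dtype=int)
    for i in range(n):
        kmat[i, i] = 1.0
        omat[i, i] = len(maps[i])
        for j in range(i + 1, n):
            shared = sorted(set(maps[i]) & set(maps[j]))
            omat[i, j] = omat[j, i] = len(shared)
            if not shared:
                continue
            a = [int(maps[i][k]) for k in shared]
            b = [int(maps[j][k]) for k in shared]
            kv = cohen_kappa(a, b)
            kmat[i, j] = kmat[j, i] = np.nan if kv is None else kv
    return kmat, omat, [d.name for d in datasets]


def save_panel(panel: Panel, out_dir: str | Path) -> None:
    """Persist a panel as per-endpoint CSVs plus a manifest JSON."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"endpoints": [], "removed_overlap": panel.removed_overlap}
    for ds, role in (
        [(panel.gold, "gold")]
        + [(p, "proxy") for p in panel.proxies]
        + [(p, "pk") for p in panel.pk]
    ):
        fname = f"{ds.name}.csv"
        pd.DataFrame(
            {
                "smiles_std": [c.smiles_std for c in ds.compounds],
                "smiles_ph7": [c.smiles_ph7 for c in ds.compounds],
                "key14": ds.keys(),
                "label": [c.label for c in ds.compounds],
                "source": [c.source for c in ds.compounds],
            }
        ).to_csv(out / fname, index=False)
        manifest["endpoints"].append(
            {"name": ds.name, "kind": ds.kind, "role": role, "n": len(ds), "file": fname}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_panel(in_dir: str | Path) -> Panel:
    import pandas as pd

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    gold = None
    proxies, pk = [], []
    for entry in manifest["endpoints"]:
        df = pd.read_csv(src / entry["file"])
        compounds = [
            StandardizedCompound(
                smiles_std=row.smiles_std,
                smiles_ph7=row.smiles_ph7 if isinstance(row.smiles_ph7, str) else row.smiles_std,
                key14=row.key14,
                label=row.label,
                source=str(row.source) if isinstance(row.source, str) else "",
            )
            for row in df.itertuples()
        ]
        ds = EndpointDataset(name=entry["name"], compounds=compounds, kind=entry["kind"])
        if entry["role"] == "gold":
            gold = ds
        elif entry["role"] == "proxy":
            proxies.append(ds)
        else:
            pk.append(ds)
    if gold is None:
        raise ValueError("panel manifest lacks a gold dataset")
    return Panel(
        gold=gold,
        proxies=proxies,
        pk=pk,
        removed_overlap=manifest.get("removed_overlap", {}),
    )


__all__ = [
    "EndpointDataset",
    "Panel",
    "dataset_from_records",
    "assemble_gold",
    "remove_overlap",
    "build_panel",
    "concordance_matrix",
    "save_panel",
    "load_panel",
    "DILIRANK_CATEGORIES",
]
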