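"""Scaffold-aware splitting: sphere-exclusion (Butina) clustering on
Tanimoto distance over 2048-bit radius-2 fingerprints, whole-cluster
train/test assignment, and nearest-neighbour similarity diagnostics."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemprep import StandardizedCompound
from .featurization import morgan_bits

# NOTE: the 0.70 cutoff is a Tanimoto DISTANCE (1 - similarity) cutoff —
# compounds at similarity >= 0.30 of a cluster centroid join its cluster.
DEFAULT_CUTOFF = 0.70


@dataclass
class SplitResult:
    train_keys: list[str]
    test_keys: list[str]
    cutoff: float
    cluster_assignments: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.train_keys) & set(self.test_keys):
            raise ValueError("train and test overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "cutoff": self.cutoff,
                    "train_keys": sorted(self.train_keys),
                    "test_keys": sorted(self.test_keys),
                    "cluster_assignments": self.cluster_assignments,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitResult":
        d = json.loads(Path(path).read_text())
        return cls(
            train_keys=d["train_keys"],
            test_keys=d["test_keys"],
            cutoff=d["cutoff"],
            cluster_assignments=d["cluster_assignments"],
        )


def _fingerprints(compounds: list[StandardizedCompound | str]) -> np.ndarray:
    return np.vstack([morgan_bits(c) for c in compounds]).astype(bool)


def tanimoto_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity of boolean fingerprint rows."""
    fps = fps.astype(np.float64)
    inter = fps @ fps.T
    pop = fps.sum(axis=1)
    union = pop[:, None] + pop[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def butina_cluster(
    compounds: list[StandardizedCompound | str], cutoff: float = DEFAULT_CUTOFF
) -> list[int]:
    """Classic sphere-exclusion clustering on Tanimoto distance.

    Candidates are ordered by neighbour count within ``cutoff`` (ties ->
    lower input index first); each candidate claims every unassigned
    compound within the cutoff, itself included.  Returns one cluster id per
    input compound; ids are assigned in claim order starting at 0.
    """
    n = len(compounds)
    if n == 0:
        raise ValueError("need at least one compound")
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    sim = tanimoto_matrix(_fingerprints(compounds))
    dist = 1.0 - sim
    within = dist <= cutoff
    np.fill_diagonal(within, True)
    neighbor_counts = within.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-neighbor_counts[i], i))
    assignments = [-1] * n
    next_id = 0
    for centroid in order:
        if assignments[centroid] != -1:
            continue
        members = [j for j in range(n) if assignments[j] == -1 and within[centroid, j]]
        for j in members:
            assignments[j] = next_id
        next_id += 1
    return assignments


def cluster_split(
    cluster_assignments: list[int],
    test_fraction: float,
    keys: list[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
) -> SplitResult:
    """Assign whole clusters to train, largest-first, until the train side
    reaches (1 - test_fraction) of the compounds; the rest is the test side.

    Ties in cluster size break toward the lower cluster id.  Deterministic.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(cluster_assignments)
    if keys is None:
        keys = [str(i) for i in range(n)]
    if len(keys) != n:
        raise ValueError("keys must align with cluster_assignments")
    clusters: dict[int, list[int]] = {}
    for i, cid in enumerate(cluster_assignments):
        clusters.setdefault(cid, []).append(i)
    if len(clusters) == 1:
        raise ValueError(
            "a single cluster contains every compound; use a smaller cutoff"
        )
    target_train = (1.0 - test_fraction) * n
    order = sorted(clusters, key=lambda cid: (-len(clusters[cid]), cid))
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cid in order:
        members = clusters[cid]
        if len(train_idx) + len(members) <= target_train:
            train_idx.extend(members)
        else:
            test_idx.extend(members)
    assignment_map = {keys[i]: cid for i, cid in enumerate(cluster_assignments)}
    return SplitResult(
        train_keys=[keys[i] for i in sorted(train_idx)],
        test_keys=[keys[i] for i in sorted(test_idx)],
        cutoff=cutoff,
        cluster_assignments=assignment_map,
    )


def butina_split(
    compounds: list[StandardizedCompound],
    cutoff: float = DEFAULT_CUTOFF,
    test_fraction: float = 0.2,
) -> SplitResult:
    assignments = butina_cluster(compounds, cutoff=cutoff)
    keys = [c.key14 for c in compounds]
    return cluster_split(assignments, test_fraction, keys=keys, cutoff=cutoff)


def nn_similarity_to_train(
    test_compound: StandardizedCompound | str,
    train_compounds: list[StandardizedCompound | str],
    k: int = 3,
) -> float:
    """Mean of the k highest Tanimoto similarities of a test compound to the
    training compounds (structural-novelty diagnostic)."""
    if not train_compounds:
        raise ValueError("train set is empty")
    if k > len(train_compounds):
        warnings.warn(f"k={k} exceeds train size {len(train_compounds)}; using all")
        k = len(train_compounds)
    t = morgan_bits(test_compound).astype(bool)
    sims = []
    for c in train_compounds:
        f = morgan_bits(c).astype(bool)
        union = np.logical_or(t, f).sum()
        sims.append(np.logical_and(t, f).sum() / union if union else 1.0)
    return float(np.mean(sorted(sims, reverse=True)[:k]))


__all__ = [
    "SplitResult",
    "butina_cluster",
    "cluster_split",
    "butina_split",
    "nn_similarity_to_train",
    "tanimoto_matrix",
    "DEFAULT_CUTOFF",
]
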