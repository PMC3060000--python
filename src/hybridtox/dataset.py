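"""Modeling-set assembly: toxicity classes, external folds, balancing, splits.

Acute-toxicity potency is modeled as -log10 LD50 in mol/kg and discretized by
the standard guideline cutoffs: > 3 is "toxic", < 2 is "nontoxic", the band
in between is "marginal" and excluded from classification modeling.  The
modeling pool is ~3:1 dominated by nontoxic compounds, so each pool is
down-sampled by removing the nontoxic compounds most structurally dissimilar
from any toxic compound until the classes are balanced.  Balanced pools are
then subdivided into training/test pairs with a sphere-exclusion procedure,
which guarantees every test compound has a training compound within the probe
radius — the interpolation regime kNN models rely on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .qhts_io import DescriptorMatrix, ToxicityRecord

__all__ = [
    "ModelingDataset",
    "ModelingSplit",
    "assign_toxicity_class",
    "balance_modeling_set",
    "build_modeling_dataset",
    "make_external_folds",
    "sphere_exclusion_split",
]

TOXIC_CUTOFF = 3.0     # -log10 LD50 (mol/kg) above which a compound is "toxic"
NONTOXIC_CUTOFF = 2.0  # below which it is "nontoxic"; between is "marginal"


def assign_toxicity_class(neg_log_ld50: float) -> str:
    """Map -log10 LD50 (mol/kg) to {toxic, nontoxic, marginal}.

    > 3 -> toxic, < 2 -> nontoxic, otherwise marginal.  The mapping partitions
    the real line; the cutoff values themselves fall in the marginal band.
    """
    x = float(neg_log_ld50)
    if not math.isfinite(x):
        raise ValueError(f"neg_log_ld50 must be finite, got {x}")
    if x > TOXIC_CUTOFF:
        return "toxic"
    if x < NONTOXIC_CUTOFF:
        return "nontoxic"
    return "marginal"


@dataclass
class ModelingDataset:
    """Binary-labeled modeling compounds (toxic=1, nontoxic=0) plus exclusions."""

    compound_ids: list[str]
    labels: dict[str, int]
    excluded_marginal: list[str]
    records: dict[str, ToxicityRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.compound_ids)


def build_modeling_dataset(
    tox_records: Sequence[ToxicityRecord],
    descriptor_matrix: DescriptorMatrix,
) -> ModelingDataset:
    """Keep toxic and nontoxic compounds, exclude marginals, attach 0/1 labels."""
    have = set(descriptor_matrix.compound_ids)
    missing = [r.compound_id for r in tox_records if r.compound_id not in have]
    if missing:
        raise ValueError(f"records without descriptors: {missing[:10]}")
    ids: list[str] = []
    labels: dict[str, int] = {}
    excluded: list[str] = []
    records: dict[str, ToxicityRecord] = {}
    for r in tox_records:
        records[r.compound_id] = r
        if r.tox_class == "marginal":
            excluded.append(r.compound_id)
        else:
            ids.append(r.compound_id)
            labels[r.compound_id] = 1 if r.tox_class == "toxic" else 0
    if not ids:
        warnings.warn("all compounds are marginal; modeling set is empty")
    return ModelingDataset(ids, labels, excluded, records)


@dataclass
class ModelingSplit:
    """One fold of the external-validation scheme.

    ``external_test`` (~20% of compounds) is never touched by balancing,
    scaling fits or training; ``modeling_pool`` is the remainder, balanced and
    subdivided into ``internal_splits`` train/test pairs for model selection.
    """

    fold_index: int
    external_test: list[str]
    modeling_pool: list[str]
    internal_splits: list[tuple[list[str], list[str]]] = field(default_factory=list)


def make_external_folds(
    ids: Sequence[str], n_folds: int = 5, seed: int = 0
) -> list[ModelingSplit]:
    """Seeded random partition into nearly equal external-test subsets.

    Fold sizes differ by at most one; fold ``i``'s subset is the external
    test set and the remaining compounds are its modeling pool.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    ids = list(ids)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} compounds, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    chunks = [list(c) for c in np.array_split(np.array(order, dtype=object), n_folds)]
    splits = []
    for i, chunk in enumerate(chunks, start=1):
        external = [str(x) for x in chunk]
        pool = [x for x in ids if x not in set(external)]
        splits.append(ModelingSplit(fold_index=i, external_test=external, modeling_pool=pool))
    return splits


def balance_modeling_set(
    pool: Sequence[str],
    labels: Mapping[str, int],
    chem_matrix: DescriptorMatrix,
    target_ratio: float = 1.0,
    seed: int | None = None,
) -> list[str]:
    """Down-sample nontoxic compounds most dissimilar from any toxic compound.

    For each nontoxic compound the Euclidean distance (in scaled chemical-
    descriptor space) to its nearest toxic compound is computed; nontoxic
    compounds are removed in descending order of that distance until
    ``n_nontoxic <= target_ratio * n_toxic``.  Toxic compounds are never
    removed.  Deterministic: ties in distance are broken by compound id.
    ``seed`` is accepted for interface symmetry but unused (no randomness).
    """
    pool = list(pool)
    toxic = [c for c in pool if labels[c] == 1]
    nontoxic = [c for c in pool if labels[c] == 0]
    if not toxic:
        raise ValueError("cannot balance a pool with no toxic compounds")
    n_keep = int(math.floor(target_ratio * len(toxic)))
    if len(nontoxic) <= n_keep:
        return pool
    x_tox = chem_matrix.subset_compounds(toxic).values
    x_non = chem_matrix.subset_compounds(nontoxic).values
    nearest = cdist(x_non, x_tox).min(axis=1)
    # farthest-from-toxic first; id breaks ties
    order = sorted(zip(nearest, nontoxic), key=lambda t: (-t[0], t[1]))
    removed = {cid for _, cid in order[: len(nontoxic) - n_keep]}
    return [c for c in pool if c not in removed]


def _sphere_exclusion_once(
    dmat: np.ndarray,
    ids: list[str],
    radius: float,
    start_with_test: bool,
) -> tuple[list[str], list[str]]:
    """One sphere-exclusion pass at a fixed probe radius.

    Repeatedly select the unassigned compound farthest from all selected
    centers (the first center is the compound with the greatest mean distance
    to all others), put it in the training set, then assign its unassigned
    neighbors within the radius alternately to test and train, nearest first.
    """
    n = len(ids)
    unassigned = set(range(n))
    train: list[int] = []
    test: list[int] = []
    dist_to_selected = np.full(n, np.inf)
    centroid_dist = None
    while unassigned:
        cands = sorted(unassigned)
        if not train and not test:
            if centroid_dist is None:
                centroid_dist = dmat.mean(axis=1)
            best_val = max(centroid_dist[i] for i in cands)
            tied = [i for i in cands if centroid_dist[i] == best_val]
            center = min(tied, key=lambda i: ids[i])
        else:
            best_val = max(dist_to_selected[i] for i in cands)
            tied = [i for i in cands if dist_to_selected[i] == best_val]
            center = min(tied, key=lambda i: ids[i])
        train.append(center)
        unassigned.remove(center)
        np.minimum(dist_to_selected, dmat[center], out=dist_to_selected)
        members = sorted(
            (i for i in unassigned if dmat[center, i] <= radius),
            key=lambda i: (dmat[center, i], ids[i]),
        )
        to_test = start_with_test
        for m in members:
            (test if to_test else train).append(m)
            unassigned.remove(m)
            np.minimum(dist_to_selected, dmat[m], out=dist_to_selected)
            to_test = not to_test
    return [ids[i] for i in sorted(train)], [ids[i] for i in sorted(test)]


def sphere_exclusion_split(
    compounds: Sequence[str],
    matrix: DescriptorMatrix,
    labels: Mapping[str, int],
    n_splits: int = 20,
    seed: int = 0,
    min_test_fraction: float = 0.10,
    max_test_fraction: float = 0.40,
) -> list[tuple[list[str], list[str]]]:
    """Diversity-driven training/test subdivisions at a schedule of probe radii.

    The ``n_splits`` probe radii are evenly spaced quantiles of the
    nearest-neighbor-distance distribution of the set, which adapts the
    schedule to any dataset density.  A radius whose split leaves the test
    fraction outside ``[min_test_fraction, max_test_fraction]`` is adjusted
    geometrically (and the adjustment logged via ``warnings``); every split is
    forced to keep both classes in its training side by moving the nearest
    missing-class test compound into training when necessary.  By
    construction every test compound lies within the probe radius of some
    training compound.
    """
    compounds = list(compounds)
    n = len(compounds)
    if n < 10:
        raise ValueError(f"need at least 10 compounds for sphere exclusion, got {n}")
    x = matrix.subset_compounds(compounds).values
    dmat = squareform(pdist(x))
    nn = np.partition(dmat + np.diag(np.full(n, np.inf)), 0, axis=1)[:, 0]
    positive = nn[nn > 0]
    floor = positive.min() * 1e-3 if positive.size else 1e-9
    qs = np.linspace(0.05, 0.95, n_splits)
    radii = np.maximum(np.quantile(nn, qs), floor)

    splits: list[tuple[list[str], list[str]]] = []
    for s in range(n_splits):
        radius = float(radii[s])
        start_with_test = bool(s % 2 == 0)
        train = test = None
        for _attempt in range(60):
            train, test = _sphere_exclusion_once(dmat, compounds, radius, start_with_test)
            frac = len(test) / n
            if frac < min_test_fraction:
                radius *= 1.35
                warnings.warn(f"split {s}: test fraction {frac:.2f} too small, radius -> {radius:.4g}")
            elif frac > max_test_fraction:
                radius *= 0.75
                warnings.warn(f"split {s}: test fraction {frac:.2f} too large, radius -> {radius:.4g}")
            else:
                break
        train_classes = {labels[c] for c in train}
        for cls in (0, 1):
            if cls not in train_classes:
                movable = [c for c in test if labels[c] == cls]
                if movable:
                    moved = movable[0]
                    test = [c for c in test if c != moved]
                    train = sorted(train + [moved])
                    warnings.warn(f"split {s}: moved {moved} to train to keep both classes")
        if not test:
            raise RuntimeError(f"split {s}: could not construct a non-empty test set")
        splits.append((train, test))
    return splits
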