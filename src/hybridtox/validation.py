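"""External validation, y-randomization robustness and descriptor-frequency analysis.

The validation protocol is 5-fold external: compounds are randomly split
into five nearly equal subsets, and for each fold the remaining ~80% form a
modeling pool that is balanced (chemical-space down-sampling of nontoxic
compounds), subdivided by sphere exclusion into internal training/test
splits, and used to train a kNN consensus ensemble.  The untouched ~20% is
scored and evaluated.  External compounds never enter balancing, descriptor
scaling fits or training, so the per-fold descriptor curation is re-fit
inside each fold.

y-Randomization retrains the identical pipeline on label-permuted modeling
pools (external labels untouched) several times; real models are trustworthy
only when the randomized CCR distribution falls significantly short of the
real mean CCR (one-sample, one-tailed t-test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import balance_modeling_set, make_external_folds, sphere_exclusion_split
from .descriptors import (
    build_bio_descriptors,
    combine_hybrid,
    filter_chemical_descriptors,
    scale_biological,
    scale_external,
    split_bio_descriptor_name,
)
from .noise_filter import FilterParams
from .qhts_io import ConcentrationResponseProfile, DescriptorMatrix
from .qsar_models import (
    EvaluationReport,
    KnnConfig,
    KnnModel,
    calls_from_scores,
    consensus_scores,
    evaluate,
    train_knn_ensemble,
)

__all__ = [
    "ValidationConfig",
    "ValidationSummary",
    "YRandomizationResult",
    "descriptor_frequency",
    "prepare_fold_matrices",
    "randomization_p_value",
    "read_split_table",
    "run_external_validation",
    "write_split_table",
    "y_randomization_test",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Settings of one external-validation experiment."""

    filter_params: FilterParams | None = FilterParams(15.0, 5.0)
    use_biological: bool = True
    r2_cutoff: float = 0.95
    n_folds: int = 5
    n_internal_splits: int = 20
    target_ratio: float = 1.0
    knn: KnnConfig = KnnConfig()
    t1: float = 0.5
    t2: float = 0.5
    seed: int = 0


@dataclass
class FoldResult:
    fold_index: int
    report: EvaluationReport | None
    n_models: int
    scores: pd.Series | None = None
    models: list[KnnModel] = field(default_factory=list)
    external_ids: list[str] = field(default_factory=list)
    balanced_ids: list[str] = field(default_factory=list)
    internal_splits: list[tuple[list[str], list[str]]] = field(default_factory=list)


@dataclass
class YRandomizationResult:
    randomized_ccrs: list[float]
    real_mean_ccr: float
    p_value: float
    flag: str  # "pass" when randomized models are significantly worse, else "discard"


@dataclass
class ValidationSummary:
    fold_results: list[FoldResult]
    mean_ccr: float | None
    config: ValidationConfig
    y_randomization: YRandomizationResult | None = None
    descriptor_frequencies: pd.Series | None = None

    @property
    def fold_ccrs(self) -> list[float]:
        return [f.report.ccr for f in self.fold_results if f.report and f.report.ccr is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fold_results:
            r = f.report
            rows.append(
                {
                    "fold": f.fold_index,
                    "ccr": None if r is None else r.ccr,
                    "sensitivity": None if r is None else r.sensitivity,
                    "specificity": None if r is None else r.specificity,
                    "coverage": None if r is None else r.coverage,
                    "n_models": f.n_models,
                }
            )
        df = pd.DataFrame(rows)
        mean_row = {"fold": "mean", "ccr": self.mean_ccr}
        return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def prepare_fold_matrices(
    pool_ids: Sequence[str],
    external_ids: Sequence[str],
    chem_raw: DescriptorMatrix,
    bio_raw: DescriptorMatrix | None,
    config: ValidationConfig,
) -> tuple[DescriptorMatrix, DescriptorMatrix, DescriptorMatrix]:
    """Fit descriptor curation on the pool only; transform the external set.

    Returns ``(pool_matrix, external_matrix, pool_chem_scaled)`` where the
    last is the chemical-only scaled matrix used for balancing distances.
    """
    chem_pool_fit = filter_chemical_descriptors(
        chem_raw.subset_compounds(pool_ids), r2_cutoff=config.r2_cutoff, seed=config.seed
    )
    chem_ext = scale_external(chem_pool_fit, chem_raw.subset_compounds(external_ids))
    if config.use_biological and bio_raw is not None:
        bio_pool = scale_biological(bio_raw.subset_compounds(pool_ids))
        bio_ext = scale_biological(bio_raw.subset_compounds(external_ids))
        pool_matrix = combine_hybrid(chem_pool_fit, bio_pool)
        ext_matrix = combine_hybrid(chem_ext, bio_ext)
    else:
        pool_matrix, ext_matrix = chem_pool_fit, chem_ext
    return pool_matrix, ext_matrix, chem_pool_fit


def _run_fold(
    split,
    labels: Mapping[str, int],
    chem_raw: DescriptorMatrix,
    bio_raw: DescriptorMatrix | None,
    config: ValidationConfig,
    permute_rng: np.random.Generator | None,
) -> FoldResult:
    pool = list(split.modeling_pool)
    external = list(split.external_test)
    fold_labels = dict(labels)
    if permute_rng is not None:
        pool_labels = [labels[c] for c in pool]
        permuted = list(permute_rng.permutation(pool_labels))
        fold_labels.update({c: int(v) for c, v in zip(pool, permuted)})

    if len({fold_labels[c] for c in pool}) < 2:
        warnings.warn(f"fold {split.fold_index}: single-class modeling pool, skipped")
        return FoldResult(split.fold_index, None, 0, external_ids=external)

    pool_matrix, ext_matrix, chem_pool = prepare_fold_matrices(
        pool, external, chem_raw, bio_raw, config
    )
    balanced = balance_modeling_set(
        pool, fold_labels, chem_pool, target_ratio=config.target_ratio
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        internal = sphere_exclusion_split(
            balanced,
            pool_matrix,
            fold_labels,
            n_splits=config.n_internal_splits,
            seed=config.seed + split.fold_index,
        )
    models = train_knn_ensemble(
        internal,
        pool_matrix.subset_compounds(balanced),
        fold_labels,
        config=_reseed(config.knn, config.seed * 1000 + split.fold_index),
    )
    split.internal_splits = internal
    if not models:
        warnings.warn(f"fold {split.fold_index}: no models retained")
        return FoldResult(
            split.fold_index, None, 0,
            external_ids=external, balanced_ids=balanced, internal_splits=internal,
        )
    scores, _cover = consensus_scores(models, ext_matrix)
    calls = calls_from_scores(scores, config.t1, config.t2)
    report = evaluate(calls, {c: labels[c] for c in external})
    return FoldResult(
        split.fold_index, report, len(models), scores=scores, models=models,
        external_ids=external, balanced_ids=balanced, internal_splits=internal,
    )


def _reseed(knn: KnnConfig, seed: int) -> KnnConfig:
    return KnnConfig(
        k_range=knn.k_range,
        subset_size_range=knn.subset_size_range,
        accept_ccr=knn.accept_ccr,
        z_ad=knn.z_ad,
        n_proposals=knn.n_proposals,
        cooling=knn.cooling,
        min_acceptance=knn.min_acceptance,
        max_temperatures=knn.max_temperatures,
        seed=seed % (2**31),
    )


def run_external_validation(
    labels: Mapping[str, int],
    chem_raw: DescriptorMatrix,
    bio_raw: DescriptorMatrix | None,
    config: ValidationConfig = ValidationConfig(),
    _permute_seed: int | None = None,
) -> ValidationSummary:
    """Full n-fold external validation of the kNN consensus pipeline.

    ``labels`` maps compound id -> 0/1 for the modeling (toxic u nontoxic)
    compounds; ``chem_raw`` is the uncurated chemical matrix and ``bio_raw``
    the unscaled (percent) biological matrix, already noise-filtered at the
    configuration's THR/MXDV.  Deterministic for a fixed config.
    """
    ids = sorted(labels)
    splits = make_external_folds(ids, n_folds=config.n_folds, seed=config.seed)
    permute_rng = (
        np.random.default_rng(_permute_seed) if _permute_seed is not None else None
    )
    fold_results = [
        _run_fold(s, labels, chem_raw, bio_raw, config, permute_rng) for s in splits
    ]
    ccrs = [f.report.ccr for f in fold_results if f.report and f.report.ccr is not None]
    mean_ccr = float(np.mean(ccrs)) if ccrs else None
    return ValidationSummary(fold_results=fold_results, mean_ccr=mean_ccr, config=config)


def y_randomization_test(
    labels: Mapping[str, int],
    chem_raw: DescriptorMatrix,
    bio_raw: DescriptorMatrix | None,
    config: ValidationConfig,
    real_summary: ValidationSummary,
    n_repeats: int = 5,
    seed: int = 0,
) -> YRandomizationResult:
    """Retrain the pipeline on permuted modeling labels and test for chance-level CCR.

    Labels are shuffled (count-preserving) within each fold's modeling pool;
    external labels are untouched.  The one-sample, one-tailed t-test asks
    whether the randomized CCR distribution reaches the real mean CCR: small
    p means randomized models are significantly worse, i.e. the real signal
    is not an artifact of the model search.  Models are flagged "discard"
    when p >= 0.05.
    """
    if real_summary.mean_ccr is None:
        raise ValueError("real validation run has no defined mean CCR")
    rand_ccrs: list[float] = []
    for r in range(n_repeats):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = run_external_validation(
                labels, chem_raw, bio_raw, config, _permute_seed=seed + 7919 * (r + 1)
            )
        if summary.mean_ccr is not None:
            rand_ccrs.append(summary.mean_ccr)
    real = real_summary.mean_ccr
    if not rand_ccrs:
        raise RuntimeError("no y-randomized repeat produced a defined CCR")
    p = randomization_p_value(rand_ccrs, real)
    flag = "pass" if p < 0.05 else "discard"
    return YRandomizationResult(
        randomized_ccrs=rand_ccrs, real_mean_ccr=real, p_value=p, flag=flag
    )


def randomization_p_value(randomized_ccrs: Sequence[float], real_ccr: float) -> float:
    """One-sample, one-tailed t-test p-value of randomized CCRs vs the real mean.

    Small p: randomized models fall significantly short of the real CCR.  With
    zero variance among the randomized CCRs the t statistic is undefined and
    an exact comparison is used instead: all equal to the real CCR -> 0.5
    (the t statistic would be 0), all below -> 0, all above -> 1.
    """
    arr = np.asarray(randomized_ccrs, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one randomized CCR")
    if np.allclose(arr.std(), 0.0):
        warnings.warn("zero variance among randomized CCRs; exact comparison used")
        if np.allclose(arr.mean(), real_ccr):
            return 0.5
        return 0.0 if arr.mean() < real_ccr else 1.0
    return float(stats.ttest_1samp(arr, popmean=real_ccr, alternative="less").pvalue)


def write_split_table(summary: ValidationSummary, path) -> None:
    """Serialize every fold's external / internal-split membership as TSV.

    One row per (fold, subset, compound); the run's seed is recorded in a
    ``# seed=`` header line so the experiment is replayable.  The table is the
    basis of the data-leakage audit: external compounds must never appear in
    any internal training/test subset.
    """
    rows = []
    for f in summary.fold_results:
        for cid in f.external_ids:
            rows.append({"fold": f.fold_index, "subset": "external", "compound_id": cid, "role": "external"})
        for j, (train, test) in enumerate(f.internal_splits):
            for cid in train:
                rows.append({"fold": f.fold_index, "subset": f"internal_{j}", "compound_id": cid, "role": "train"})
            for cid in test:
                rows.append({"fold": f.fold_index, "subset": f"internal_{j}", "compound_id": cid, "role": "test"})
    with open(path, "w") as fh:
        fh.write(f"# seed={summary.config.seed}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_split_table(path) -> tuple[pd.DataFrame, int]:
    with open(path) as fh:
        header = fh.readline().strip()
        seed = int(header.split("=", 1)[1]) if header.startswith("# seed=") else -1
        df = pd.read_csv(fh, sep="\t", dtype={"compound_id": str})
    return df, seed


def descriptor_frequency(
    models: Sequence[KnnModel],
    descriptor_names: Sequence[str] | None = None,
) -> tuple[pd.Series, float, list[str], pd.DataFrame]:
    """Occurrence frequency of each descriptor across retained kNN models.

    Returns ``(frequencies, mean_frequency, above_mean, bio_pivot)`` where
    ``frequencies`` is the fraction of models whose subset contains each
    descriptor, ``above_mean`` lists descriptors with above-average frequency
    and ``bio_pivot`` lays the biological frequencies out as a cell line x
    concentration grid (empty when no biological descriptor occurs).
    """
    if not models:
        raise ValueError("need at least one model")
    if descriptor_names is None:
        descriptor_names = sorted({d for m in models for d in m.descriptor_subset})
    counts = pd.Series(0, index=list(descriptor_names), dtype=float)
    for m in models:
        for d in m.descriptor_subset:
            if d in counts.index:
                counts[d] += 1
    freq = counts / len(models)
    mean_freq = float(freq.mean())
    above = list(freq[freq > mean_freq].index)

    bio_entries = []
    for name, f in freq.items():
        if "@" in name:
            line, conc = split_bio_descriptor_name(name)
            bio_entries.append({"cell_line": line, "concentration": conc, "frequency": f})
    if bio_entries:
        pivot = pd.DataFrame(bio_entries).pivot_table(
            index="cell_line", columns="concentration", values="frequency"
        )
    else:
        pivot = pd.DataFrame()
    return freq, mean_freq, above, pivot
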