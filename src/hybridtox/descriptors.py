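"""Biological descriptors, curve fingerprints, chemical-descriptor curation.

Every (cell line, concentration) pair of the filtered qHTS panel becomes one
biological descriptor: with the 13-line panel and 14-point concentration grid
this yields 14 x 13 = 182 biological columns per THR/MXDV setting.  Chemical
descriptor matrices (computed externally, e.g. by a 2D/3D descriptor engine)
are curated by a low-variance filter, a pairwise r^2 > 0.95 redundancy filter
and range scaling into [0, 1], so that Euclidean distance treats all columns
alike; biological responses are divided by 100 for the same reason before the
two blocks are concatenated into a hybrid matrix.

Curve fingerprints (two bits per concentration, quartile bins of the full
0-100 response scale) summarize curve shape for reporting; they are not model
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .noise_filter import FilterParams, filter_profiles
from .qhts_io import ASSAY_PANEL, ConcentrationResponseProfile, DescriptorMatrix, default_concentration_grid

__all__ = [
    "CurveFingerprint",
    "build_bio_descriptors",
    "combine_hybrid",
    "encode_fingerprint",
    "filter_chemical_descriptors",
    "pairwise_distance_comparison",
    "scale_biological",
    "scale_external",
]


@dataclass(frozen=True)
class CurveFingerprint:
    """2-bits-per-concentration encoding of a filtered curve.

    ``bits`` runs from the lowest to the highest concentration; ``int_value``
    reads the string most-significant-bit first, so the highest-concentration
    pair contributes the least-significant bits.
    """

    bits: str
    int_value: int


def encode_fingerprint(
    responses: Sequence[float],
    scale_max: float = 100.0,
    expected_length: int = 14,
) -> CurveFingerprint:
    """Encode a filtered response curve as quartile bins of the response scale.

    Bins (fractions of ``scale_max``): [0, 25%) -> ``00``, [25%, 50%) -> ``01``,
    [50%, 75%) -> ``10``, >= 75% -> ``11``.  The thresholds are fractions of
    the full response scale, not of the per-curve maximum, so weak and strong
    toxicants encode differently.
    """
    r = np.asarray(responses, dtype=float)
    if expected_length is not None and r.size != expected_length:
        raise ValueError(f"expected {expected_length} responses, got {r.size}")
    if scale_max <= 0:
        raise ValueError("scale_max must be positive")
    frac = r / scale_max
    pieces = []
    for f in frac:
        if f < 0.25:
            pieces.append("00")
        elif f < 0.50:
            pieces.append("01")
        elif f < 0.75:
            pieces.append("10")
        else:
            pieces.append("11")
    bits = "".join(pieces)
    return CurveFingerprint(bits=bits, int_value=int(bits, 2))


def bio_descriptor_name(cell_line: str, concentration: float) -> str:
    return f"{cell_line}@{concentration:g}"


def split_bio_descriptor_name(name: str) -> tuple[str, float]:
    line, _, conc = name.rpartition("@")
    return line, float(conc)


def build_bio_descriptors(
    profiles: Sequence[ConcentrationResponseProfile],
    params: FilterParams | None = None,
    panel: Sequence[str] = ASSAY_PANEL,
    grid: Sequence[float] | None = None,
) -> DescriptorMatrix:
    """Lay filtered responses out as a compound x (cell line, concentration) matrix.

    One column per panel cell line and grid concentration, named
    ``<cell_line>@<concentration>``; the value is the (filtered) response in
    percent.  When ``params`` is given the noise filter is applied here.
    Compounds missing a cell line get zeros in its columns and are flagged.
    """
    if grid is None:
        grid = default_concentration_grid()
    grid = np.asarray(grid, dtype=float)
    panel = list(panel)
    panel_set = set(panel)
    unknown = sorted({p.cell_line for p in profiles} - panel_set)
    if unknown:
        raise ValueError(f"profiles with cell lines outside the panel: {unknown}")
    if params is not None:
        profiles = filter_profiles(profiles, params)

    columns = [bio_descriptor_name(line, c) for line in panel for c in grid]
    compound_order: list[str] = []
    per_compound: dict[str, dict[str, np.ndarray]] = {}
    for p in profiles:
        if len(p) != len(grid):
            raise ValueError(
                f"{p.compound_id}/{p.cell_line}: {len(p)} points, grid has {len(grid)}"
            )
        if p.compound_id not in per_compound:
            per_compound[p.compound_id] = {}
            compound_order.append(p.compound_id)
        per_compound[p.compound_id][p.cell_line] = np.asarray(p.responses)

    rows = np.zeros((len(compound_order), len(columns)))
    flags: dict[str, list[str]] = {}
    for i, cid in enumerate(compound_order):
        curves = per_compound[cid]
        missing = [line for line in panel if line not in curves]
        if missing:
            flags[cid] = missing
        for j, line in enumerate(panel):
            if line in curves:
                rows[i, j * len(grid) : (j + 1) * len(grid)] = curves[line]
    data = pd.DataFrame(rows, index=pd.Index(compound_order, name="compound_id"), columns=columns)
    return DescriptorMatrix(data, origin="biological", scaled=False, flags=flags)


def scale_biological(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Divide percent responses by 100 so biological columns live in [0, 1]."""
    if matrix.scaled:
        return matrix
    if any(tag != "biological" for tag in matrix.origin.values()):
        raise ValueError("scale_biological expects a biological-origin matrix")
    return DescriptorMatrix(matrix.data / 100.0, origin=matrix.origin, scaled=True, flags=matrix.flags)


# ---------------------------------------------------------------------------
# Chemical-descriptor curation
# ---------------------------------------------------------------------------

def _low_variance_columns(df: pd.DataFrame) -> list[str]:
    """Columns that are constant, or constant except for a single compound."""
    bad = []
    n = len(df)
    for col in df.columns:
        counts = df[col].value_counts()
        if counts.iloc[0] >= n - 1:
            bad.append(col)
    return bad


def filter_chemical_descriptors(
    matrix: DescriptorMatrix,
    r2_cutoff: float = 0.95,
    seed: int = 0,
) -> DescriptorMatrix:
    """Low-variance and redundancy filtering plus range scaling of chemical columns.

    1. Drop columns that are constant or constant for all but one compound.
    2. Among the survivors, list every unordered pair with squared Pearson
       correlation above ``r2_cutoff`` (an undefined correlation counts as a
       violation), sort pairs by descending r^2 (ties by name), and walk the
       list removing one member of each still-intact pair, chosen by the
       seeded generator.
    3. Range scale survivors to [0, 1] per column, retaining per-column
       (min, max) so external compounds can be transformed with the training
       ranges only.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 compounds to curate descriptors")
    df = matrix.data.copy()
    df = df.drop(columns=_low_variance_columns(df))

    cols = list(df.columns)
    x = df.to_numpy()
    # r^2 for every pair; columns here are non-constant so std > 0, but guard
    # against float underflow producing NaNs and treat those as violations.
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    offending: list[tuple[float, str, str]] = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r2 = corr[a, b] ** 2
            if np.isnan(r2) or r2 > r2_cutoff:
                offending.append((2.0 if np.isnan(r2) else r2, cols[a], cols[b]))
    offending.sort(key=lambda t: (-t[0], t[1], t[2]))

    rng = np.random.default_rng(seed)
    alive = set(cols)
    for _, a, b in offending:
        if a in alive and b in alive:
            alive.remove(b if rng.integers(2) else a)
    survivors = [c for c in cols if c in alive]
    df = df[survivors]

    col_min = df.min()
    col_max = df.max()
    scaled = (df - col_min) / (col_max - col_min)
    return DescriptorMatrix(
        scaled,
        origin={c: matrix.origin[c] for c in survivors},
        scaled=True,
        scaling_params=(col_min, col_max),
        flags=matrix.flags,
    )


def scale_external(fitted: DescriptorMatrix, external: DescriptorMatrix) -> DescriptorMatrix:
    """Transform external compounds with the training min/max, clipping to [0, 1]."""
    if fitted.scaling_params is None:
        raise ValueError("matrix carries no scaling parameters (not fit by filter_chemical_descriptors)")
    col_min, col_max = fitted.scaling_params
    cols = fitted.descriptor_names
    missing = [c for c in cols if c not in external.data.columns]
    if missing:
        raise ValueError(f"external matrix lacks descriptors: {missing[:5]}")
    scaled = (external.data[cols] - col_min) / (col_max - col_min)
    scaled = scaled.clip(0.0, 1.0)
    return DescriptorMatrix(
        scaled,
        origin={c: fitted.origin[c] for c in cols},
        scaled=True,
        scaling_params=fitted.scaling_params,
    )


def combine_hybrid(chem: DescriptorMatrix, bio: DescriptorMatrix) -> DescriptorMatrix:
    """Concatenate scaled chemical and biological blocks column-wise."""
    if bio.shape[1] == 0:
        return chem
    if chem.compound_ids != bio.compound_ids:
        diff = set(chem.compound_ids) ^ set(bio.compound_ids)
        if diff:
            raise ValueError(f"compound sets differ: {sorted(diff)[:10]}")
        raise ValueError("compound order differs between chemical and biological matrices")
    if not (chem.scaled and bio.scaled):
        raise ValueError("both matrices must be scaled to [0, 1] before combining")
    overlap = set(chem.descriptor_names) & set(bio.descriptor_names)
    if overlap:
        raise ValueError(f"descriptor name collision: {sorted(overlap)[:5]}")
    data = pd.concat([chem.data, bio.data], axis=1)
    origin = {**chem.origin, **bio.origin}
    return DescriptorMatrix(data, origin=origin, scaled=True, flags={**chem.flags, **bio.flags})


# ---------------------------------------------------------------------------
# Chemical-vs-biological distance comparison
# ---------------------------------------------------------------------------

def pairwise_distance_comparison(
    chem: DescriptorMatrix,
    bio: DescriptorMatrix,
    labels: Mapping[str, str],
) -> tuple[pd.DataFrame, float]:
    """Euclidean distances of every compound pair in both descriptor spaces.

    Returns a DataFrame with one row per unordered pair (columns
    ``compound_a``, ``compound_b``, ``chem_distance``, ``bio_distance``,
    ``pair_class`` in {both toxic, both nontoxic, mixed}) and the Pearson
    correlation between the two distance vectors.  A near-zero correlation
    means the two descriptor spaces perceive compound similarity differently,
    i.e. each can contribute non-redundant information to a hybrid model.
    """
    if chem.compound_ids != bio.compound_ids:
        raise ValueError("matrices must cover the same compounds in the same order")
    ids = chem.compound_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 compounds for pairwise distances")
    d_chem = pdist(chem.values)
    d_bio = pdist(bio.values)
    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]

    def pair_class(a: str, b: str) -> str:
        la, lb = labels.get(a), labels.get(b)
        if la == lb == "toxic":
            return "both toxic"
        if la == lb == "nontoxic":
            return "both nontoxic"
        return "mixed"

    df = pd.DataFrame(
        {
            "compound_a": [ids[i] for i, _ in pairs],
            "compound_b": [ids[j] for _, j in pairs],
            "chem_distance": d_chem,
            "bio_distance": d_bio,
            "pair_class": [pair_class(ids[i], ids[j]) for i, j in pairs],
        }
    )
    if np.std(d_chem) == 0 or np.std(d_bio) == 0:
        corr = float("nan")
    else:
        corr = float(pearsonr(d_chem, d_bio)[0])
    return df, corr
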