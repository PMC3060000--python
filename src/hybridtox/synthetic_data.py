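"""Synthetic qHTS + chemical-descriptor + LD50 datasets with controllable signal.

The generator emulates the three inputs of the pipeline so that every stage
is testable without downloads:

* **Viability curves.**  Each compound carries a latent *in vitro* potency
  ``v ~ U(0, 1)`` shared across the cell-line panel.  Per cell line the
  half-maximal concentration is placed log-uniformly by ``v`` (plus per-line
  jitter) over a span that extends ``inactive_log_extension`` decades beyond
  the highest tested concentration, so that a realistic fraction of compounds
  shows little or no response within the assay range — in real viability
  screens most library compounds are inactive, and in vitro responses alone
  are weak classifiers of in vivo toxicity.  Responses follow a Hill curve
  ``R(c) = Emax * c^h / (AC50^h + c^h)`` with Gaussian baseline noise and
  isolated spike artifacts — the kind of single-point excursions the
  monotonicity filter is designed to repair.
* **Chemical descriptors.**  A latent chemical toxicity axis ``u ~ N(0, 1)``
  loads on a designated informative subset of descriptors; the remaining
  descriptors are correlated noise from a small factor model.
* **LD50 labels.**  Potency on the -log10 mol/kg scale is a linear blend,
  ``intercept + w_chem * u + w_bio * v_std + noise``, so the class thresholds
  (2 and 3) apply verbatim and both descriptor spaces carry real, partially
  non-overlapping signal.  With the default weights the toxic / marginal /
  nontoxic proportions approximate the ~13% / 47% / 40% mix of the real
  qHTS LD50 collection.

Ground truth (latents, AC50s, informative descriptor ids) is returned for
recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .qhts_io import (
    ASSAY_PANEL,
    ConcentrationResponseProfile,
    DescriptorMatrix,
    ToxicityRecord,
    default_concentration_grid,
)

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset", "generate_worked_examples"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults define the reference conditions."""

    n_compounds: int = 400
    n_chem_descriptors: int = 100
    n_informative_chem: int = 10
    panel: tuple[str, ...] = ASSAY_PANEL
    grid: tuple[float, ...] = tuple(default_concentration_grid())
    hill_slope_range: tuple[float, float] = (1.0, 3.0)
    emax_range: tuple[float, float] = (60.0, 100.0)
    ac50_line_jitter: float = 0.5     # sd of per-cell-line log10 AC50 noise
    inactive_log_extension: float = 2.5  # decades beyond the top concentration the AC50s reach
    baseline_noise_sd: float = 10.0   # percent
    spike_probability: float = 0.15   # per data point
    spike_magnitude: float = 60.0     # percent
    chem_signal_weight: float = 0.50  # contribution of the chemical latent to -log10 LD50
    bio_signal_weight: float = 0.30   # contribution of the in vitro latent
    label_noise_sd: float = 0.30
    potency_intercept: float = 2.18   # centers the class mix near the real collection's
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(b > a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("concentration grid must be strictly increasing")
        if not (0.0 <= self.spike_probability <= 1.0):
            raise ValueError("spike_probability must be in [0, 1]")
        if self.chem_signal_weight < 0 or self.bio_signal_weight < 0:
            raise ValueError("signal weights must be >= 0")


@dataclass
class SyntheticDataset:
    profiles: list[ConcentrationResponseProfile]
    chem: DescriptorMatrix         # raw (unscaled) chemical descriptors
    tox_records: list[ToxicityRecord]
    truth: dict = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, int]:
        """0/1 labels for the toxic u nontoxic (non-marginal) compounds."""
        out = {}
        for r in self.tox_records:
            if r.tox_class == "toxic":
                out[r.compound_id] = 1
            elif r.tox_class == "nontoxic":
                out[r.compound_id] = 0
        return out


def _hill(c: np.ndarray, emax: float, ac50: float, h: float) -> np.ndarray:
    return emax * c**h / (ac50**h + c**h)


def generate_dataset(config: SimulationConfig = SimulationConfig()) -> SyntheticDataset:
    """Draw one synthetic study from the configuration's generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    grid = np.asarray(config.grid)
    log_lo, log_hi = np.log10(grid[0]), np.log10(grid[-1])
    ids = [f"CMP{i:05d}" for i in range(n)]

    # Latents: chemical axis u and in vitro potency v.
    u = rng.standard_normal(n)
    v = rng.uniform(0.0, 1.0, size=n)
    v_std = (v - 0.5) / np.sqrt(1.0 / 12.0)

    # Viability curves.
    quant_floor = 0.25 * 100.0
    if config.bio_signal_weight > 0 and config.emax_range[1] < quant_floor:
        warnings.warn(
            "emax ceiling below the fingerprint quantization floor with nonzero "
            "biological signal weight; biological descriptors may carry no signal"
        )
    profiles: list[ConcentrationResponseProfile] = []
    ac50s = np.empty((n, len(config.panel)))
    log_top = log_hi + config.inactive_log_extension
    for j, line in enumerate(config.panel):
        log_ac50 = log_top - v * (log_top - log_lo) + rng.normal(0.0, config.ac50_line_jitter, n)
        log_ac50 = np.clip(log_ac50, log_lo - 1.0, log_top + 1.0)
        ac50s[:, j] = 10.0**log_ac50
        h = rng.uniform(*config.hill_slope_range, size=n)
        emax = rng.uniform(*config.emax_range, size=n)
        for i in range(n):
            r = _hill(grid, emax[i], ac50s[i, j], h[i])
            r = r + rng.normal(0.0, config.baseline_noise_sd, size=grid.size)
            spikes = rng.random(grid.size) < config.spike_probability
            signs = rng.choice([-1.0, 1.0], size=grid.size)
            r = r + spikes * signs * config.spike_magnitude
            profiles.append(
                ConcentrationResponseProfile(ids[i], line, tuple(grid), tuple(r))
            )

    # Chemical descriptors: informative columns load on u, the rest on shared
    # nuisance factors so the matrix is realistically correlated.
    informative = [f"D{j:03d}" for j in range(config.n_informative_chem)]
    noise_names = [f"D{j:03d}" for j in range(config.n_informative_chem, config.n_chem_descriptors)]
    cols = {}
    for name in informative:
        loading = rng.uniform(0.6, 0.9)
        cols[name] = loading * u + np.sqrt(1 - loading**2) * rng.standard_normal(n)
    n_factors = 5
    factors = rng.standard_normal((n, n_factors))
    for name in noise_names:
        lam = rng.normal(0.0, 0.4, size=n_factors)
        cols[name] = factors @ lam + rng.standard_normal(n)
    chem = DescriptorMatrix(
        pd.DataFrame(cols, index=pd.Index(ids, name="compound_id")), origin="chemical"
    )

    # Labels on the -log10 mol/kg scale; thresholds 2 and 3 apply verbatim.
    potency = (
        config.potency_intercept
        + config.chem_signal_weight * u
        + config.bio_signal_weight * v_std
        + rng.normal(0.0, config.label_noise_sd, size=n)
    )
    tox_records = [ToxicityRecord.from_potency(cid, p) for cid, p in zip(ids, potency)]

    truth = {
        "latent_chem": pd.Series(u, index=ids),
        "latent_bio": pd.Series(v, index=ids),
        "ac50": pd.DataFrame(ac50s, index=ids, columns=list(config.panel)),
        "informative_descriptors": informative,
        "potency": pd.Series(potency, index=ids),
    }
    return SyntheticDataset(profiles=profiles, chem=chem, tox_records=tox_records, truth=truth)


def generate_worked_examples(
    grid: Sequence[float] | None = None, cell_line: str = "Jurkat"
) -> dict[str, ConcentrationResponseProfile]:
    """Deterministic fixture curves exercising each noise-filter behavior.

    * ``fingerprint_127`` — ten baseline points, one response in the 25-50%
      bin, three in the > 75% bin: encodes to the integer 127.
    * ``single_spike`` — one mid-curve dip; the filter repairs exactly one
      point by neighbor interpolation.
    * ``terminal_drop`` — the curve collapses at the top concentrations; the
      filter extends the last valid response.
    * ``baseline_noise`` — sub-threshold jitter only; filters to all zeros at
      THR = 15.
    """
    if grid is None:
        grid = default_concentration_grid()
    grid = tuple(float(c) for c in grid)

    def make(cid: str, responses: Sequence[float]) -> ConcentrationResponseProfile:
        return ConcentrationResponseProfile(cid, cell_line, grid, tuple(responses))

    return {
        "fingerprint_127": make("FIX-FP127", [5.0] * 10 + [30.0] + [90.0] * 3),
        "single_spike": make(
            "FIX-SPIKE", [0.0] * 6 + [50.0, 10.0, 90.0] + [95.0] * 5
        ),
        "terminal_drop": make("FIX-DROP", [0.0] * 10 + [80.0, 80.0, 0.0, 0.0]),
        "baseline_noise": make(
            "FIX-NOISE",
            [3.0, -6.0, 9.0, -11.0, 5.0, -2.0, 12.0, -9.0, 7.0, -4.0, 10.0, -12.0, 6.0, -8.0],
        ),
    }
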