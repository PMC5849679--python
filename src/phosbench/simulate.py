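"""Synthetic multiplexed-quantification data with known ground truth.

Two benchmark designs are emulated:

* a mixed-species spike-in: yeast phosphopeptides mixed at fixed 1:4:10
  ratios into a constant 1:1:1 human background, all quantified within one
  multiplexed run (three mixing replicates per ratio level);
* a stoichiometry series: phosphosites whose true occupancy steps from
  10% to 90% across the channels of a single plex, with the matching
  non-phospho counterpart intensities constructed so that mass
  conservation a*P + b*N = amount holds exactly before noise.

Method-specific quantification characteristics are captured by a
:class:`MethodProfile`: co-isolation contamination (the mechanism behind
isobaric ratio compression — a Beta-distributed per-feature fraction of
reporter signal replaced by the sample-average channel profile),
multiplicative log-normal noise, an additive intensity floor (modelling
the low reporter signal-to-noise of MS3 acquisition), stochastic
detection, and intensity-dependent (logistic) dropout for label-free and
SILAC workflows.  Profile defaults are calibrated only to reproduce the
qualitative orderings seen in real method comparisons (MS2 compressed but
precise, MS3 decompressed but noisier); they are not measurements.

All draws flow from one seeded generator per call; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import IntensityTable

__all__ = [
    "MixDesign",
    "StoichDesign",
    "MethodProfile",
    "apply_coisolation",
    "simulate_mixed_species",
    "simulate_stoichiometry_plex",
    "builtin_designs",
    "get_preset",
]


# ---------------------------------------------------------------------------
# Designs and profiles
# ---------------------------------------------------------------------------

@dataclass
class MixDesign:
    """Mixed-species spike-in layout (channels = condition x replicate)."""

    #: condition label -> species -> relative level (> 0)
    levels: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "1x": {"yeast": 1.0, "human": 1.0},
            "4x": {"yeast": 4.0, "human": 1.0},
            "10x": {"yeast": 10.0, "human": 1.0},
        }
    )
    n_replicates: int = 3
    #: species -> number of simulated features
    n_features: Mapping[str, int] = field(
        default_factory=lambda: {"yeast": 500, "human": 1500}
    )
    base_meanlog: float = math.log(1e6)
    base_sdlog: float = 1.2
    #: CV of the per-channel loading (pipetting) error
    loading_cv: float = 0.02
    reference_condition: str = "1x"

    def __post_init__(self) -> None:
        for cond, per_species in self.levels.items():
            for sp, lv in per_species.items():
                if lv <= 0:
                    raise ValueError(f"level for {sp!r} in {cond!r} must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.reference_condition not in self.levels:
            raise ValueError("reference_condition must be a condition label")

    @property
    def conditions(self) -> tuple:
        return tuple(self.levels)

    @property
    def channels(self) -> tuple:
        return tuple(
            f"{cond}.r{rep}"
            for cond in self.levels
            for rep in range(1, self.n_replicates + 1)
        )


@dataclass
class StoichDesign:
    """Occupancy-series layout for the stoichiometry benchmark."""

    #: true per-channel occupancy, in [0, 1]
    occupancies: tuple = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))
    n_sites: int = 300
    n_tech_replicates: int = 3
    a_range: tuple = (0.5, 5.0)
    b_range: tuple = (0.5, 5.0)
    #: occupancy of the constant contaminating background pool
    background_occupancy: float = 0.5
    protein_mode: str = "constant-one"  # or "varying"
    base_meanlog: float = math.log(1e6)
    base_sdlog: float = 1.0
    #: equal channel loading by default: the occupancy series is mixed from
    #: one pool, and the protein-constant-one analysis assumes it
    loading_cv: float = 0.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancies, dtype=float)
        if occ.min() < 0 or occ.max() > 1:
            raise ValueError("occupancies must lie in [0, 1]")
        if not 0 <= self.background_occupancy <= 1:
            raise ValueError("background_occupancy must lie in [0, 1]")
        for name, rng_ in (("a_range", self.a_range), ("b_range", self.b_range)):
            if rng_[0] <= 0 or rng_[1] < rng_[0]:
                raise ValueError(f"{name} must be positive and ordered")
        if self.protein_mode not in ("constant-one", "varying"):
            raise ValueError("protein_mode must be 'constant-one' or 'varying'")

    @property
    def channels(self) -> tuple:
        return tuple(f"ch{i + 1}" for i in range(len(self.occupancies)))


@dataclass
class MethodProfile:
    """Noise / contamination / missingness parameters of one method."""

    name: str
    #: Beta(alpha, beta) for the per-feature co-isolation fraction; None = 0
    contamination_alpha: float | None = None
    contamination_beta: float | None = None
    noise_cv: float = 0.10
    additive_floor: float = 0.0
    detection_fraction: float = 1.0
    #: logistic P(missing) = sigmoid(intercept + slope * log10 intensity)
    dropout_intercept: float | None = None
    dropout_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.contamination_alpha is not None:
            if self.contamination_alpha <= 0 or self.contamination_beta <= 0:
                raise ValueError("Beta parameters must be positive")
            if self.contamination_mean >= 1.0:
                raise ValueError("mean contamination fraction must be < 1")
        if self.noise_cv < 0 or self.additive_floor < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 < self.detection_fraction <= 1.0:
            raise ValueError("detection_fraction must be in (0, 1]")

    @property
    def contamination_mean(self) -> float:
        if self.contamination_alpha is None:
            return 0.0
        return self.contamination_alpha / (self.contamination_alpha + self.contamination_beta)

    def sample_contamination(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.contamination_alpha is None:
            return np.zeros(n)
        return rng.beta(self.contamination_alpha, self.contamination_beta, size=n)


# ---------------------------------------------------------------------------
# Core mechanisms
# ---------------------------------------------------------------------------

def apply_coisolation(
    true_matrix: np.ndarray,
    background_profile: np.ndarray,
    f: np.ndarray | float,
) -> np.ndarray:
    """Convex co-isolation interference model for reporter intensities.

    Per feature, a fraction ``f`` of the total reporter signal is replaced
    by signal distributed across channels according to the contaminating
    pool's profile::

        observed_j = (1 - f) * true_j + f * background_profile_j * sum(true)

    Row totals are preserved exactly and the map is linear in ``f``.
    ``f = 1`` (pure background) is permitted for limiting-case analyses.
    """
    X = np.asarray(true_matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("intensities must be non-negative")
    g = np.asarray(background_profile, dtype=float)
    if g.shape != (X.shape[1],):
        raise ValueError("background_profile length must match channel count")
    if abs(g.sum() - 1.0) > 1e-9:
        raise ValueError("background_profile must sum to 1")
    f = np.asarray(f, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("contamination fractions must lie in [0, 1]")
    f = np.broadcast_to(f, (X.shape[0],))[:, None]
    totals = X.sum(axis=1, keepdims=True)
    return (1.0 - f) * X + f * totals * g[None, :]


def _mult_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def _apply_measurement_noise(
    rng: np.random.Generator, X: np.ndarray, profile: MethodProfile
) -> np.ndarray:
    out = X * _mult_noise(rng, X.shape, profile.noise_cv)
    if profile.additive_floor > 0:
        out = out + rng.normal(0.0, profile.additive_floor, size=X.shape)
    return np.clip(out, 0.0, None)


def _apply_missingness(
    rng: np.random.Generator, X: np.ndarray, profile: MethodProfile
) -> np.ndarray:
    out = X.copy()
    if profile.detection_fraction < 1.0:
        undetected = rng.random(X.shape[0]) > profile.detection_fraction
        out[undetected] = np.nan
    if profile.dropout_intercept is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            logit = profile.dropout_intercept + profile.dropout_slope * np.log10(
                np.where(out > 0, out, 1e-12)
            )
        p_miss = 1.0 / (1.0 + np.exp(-logit))
        out[rng.random(X.shape) < p_miss] = np.nan
    return out


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_mixed_species(
    design: MixDesign, profile: MethodProfile, seed: int
) -> tuple[IntensityTable, pd.DataFrame]:
    """Simulate the mixed-species spike-in under one method profile.

    Returns the intensity table (features x channels) and a per-feature
    truth frame with the species label and the true log2 ratio of each
    condition against the reference condition.
    """
    rng = np.random.default_rng(seed)
    channels = design.channels
    conditions = [ch.rsplit(".r", 1)[0] for ch in channels]
    replicates = [int(ch.rsplit(".r", 1)[1]) for ch in channels]

    loading = _mult_noise(rng, len(channels), design.loading_cv)

    rows, feature_ids, species_col = [], [], []
    for sp in design.n_features:
        n = design.n_features[sp]
        base = rng.lognormal(design.base_meanlog, design.base_sdlog, size=n)
        level = np.array([design.levels[c][sp] for c in conditions])
        rows.append(base[:, None] * level[None, :] * loading[None, :])
        feature_ids += [f"{sp}_{i + 1}" for i in range(n)]
        species_col += [sp] * n
    true = np.vstack(rows)

    observed = true
    f = profile.sample_contamination(rng, true.shape[0])
    if profile.contamination_mean > 0:
        bg_profile = true.sum(axis=0) / true.sum()
        observed = apply_coisolation(observed, bg_profile, f)
    observed = _apply_measurement_noise(rng, observed, profile)
    observed = _apply_missingness(rng, observed, profile)

    values = pd.DataFrame(observed, index=feature_ids, columns=list(channels))
    fmeta = pd.DataFrame({"species": species_col}, index=feature_ids)
    smeta = pd.DataFrame(
        {
            "method": profile.name,
            "channel": list(channels),
            "condition": conditions,
            "replicate": replicates,
        },
        index=list(channels),
    )
    table = IntensityTable(values, fmeta, smeta)

    ref = design.reference_condition
    truth = pd.DataFrame({"species": species_col}, index=feature_ids)
    truth["contamination_f"] = f
    for cond in design.conditions:
        if cond == ref:
            continue
        truth[f"log2_{cond}_vs_{ref}"] = [
            math.log2(design.levels[cond][sp] / design.levels[ref][sp])
            for sp in species_col
        ]
    return table, truth


def simulate_stoichiometry_plex(
    design: StoichDesign, profile: MethodProfile, seed: int
) -> tuple[IntensityTable, IntensityTable, IntensityTable, dict]:
    """Simulate phospho / non-phospho / protein tables for one plex.

    Per site, response factors a and b are drawn log-uniformly, a base
    amount log-normally, and the pre-noise intensities are constructed so
    that a * P_j + b * N_j equals the channel amount exactly.  Co-isolation
    contamination (flat channel profile: the equal-amount constant-
    occupancy background pool dominates the co-isolated signal) is applied
    independently to the phospho and non-phospho rows, then measurement
    noise per the profile.  The protein table is constant one or the true
    channel amounts with noise, per ``design.protein_mode``.

    The returned truth dict carries per-site response factors and
    contamination fractions, the shared per-channel occupancy vector, and
    the pre-noise matrices (for conservation checks).
    """
    rng = np.random.default_rng(seed)
    nch = len(design.occupancies)
    occ = np.asarray(design.occupancies, dtype=float)
    columns = [
        f"{ch}.t{t}"
        for t in range(1, design.n_tech_replicates + 1)
        for ch in design.channels
    ]
    chan_labels = [c.split(".t")[0] for c in columns]
    tech = [int(c.split(".t")[1]) for c in columns]
    occ_cols = np.tile(occ, design.n_tech_replicates)
    ncol = len(columns)

    site_ids = [f"site_{i + 1}" for i in range(design.n_sites)]
    a = np.exp(rng.uniform(math.log(design.a_range[0]), math.log(design.a_range[1]),
                           size=design.n_sites))
    b = np.exp(rng.uniform(math.log(design.b_range[0]), math.log(design.b_range[1]),
                           size=design.n_sites))
    base = rng.lognormal(design.base_meanlog, design.base_sdlog, size=design.n_sites)
    loading = _mult_noise(rng, ncol, design.loading_cv)
    amount = base[:, None] * loading[None, :]

    P0 = occ_cols[None, :] * amount / a[:, None]
    N0 = (1.0 - occ_cols[None, :]) * amount / b[:, None]

    flat = np.full(ncol, 1.0 / ncol)
    f_p = profile.sample_contamination(rng, design.n_sites)
    f_n = profile.sample_contamination(rng, design.n_sites)
    P = apply_coisolation(P0, flat, f_p) if profile.contamination_mean > 0 else P0
    N = apply_coisolation(N0, flat, f_n) if profile.contamination_mean > 0 else N0
    P = _apply_measurement_noise(rng, P, profile)
    N = _apply_measurement_noise(rng, N, profile)

    smeta = pd.DataFrame(
        {
            "method": profile.name,
            "channel": chan_labels,
            "condition": chan_labels,
            "replicate": tech,
        },
        index=columns,
    )

    def table(matrix, prefix):
        ids = [f"{prefix}_{s}" for s in site_ids]
        return IntensityTable(
            pd.DataFrame(matrix, index=ids, columns=columns),
            pd.DataFrame(index=pd.Index(ids)),
            smeta.copy(),
        )

    phospho = table(P, "p")
    nonphospho = table(N, "np")
    if design.protein_mode == "constant-one":
        T = np.ones_like(amount)
    else:
        T = _apply_measurement_noise(rng, amount.copy(), profile)
    protein = table(T, "prot")

    truth = {
        "occupancy_by_channel": dict(zip(design.channels, occ)),
        "occupancy_by_column": pd.Series(occ_cols, index=columns),
        "a": pd.Series(a, index=site_ids),
        "b": pd.Series(b, index=site_ids),
        "contamination_f_phospho": pd.Series(f_p, index=site_ids),
        "contamination_f_nonphospho": pd.Series(f_n, index=site_ids),
        "background_occupancy": design.background_occupancy,
        "P0": pd.DataFrame(P0, index=site_ids, columns=columns),
        "N0": pd.DataFrame(N0, index=site_ids, columns=columns),
        "amount": pd.DataFrame(amount, index=site_ids, columns=columns),
        "site_ids": site_ids,
    }
    return phospho, nonphospho, protein, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def builtin_designs() -> dict:
    """Named, validated presets for the benchmark designs and methods."""
    return {
        "fig2-mix": MixDesign(),
        "fig6-stoich": StoichDesign(),
        "tmt-ms2": MethodProfile(
            name="tmt-ms2", contamination_alpha=15.0, contamination_beta=35.0,
            noise_cv=0.08, additive_floor=5e2,
        ),
        "tmt-ms3": MethodProfile(
            name="tmt-ms3", contamination_alpha=4.0, contamination_beta=46.0,
            noise_cv=0.15, additive_floor=5e3, detection_fraction=0.7,
        ),
        "lfq": MethodProfile(
            name="lfq", noise_cv=0.25, additive_floor=1e3,
            detection_fraction=0.9, dropout_intercept=8.0, dropout_slope=-2.0,
        ),
        "silac": MethodProfile(
            name="silac", noise_cv=0.18, additive_floor=1e3,
            detection_fraction=0.85, dropout_intercept=6.0, dropout_slope=-2.0,
        ),
    }


def get_preset(name: str):
    """Look up a named preset; unknown names list the available ones."""
    presets = builtin_designs()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[name]
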