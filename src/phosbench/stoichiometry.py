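"""Multiplexed phosphorylation-site stoichiometry by 3D multiple regression.

For one phosphosite measured across the channels of a multiplexed run we
observe three intensities per channel j: the phosphopeptide P_j, its
non-phosphorylated counterpart N_j, and the parent protein T_j.  Mass
conservation ties them together: with unknown positive response factors
a (phospho) and b (non-phospho),

    a * P_j + b * N_j = T_j            (protein scale absorbed)

for every channel.  Dividing by T_j (p_j = P_j / T_j, n_j = N_j / T_j)
turns the conservation plane into a straight line

    n = c0 + c1 * p,    with  a = -c1 / c0,  b = 1 / c0,

fitted here by ordinary least squares with intercept.  The per-channel
occupancy (fraction of protein copies phosphorylated) follows as

    s_j = a * P_j / (a * P_j + b * N_j) = (-c1 * p_j) / (n_j - c1 * p_j).

The two-sided t-test p-value of H0: c1 = 0 is the per-site quality score:
sites whose channels do not actually vary in occupancy (or are swamped by
co-isolation interference) produce flat, insignificant slopes.  Occupancy
estimates falling outside [0, 1] ("illegal" values) are flagged and
excluded from summaries but retained for audit.  A fit with c0 <= 0 or
c1 >= 0 contradicts positive response factors and is marked degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import IntensityTable
from .benchstats import error_decomposition

__all__ = [
    "StoichObservations",
    "StoichFit",
    "InsufficientDataError",
    "AmbiguousMatchError",
    "fit_3dmm",
    "batch_stoichiometry",
    "filter_by_slope_p",
    "occupancy_error_sweep",
    "fits_to_frame",
]


class InsufficientDataError(ValueError):
    """Fewer than the minimum usable observations for a regression fit."""


class AmbiguousMatchError(ValueError):
    """A phosphosite maps to more than one counterpart/protein record."""


@dataclass
class StoichObservations:
    """Per-channel (P, N, T) intensity triples for one phosphosite.

    ``T`` may be the constant 1 when protein levels are unregulated by
    design (the benchmark configuration).  Labels are optional channel
    names carried through to the fit.
    """

    P: np.ndarray
    N: np.ndarray
    T: np.ndarray
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        T = np.asarray(self.T, dtype=float)
        if T.ndim == 0:
            T = np.full_like(self.P, float(T))
        self.T = T
        if not (self.P.shape == self.N.shape == self.T.shape):
            raise ValueError("P, N, T must have equal length")
        usable = self.usable_mask()
        with np.errstate(invalid="ignore"):
            if (self.P[usable] < 0).any() or (self.N[usable] < 0).any():
                raise ValueError("intensities must be non-negative")
        if not self.labels:
            self.labels = tuple(f"obs{i + 1}" for i in range(self.P.size))

    def usable_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (
                np.isfinite(self.P)
                & np.isfinite(self.N)
                & np.isfinite(self.T)
                & (self.T > 0)
            )


@dataclass
class StoichFit:
    """Result of one 3D-regression stoichiometry fit."""

    c0: float
    c1: float
    a: float
    b: float
    slope_p: float
    occupancies: np.ndarray
    illegal: np.ndarray
    n_obs: int
    degenerate: bool
    residual_sd: float
    labels: tuple = ()
    site_id: str | None = None

    @property
    def illegal_count(self) -> int:
        return int(np.sum(self.illegal))

    def legal_occupancies(self) -> np.ndarray:
        """Occupancy estimates within [0, 1] (illegal values excluded)."""
        return self.occupancies[~self.illegal]

    def occupancy_by_label(self, reducer=np.median) -> dict:
        """Per-channel/condition summary of legal occupancies.

        Observations sharing a label (e.g. technical replicates of one
        channel) are reduced with ``reducer`` (median by default, for
        robustness); labels with only illegal estimates map to NaN.
        """
        out: dict = {}
        for lab in dict.fromkeys(self.labels):
            mask = np.array([l == lab for l in self.labels]) & ~self.illegal
            out[lab] = float(reducer(self.occupancies[mask])) if mask.any() else float("nan")
        return out


def _degenerate_fit(obs: StoichObservations, c0=math.nan, c1=math.nan,
                    residual_sd=math.nan) -> StoichFit:
    n = int(obs.usable_mask().sum())
    occ = np.full(obs.P.shape, np.nan)
    return StoichFit(
        c0=c0, c1=c1, a=math.nan, b=math.nan, slope_p=1.0,
        occupancies=occ, illegal=np.ones(obs.P.shape, dtype=bool),
        n_obs=n, degenerate=True, residual_sd=residual_sd, labels=obs.labels,
    )


def fit_3dmm(obs: StoichObservations) -> StoichFit:
    """Fit the conservation-plane regression for one phosphosite.

    Requires >= 4 usable observations (P, N, T present, T > 0).  Zero
    variance in the protein-normalized phospho intensities yields a
    degenerate result (no exception).  A perfect fit (zero residual
    variance) reports ``slope_p = 0`` — the infinite-t limit.
    """
    mask = obs.usable_mask()
    n = int(mask.sum())
    if n < 4:
        raise InsufficientDataError(
            f"need >= 4 usable observations, got {n}"
        )
    p = obs.P[mask] / obs.T[mask]
    q = obs.N[mask] / obs.T[mask]
    if np.ptp(p) == 0.0:
        return _degenerate_fit(obs)

    pbar, qbar = p.mean(), q.mean()
    sxx = float(np.sum((p - pbar) ** 2))
    sxy = float(np.sum((p - pbar) * (q - qbar)))
    c1 = sxy / sxx
    c0 = qbar - c1 * pbar
    resid = q - (c0 + c1 * p)
    ssr = float(np.sum(resid**2))
    residual_sd = math.sqrt(max(ssr, 0.0) / (n - 2)) if n > 2 else math.nan

    # two-sided t-test of H0: slope = 0
    if ssr <= 1e-24 * max(1.0, float(np.sum(q**2))):
        slope_p = 0.0
        residual_sd = 0.0
    else:
        se = math.sqrt(ssr / (n - 2) / sxx)
        tstat = c1 / se
        slope_p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))

    if c0 <= 0.0 or c1 >= 0.0:
        return _degenerate_fit(obs, c0=c0, c1=c1, residual_sd=residual_sd)

    a = -c1 / c0
    b = 1.0 / c0

    occ = np.full(obs.P.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_all = np.where(mask, obs.P / obs.T, np.nan)
        q_all = np.where(mask, obs.N / obs.T, np.nan)
        denom = q_all - c1 * p_all
        occ = np.where(denom != 0.0, (-c1 * p_all) / denom, np.nan)
    illegal = ~((occ >= 0.0) & (occ <= 1.0))  # NaN -> illegal

    return StoichFit(
        c0=c0, c1=c1, a=a, b=b, slope_p=slope_p,
        occupancies=occ, illegal=illegal, n_obs=n, degenerate=False,
        residual_sd=residual_sd, labels=obs.labels,
    )


def batch_stoichiometry(
    phospho: IntensityTable,
    nonphospho: IntensityTable,
    protein: IntensityTable | None,
    matching: Mapping[str, tuple] | pd.DataFrame,
) -> tuple[dict[str, StoichFit], dict[str, str]]:
    """Fit the stoichiometry model for every matched phosphosite.

    ``matching`` maps each phosphosite id to its non-phospho counterpart
    id (and, unless ``protein`` is None — the constant-one surrogate — a
    protein record id): either a mapping ``site -> (counterpart, protein)``
    / ``site -> counterpart`` or a DataFrame with columns ``site_id``,
    ``counterpart_id`` and optionally ``protein_id``.

    Technical replicates enter as additional observations of the same
    plane: all sample columns shared by the matched tables are pooled
    into one fit per site.

    Returns ``(fits, skipped)`` where ``skipped`` maps unmatched site ids
    to a reason (``no counterpart`` / ``no protein`` / ``insufficient
    observations`` / ``degenerate``... degenerate fits are kept in
    ``fits``; only hard failures are skipped).
    """
    if isinstance(matching, pd.DataFrame):
        if matching["site_id"].duplicated().any():
            dup = matching.loc[matching["site_id"].duplicated(), "site_id"].tolist()
            raise AmbiguousMatchError(f"sites matched to multiple counterparts: {dup}")
        records = {
            row.site_id: (row.counterpart_id, getattr(row, "protein_id", None))
            for row in matching.itertuples()
        }
    else:
        records = {}
        for site, val in matching.items():
            if isinstance(val, (tuple, list)):
                records[site] = (val[0], val[1] if len(val) > 1 else None)
            else:
                records[site] = (val, None)

    samples = phospho.sample_ids
    if not nonphospho.sample_ids.equals(samples):
        raise ValueError("phospho and non-phospho tables must share sample columns")
    labels = _observation_labels(phospho)

    fits: dict[str, StoichFit] = {}
    skipped: dict[str, str] = {}
    for site, (counterpart, prot_id) in records.items():
        if site not in phospho.feature_ids:
            skipped[site] = "no phospho record"
            continue
        if counterpart not in nonphospho.feature_ids:
            skipped[site] = "no counterpart"
            continue
        P = phospho.values.loc[site].to_numpy(dtype=float)
        N = nonphospho.values.loc[counterpart].to_numpy(dtype=float)
        if protein is None:
            T = np.ones_like(P)
        else:
            if prot_id is None or prot_id not in protein.feature_ids:
                skipped[site] = "no protein"
                continue
            T = protein.values.loc[prot_id].reindex(samples).to_numpy(dtype=float) \
                if not protein.sample_ids.equals(samples) \
                else protein.values.loc[prot_id].to_numpy(dtype=float)
        try:
            fit = fit_3dmm(StoichObservations(P, N, T, labels=labels))
        except InsufficientDataError:
            skipped[site] = "insufficient observations"
            continue
        fit.site_id = site
        fits[site] = fit
    return fits, skipped


def _observation_labels(table: IntensityTable) -> tuple:
    meta = table.sample_meta
    if "channel" in meta.columns and meta["channel"].notna().all():
        return tuple(str(c) for c in meta["channel"])
    return tuple(str(s) for s in table.sample_ids)


def filter_by_slope_p(
    fits: Iterable[StoichFit] | Mapping[str, StoichFit], alpha: float
):
    """Keep non-degenerate fits whose slope p-value is <= ``alpha``."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if isinstance(fits, Mapping):
        return {
            k: f for k, f in fits.items() if not f.degenerate and f.slope_p <= alpha
        }
    return [f for f in fits if not f.degenerate and f.slope_p <= alpha]


def occupancy_error_sweep(
    fits: Iterable[StoichFit] | Mapping[str, StoichFit],
    truth: Mapping[str, float] | Mapping[str, Sequence[float]] | Sequence[float],
    alphas: Sequence[float],
) -> pd.DataFrame:
    """Accuracy/precision of occupancy estimates across p-value cutoffs.

    For each cutoff in ``alphas``, fits surviving :func:`filter_by_slope_p`
    contribute their legal per-observation occupancy estimates, grouped by
    true occupancy level; each (cutoff, level) cell is summarized by the
    squared-bias + variance decomposition of the mean squared error.
    ``truth`` is either one occupancy per observation label (a sequence or
    label->value mapping, shared by all sites) or a per-site mapping to
    such vectors.  Cutoffs with no surviving estimates at a level yield a
    row with ``n_sites = 0`` and missing statistics.
    """
    if len(alphas) == 0:
        raise ValueError("alphas must be non-empty")
    fit_list = list(fits.values()) if isinstance(fits, Mapping) else list(fits)

    def truth_for(fit: StoichFit) -> np.ndarray:
        t = truth
        if isinstance(t, Mapping) and fit.site_id in t:
            t = t[fit.site_id]
        if isinstance(t, Mapping):
            return np.array([t[lab] for lab in fit.labels], dtype=float)
        return np.asarray(t, dtype=float)

    rows = []
    for alpha in alphas:
        surviving = filter_by_slope_p(fit_list, alpha)
        pooled: dict[float, list] = {}
        n_sites: dict[float, set] = {}
        for fit in surviving:
            tvec = truth_for(fit)
            for est, ill, tv in zip(fit.occupancies, fit.illegal, tvec):
                if ill:
                    continue
                pooled.setdefault(tv, []).append(est)
                n_sites.setdefault(tv, set()).add(id(fit))
        levels = sorted(pooled) if pooled else sorted(
            {lv for f in fit_list for lv in np.atleast_1d(truth_for(f))}
        )
        for level in levels:
            ests = pooled.get(level, [])
            if ests:
                dec = error_decomposition(np.asarray(ests), truth=level)
                rows.append(
                    dict(alpha=alpha, level=level, n_sites=len(n_sites[level]),
                         n_estimates=dec.n, bias=dec.bias,
                         positive_bias=dec.positive_bias,
                         variance=dec.variance, mse=dec.mse)
                )
            else:
                rows.append(
                    dict(alpha=alpha, level=level, n_sites=0, n_estimates=0,
                         bias=np.nan, positive_bias=np.nan, variance=np.nan,
                         mse=np.nan)
                )
    return pd.DataFrame(rows)


def fits_to_frame(fits: Mapping[str, StoichFit]) -> pd.DataFrame:
    """Tabulate fits: one row per site, one occupancy column per label."""
    rows = []
    for site, f in fits.items():
        row = dict(
            site_id=site, n_obs=f.n_obs, c0=f.c0, c1=f.c1, a=f.a, b=f.b,
            slope_p=f.slope_p, degenerate=f.degenerate,
            illegal_count=f.illegal_count, residual_sd=f.residual_sd,
        )
        row.update(
            {f"occ_{lab}": v for lab, v in f.occupancy_by_label().items()}
        )
        rows.append(row)
    return pd.DataFrame(rows)
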