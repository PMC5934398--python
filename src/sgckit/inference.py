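"""Bootstrap and permutation inference on directed spectra.

Implements the resampling machinery around the VAR spectral estimates:
paired bootstrap spectra, directional-asymmetry testing with an omnibus
(max-deviation) standard error, spectral peak identification with a
trial-shuffle null threshold, consistent-pair selection by the confidence
interval of the mean peak frequency, the time-reversal spuriousness control,
and the coherence-vs-sGC correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from sgckit._batch import batch_bivariate_spectra, weighted_models
from sgckit.ensemble import TrialEnsemble
from sgckit.spectral import (
    DEFAULT_ORDER,
    FitError,
    default_freq_grid,
    models_from_gram,
    pairwise_spectra,
    trial_gram_stack,
    SpectrumSet,
)

DEFAULT_B = 1000
DEFAULT_N_NULL = 1000

__all__ = [
    "BootstrapStats",
    "BootstrapSpectra",
    "PeakTable",
    "AsymmetryResult",
    "PairSelection",
    "bootstrap_spectra",
    "directional_asymmetry",
    "find_peaks",
    "peak_null_threshold",
    "tabulate_peaks",
    "select_consistent_pairs",
    "time_reversal_test",
    "coherence_gc_correlation",
]


@dataclass
class BootstrapStats:
    """Per-bootstrap statistics with their (possibly omnibus) standard error."""

    B: int
    stat_per_boot: np.ndarray           # (B,) or (B, F)
    mean: np.ndarray | float
    se: float | np.ndarray
    ci_low: np.ndarray | float
    ci_high: np.ndarray | float
    n: int

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("need B >= 2 bootstraps")
        if np.any(np.asarray(self.se) < 0):
            raise ValueError("standard error must be >= 0")
        if np.any(np.asarray(self.ci_low) > np.asarray(self.mean) + 1e-12) or np.any(
            np.asarray(self.ci_high) < np.asarray(self.mean) - 1e-12
        ):
            raise ValueError("CI must bracket the mean")


@dataclass
class BootstrapSpectra:
    """Spectra over B paired bootstrap resamples for a set of ordered pairs.

    ``sgc[(source, target)]`` is a (B, F) array; ``coherence`` is keyed by
    the sorted channel pair. All pairs share the same trial resamples
    (paired resampling), so difference statistics are paired by resample.
    """

    freqs: np.ndarray
    pairs: list[tuple[str, str]]
    sgc: dict[tuple[str, str], np.ndarray]
    coherence: dict[tuple[str, str], np.ndarray]
    full_fit: SpectrumSet
    B: int
    seed: int | None
    provenance: dict = field(default_factory=dict)

    def mean_sgc(self, pair: tuple[str, str]) -> np.ndarray:
        return self.sgc[pair].mean(axis=0)

    def mean_coherence(self, pair: tuple[str, str]) -> np.ndarray:
        return self.coherence[tuple(sorted(pair))].mean(axis=0)


def _bootstrap_counts(B: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Trial multiplicity matrix for B resamples of n trials with replacement."""
    idx = rng.integers(0, n, size=(B, n))
    flat = (idx + n * np.arange(B)[:, None]).ravel()
    return np.bincount(flat, minlength=B * n).reshape(B, n).astype(np.float64)


def bootstrap_spectra(
    ensemble: TrialEnsemble,
    pairs: Sequence[tuple[str, str]],
    order: int = DEFAULT_ORDER,
    B: int = DEFAULT_B,
    seed: int | None = None,
    freqs: np.ndarray | None = None,
    trial_index: np.ndarray | None = None,
) -> BootstrapSpectra:
    """Paired bootstrap AR spectra for ordered (source, target) pairs.

    Each resample draws ``n`` trials with replacement (``n`` = trial count,
    or the length of ``trial_index`` if a trial subset is given); one draw is
    shared by every pair. Alongside the per-resample spectra, the all-trials
    fit is returned; its spectra agree with the bootstrap mean up to
    stochastic tolerance.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=np.float64)
    rng = np.random.default_rng(seed)
    if trial_index is None:
        trial_index = np.arange(ensemble.n_trials)
    n = len(trial_index)
    T = ensemble.n_samples
    rows = T - order
    counts = _bootstrap_counts(B, n, rng)

    sgc: dict[tuple[str, str], np.ndarray] = {}
    coherence: dict[tuple[str, str], np.ndarray] = {}
    for source, target in pairs:
        data = ensemble.channel_data([target, source])[trial_index]
        gram = trial_gram_stack(data, order)
        try:
            coeffs, sigma = weighted_models(gram, counts, order, rows)
            out = batch_bivariate_spectra(coeffs, sigma, freqs, ensemble.sampling_rate)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise FitError(f"bootstrap fit failed for pair {(source, target)}: {exc}")
        sgc[(source, target)] = out["sgc_yx"]
        sgc[(target, source)] = out["sgc_xy"]
        coherence[tuple(sorted((source, target)))] = out["coherence"]

    sub = ensemble.select_trials(trial_index) if n != ensemble.n_trials else ensemble
    full = pairwise_spectra(sub, pairs, order, freqs)
    return BootstrapSpectra(
        freqs=freqs,
        pairs=[tuple(p) for p in pairs],
        sgc=sgc,
        coherence=coherence,
        full_fit=full,
        B=B,
        seed=seed,
        provenance={"order": order, "n_trials": n, "B": B, "seed": seed},
    )


# ---------------------------------------------------------------------------
# directional asymmetry with omnibus correction
# ---------------------------------------------------------------------------

@dataclass
class AsymmetryResult:
    freqs: np.ndarray
    significant: np.ndarray            # boolean mask over freqs
    stats: BootstrapStats
    alpha: float

    def significant_freqs(self) -> np.ndarray:
        return self.freqs[self.significant]


def directional_asymmetry(
    topdown_boots: np.ndarray,
    bottomup_boots: np.ndarray,
    n: int,
    alpha: float = 0.001,
    freqs: np.ndarray | None = None,
) -> AsymmetryResult:
    """Omnibus-corrected bootstrap test of top-down minus bottom-up spectra.

    Per-bootstrap difference spectra are reduced to a single standard error
    by replacing each resample's squared deviation with its maximal squared
    absolute deviation over frequency; the per-frequency CI is then
    ``mean +/- SE * t_{1 - alpha/2}(n - 1)`` and a frequency is significant
    when its CI excludes zero.
    """
    topdown = np.asarray(topdown_boots, dtype=np.float64)
    bottomup = np.asarray(bottomup_boots, dtype=np.float64)
    if topdown.shape != bottomup.shape:
        raise ValueError(
            f"mismatched bootstrap shapes {topdown.shape} vs {bottomup.shape}"
        )
    B, F = topdown.shape
    if freqs is None:
        freqs = np.arange(F, dtype=np.float64)
    diff = topdown - bottomup
    mean = diff.mean(axis=0)
    dev = diff - mean
    omnibus_se = float(np.sqrt((np.abs(dev).max(axis=1) ** 2).sum() / (B - 1)))
    tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, n - 1))
    ci_low = mean - omnibus_se * tcrit
    ci_high = mean + omnibus_se * tcrit
    significant = (ci_low > 0.0) | (ci_high < 0.0)
    stats = BootstrapStats(
        B=B, stat_per_boot=diff, mean=mean, se=omnibus_se,
        ci_low=ci_low, ci_high=ci_high, n=n,
    )
    return AsymmetryResult(
        freqs=np.asarray(freqs, dtype=np.float64),
        significant=significant,
        stats=stats,
        alpha=alpha,
    )


def pointwise_se(stat_per_boot: np.ndarray) -> np.ndarray:
    """Plain bootstrap SE per frequency (no omnibus correction)."""
    stat = np.asarray(stat_per_boot, dtype=np.float64)
    B = stat.shape[0]
    return np.sqrt(((stat - stat.mean(axis=0)) ** 2).sum(axis=0) / (B - 1))


# ---------------------------------------------------------------------------
# peak identification
# ---------------------------------------------------------------------------

def find_peaks(
    freqs: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] = (5.0, 90.0),
    smooth: int = 1,
) -> list[tuple[float, float]]:
    """Local maxima by sign change of the (optionally smoothed) first
    difference, refined by quadratic interpolation through the three samples
    around each maximum. Band-edge samples are never returned as peaks.

    Returns ``[(freq_hz, height), ...]`` in increasing frequency order.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    f = freqs[sel]
    v = values[sel]
    if len(f) < 3:
        return []
    d = np.diff(v)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        d = np.convolve(d, kernel, mode="same")
    peaks: list[tuple[float, float]] = []
    for i in range(1, len(f) - 1):
        if d[i - 1] > 0.0 and d[i] <= 0.0:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            if denom >= 0.0:  # not locally concave after smoothing; skip
                continue
            delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            step_l = f[i] - f[i - 1]
            step_r = f[i + 1] - f[i]
            step = step_l if delta < 0 else step_r
            freq = f[i] + delta * step
            height = v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta
            peaks.append((float(freq), float(height)))
    return peaks


def nearest_peak(
    peaks: Sequence[tuple[float, float]], target: float
) -> tuple[float, float] | None:
    """Peak closest to ``target`` Hz; ties break toward the lower frequency."""
    if not peaks:
        return None
    best = min(peaks, key=lambda p: (abs(p[0] - target), p[0]))
    return best


def peak_null_threshold(
    ensemble: TrialEnsemble,
    pairs: Sequence[tuple[str, str]],
    order: int = DEFAULT_ORDER,
    n_null: int = DEFAULT_N_NULL,
    seed: int | None = None,
    q: float = 0.95,
    freqs: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Trial-shuffle null threshold for directed spectral peak magnitudes.

    Per null resample the trial correspondence between the two channels of
    every pair is permuted (destroying cross-channel dependence, preserving
    marginals), models are refit, and the maximum source->target sGC over
    all frequencies and pairs is recorded. The threshold is the ``q``
    quantile of the ``n_null`` maxima; a peak is significant iff its
    magnitude exceeds it (multiplicity is controlled across frequencies and
    pairs jointly).

    Returns ``(threshold, null_maxima)``.
    """
    if ensemble.n_trials < 2:
        raise ValueError("need >= 2 trials to permute trial correspondence")
    if n_null * (1.0 - q) < 1.0:
        raise ValueError(
            f"n_null={n_null} cannot resolve the {q:.3f} quantile "
            f"(need n_null >= {int(np.ceil(1.0 / (1.0 - q)))})"
        )
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=np.float64)
    rng = np.random.default_rng(seed)
    n = ensemble.n_trials
    m = order
    T = ensemble.n_samples
    rows = T - m
    n_eff = n * rows

    # Under a trial permutation of the source channel only the target x source
    # cross-products of the pooled normal equations change; precompute the
    # per-trial single-channel column stacks and the invariant blocks.
    precomp = []
    for s, t in pairs:
        data = ensemble.channel_data([t, s])  # channel 0 = target, 1 = source
        cols = []
        for c in (0, 1):
            dc = data[:, c, :]
            lag = np.stack([dc[:, m - i: T - i] for i in range(1, m + 1)], axis=2)
            cols.append(np.concatenate([lag, dc[:, m:, None]], axis=2))  # (n, rows, m+1)
        Tstack, Sstack = cols
        G_tt = np.einsum("nri,nrj->ij", Tstack, Tstack)
        G_ss = np.einsum("nri,nrj->ij", Sstack, Sstack)
        precomp.append((s, t, Tstack, Sstack, G_tt, G_ss))

    D = 2 * m + 2
    t_cols = np.r_[2 * np.arange(m), 2 * m]          # target lag cols + y_target
    s_cols = np.r_[2 * np.arange(m) + 1, 2 * m + 1]  # source lag cols + y_source
    maxima = np.empty(n_null)
    for b in range(n_null):
        mx = -np.inf
        for s, t, Tstack, Sstack, G_tt, G_ss in precomp:
            perm = rng.permutation(n)
            G_ts = np.einsum("nri,nrj->ij", Tstack, Sstack[perm])
            G = np.empty((D, D))
            G[np.ix_(t_cols, t_cols)] = G_tt
            G[np.ix_(s_cols, s_cols)] = G_ss
            G[np.ix_(t_cols, s_cols)] = G_ts
            G[np.ix_(s_cols, t_cols)] = G_ts.T
            coeffs, sigma = models_from_gram(G[None], m, 2, n_eff)
            out = batch_bivariate_spectra(
                coeffs, sigma, freqs, ensemble.sampling_rate
            )
            mx = max(mx, float(out["sgc_yx"].max()))
        maxima[b] = mx
    threshold = float(np.quantile(maxima, q))
    return threshold, maxima


@dataclass
class PeakTable:
    """Per pair x bootstrap peak inventory with significance flags."""

    table: pd.DataFrame   # columns: source, target, bootstrap_id, peak_freq, peak_mag, is_significant
    null_threshold: float | None
    band: tuple[float, float]

    def pair_summary(self) -> pd.DataFrame:
        g = self.table.groupby(["source", "target"])["peak_freq"]
        return pd.DataFrame({"mean_peak_freq": g.mean(), "sd_peak_freq": g.std()})


def tabulate_peaks(
    boots: BootstrapSpectra,
    pairs: Sequence[tuple[str, str]] | None = None,
    null_threshold: float | None = None,
    band: tuple[float, float] = (5.0, 90.0),
    smooth: int = 1,
) -> PeakTable:
    """Find all directed-sGC peaks in every bootstrap resample of each pair."""
    if pairs is None:
        pairs = boots.pairs
    rows = []
    for s, t in pairs:
        arr = boots.sgc[(s, t)]
        for b in range(arr.shape[0]):
            for freq, mag in find_peaks(boots.freqs, arr[b], band, smooth):
                rows.append((s, t, b, freq, mag))
    table = pd.DataFrame(
        rows, columns=["source", "target", "bootstrap_id", "peak_freq", "peak_mag"]
    )
    if null_threshold is not None:
        table["is_significant"] = table["peak_mag"] > null_threshold
    else:
        table["is_significant"] = True
    return PeakTable(table=table, null_threshold=null_threshold, band=band)


# ---------------------------------------------------------------------------
# consistent-pair selection
# ---------------------------------------------------------------------------

@dataclass
class PairSelection:
    retained: list[tuple[str, str]]
    excluded: list[tuple[str, str]]
    modal_freq: float
    ci: tuple[float, float]
    per_pair_mean_freq: pd.Series
    per_boot_mean_freq: np.ndarray


def modal_peak_frequency(
    table: pd.DataFrame,
    band: tuple[float, float] = (5.0, 90.0),
    significant_only: bool = True,
    grid_step: float = 0.25,
    bw: float | None = None,
) -> float:
    """Mode of the smoothed empirical peak-frequency density."""
    rows = table[table["is_significant"]] if significant_only else table
    if len(rows) == 0:
        rows = table
    f = rows["peak_freq"].to_numpy()
    if len(f) == 0:
        raise ValueError("no peaks to summarize")
    if len(np.unique(f)) == 1:
        return float(f[0])
    grid = np.arange(band[0], band[1] + grid_step, grid_step)
    kde = sps.gaussian_kde(f, bw_method=bw)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def select_consistent_pairs(
    peaks: PeakTable,
    n: int,
    modal_freq: float | None = None,
    level: float = 0.95,
) -> PairSelection:
    """Retain pairs whose mean nearest-peak frequency falls inside the CI of
    the across-pair mean peak frequency.

    Per bootstrap, each pair contributes its peak nearest the global modal
    frequency; the across-pair mean per bootstrap gives a bootstrap SE and a
    ``level`` CI (t multiplier with n - 1 df). Pairs whose own
    across-bootstrap mean nearest-peak frequency lies inside the CI are
    retained. Pairs with no detected peak in any bootstrap are excluded with
    a warning.
    """
    table = peaks.table
    if modal_freq is None:
        modal_freq = modal_peak_frequency(table, peaks.band)
    all_pairs = list(dict.fromkeys(zip(table["source"], table["target"])))
    B = int(table["bootstrap_id"].max()) + 1 if len(table) else 0
    nearest = np.full((B, len(all_pairs)), np.nan)
    for j, (s, t) in enumerate(all_pairs):
        sub = table[(table["source"] == s) & (table["target"] == t)]
        order_key = (sub["peak_freq"] - modal_freq).abs() + 1e-9 * sub["peak_freq"]
        best = sub.loc[order_key.groupby(sub["bootstrap_id"]).idxmin()]
        nearest[best["bootstrap_id"].to_numpy(), j] = best["peak_freq"].to_numpy()

    empty = [p for j, p in enumerate(all_pairs) if np.all(np.isnan(nearest[:, j]))]
    if empty:
        warnings.warn(f"pairs with no detected peaks excluded: {empty}")
    keep_cols = [j for j, p in enumerate(all_pairs) if p not in empty]
    pairs_kept = [all_pairs[j] for j in keep_cols]
    nearest = nearest[:, keep_cols]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_boot = np.nanmean(nearest, axis=1)
    per_boot = per_boot[np.isfinite(per_boot)]
    if len(per_boot) < 2:
        raise ValueError("fewer than 2 bootstraps with any detected peak")
    grand = float(per_boot.mean())
    se = float(np.sqrt(((per_boot - grand) ** 2).sum() / (len(per_boot) - 1)))
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, n - 1))
    ci = (grand - se * tcrit, grand + se * tcrit)

    per_pair_mean = pd.Series(
        np.nanmean(nearest, axis=0),
        index=pd.MultiIndex.from_tuples(pairs_kept, names=["source", "target"]),
        name="mean_nearest_peak_freq",
    )
    retained = [
        p for p, mu in per_pair_mean.items() if ci[0] <= mu <= ci[1]
    ]
    excluded = [p for p in all_pairs if p not in retained]
    return PairSelection(
        retained=retained,
        excluded=excluded,
        modal_freq=modal_freq,
        ci=ci,
        per_pair_mean_freq=per_pair_mean,
        per_boot_mean_freq=per_boot,
    )


# ---------------------------------------------------------------------------
# time-reversal control
# ---------------------------------------------------------------------------

def _pair_sgc(
    ensemble: TrialEnsemble,
    source: str,
    target: str,
    order: int,
    freqs: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(source->target, target->source) sGC spectra from the all-trials fit."""
    data = ensemble.channel_data([target, source])
    gram = trial_gram_stack(data, order)
    rows = ensemble.n_samples - order
    ones = np.ones((1, ensemble.n_trials))
    coeffs, sigma = weighted_models(gram, ones, order, rows)
    out = batch_bivariate_spectra(coeffs, sigma, freqs, ensemble.sampling_rate)
    return out["sgc_yx"][0], out["sgc_xy"][0]


def time_reversal_test(
    ensemble: TrialEnsemble,
    pairs: Sequence[tuple[str, str]],
    band_freqs: np.ndarray,
    order: int = DEFAULT_ORDER,
    alpha: float = 0.05,
    unit: str = "freq_bins",
    n_splits: int = 10,
) -> pd.DataFrame:
    """Net-flow vs reverse-net-flow spuriousness control per pair.

    Net flow = top-down minus bottom-up sGC on the frequencies of established
    asymmetry; the same quantity is recomputed with samples flipped within
    each trial. A genuine lagged interaction changes sign under reversal
    while shared-input artifacts do not, so (net flow - reverse net flow) is
    t-tested against zero; two-tailed p-values are Bonferroni-corrected by
    the pair count. ``significant`` means the causal relation is *not*
    rejected as spurious.

    ``unit`` selects the t-test's sample unit. ``"freq_bins"`` treats the
    band's frequency samples as replicates (df = n_bins - 1); note that AR
    spectra are smooth, so bins are strongly correlated and this unit is
    anticonservative under the null. ``"trial_splits"`` computes the
    band-averaged statistic on ``n_splits`` disjoint trial groups
    (df = n_splits - 1), which yields independent replicates and a
    calibrated null.
    """
    band_freqs = np.asarray(band_freqs, dtype=np.float64)
    if band_freqs.size == 0:
        raise ValueError("empty frequency band for time-reversal test")
    if unit not in ("freq_bins", "trial_splits"):
        raise ValueError(f"unknown sample unit {unit!r}")
    reversed_ens = ensemble.time_reversed()
    rows = []
    for s, t in pairs:
        if unit == "freq_bins":
            td, bu = _pair_sgc(ensemble, s, t, order, band_freqs)
            td_r, bu_r = _pair_sgc(reversed_ens, s, t, order, band_freqs)
            net = td - bu
            net_r = td_r - bu_r
            stat = net - net_r
            net_mean, net_r_mean = float(net.mean()), float(net_r.mean())
        else:
            groups = np.array_split(np.arange(ensemble.n_trials), n_splits)
            stat = np.empty(n_splits)
            nets = np.empty(n_splits)
            nets_r = np.empty(n_splits)
            for g, idx in enumerate(groups):
                fwd = ensemble.select_trials(idx)
                rev = reversed_ens.select_trials(idx)
                td, bu = _pair_sgc(fwd, s, t, order, band_freqs)
                td_r, bu_r = _pair_sgc(rev, s, t, order, band_freqs)
                nets[g] = (td - bu).mean()
                nets_r[g] = (td_r - bu_r).mean()
                stat[g] = nets[g] - nets_r[g]
            net_mean, net_r_mean = float(nets.mean()), float(nets_r.mean())
        tval, p = sps.ttest_1samp(stat, 0.0)
        p_corr = min(1.0, float(p) * len(pairs))
        rows.append((s, t, net_mean, net_r_mean,
                     float(tval), float(p), p_corr, p_corr < alpha))
    return pd.DataFrame(
        rows,
        columns=["source", "target", "net_flow", "reverse_net_flow",
                 "t", "p", "p_bonferroni", "significant"],
    )


# ---------------------------------------------------------------------------
# coherence vs sGC correlation
# ---------------------------------------------------------------------------

def coherence_gc_correlation(
    coherence: np.ndarray,
    sgc: np.ndarray,
    normalized: bool = False,
) -> tuple[float, float]:
    """Pearson correlation between coherence and directed sGC at a peak
    frequency across pairs; returns ``(r, r_squared)``.

    Plain mode: one scalar per pair in each input. Normalized mode: inputs
    are (n_pairs, B) arrays of per-bootstrap values; each pair's values are
    mean-aligned and variance-standardized over bootstraps before pooling.
    """
    coherence = np.asarray(coherence, dtype=np.float64)
    sgc = np.asarray(sgc, dtype=np.float64)
    if coherence.shape != sgc.shape:
        raise ValueError("coherence and sgc inputs must have matching shapes")
    if normalized:
        if coherence.ndim != 2:
            raise ValueError("normalized mode expects (n_pairs, B) arrays")
        def _standardize(a: np.ndarray) -> np.ndarray:
            sd = a.std(axis=1, ddof=1, keepdims=True)
            if np.any(sd == 0):
                raise ValueError("zero variance over bootstraps; correlation undefined")
            return (a - a.mean(axis=1, keepdims=True)) / sd
        x = _standardize(coherence).ravel()
        y = _standardize(sgc).ravel()
    else:
        if coherence.ndim != 1 or len(coherence) < 3:
            raise ValueError("need >= 3 pairs of scalar values")
        x, y = coherence, sgc
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input; correlation undefined")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r
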