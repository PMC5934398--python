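"""Decoding a two-level condition from directed spectral-peak patterns.

Implements the delete-d jackknife SVM protocol: per repeat, each condition's
trials are split in half; bootstrap exemplars of the top-down sGC pattern
are drawn per half; the feature per retained pair is the magnitude of the
directed-sGC peak nearest the target frequency (z-scored jointly over both
halves and both conditions); a linear SVM trained on one half is scored on
the other. The spread of per-repeat accuracies gives the delete-d jackknife
standard error (JSVE approximation over M random splits), and a one-sample
t-test compares mean accuracy with the 50% chance level.

The random-frequency control replaces the peak feature with the sGC
magnitude at a frequency drawn uniformly at random (fresh per resample and
pair), destroying the frequency specificity while preserving everything
else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

from sgckit._batch import batch_bivariate_spectra, weighted_models
from sgckit.ensemble import TrialEnsemble
from sgckit.inference import BootstrapSpectra, find_peaks, nearest_peak
from sgckit.spectral import DEFAULT_ORDER, default_freq_grid, trial_gram_stack

__all__ = [
    "FeatureSet",
    "DecodingResult",
    "extract_features",
    "decode_context",
    "control_decode",
    "jsve_se",
    "delete_d_se",
]

BLOCKS = (("train", 0), ("train", 1), ("test", 0), ("test", 1))


# ---------------------------------------------------------------------------
# delete-d jackknife standard errors
# ---------------------------------------------------------------------------

def _delete_d_check(n: int, d: int) -> None:
    if d <= 0 or d >= n:
        raise ValueError(f"delete-d requires 0 < d < n, got d={d}, n={n}")


def delete_d_se(per_subset_stats: np.ndarray, n: int, d: int) -> float:
    """Exact delete-d jackknife SE over *all* C(n, d) subsets.

    ``sqrt[ (n-d) / (d * C(n,d)) * sum_z (theta(z) - mean)^2 ]``; the caller
    must supply one statistic per possible subset.
    """
    _delete_d_check(n, d)
    stats = np.asarray(per_subset_stats, dtype=np.float64)
    total = comb(n, d)
    if len(stats) != total:
        raise ValueError(
            f"expected one statistic per subset: C({n},{d}) = {total}, "
            f"got {len(stats)}"
        )
    dev = stats - stats.mean()
    return float(np.sqrt((n - d) / (d * total) * np.sum(dev**2)))


def jsve_se(per_subset_stats: np.ndarray, n: int, d: int) -> float:
    """Jackknife-sampling variance estimator of the delete-d SE.

    Monte-Carlo version over ``M = len(per_subset_stats)`` random subsets:
    ``sqrt[ (n-d) / (d * M) * sum_z (theta(z) - mean)^2 ]``.
    """
    _delete_d_check(n, d)
    stats = np.asarray(per_subset_stats, dtype=np.float64)
    M = len(stats)
    if M < 2:
        raise ValueError("need M >= 2 subset statistics")
    dev = stats - stats.mean()
    return float(np.sqrt((n - d) / (d * M) * np.sum(dev**2)))


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

@dataclass
class FeatureSet:
    """Z-scored exemplar-by-pair feature blocks.

    ``blocks[(role, condition)]`` is a (kept exemplars, n_pairs) matrix;
    z-scoring parameters are shared across the union of all blocks, so each
    feature column has mean 0 and unit variance over that union.
    """

    blocks: dict[tuple[str, str], np.ndarray]
    pairs: list[tuple[str, str]]
    deleted_count: int
    total_exemplars: int
    target_freq: float | None

    @property
    def deleted_fraction(self) -> float:
        return self.deleted_count / self.total_exemplars if self.total_exemplars else 0.0


def _peak_features(
    sgc_rows: np.ndarray, freqs: np.ndarray, target: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Magnitude of the peak nearest ``target`` per spectrum row (NaN if none)."""
    out = np.full(sgc_rows.shape[0], np.nan)
    for i in range(sgc_rows.shape[0]):
        pk = nearest_peak(find_peaks(freqs, sgc_rows[i], band), target)
        if pk is not None:
            out[i] = pk[1]
    return out


def _zscore_blocks(
    raw: Mapping[tuple, np.ndarray],
) -> dict[tuple, np.ndarray]:
    """Joint z-scoring across the union of all blocks, per feature column.

    This mirrors the 'balanced features' convention: normalization
    parameters are computed over train and test exemplars of both
    conditions. (The train/test leakage this implies is intentional fidelity
    to the protocol; see decode_context(leakage_free=...) for the clean
    alternative.)
    """
    stacked = np.concatenate(list(raw.values()), axis=0)
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return {k: (v - mu) / sd for k, v in raw.items()}


def extract_features(
    boot_spectra: Mapping[tuple[str, str], BootstrapSpectra],
    retained_pairs: Sequence[tuple[str, str]],
    target_freq: float = 16.0,
    band: tuple[float, float] = (5.0, 90.0),
) -> FeatureSet:
    """Nearest-peak sGC magnitudes as z-scored classification features.

    ``boot_spectra`` maps (role, condition) blocks to their bootstrap
    spectra. Exemplars in which any retained pair lacks a peak are deleted
    (counted); z-scoring is joint across all blocks.
    """
    retained_pairs = [tuple(p) for p in retained_pairs]
    raw: dict[tuple[str, str], np.ndarray] = {}
    deleted = 0
    total = 0
    for key, boots in boot_spectra.items():
        cols = [
            _peak_features(boots.sgc[p], boots.freqs, target_freq, band)
            for p in retained_pairs
        ]
        X = np.column_stack(cols)
        valid = np.all(np.isfinite(X), axis=1)
        deleted += int((~valid).sum())
        total += X.shape[0]
        raw[key] = X[valid]
    if all(len(v) == 0 for v in raw.values()):
        raise ValueError("all exemplars deleted: no pair had a usable peak")
    return FeatureSet(
        blocks=_zscore_blocks(raw),
        pairs=retained_pairs,
        deleted_count=deleted,
        total_exemplars=total,
        target_freq=target_freq,
    )


# ---------------------------------------------------------------------------
# decoding protocol
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    mean_accuracy: float
    se_jsve: float
    n: int
    d: int
    M: int
    t_stat: float
    p_value: float
    per_repeat_accuracy: np.ndarray
    skipped_repeats: int = 0
    deleted_fraction: float = 0.0
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_accuracy <= 1.0:
            raise ValueError("mean accuracy must be in [0, 1]")
        if self.se_jsve < 0:
            raise ValueError("SE must be >= 0")
        if self.M < 1:
            raise ValueError("M must be >= 1")

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "se_jsve": self.se_jsve,
            "n": self.n,
            "d": self.d,
            "M": self.M,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "skipped_repeats": self.skipped_repeats,
            "deleted_fraction": self.deleted_fraction,
            "config": self.config,
        }


def _make_classifier(kind: str, cost: float):
    if kind == "svm":
        return SVC(kernel="linear", C=cost)
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown classifier {kind!r}")


def _decode_impl(
    ensemble: TrialEnsemble,
    retained_pairs: Sequence[tuple[str, str]],
    *,
    order: int,
    B_exemplars: int,
    repeats: int,
    cost: float,
    seed: int | None,
    target_freq: float,
    freqs: np.ndarray | None,
    band: tuple[float, float],
    feature_mode: str,
    freq_range: tuple[float, float],
    classifier: str,
    leakage_free: bool,
) -> DecodingResult:
    conditions = ensemble.condition_names()
    if len(conditions) != 2:
        raise ValueError(
            f"decoding requires exactly 2 condition labels, found {conditions}"
        )
    retained_pairs = [tuple(p) for p in retained_pairs]
    if not retained_pairs:
        raise ValueError("retained_pairs must be non-empty")
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=np.float64)
    rng = np.random.default_rng(seed)

    cond_idx = {c: ensemble.condition_trials(c) for c in conditions}
    n_min = min(len(v) for v in cond_idx.values())
    h = n_min // 2                 # per-condition half size
    if h < 2:
        raise ValueError("too few trials per condition to split in half")
    d = 2 * h                      # deleted-half size (both conditions)
    n = 4 * h                      # trials entering each repeat
    rows = ensemble.n_samples - order

    # per-trial gram blocks, computed once per pair over all trials
    grams = {
        (s, t): trial_gram_stack(ensemble.channel_data([t, s]), order)
        for s, t in retained_pairs
    }
    p_uniform = np.full(h, 1.0 / h)

    accs = []
    skipped = 0
    deleted = 0
    total_exemplars = 0
    for _ in range(repeats):
        halves: dict[tuple[str, int], np.ndarray] = {}
        for ci, c in enumerate(conditions):
            perm = rng.permutation(cond_idx[c])[: 2 * h]
            halves[("train", ci)] = perm[:h]
            halves[("test", ci)] = perm[h:]
        raw: dict[tuple[str, int], np.ndarray] = {}
        ok = True
        for key in BLOCKS:
            counts = rng.multinomial(h, p_uniform, size=B_exemplars).astype(np.float64)
            cols = []
            for p in retained_pairs:
                gram_block = grams[p][halves[key]]
                coeffs, sigma = weighted_models(gram_block, counts, order, rows)
                out = batch_bivariate_spectra(
                    coeffs, sigma, freqs, ensemble.sampling_rate
                )
                td = out["sgc_yx"]
                if feature_mode == "peak":
                    cols.append(_peak_features(td, freqs, target_freq, band))
                else:  # random-frequency control
                    fr = rng.uniform(freq_range[0], freq_range[1], size=B_exemplars)
                    vals = np.array(
                        [np.interp(fr[i], freqs, td[i]) for i in range(B_exemplars)]
                    )
                    cols.append(vals)
            X = np.column_stack(cols)
            valid = np.all(np.isfinite(X), axis=1)
            deleted += int((~valid).sum())
            total_exemplars += X.shape[0]
            raw[key] = X[valid]
            if len(raw[key]) == 0:
                ok = False
        if not ok or any(len(raw[("train", ci)]) == 0 for ci in (0, 1)):
            skipped += 1
            warnings.warn("repeat skipped: a training block lost all exemplars")
            continue

        if leakage_free:
            train_stack = np.concatenate(
                [raw[("train", 0)], raw[("train", 1)]], axis=0
            )
            mu = train_stack.mean(axis=0)
            sd = train_stack.std(axis=0, ddof=0)
            sd = np.where(sd == 0, 1.0, sd)
            blocks = {k: (v - mu) / sd for k, v in raw.items()}
        else:
            blocks = _zscore_blocks(raw)

        Xtr = np.concatenate([blocks[("train", 0)], blocks[("train", 1)]])
        ytr = np.concatenate(
            [np.zeros(len(blocks[("train", 0)])), np.ones(len(blocks[("train", 1)]))]
        )
        Xte = np.concatenate([blocks[("test", 0)], blocks[("test", 1)]])
        yte = np.concatenate(
            [np.zeros(len(blocks[("test", 0)])), np.ones(len(blocks[("test", 1)]))]
        )
        clf = _make_classifier(classifier, cost)
        clf.fit(Xtr, ytr)
        accs.append(float(np.mean(clf.predict(Xte) == yte)))

    if len(accs) < 2:
        raise ValueError(
            f"decoding produced {len(accs)} usable repeats; need >= 2"
        )
    accs = np.asarray(accs)
    mean_acc = float(accs.mean())
    se = jsve_se(accs, n, d)
    if se > 0:
        t_stat = (mean_acc - 0.5) / se
        p_value = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
    else:
        t_stat = np.inf if mean_acc != 0.5 else 0.0
        p_value = 0.0 if mean_acc != 0.5 else 1.0
    return DecodingResult(
        mean_accuracy=mean_acc,
        se_jsve=se,
        n=n,
        d=d,
        M=len(accs),
        t_stat=float(t_stat),
        p_value=p_value,
        per_repeat_accuracy=accs,
        skipped_repeats=skipped,
        deleted_fraction=deleted / total_exemplars if total_exemplars else 0.0,
        config={
            "order": order,
            "B_exemplars": B_exemplars,
            "repeats": repeats,
            "cost": cost,
            "seed": seed,
            "target_freq": target_freq,
            "feature_mode": feature_mode,
            "freq_range": list(freq_range),
            "classifier": classifier,
            "leakage_free": leakage_free,
            "conditions": conditions,
            "retained_pairs": [list(p) for p in retained_pairs],
        },
    )


def decode_context(
    ensemble: TrialEnsemble,
    retained_pairs: Sequence[tuple[str, str]],
    order: int = DEFAULT_ORDER,
    B_exemplars: int = 200,
    repeats: int = 5000,
    cost: float = 1.0,
    seed: int | None = None,
    target_freq: float = 16.0,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = (5.0, 90.0),
    classifier: str = "svm",
    leakage_free: bool = False,
) -> DecodingResult:
    """Decode the two-level condition from top-down peak-sGC patterns.

    Per repeat: split each condition's trials at random into halves; draw
    ``B_exemplars`` bootstrap resamples per half per condition (one draw
    shared by all pairs); extract the nearest-to-``target_freq`` directed
    peak magnitude per retained pair; z-score features jointly; fit a linear
    SVM (``cost``) on one half's exemplars and score on the other's.
    Aggregates mean accuracy, the JSVE standard error over repeats, and a
    one-sample t-test against 50% with ``n - 1`` degrees of freedom.
    """
    return _decode_impl(
        ensemble, retained_pairs, order=order, B_exemplars=B_exemplars,
        repeats=repeats, cost=cost, seed=seed, target_freq=target_freq,
        freqs=freqs, band=band, feature_mode="peak",
        freq_range=(5.0, 50.0), classifier=classifier,
        leakage_free=leakage_free,
    )


def control_decode(
    ensemble: TrialEnsemble,
    retained_pairs: Sequence[tuple[str, str]],
    order: int = DEFAULT_ORDER,
    B_exemplars: int = 200,
    repeats: int = 5000,
    cost: float = 1.0,
    seed: int | None = None,
    freq_range: tuple[float, float] = (5.0, 50.0),
    freqs: np.ndarray | None = None,
    classifier: str = "svm",
    leakage_free: bool = False,
) -> DecodingResult:
    """Random-frequency control: identical protocol, but each feature is the
    top-down sGC magnitude at a frequency drawn uniformly in ``freq_range``
    (fresh draw per resample and pair)."""
    return _decode_impl(
        ensemble, retained_pairs, order=order, B_exemplars=B_exemplars,
        repeats=repeats, cost=cost, seed=seed, target_freq=np.nan,
        freqs=freqs, band=(5.0, 90.0), feature_mode="random",
        freq_range=freq_range, classifier=classifier,
        leakage_free=leakage_free,
    )
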