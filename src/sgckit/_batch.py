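"""Vectorized bivariate VAR refitting for bootstrap / permutation loops.

A trial's contribution to the pooled normal equations is a fixed cross
product block (see :func:`sgckit.spectral.trial_gram_stack`), so a bootstrap
resample's fit is a count-weighted sum of per-trial blocks followed by one
(batched) solve. Spectra for all resamples are then evaluated with
closed-form 2x2 inverses. Used by :mod:`sgckit.inference` and
:mod:`sgckit.decoding`; not part of the public API.
"""

from __future__ import annotations

import numpy as np

from sgckit.spectral import models_from_gram


def weighted_models(
    gram_stack: np.ndarray,
    counts: np.ndarray,
    order: int,
    rows_per_trial: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one bivariate VAR per row of ``counts``.

    gram_stack: (n_trials, D, D) per-trial blocks (D = 2*order + 2).
    counts: (B, n_trials) trial multiplicities per resample (need not sum to
    n_trials; n_eff follows the actual resample size).
    Returns coeffs (B, m, 2, 2) and sigma (B, 2, 2).
    """
    n, D, _ = gram_stack.shape
    flat = gram_stack.reshape(n, D * D)
    G = (counts @ flat).reshape(-1, D, D)
    n_eff = counts.sum(axis=1) * rows_per_trial
    coeffs, sigma = models_from_gram(G, order, 2, 1)
    sigma = sigma / n_eff[:, None, None]
    return coeffs, sigma


def batch_bivariate_spectra(
    coeffs: np.ndarray,
    sigma: np.ndarray,
    freqs: np.ndarray,
    sampling_rate: float,
) -> dict[str, np.ndarray]:
    """Power/coherence/directed-sGC for a batch of bivariate models.

    coeffs: (B, m, 2, 2), sigma: (B, 2, 2). Channel 0 is X, channel 1 is Y.
    Returns arrays of shape (B, F): ``sgc_yx`` (Y -> X), ``sgc_xy``,
    ``coherence``; and ``power`` of shape (B, 2, F).
    """
    B, m, _, _ = coeffs.shape
    freqs = np.asarray(freqs, dtype=np.float64)
    phase = np.exp(
        -2j * np.pi * np.outer(freqs, np.arange(1, m + 1)) / sampling_rate
    )  # (F, m)
    Aw = np.einsum("fm,bmij->bfij", phase, coeffs)
    M = -Aw
    M[:, :, 0, 0] += 1.0
    M[:, :, 1, 1] += 1.0
    det = M[:, :, 0, 0] * M[:, :, 1, 1] - M[:, :, 0, 1] * M[:, :, 1, 0]
    H = np.empty_like(M)
    H[:, :, 0, 0] = M[:, :, 1, 1] / det
    H[:, :, 1, 1] = M[:, :, 0, 0] / det
    H[:, :, 0, 1] = -M[:, :, 0, 1] / det
    H[:, :, 1, 0] = -M[:, :, 1, 0] / det

    S = np.einsum("bfij,bjk,bflk->bfil", H, sigma.astype(complex), H.conj())
    Sxx = S[:, :, 0, 0].real
    Syy = S[:, :, 1, 1].real
    Sxy = S[:, :, 0, 1]
    coherence = np.clip(np.abs(Sxy) ** 2 / (Sxx * Syy), 0.0, 1.0 - 1e-15)

    partial_y = sigma[:, 1, 1] - sigma[:, 0, 1] ** 2 / sigma[:, 0, 0]
    partial_x = sigma[:, 0, 0] - sigma[:, 0, 1] ** 2 / sigma[:, 1, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        sgc_yx = np.log(Sxx / (Sxx - partial_y[:, None] * np.abs(H[:, :, 0, 1]) ** 2))
        sgc_xy = np.log(Syy / (Syy - partial_x[:, None] * np.abs(H[:, :, 1, 0]) ** 2))
    sgc_yx = np.clip(np.nan_to_num(sgc_yx, nan=0.0, posinf=np.inf), 0.0, None)
    sgc_xy = np.clip(np.nan_to_num(sgc_xy, nan=0.0, posinf=np.inf), 0.0, None)
    power = np.stack([Sxx, Syy], axis=1)
    return {
        "sgc_yx": sgc_yx,
        "sgc_xy": sgc_xy,
        "coherence": coherence,
        "power": power,
    }
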