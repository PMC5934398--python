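"""End-to-end analysis driver.

Sequences the full chain on one ensemble: (optional) simulation ->
ensemble-mean subtraction -> AIC order check -> bootstrap spectra -> 1/f
background removal -> directional asymmetry -> peak identification with
trial-shuffle null -> consistent-pair selection -> time-reversal control ->
coherence/sGC correlation -> context decoding plus random-frequency control.
Each stage writes its table under the output directory; ``summary.json`` is
deterministic for a fixed config and seed, and ``provenance.json`` records
versions, seeds and wall times.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from hashlib import sha256
from pathlib import Path

import numpy as np
import pandas as pd

import sgckit
from sgckit.config import RunConfig
from sgckit.decoding import control_decode, decode_context
from sgckit.ensemble import TrialEnsemble
from sgckit.inference import (
    bootstrap_spectra,
    directional_asymmetry,
    peak_null_threshold,
    select_consistent_pairs,
    tabulate_peaks,
    time_reversal_test,
)
from sgckit.io import read_ensemble, write_ensemble
from sgckit.spectral import (
    remove_background,
    select_order_aic,
    subtract_ensemble_mean,
)
from sgckit import inference

logger = logging.getLogger("sgckit.pipeline")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def topdown_pairs(ensemble: TrialEnsemble) -> list[tuple[str, str]]:
    """All ordered (higher, lower) channel pairs."""
    return [
        (h, l) for h in ensemble.higher_channels() for l in ensemble.lower_channels()
    ]


def load_or_simulate(config: RunConfig) -> TrialEnsemble:
    if config.input_path is not None:
        return read_ensemble(config.input_path)
    from sgckit.synth import simulate_trials

    return simulate_trials(config.build_simulation_spec())


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the summary dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    summary: dict = {"config": config.to_dict()}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    freqs = np.arange(
        config.band[0], config.band[1] + config.freq_step / 2, config.freq_step
    )

    s = stage("input")
    ensemble = load_or_simulate(config)
    if config.input_path is None:
        write_ensemble(ensemble, out / "ensemble.h5")
    summary["input"] = {
        "n_trials": ensemble.n_trials,
        "n_channels": ensemble.n_channels,
        "n_samples": ensemble.n_samples,
        "sampling_rate": ensemble.sampling_rate,
        "conditions": ensemble.condition_names(),
    }
    done(s)

    s = stage("mean_subtraction")
    centered = subtract_ensemble_mean(ensemble)
    done(s)

    pairs = topdown_pairs(ensemble)
    if not pairs:
        raise ValueError("ensemble has no (higher, lower) channel pairs")

    s = stage("aic")
    h, l = pairs[0]
    best_order, curve = select_order_aic(centered, [l, h], config.order_scan)
    curve.to_csv(out / "aic_curve.csv")
    summary["aic"] = {"scanned": list(config.order_scan), "argmin": best_order,
                      "used_order": config.order}
    done(s)

    s = stage("bootstrap_spectra")
    boots = bootstrap_spectra(
        centered, pairs, config.order, config.B, config.seed, freqs
    )
    boots.full_fit.to_frame().to_csv(out / "spectra_full_fit.csv", index=False)
    done(s)

    s = stage("background_removal")
    bg_rows = []
    for ch, p in boots.full_fit.power.items():
        res = remove_background(freqs, p, tuple(config.fit_band))
        bg_rows.append(pd.DataFrame({
            "channel": ch, "freq_hz": freqs, "power": p,
            "residual_db": res["residual"],
            "background_db": res["background_db"],
        }))
    pd.concat(bg_rows, ignore_index=True).to_csv(
        out / "power_background.csv", index=False
    )
    done(s)

    s = stage("asymmetry")
    td = np.mean([boots.sgc[(hh, ll)] for hh, ll in pairs], axis=0)
    bu = np.mean([boots.sgc[(ll, hh)] for hh, ll in pairs], axis=0)
    asym = directional_asymmetry(
        td, bu, ensemble.n_trials, config.alpha_asymmetry, freqs
    )
    sig_freqs = asym.significant_freqs()
    pd.DataFrame({
        "freq_hz": freqs,
        "mean_diff": asym.stats.mean,
        "ci_low": asym.stats.ci_low,
        "ci_high": asym.stats.ci_high,
        "significant": asym.significant,
    }).to_csv(out / "asymmetry.csv", index=False)
    summary["asymmetry"] = {
        "alpha": config.alpha_asymmetry,
        "omnibus_se": asym.stats.se,
        "significant_freqs_hz": sig_freqs.tolist(),
    }
    done(s)

    s = stage("peaks")
    threshold, null_max = peak_null_threshold(
        centered, pairs, config.order, config.n_null, config.seed + 1,
        1.0 - config.alpha_peaks, freqs,
    )
    peaks = tabulate_peaks(boots, pairs, threshold, tuple(config.band))
    peaks.table.to_csv(out / "peaks.csv", index=False)
    summary["peaks"] = {
        "null_threshold": threshold,
        "n_null": config.n_null,
        "n_significant": int(peaks.table["is_significant"].sum()),
        "n_total": int(len(peaks.table)),
    }
    done(s)

    s = stage("pair_selection")
    selection = select_consistent_pairs(peaks, ensemble.n_trials)
    retained = selection.retained
    summary["pair_selection"] = {
        "modal_freq_hz": selection.modal_freq,
        "ci_hz": list(selection.ci),
        "retained": [list(p) for p in retained],
        "excluded": [list(p) for p in selection.excluded],
    }
    done(s)

    s = stage("time_reversal")
    if sig_freqs.size:
        tr = time_reversal_test(
            centered, retained or pairs, sig_freqs, config.order,
            config.alpha_trtest,
        )
        tr.to_csv(out / "time_reversal.csv", index=False)
        summary["time_reversal"] = {
            "n_pairs": len(tr),
            "n_not_spurious": int(tr["significant"].sum()),
        }
    else:
        summary["time_reversal"] = {"skipped": "no significant asymmetry band"}
    done(s)

    s = stage("coherence_correlation")
    corr_pairs = retained if len(retained) >= 3 else pairs
    if len(corr_pairs) >= 3:
        fi = int(np.argmin(np.abs(freqs - selection.modal_freq)))
        coh = np.array([boots.mean_coherence(p)[fi] for p in corr_pairs])
        td_v = np.array([boots.mean_sgc(p)[fi] for p in corr_pairs])
        bu_v = np.array([boots.mean_sgc((p[1], p[0]))[fi] for p in corr_pairs])
        try:
            r_td, r2_td = inference.coherence_gc_correlation(coh, td_v)
            r_bu, r2_bu = inference.coherence_gc_correlation(coh, bu_v)
            summary["coherence_correlation"] = {
                "freq_hz": float(freqs[fi]),
                "topdown": {"r": r_td, "r_squared": r2_td},
                "bottomup": {"r": r_bu, "r_squared": r2_bu},
            }
        except ValueError as exc:
            summary["coherence_correlation"] = {"skipped": str(exc)}
    else:
        summary["coherence_correlation"] = {"skipped": "fewer than 3 pairs"}
    done(s)

    s = stage("decoding")
    if len(ensemble.condition_names()) == 2:
        dec_pairs = retained or pairs
        dec = decode_context(
            centered, dec_pairs, config.order, config.B_exemplars,
            config.repeats, config.cost, config.seed + 2, config.target_freq,
            freqs,
        )
        np.savetxt(out / "decode_accuracy.csv", dec.per_repeat_accuracy,
                   delimiter=",", fmt="%.17g")
        ctrl = control_decode(
            centered, dec_pairs, config.order, config.B_exemplars,
            config.repeats, config.cost, config.seed + 3,
            tuple(config.control_freq_range), freqs,
        )
        summary["decoding"] = dec.to_dict()
        summary["decoding_control"] = ctrl.to_dict()
        _dump(dec.to_dict(), out / "decoding.json")
        _dump(ctrl.to_dict(), out / "decoding_control.json")
    else:
        summary["decoding"] = {"skipped": "need exactly 2 condition labels"}
    done(s)

    _dump(summary, out / "summary.json")
    config_text = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "package": "sgckit",
        "version": sgckit.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config_sha256": sha256(config_text.encode()).hexdigest(),
        "wall_times_s": timings,
    }
    _dump(provenance, out / "provenance.json")
    return summary
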