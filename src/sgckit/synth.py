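"""Ground-truth VAR oscillator networks and trial-ensemble simulation.

Each channel is a damped AR(2) oscillator (pole radius ``r`` at the target
resonance frequency); directed influence between channels is injected as
lagged cross-coefficients. Two-condition ensembles differ only in the
strength of selected top-down (higher-area -> lower-area) couplings, so any
decodable difference downstream is attributable to directed influence alone.

Amplitudes are in arbitrary units; the generator makes no claim of
biophysical realism beyond the dynamical structure (narrowband resonance,
optional 1/f-like background, optional instantaneous mixing).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from sgckit.ensemble import TrialEnsemble

# IIR approximation of a 1/f amplitude spectrum (cascade of first-order
# sections; coefficients are the conventional "pinking" filter for white
# noise sampled anywhere in the audio-to-LFP range).
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


class StationarityError(ValueError):
    """Raised when the implied VAR is not stable (companion radius >= 1)."""

    def __init__(self, radius: float, msg: str | None = None):
        self.radius = radius
        super().__init__(
            msg or f"implied VAR is non-stationary: companion spectral radius "
            f"{radius:.6f} >= 1"
        )


@dataclass(frozen=True)
class Coupling:
    """One directed lagged coefficient: ``target_t += coeff * source_(t-lag)``."""

    source: str
    target: str
    coeff: float
    lag: int = 1

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError(f"coupling lag must be >= 1, got {self.lag}")


@dataclass
class NetworkSpec:
    """Structural description of a lower/higher two-area oscillator network.

    Channels are labeled ``L1..Ln`` (lower area) then ``H1..Hm`` (higher
    area), in that order.
    """

    n_lower: int
    n_higher: int
    osc_freq: float = 16.0
    osc_damping: float = 0.9
    coupling: tuple[Coupling, ...] = ()
    noise_cov: np.ndarray | None = None
    pink_noise_gain: float = 0.0
    mixing: np.ndarray | None = None
    sampling_rate: float = 200.0

    def __post_init__(self) -> None:
        self.coupling = tuple(self.coupling)
        if self.n_lower < 0 or self.n_higher < 0 or self.n_channels == 0:
            raise ValueError("need at least one channel")
        if not 0.0 <= self.osc_damping < 1.0:
            raise ValueError(f"osc_damping must be in [0, 1), got {self.osc_damping}")
        if self.osc_freq >= self.sampling_rate / 2.0:
            raise ValueError(
                f"osc_freq {self.osc_freq} >= Nyquist {self.sampling_rate / 2.0}"
            )
        if self.noise_cov is None:
            self.noise_cov = np.eye(self.n_channels)
        self.noise_cov = np.asarray(self.noise_cov, dtype=np.float64)
        if self.noise_cov.shape != (self.n_channels, self.n_channels):
            raise ValueError("noise_cov shape does not match channel count")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        # positive definiteness; cholesky also needed for simulation
        try:
            np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise_cov must be positive definite") from None
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=np.float64)
            if self.mixing.shape != (self.n_channels, self.n_channels):
                raise ValueError("mixing matrix shape does not match channel count")
        labels = set(self.channel_labels)
        for c in self.coupling:
            if c.source not in labels or c.target not in labels:
                raise ValueError(f"coupling references unknown channel: {c}")

    @property
    def n_channels(self) -> int:
        return self.n_lower + self.n_higher

    @property
    def channel_labels(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.n_lower)] + [
            f"H{i + 1}" for i in range(self.n_higher)
        ]

    @property
    def areas(self) -> dict[str, str]:
        out = {f"L{i + 1}": "lower" for i in range(self.n_lower)}
        out.update({f"H{i + 1}": "higher" for i in range(self.n_higher)})
        return out

    def is_top_down(self, c: Coupling) -> bool:
        return self.areas[c.source] == "higher" and self.areas[c.target] == "lower"

    def with_coupling_scaled(self, factors: Mapping[tuple[str, str], float]) -> "NetworkSpec":
        """Return a copy with coupling coefficients on (source, target) edges
        multiplied by the given factors."""
        factors = dict(factors)
        known = {(c.source, c.target) for c in self.coupling}
        unknown = set(factors) - known
        if unknown:
            raise ValueError(f"no coupling on edges {sorted(unknown)}")
        new = tuple(
            replace(c, coeff=c.coeff * factors.get((c.source, c.target), 1.0))
            for c in self.coupling
        )
        return replace(self, coupling=new)


@dataclass
class ConditionPairSpec:
    """A base network plus per-condition top-down coupling modifications.

    ``condition_deltas`` maps condition name -> {(source, target): factor}.
    Only top-down edges may differ between conditions, so downstream decoding
    cannot exploit anything but the top-down coupling pattern.
    """

    base: NetworkSpec
    condition_deltas: dict[str, dict[tuple[str, str], float]] | None = None
    trials_per_condition: int = 1000
    samples_per_trial: int = 17
    seed: int = 0
    burn_in: int = 200

    def __post_init__(self) -> None:
        if self.samples_per_trial < 1:
            raise ValueError("samples_per_trial must be >= 1")
        if self.trials_per_condition < 0:
            raise ValueError("trials_per_condition must be >= 0")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.condition_deltas:
            topdown = {
                (c.source, c.target)
                for c in self.base.coupling
                if self.base.is_top_down(c)
            }
            for name, deltas in self.condition_deltas.items():
                offending = set(deltas) - topdown
                if offending:
                    raise ValueError(
                        f"condition {name!r} modifies non-top-down edges "
                        f"{sorted(offending)}; only top-down couplings may "
                        "differ between conditions"
                    )

    @property
    def sampling_rate(self) -> float:
        return self.base.sampling_rate

    def condition_specs(self) -> dict[str, NetworkSpec]:
        if not self.condition_deltas:
            return {"none": self.base}
        return {
            name: self.base.with_coupling_scaled(deltas)
            for name, deltas in self.condition_deltas.items()
        }


def companion_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix for coefficients (p, k, k)."""
    p, k, _ = coeffs.shape
    comp = np.zeros((p * k, p * k))
    comp[:k, :] = np.concatenate(coeffs, axis=1)
    if p > 1:
        comp[k:, : (p - 1) * k] = np.eye((p - 1) * k)
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def build_var(spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Exact VAR realization of a :class:`NetworkSpec`.

    Returns ``(coeffs, noise_cov)`` with ``coeffs[i]`` the lag-(i+1)
    coefficient matrix (``coeffs[i][target, source]``). Each channel carries
    the AR(2) oscillator ``a1 = 2 r cos(2 pi f / rate)``, ``a2 = -r^2``;
    cross-channel couplings are added at their stated lags. Raises
    :class:`StationarityError` if the companion matrix has spectral radius
    >= 1.
    """
    k = spec.n_channels
    max_lag = max([2] + [c.lag for c in spec.coupling])
    coeffs = np.zeros((max_lag, k, k))
    r = spec.osc_damping
    if r > 0.0:
        theta = 2.0 * np.pi * spec.osc_freq / spec.sampling_rate
        a1 = 2.0 * r * np.cos(theta)
        a2 = -(r**2)
        for i in range(k):
            coeffs[0, i, i] = a1
            coeffs[1, i, i] = a2
    labels = spec.channel_labels
    index = {c: i for i, c in enumerate(labels)}
    for c in spec.coupling:
        coeffs[c.lag - 1, index[c.target], index[c.source]] += c.coeff
    radius = companion_radius(coeffs)
    if radius >= 1.0:
        raise StationarityError(radius)
    return coeffs, spec.noise_cov.copy()


def _simulate_var_batch(
    coeffs: np.ndarray,
    noise_chol: np.ndarray,
    n_trials: int,
    n_samples: int,
    burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n_trials`` independent VAR realizations (vectorized over
    trials). Returns (trials, channels, samples) with burn-in discarded."""
    p, k, _ = coeffs.shape
    total = burn_in + n_samples
    eps = rng.standard_normal((total, n_trials, k)) @ noise_chol.T
    x = np.zeros((total, n_trials, k))
    coeffs_t = coeffs.transpose(0, 2, 1)  # for right-multiplication
    for t in range(total):
        acc = eps[t]
        for i in range(min(p, t)):
            acc = acc + x[t - i - 1] @ coeffs_t[i]
        x[t] = acc
    out = x[burn_in:].transpose(1, 2, 0)
    if not np.all(np.isfinite(out)):
        raise StationarityError(np.inf, "simulation produced non-finite values "
                                "(stationarity violation)")
    return np.ascontiguousarray(out)


def pink_noise(
    n_trials: int, n_channels: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """1/f-like noise via a fixed first-order IIR cascade, unit-ish variance.

    A 200-sample pre-roll absorbs the filter transient.
    """
    pre = 200
    white = rng.standard_normal((n_trials, n_channels, pre + n_samples))
    pinked = lfilter(_PINK_B, _PINK_A, white, axis=-1)[..., pre:]
    return pinked / np.std(pinked) if pinked.size else pinked


def simulate_trials(spec: ConditionPairSpec) -> TrialEnsemble:
    """Draw a labeled two-condition (or unlabeled) trial ensemble.

    Trials are independent realizations: each trial gets its own burn-in,
    which is discarded. Pink noise, if requested, is added per channel after
    the VAR simulation; instantaneous mixing, if specified, is applied last.
    Identical seeds give bit-identical output.
    """
    rng_root = np.random.default_rng(spec.seed)
    cond_specs = spec.condition_specs()
    streams = rng_root.spawn(len(cond_specs))

    blocks: list[np.ndarray] = []
    labels: list[str] = []
    k = spec.base.n_channels
    for (name, net), rng in zip(cond_specs.items(), streams):
        coeffs, noise_cov = build_var(net)
        chol = np.linalg.cholesky(noise_cov)
        n = spec.trials_per_condition
        if n == 0:
            data = np.zeros((0, k, spec.samples_per_trial))
        else:
            data = _simulate_var_batch(
                coeffs, chol, n, spec.samples_per_trial, spec.burn_in, rng
            )
            if net.pink_noise_gain != 0.0:
                data = data + net.pink_noise_gain * pink_noise(
                    n, k, spec.samples_per_trial, rng
                )
            if net.mixing is not None:
                data = np.einsum("ij,njs->nis", net.mixing, data)
        blocks.append(data)
        labels.extend([name] * data.shape[0])

    data = np.concatenate(blocks, axis=0) if blocks else np.zeros((0, k, spec.samples_per_trial))
    return TrialEnsemble(
        data=data,
        sampling_rate=spec.sampling_rate,
        channel_labels=spec.base.channel_labels,
        areas=spec.base.areas,
        conditions=np.array(labels, dtype=object),
    )


def canonical_network(
    topdown: Sequence[tuple[str, str, float]] = (("H1", "L1", 0.25), ("H2", "L2", 0.15)),
    **overrides,
) -> NetworkSpec:
    """The 3-lower / 2-higher 16 Hz reference network used across the test
    suite and the shipped example configs (top-down lag-1 couplings only)."""
    kwargs = dict(
        n_lower=3,
        n_higher=2,
        osc_freq=16.0,
        osc_damping=0.9,
        coupling=tuple(Coupling(s, t, c, 1) for s, t, c in topdown),
        sampling_rate=200.0,
    )
    kwargs.update(overrides)
    return NetworkSpec(**kwargs)


def decoding_benchmark_spec(
    trials_per_condition: int = 2000,
    seed: int = 11,
    contrast: float = 0.3,
    identical: bool = False,
) -> ConditionPairSpec:
    """Two-condition benchmark for decoder validation.

    Same structure as the canonical network but with a sharp resonance
    (pole radius 0.97), weak top-down couplings and a strong 1/f
    background, so that directed influence is confined to a narrow beta
    band and its magnitude is comparable to estimation noise — the regime
    in which the frequency-specificity (random-frequency) control is
    expected to sit at chance. Conditions differ by ``+/- contrast`` on the
    H1 -> L1 coupling (or not at all when ``identical``).
    """
    net = canonical_network(
        topdown=(("H1", "L1", 0.018), ("H2", "L2", 0.013)),
        osc_damping=0.97,
        pink_noise_gain=2.0,
    )
    c = 0.0 if identical else contrast
    deltas = {
        "contingency1": {("H1", "L1"): 1.0 + c},
        "contingency2": {("H1", "L1"): 1.0 - c},
    }
    return ConditionPairSpec(
        base=net,
        condition_deltas=deltas,
        trials_per_condition=trials_per_condition,
        samples_per_trial=17,
        seed=seed,
    )
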