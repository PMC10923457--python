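"""Synthetic in vitro power sweeps.

Emulates the tissue-cutting bench experiment: the knife is run at a set of
power levels (20-80 W in 10 W steps by default) and tip temperature, net
waste-gas flow, tar and particle formation rates are recorded.  Responses
are drawn from the calibration polynomials as ground truth with
multiplicative Gaussian noise,

    y = truth(P) * (1 + e),   e ~ N(0, noise_cv^2),

clamped at zero.  Multiplicative noise is the natural model here because
the four responses span several orders of magnitude; the original study
reports no replicate counts or uncertainties, so the default coefficient of
variation (0.02) is a declared assumption.

Each response draws from its own child seed of the design seed, so adding
a response never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

from .empirical import CalibrationSet, PowerSweepRecord, fit_calibration

__all__ = ["SweepDesign", "generate_sweep", "recovery_experiment"]

DEFAULT_POWERS = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0)

_RESPONSES = ("tip_temp", "waste_gas_flow", "tar_rate", "particle_rate")


@dataclass(frozen=True)
class SweepDesign:
    """Design of one synthetic power-sweep experiment."""

    powers: tuple[float, ...] = DEFAULT_POWERS
    noise_cv: float = 0.02
    seed: int = 0
    replicate_count: int = 1

    def __post_init__(self) -> None:
        p = tuple(float(v) for v in self.powers)
        if any(v <= 0 for v in p) or len(set(p)) != len(p):
            raise ValueError("powers must be positive and distinct")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        object.__setattr__(self, "powers", p)


def _truth_table(design: SweepDesign, truth: CalibrationSet) -> dict[str, np.ndarray]:
    p = np.asarray(design.powers)
    return {
        "tip_temp": npoly.polyval(p, truth.temp_coeffs),
        "waste_gas_flow": npoly.polyval(p, truth.flow_coeffs),
        # refitting must see the raw (unclamped) cubic, noise is applied to it
        "particle_rate": npoly.polyval(p, truth.particle_coeffs),
        "tar_rate": npoly.polyval(p, truth.tar_coeffs),
    }


def generate_sweep(design: SweepDesign,
                   truth: CalibrationSet | None = None) -> list[PowerSweepRecord]:
    """Generate one synthetic sweep: ``replicate_count`` records per power.

    Deterministic for a fixed ``design.seed``.  Responses are clamped at
    zero after the noise is applied, so records always satisfy the
    non-negativity invariants of :class:`PowerSweepRecord`.
    """
    truth = truth or CalibrationSet()
    table = _truth_table(design, truth)
    ss = np.random.SeedSequence(design.seed)
    streams = {name: np.random.default_rng(child)
               for name, child in zip(_RESPONSES, ss.spawn(len(_RESPONSES)))}
    n_p, n_r = len(design.powers), design.replicate_count
    noisy = {}
    for name in _RESPONSES:
        eps = streams[name].normal(0.0, design.noise_cv, size=(n_r, n_p)) \
            if design.noise_cv > 0 else np.zeros((n_r, n_p))
        noisy[name] = np.maximum(table[name][None, :] * (1.0 + eps), 0.0)
    records = []
    for r in range(n_r):
        for i, p in enumerate(design.powers):
            records.append(PowerSweepRecord(
                power=p,
                tip_temp=float(noisy["tip_temp"][r, i]),
                waste_gas_flow=float(noisy["waste_gas_flow"][r, i]),
                tar_rate=float(noisy["tar_rate"][r, i]),
                particle_rate=float(noisy["particle_rate"][r, i]),
            ))
    return records


def recovery_experiment(design: SweepDesign, truth: CalibrationSet | None = None,
                        trials: int = 100):
    """Monte-Carlo parameter-recovery study: generate -> fit, repeatedly.

    Returns a pandas DataFrame with one row per polynomial coefficient and
    columns ``truth``, ``bias``, ``rmse``, ``se`` (standard error of the
    bias estimate over trials).
    """
    import pandas as pd

    if trials < 1:
        raise ValueError("trials must be >= 1")
    truth = truth or CalibrationSet()
    names = ["temp_coeffs", "flow_coeffs", "particle_coeffs", "tar_coeffs"]
    est: dict[tuple[str, int], list[float]] = {}
    for t in range(trials):
        d = SweepDesign(powers=design.powers, noise_cv=design.noise_cv,
                        seed=design.seed + t, replicate_count=design.replicate_count)
        fitted, _ = fit_calibration(generate_sweep(d, truth))
        for name in names:
            for j, c in enumerate(getattr(fitted, name)):
                est.setdefault((name, j), []).append(c)
    rows = []
    for name in names:
        true_c = getattr(truth, name)
        for j, tc in enumerate(true_c):
            e = np.asarray(est[(name, j)])
            rows.append({
                "response": name, "order": j, "truth": tc,
                "bias": float(e.mean() - tc),
                "rmse": float(np.sqrt(np.mean((e - tc) ** 2))),
                "se": float(e.std(ddof=1) / np.sqrt(trials)) if trials > 1 else 0.0,
            })
    return pd.DataFrame(rows)
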