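"""Synthetic drug-screen cohorts with planted biomarker-sensitivity structure.

The generator emulates an ex-vivo screen paired with binary lesion calls:
each drug has a baseline potency (log10 µM), selected (lesion, drug) pairs
carry a planted carrier-specific sensitivity shift, measurement noise is
Gaussian on the log10 scale, and cells go missing completely at random.
Effects are additive on log10 IC50 — the simplest generative structure the
downstream rank tests and the IC50* transform assume.

Default parameters define the reference study conditions used throughout
the test-bench: a 200-patient, 30-drug, 12-lesion cohort with three
planted pairs of shift 2 log10 units, noise SD 0.4, 5% missingness, and
planted prevalences 0.30 / 0.15 / 0.20 — prevalences chosen so the three
subgroups stack into a depth-4 decision list with a well-populated
default level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import LesionMatrix, ResponseMatrix

__all__ = ["SyntheticTruth", "generate_cohort", "DEFAULT_PLANTED_DELTA"]

#: planted carrier sensitivity shift, log10 IC50 units
DEFAULT_PLANTED_DELTA = 2.0
#: reference prevalences of the three planted lesions
DEFAULT_PLANTED_PREVALENCES = (0.30, 0.15, 0.20)
#: log10-scale measurement noise SD
DEFAULT_SIGMA = 0.4
#: missing-completely-at-random cell rate
DEFAULT_MISSING_RATE = 0.05
#: background prevalence of non-planted lesions
DEFAULT_BACKGROUND_PREVALENCE = 0.10

_IC50_FLOOR_UM = 1e-3
_IC50_CEIL_UM = 10.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted: tuple[tuple[str, str, float], ...]  # (lesion, drug, delta)
    prevalences: dict[str, float]
    mu: dict[str, float]  # drug -> baseline log10 IC50 (µM)
    sigma: float
    missing_rate: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "planted": [list(t) for t in self.planted],
            "prevalences": self.prevalences,
            "mu": self.mu,
            "sigma": self.sigma,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }


def _default_planted(T: int, B: int) -> list[tuple[int, int, float]]:
    k = min(3, T, B)
    return [(i, i, DEFAULT_PLANTED_DELTA) for i in range(k)]


def generate_cohort(
    P: int = 200,
    T: int = 30,
    B: int = 12,
    planted: list[tuple[int, int, float]] | None = None,
    prevalences: dict[int, float] | None = None,
    mu: np.ndarray | None = None,
    sigma: float = DEFAULT_SIGMA,
    missing_rate: float = DEFAULT_MISSING_RATE,
    mutually_exclusive: list[tuple[int, int]] | None = None,
    seed: int = 0,
) -> tuple[ResponseMatrix, LesionMatrix, SyntheticTruth]:
    """Generate a cohort of P patients, T drugs, B lesions.

    Parameters
    ----------
    planted
        (lesion index, drug index, delta) triples; carriers of the lesion
        have their log10 IC50 for the drug lowered by delta.  Defaults to
        three pairs (lesion i -> drug i) with delta 2.
    prevalences
        Bernoulli carrier probability per lesion index; planted lesions
        default to 0.30/0.15/0.20, others to 0.10.
    mu
        Per-drug baseline log10 IC50 (µM); default drawn N(0, 0.5).
    mutually_exclusive
        Optional lesion-index pairs forced never to co-occur (the second
        lesion is zeroed wherever the first is present).
    """
    if min(P, T, B) < 1:
        raise ValueError("P, T and B must all be >= 1")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if planted is None:
        planted = _default_planted(T, B)
    for b, t, delta in planted:
        if not (0 <= b < B and 0 <= t < T):
            raise ValueError(f"planted pair ({b}, {t}) out of range")
        if delta < 0:
            raise ValueError("planted deltas must be >= 0")

    prev = np.full(B, DEFAULT_BACKGROUND_PREVALENCE)
    for rank, (b, _, _) in enumerate(planted):
        prev[b] = DEFAULT_PLANTED_PREVALENCES[
            min(rank, len(DEFAULT_PLANTED_PREVALENCES) - 1)
        ]
    for b, frac in (prevalences or {}).items():
        if not 0 < frac < 1:
            raise ValueError("prevalences must be in (0, 1)")
        prev[b] = frac

    drug_ids = [f"D{i:02d}" for i in range(T)]
    lesion_ids = [f"L{i:02d}" for i in range(B)]
    patient_ids = [f"P{i:03d}" for i in range(P)]

    status = (rng.random((B, P)) < prev[:, None]).astype(np.int8)
    for a, b in mutually_exclusive or []:
        status[b, status[a] == 1] = 0

    if mu is None:
        mu_arr = rng.normal(0.0, 0.5, size=T)
    else:
        mu_arr = np.asarray(mu, dtype=float)
        if mu_arr.shape != (T,):
            raise ValueError("mu must have one baseline per drug")

    log_ic50 = np.tile(mu_arr[:, None], (1, P)) + rng.normal(0.0, sigma, (T, P))
    for b, t, delta in planted:
        log_ic50[t] -= delta * status[b]

    raw = np.power(10.0, log_ic50)
    out_of_range = (raw > _IC50_CEIL_UM) | (raw < _IC50_FLOOR_UM)
    if out_of_range.mean() > 0.10:
        warnings.warn(
            f"{out_of_range.mean():.0%} of generated IC50s fall outside "
            f"({_IC50_FLOOR_UM}, {_IC50_CEIL_UM}] µM and were clipped"
        )
    values = np.clip(raw, _IC50_FLOOR_UM, _IC50_CEIL_UM)

    if missing_rate > 0:
        mask = rng.random((T, P)) < missing_rate
        values = values.astype(float)
        values[mask] = np.nan

    resp = ResponseMatrix(
        pd.DataFrame(values, index=drug_ids, columns=patient_ids)
    )
    lesions = LesionMatrix(
        pd.DataFrame(status, index=lesion_ids, columns=patient_ids)
    )
    truth = SyntheticTruth(
        planted=tuple(
            (lesion_ids[b], drug_ids[t], float(d)) for b, t, d in planted
        ),
        prevalences={lesion_ids[i]: float(prev[i]) for i in range(B)},
        mu={drug_ids[i]: float(mu_arr[i]) for i in range(T)},
        sigma=float(sigma),
        missing_rate=float(missing_rate),
        seed=int(seed),
    )
    return resp, lesions, truth
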