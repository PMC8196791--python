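"""Synthetic CGM scenarios with known compositional structure.

Real CGM study data are rarely shareable, so every stage of the pipeline
is exercised on simulated patients whose ground truth is known: a patient
is described by archetype time-in-range compositions for each 24-h day
category and each 6-h period category, log-ratio noise around the
archetypes, a per-anchor transition kernel from day categories to the
category of the following 6-h period, and a missing-at-random sample drop
rate.  Minute-level traces are synthesized so that re-deriving the
composition from the trace recovers the target exactly (after rounding
minutes to whole 5-min samples).

The default scenario emulates the qualitative structure reported for
T1D patients: a hypoglycemia-prone day type (V), a level-1-hypo day type
(W), a well-controlled day type (X) and a hyperglycemia-dominated day
type (Y), with 6-h categories A (hypo-exposed), B (in-target with traces
of hypoglycemia), C (mildly elevated) and D (strongly hyperglycemic).
Category names follow the letter convention used downstream: within each
duration, archetypes are ordered by decreasing first balance (hypo-
dominant first).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cgm_io import CGMSeries
from .composition import Composition, close
from .coordinates import ilr_inverse, ilr_transform

#: glucose bands used to draw sample values inside each range (mg/dL);
#: CGM sensors clip near 40 and 400, hence the outer bounds
TRACE_BANDS = ((40.0, 54.0), (54.0, 70.0), (70.0, 180.0),
               (np.nextafter(180.0, 400), 250.0), (np.nextafter(250.0, 400), 400.0))


def _closed(parts, C) -> np.ndarray:
    return np.asarray(close(np.asarray(parts, dtype=float), C))


@dataclass(frozen=True)
class PatientScenario:
    """Ground-truth description of one simulated patient."""

    archetypes_24h: dict[str, np.ndarray]
    archetypes_6h: dict[str, np.ndarray]
    day_frequencies: dict[str, float]
    kernels: dict[str, pd.DataFrame]   # anchor "HH:MM" -> row-stochastic matrix
    noise_scale: float = 0.3
    missingness: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        a24 = {k: _closed(v, 1440.0) for k, v in self.archetypes_24h.items()}
        a6 = {k: _closed(v, 360.0) for k, v in self.archetypes_6h.items()}
        for name, arr in {**a24, **a6}.items():
            if np.any(arr <= 0):
                raise ValueError(f"archetype {name!r} must be strictly positive")
        freqs = {k: float(v) for k, v in self.day_frequencies.items()}
        if set(freqs) != set(a24) or abs(sum(freqs.values()) - 1) > 1e-9:
            raise ValueError("day frequencies must cover the 24-h archetypes and sum to 1")
        kernels = {}
        for anchor, K in self.kernels.items():
            K = pd.DataFrame(K).astype(float)
            if set(K.index) != set(a24) or set(K.columns) != set(a6):
                raise ValueError(f"kernel at {anchor} must map day to 6-h categories")
            if np.any(K.to_numpy() < 0) or not np.allclose(K.sum(axis=1), 1.0):
                raise ValueError(f"kernel at {anchor} must be row-stochastic")
            kernels[anchor] = K
        if not (0 <= self.missingness < 0.3):
            raise ValueError("missingness must be in [0, 0.3)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        object.__setattr__(self, "archetypes_24h", a24)
        object.__setattr__(self, "archetypes_6h", a6)
        object.__setattr__(self, "day_frequencies", freqs)
        object.__setattr__(self, "kernels", kernels)

    @property
    def day_categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.archetypes_24h))

    @property
    def period_categories(self) -> tuple[str, ...]:
        return tuple(sorted(self.archetypes_6h))

    @classmethod
    def default(cls, seed: int | None = None,
                missingness: float = 0.05) -> "PatientScenario":
        """A four-day-category, four-period-category T1D-like patient."""
        archetypes_24h = {
            "V": (40.0, 60.0, 880.0, 380.0, 80.0),
            "W": (1.0, 45.0, 1075.0, 300.0, 19.0),
            "X": (0.05, 1.0, 1250.0, 180.0, 8.95),
            "Y": (0.02, 0.8, 700.0, 560.0, 179.18),
        }
        archetypes_6h = {
            "A": (3.0, 25.0, 325.0, 6.0, 1.0),
            "B": (0.4, 1.6, 355.0, 2.0, 1.0),
            "C": (0.02, 0.1, 250.0, 108.0, 1.88),
            "D": (0.03, 0.08, 40.0, 225.0, 94.89),
        }
        day_frequencies = {"V": 0.2, "W": 0.3, "X": 0.3, "Y": 0.2}
        kernel = pd.DataFrame(
            [
                [0.55, 0.20, 0.15, 0.10],
                [0.50, 0.30, 0.10, 0.10],
                [0.10, 0.60, 0.10, 0.20],
                [0.05, 0.30, 0.55, 0.10],
            ],
            index=["V", "W", "X", "Y"],
            columns=["A", "B", "C", "D"],
        )
        kernels = {a: kernel.copy() for a in ("00:00", "06:00", "12:00", "18:00")}
        return cls(archetypes_24h, archetypes_6h, day_frequencies, kernels,
                   noise_scale=0.3, missingness=missingness, seed=seed)


def sample_composition(archetype, noise_scale: float, rng) -> Composition:
    """Perturb an archetype by additive Gaussian noise in ilr space.

    The perturbation is applied to the ilr coordinates and mapped back to
    the simplex, so the sample is strictly positive by construction and
    closes to the archetype's total.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(archetype, dtype=float)
    y = ilr_transform(a)
    y = y + rng.normal(0.0, noise_scale, size=y.shape)
    return ilr_inverse(y, C=a.sum())


def largest_remainder_counts(minutes, cadence: float = 5.0) -> np.ndarray:
    """Round minutes-per-range to whole sample counts preserving the total.

    Floors each quotient and hands the remaining samples to the largest
    fractional parts (ties to the lower index), so counts always sum to
    ``total_minutes / cadence``.
    """
    q = np.asarray(minutes, dtype=float) / cadence
    total = int(round(q.sum()))
    base = np.floor(q).astype(int)
    short = total - base.sum()
    if short > 0:
        frac = q - base
        order = np.lexsort((np.arange(len(q)), -frac))
        base[order[:short]] += 1
    return base


def trace_for_composition(target, duration: float | None = None,
                          cadence: int = 5, rng=None,
                          start: dt.datetime | None = None):
    """Synthesize a CGM trace realizing a target composition.

    Each range receives ``round(target_i / cadence)`` samples by largest-
    remainder rounding; values are drawn uniformly inside the range's
    glucose band.  Returns ``(times, glucose)``; re-deriving the
    composition from the trace gives exactly the rounded target.
    """
    t = np.asarray(target, dtype=float)
    total = t.sum()
    if duration is not None and abs(total - duration) > 1e-6:
        raise ValueError(f"target closes to {total} min but duration={duration}")
    rng = np.random.default_rng(rng)
    counts = largest_remainder_counts(t, cadence)
    values = np.concatenate([
        rng.uniform(lo, hi, size=c) for (lo, hi), c in zip(TRACE_BANDS, counts)
    ])
    if start is None:
        start = dt.datetime(2021, 1, 1)
    times = (np.datetime64(start, "ns")
             + np.arange(len(values)) * np.timedelta64(cadence * 60_000_000_000, "ns"))
    return times, values


@dataclass(frozen=True)
class SimulatedPatient:
    """A generated CGM series together with its ground truth."""

    series: CGMSeries
    day_categories: tuple[str, ...]       # category of each day (00:00-24:00)
    follower_categories: tuple[str, ...]  # category of first 6 h of each next day
    scenario: PatientScenario


def generate_patient(scenario: PatientScenario, n_days: int,
                     start: dt.datetime | None = None,
                     patient_id: str = "synthetic") -> SimulatedPatient:
    """Simulate a patient's CGM series with embedded transition structure.

    Day categories are drawn i.i.d. from the scenario frequencies.  The
    first 6-h block of each day after the first is generated from the 6-h
    archetype of the category drawn from the 00:00 transition kernel given
    the previous day's category; the remaining 18 h realize the day's own
    archetype.  Missing samples are dropped MCAR at the scenario rate.
    Identical seeds give byte-identical output.
    """
    if start is None:
        start = dt.datetime(2021, 1, 1)
    if start.time() != dt.time(0):
        raise ValueError("series must start at 00:00")
    rng = np.random.default_rng(scenario.seed)
    cats = scenario.day_categories
    freqs = np.asarray([scenario.day_frequencies[c] for c in cats])
    day_cats = rng.choice(cats, size=n_days, p=freqs)
    kernel = scenario.kernels["00:00"]

    all_times, all_values = [], []
    followers = []
    for d in range(n_days):
        day_start = start + dt.timedelta(days=d)
        if d == 0:
            comp = sample_composition(scenario.archetypes_24h[day_cats[0]],
                                      scenario.noise_scale, rng)
            t, v = trace_for_composition(comp, 1440, rng=rng, start=day_start)
            all_times.append(t); all_values.append(v)
        else:
            prev = day_cats[d - 1]
            p_row = kernel.loc[prev].to_numpy()
            follower = rng.choice(kernel.columns.to_numpy(), p=p_row)
            followers.append(str(follower))
            comp6 = sample_composition(scenario.archetypes_6h[follower],
                                       scenario.noise_scale, rng)
            t6, v6 = trace_for_composition(comp6, 360, rng=rng, start=day_start)
            comp18 = close(sample_composition(scenario.archetypes_24h[day_cats[d]],
                                              scenario.noise_scale, rng), 1080)
            t18, v18 = trace_for_composition(
                comp18, 1080, rng=rng, start=day_start + dt.timedelta(hours=6)
            )
            all_times.extend([t6, t18]); all_values.extend([v6, v18])

    times = np.concatenate(all_times)
    values = np.concatenate(all_values)
    if scenario.missingness > 0:
        keep = rng.random(len(times)) >= scenario.missingness
        times, values = times[keep], values[keep]
    series = CGMSeries(patient_id, times, values)
    return SimulatedPatient(series, tuple(day_cats.tolist()), tuple(followers),
                            scenario)


@dataclass(frozen=True)
class SimulatedPairs:
    """Composition-level (24-h, following 6-h) pairs with ground truth."""

    compositions_24h: np.ndarray   # (n, 5) minutes, closed to 1440
    compositions_6h: np.ndarray    # (n, 5) minutes, closed to 360
    day_categories: tuple[str, ...]
    follower_categories: tuple[str, ...]


def sample_pairs(scenario: PatientScenario, n_pairs: int,
                 anchor: str = "00:00", rng=None) -> SimulatedPairs:
    """Draw i.i.d. (day category, follower category) pairs from the
    scenario kernel and realize both as noisy archetype compositions."""
    rng = np.random.default_rng(scenario.seed if rng is None else rng)
    cats = scenario.day_categories
    freqs = np.asarray([scenario.day_frequencies[c] for c in cats])
    kernel = scenario.kernels[anchor]
    day_cats = rng.choice(cats, size=n_pairs, p=freqs)
    comp24, comp6, followers = [], [], []
    for c in day_cats:
        follower = rng.choice(kernel.columns.to_numpy(), p=kernel.loc[c].to_numpy())
        followers.append(str(follower))
        comp24.append(np.asarray(sample_composition(
            scenario.archetypes_24h[c], scenario.noise_scale, rng)))
        comp6.append(np.asarray(sample_composition(
            scenario.archetypes_6h[follower], scenario.noise_scale, rng)))
    return SimulatedPairs(np.asarray(comp24), np.asarray(comp6),
                          tuple(day_cats.tolist()), tuple(followers))


def scenario_to_yaml(scenario: PatientScenario, path) -> None:
    payload = {
        "archetypes_24h": {k: v.tolist() for k, v in scenario.archetypes_24h.items()},
        "archetypes_6h": {k: v.tolist() for k, v in scenario.archetypes_6h.items()},
        "day_frequencies": scenario.day_frequencies,
        "kernels": {
            a: {"index": list(K.index), "columns": list(K.columns),
                "values": K.to_numpy().tolist()}
            for a, K in scenario.kernels.items()
        },
        "noise_scale": scenario.noise_scale,
        "missingness": scenario.missingness,
        "seed": scenario.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def scenario_from_yaml(path) -> PatientScenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kernels = {
        a: pd.DataFrame(K["values"], index=K["index"], columns=K["columns"])
        for a, K in d["kernels"].items()
    }
    return PatientScenario(
        archetypes_24h=d["archetypes_24h"],
        archetypes_6h=d["archetypes_6h"],
        day_frequencies=d["day_frequencies"],
        kernels=kernels,
        noise_scale=float(d.get("noise_scale", 0.3)),
        missingness=float(d.get("missingness", 0.05)),
        seed=d.get("seed"),
    )
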