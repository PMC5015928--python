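"""Simulation study of the power to detect selection from temporal samples.

For a haploid Wright-Fisher population of constant size N sampled at a
fixed generation schedule, each grid cell crosses a selection coefficient
with an initial favored-allele frequency and an observation mode (census,
or binomial sampling at per-timepoint depths).  Power at a given false
positive rate is estimated by simulating matched selected and neutral
arms: the detection threshold for each statistic is the (1 - fpr) quantile
of the neutral arm's |statistic|, and power is the percentage of selected
loci exceeding it.  Absolute values are used throughout because the
polarity of selection relative to the tracked allele is unknown in real
data.  Fixation truncation applies to delta f and Fst; the logistic slope
uses all timepoints and is fitted on unweighted proportions, matching the
convention of the scan statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import (DEFAULT_GENERATIONS, SamplingSchedule,
                       observe_frequencies, wright_fisher_frequencies)
from .temporal import (delta_f_many, fst_many, logistic_beta_many,
                       timepoints_used)

#: per-timepoint sample sizes of the reference sampled design
STUDY_SAMPLE_SIZES = (31, 28, 59, 59, 22)

STATISTICS = ("delta_f", "logistic_beta", "fst")


@dataclass
class PowerGridResult:
    """Tidy power table plus the thresholds and settings that produced it."""

    table: pd.DataFrame          # statistic, s, p0, sampling, power, threshold
    reps: int
    fpr: float
    N: int
    seed: int

    def average_power(self) -> pd.DataFrame:
        """Mean power over the (s, p0) cells, per statistic and mode."""
        return (self.table.groupby(["statistic", "sampling"])["power"]
                .mean().reset_index(name="average_power"))

    def pivot(self, sampling: str) -> pd.DataFrame:
        """Statistic x (p0, s) layout for one sampling mode."""
        sub = self.table[self.table["sampling"] == sampling]
        return sub.pivot_table(index="statistic", columns=["p0", "s"],
                               values="power")


def _cell_statistics(obs: np.ndarray, pop: np.ndarray,
                     generations) -> dict[str, np.ndarray]:
    # fixation truncation follows the true population path, which the
    # simulation knows; the allele -- not its noisy sample estimate --
    # is what reaches fixation
    n_used = timepoints_used(pop)
    slopes, _ = delta_f_many(obs, generations, n_used=n_used)
    betas, _ = logistic_beta_many(obs, generations, weights=None)
    fst, _ = fst_many(obs, n_used=n_used)
    return {"delta_f": np.abs(slopes), "logistic_beta": np.abs(betas),
            "fst": np.abs(fst)}


def simulate_arm(N: int, s: float, p0: float, schedule: SamplingSchedule,
                 reps: int, rng, sampling_method: str = "hypergeometric"):
    """(observed, population) frequencies for one simulation arm.

    Sampled observation draws distinct lines without replacement from the
    N-line population by default (``sampling_method="binomial"`` for
    with-replacement draws).
    """
    gens = np.asarray(schedule.generations)
    pop = wright_fisher_frequencies(N, s, p0, int(gens.max()), reps=reps,
                                    seed=rng)[:, gens]
    obs = observe_frequencies(pop, schedule, seed=rng,
                              method=sampling_method, N=N)
    return obs, pop


def power_cell(N: int, s: float, p0: float, schedule: SamplingSchedule,
               reps: int, fpr: float, rng,
               sampling_method: str = "hypergeometric"
               ) -> dict[str, tuple[float, float]]:
    """Power (%) and threshold per statistic for one (s, p0, mode) cell.

    The neutral arm is simulated at the same initial frequency; the
    threshold is the (1 - fpr) quantile of the neutral |statistic|.
    """
    gens = np.asarray(schedule.generations)
    sel, sel_pop = simulate_arm(N, s, p0, schedule, reps, rng,
                                sampling_method)
    neu, neu_pop = simulate_arm(N, 0.0, p0, schedule, reps, rng,
                                sampling_method)
    sel_stats = _cell_statistics(sel, sel_pop, gens)
    neu_stats = _cell_statistics(neu, neu_pop, gens)
    out = {}
    for stat in STATISTICS:
        neutral = neu_stats[stat]
        if np.allclose(neutral, neutral[0]):
            out[stat] = (0.0, float(neutral[0]))  # degenerate null
            continue
        thr = float(np.quantile(neutral, 1.0 - fpr))
        power = 100.0 * float(np.mean(sel_stats[stat] > thr))
        out[stat] = (power, thr)
    return out


def run_power_grid(s_values=(0.02, 0.05, 0.1), p0_values=(0.2, 0.5, 0.8),
                   N: int = 200, generations=DEFAULT_GENERATIONS,
                   sampling=("census", "sampled"),
                   sample_sizes=STUDY_SAMPLE_SIZES,
                   reps: int = 5000, fpr: float = 0.05,
                   seed: int = 0,
                   sampling_method: str = "hypergeometric") -> PowerGridResult:
    """Full power grid over selection strength, start frequency and mode.

    ``sampling`` may contain ``"census"`` (sample frequency equals
    population frequency) and/or ``"sampled"`` (binomial observation at
    ``sample_sizes``).  Results are reproducible bit-for-bit for a given
    seed; each cell consumes an independent child RNG stream.
    """
    if reps < 1:
        raise ValueError("reps must be positive")
    modes = {}
    for mode in sampling:
        if mode == "census":
            modes[mode] = SamplingSchedule(tuple(generations), None)
        elif mode == "sampled":
            modes[mode] = SamplingSchedule(tuple(generations),
                                           tuple(sample_sizes))
        else:
            raise ValueError(f"unknown sampling mode {mode!r}")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(modes) * len(s_values) * len(p0_values)))
    rows = []
    for mode, schedule in modes.items():
        for p0 in p0_values:
            for s in s_values:
                rng = np.random.default_rng(next(children))
                cell = power_cell(N, s, p0, schedule, reps, fpr, rng,
                                  sampling_method)
                for stat, (power, thr) in cell.items():
                    rows.append((stat, s, p0, mode, power, thr))
    table = pd.DataFrame(rows, columns=["statistic", "s", "p0", "sampling",
                                        "power", "threshold"])
    return PowerGridResult(table, reps, fpr, N, seed)
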