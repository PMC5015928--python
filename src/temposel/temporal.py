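"""Time-serial selection statistics on per-locus allele-frequency series.

A decade-stamped panel of inbred lines is treated as sequential samples
from one evolving population.  Release decades map to effective generation
numbers (pre-1970 pool -> 0, then 15, 25, 35, 45), and each locus yields a
short frequency series for the allele that was major in the first cohort.
Three per-locus statistics summarize the series:

* **delta f** -- ordinary least-squares slope of frequency on generation,
  using only timepoints up to and including the first that reaches the
  fixation bounds (<0.05 or >0.95);
* **logistic beta** -- slope of a binomial-family regression of frequency
  on generation (all timepoints);
* **temporal Fst** -- homozygosity contrast between the first and last
  (post-truncation) timepoints.

Batch (`*_many`) variants operate on (loci x timepoints) arrays and are the
workhorses of the power analysis and the genome scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._glm import logistic_slope_many

#: decade cohort -> effective generation number
GENERATION_MAP = {"pre1970s": 0, "1970s": 15, "1980s": 25, "1990s": 35,
                  "2000s": 45}
#: fixation bounds for series truncation
FIXATION_BOUNDS = (0.05, 0.95)


@dataclass
class TemporalFrequencySeries:
    """Observed major-allele frequencies of one locus over the schedule.

    Polarity: the tracked allele is the one that was major in the first
    cohort.  ``sample_sizes`` is None for census observation.
    """

    locus: str
    generations: tuple
    freqs: np.ndarray
    sample_sizes: np.ndarray | None = None
    counts: np.ndarray | None = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.freqs) != len(self.generations):
            raise ValueError("freqs/generations length mismatch")
        if self.sample_sizes is not None:
            self.sample_sizes = np.asarray(self.sample_sizes)
            if len(self.sample_sizes) != len(self.generations):
                raise ValueError("sample_sizes/generations length mismatch")


# ---------------------------------------------------------------------------
# truncation and the three statistics
# ---------------------------------------------------------------------------

def timepoints_used(freqs: np.ndarray, bounds=FIXATION_BOUNDS) -> np.ndarray:
    """Number of leading timepoints retained per locus.

    The first timepoint at which the frequency leaves ``bounds`` (< lo or
    > hi) is included; everything after it is discarded.
    """
    f = np.atleast_2d(freqs)
    fixed = (f < bounds[0]) | (f > bounds[1])
    first = np.where(fixed.any(axis=1), fixed.argmax(axis=1),
                     f.shape[1] - 1)
    return first + 1


def delta_f_many(freqs: np.ndarray, generations,
                 bounds=FIXATION_BOUNDS, n_used=None):
    """OLS slope of frequency on generation, truncated at fixation.

    Returns ``(slopes, n_used)``; loci with fewer than two usable
    timepoints get slope 0 (``n_used`` tells them apart).  ``n_used``
    may be supplied to truncate on an external reference path (e.g. the
    true population frequencies in a simulation study).
    """
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    x = np.asarray(generations, dtype=float)
    if n_used is None:
        n_used = timepoints_used(f, bounds)
    mask = np.arange(f.shape[1])[None, :] < n_used[:, None]
    w = mask.astype(float)
    sw = w.sum(axis=1)
    xbar = (w * x).sum(axis=1) / sw
    ybar = (w * f).sum(axis=1) / sw
    dx = (x[None, :] - xbar[:, None]) * w
    sxx = (dx * dx).sum(axis=1)
    sxy = (dx * (f - ybar[:, None]) * w).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = np.where(sxx > 0, sxy / np.maximum(sxx, 1e-300), 0.0)
    slopes = np.where(n_used >= 2, slopes, 0.0)
    return slopes, n_used


def delta_f(series: TemporalFrequencySeries, bounds=FIXATION_BOUNDS) -> float:
    """Per-generation frequency change of one series (see module docs)."""
    slopes, _ = delta_f_many(series.freqs[None, :], series.generations, bounds)
    return float(slopes[0])


@dataclass
class LogisticBetaResult:
    """Fitted log-odds slope with degeneracy flags."""

    beta: float
    converged: bool
    separated: bool
    weighted: bool

    def __float__(self):
        return float(self.beta)


def logistic_beta_many(freqs: np.ndarray, generations, weights=None):
    """Raw per-locus logistic slopes over all timepoints (no truncation)."""
    return logistic_slope_many(np.atleast_2d(freqs),
                               np.asarray(generations, dtype=float), weights)


def logistic_beta(series: TemporalFrequencySeries,
                  weighted: bool = True) -> LogisticBetaResult:
    """Binomial-GLM slope of frequency on generation.

    With ``weighted=True`` and sample sizes present, the fit uses the
    per-timepoint sample sizes as binomial weights; otherwise plain
    proportions with unit weights (the convention of an R
    ``glm(y ~ x, family=binomial)`` call on frequencies).  Fully fixed
    series (every frequency exactly 0 or 1) are degenerate: beta is
    reported as a signed infinity sentinel with ``separated=True``.
    """
    f = np.asarray(series.freqs, dtype=float)
    use_w = weighted and series.sample_sizes is not None
    w = series.sample_sizes if use_w else None
    separated = bool(np.all((f == 0.0) | (f == 1.0)))
    if separated and (f == f[0]).all():
        beta = math.inf if f[0] == 1.0 else -math.inf
        return LogisticBetaResult(beta, False, True, use_w)
    slopes, conv = logistic_slope_many(f[None, :],
                                       np.asarray(series.generations, float),
                                       w)
    return LogisticBetaResult(float(slopes[0]), bool(conv[0]), separated,
                              use_w)


def fst_many(freqs: np.ndarray, bounds=FIXATION_BOUNDS, n_used=None):
    """Temporal Fst per locus between first and last retained timepoints.

    With homozygosity J(p) = p^2 + (1-p)^2 at the two endpoints,
    ``fst = (J_w - J_b) / (1 - J_b)`` where J_w averages the endpoint
    homozygosities and J_b is the homozygosity of the pooled endpoint
    frequency.  Loci with both endpoints fixed for the same allele
    (J_b = 1) get 0 by convention.
    """
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    if n_used is None:
        n_used = timepoints_used(f, bounds)
    rows = np.arange(f.shape[0])
    p1 = f[rows, 0]
    p2 = f[rows, n_used - 1]
    j1 = p1 ** 2 + (1 - p1) ** 2
    j2 = p2 ** 2 + (1 - p2) ** 2
    jw = (j1 + j2) / 2
    pbar = (p1 + p2) / 2
    jb = pbar ** 2 + (1 - pbar) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(jb < 1.0, (jw - jb) / np.where(jb < 1.0, 1 - jb, 1.0),
                       0.0)
    return fst, n_used


def temporal_fst(series: TemporalFrequencySeries,
                 bounds=FIXATION_BOUNDS) -> float:
    """Temporal Fst of one series (see :func:`fst_many`)."""
    fst, _ = fst_many(series.freqs[None, :], bounds)
    return float(fst[0])


# ---------------------------------------------------------------------------
# building series from a genotype matrix
# ---------------------------------------------------------------------------

def cohort_allele_frequencies(g, population: str,
                              generation_map=None):
    """Per-locus allele-1 frequencies and called-line counts per cohort.

    Returns ``(generations, freq1, n_called, marker_ids)`` where ``freq1``
    and ``n_called`` are (loci x timepoints).  Heterozygous calls
    contribute half an allele; missing calls leave the denominator.
    Raises if any cohort of the population is empty.
    """
    gen_map = dict(generation_map or GENERATION_MAP)
    cohorts = sorted(gen_map, key=gen_map.get)
    sub = g.lines_in(population=population)
    freq_cols, n_cols = [], []
    for cohort in cohorts:
        cg = sub.lines_in(cohort=cohort)
        if cg.n_lines == 0:
            raise ValueError(
                f"cohort {cohort!r} of population {population!r} is empty")
        calls = cg.calls
        dose = np.zeros(calls.shape, dtype=float)
        dose[calls == 1] = 1.0
        dose[calls == 2] = 0.5
        called = calls != -1
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            f1 = np.where(n > 0, (dose * called).sum(axis=0)
                          / np.maximum(n, 1), np.nan)
        freq_cols.append(f1)
        n_cols.append(n)
    gens = tuple(gen_map[c] for c in cohorts)
    return (gens, np.column_stack(freq_cols), np.column_stack(n_cols),
            list(g.markers["marker"]))


def build_frequency_series(g, population: str,
                           initial_freq_range=(0.5, 0.6), *,
                           strict_upper: bool = False,
                           generation_map=None) -> list[TemporalFrequencySeries]:
    """Per-locus major-allele frequency series for one population.

    The tracked allele is the major allele of the first cohort; loci are
    retained when its initial frequency falls in ``initial_freq_range``
    (inclusive bounds, or a strict upper bound with ``strict_upper`` --
    used by the genome scan's "< 0.95" filter).  Loci with any uncallable
    cohort (no genotyped line) are dropped.
    """
    gens, f1, n, markers = cohort_allele_frequencies(g, population,
                                                     generation_map)
    major_is_1 = f1[:, 0] >= 0.5
    fmaj = np.where(major_is_1[:, None], f1, 1.0 - f1)
    lo, hi = initial_freq_range
    f0 = fmaj[:, 0]
    keep = np.isfinite(fmaj).all(axis=1) & (f0 >= lo)
    keep &= (f0 < hi) if strict_upper else (f0 <= hi)
    out = []
    for i in np.flatnonzero(keep):
        out.append(TemporalFrequencySeries(markers[i], gens, fmaj[i], n[i]))
    return out


def series_matrix(series_list):
    """Stack a series list into (freqs, sample_sizes, generations)."""
    if not series_list:
        raise ValueError("no series")
    gens = series_list[0].generations
    freqs = np.vstack([s.freqs for s in series_list])
    if series_list[0].sample_sizes is None:
        sizes = None
    else:
        sizes = np.vstack([s.sample_sizes for s in series_list])
    return freqs, sizes, gens


# ---------------------------------------------------------------------------
# neutral thresholds for the selection scan
# ---------------------------------------------------------------------------

@dataclass
class NeutralThresholds:
    """Simulated neutral |delta f| distribution and its tail threshold."""

    threshold: float
    neutral_abs_delta_f: np.ndarray
    ne: int
    tail: float
    n_sim: int
    seed: int


def neutral_thresholds(ne: int, initial_freqs, schedule=None,
                       tail: float = 0.05, n_sim: int = 10_000,
                       seed: int = 0) -> NeutralThresholds:
    """Neutral-drift |delta f| threshold at the given tail probability.

    Simulates ``n_sim`` neutral haploid WF loci at population size ``ne``
    with starting frequencies resampled from the supplied empirical
    spectrum (so the null reflects the panel's real starting frequencies),
    observes them through the sampling schedule, and returns the
    ``1 - tail`` quantile of |delta f|.
    """
    from .simulate import (SamplingSchedule, observe_frequencies,
                           wright_fisher_frequencies)

    schedule = schedule or SamplingSchedule()
    rng = np.random.default_rng(seed)
    p0 = rng.choice(np.asarray(initial_freqs, dtype=float), size=n_sim)
    gens = np.asarray(schedule.generations)
    pop = wright_fisher_frequencies(int(round(ne)), 0.0, p0,
                                    int(gens.max()), reps=n_sim, seed=rng)
    obs = observe_frequencies(pop[:, gens], schedule, seed=rng)
    slopes, _ = delta_f_many(obs, gens)
    thr = float(np.quantile(np.abs(slopes), 1.0 - tail))
    return NeutralThresholds(thr, np.abs(slopes), int(round(ne)), tail,
                             n_sim, seed)
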