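"""Synthetic data generation: ancestor panels, recombinant-inbred mosaic
cohorts with known per-marker ancestry, and haploid Wright-Fisher
trajectories with selection and statistical sampling.

Everything downstream of the file readers can be exercised on data from
this module alone.  The generators emulate the structure of a mid-century
soybean breeding panel: a few dozen fully homozygous ancestor haplotypes
(some pairs nearly identical-by-state), decade-stamped cohorts of inbred
mosaic descendants, and per-locus allele-frequency trajectories in a small
closed breeding population.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import A0, A1, HET, MISSING, GenotypeMatrix
from .temporal import TemporalFrequencySeries

#: decade cohorts mapped to effective generation numbers.  Generation 0
#: pools the pre-1970 releases; subsequent decades advance by the assumed
#: effective generations per decade (15 for the first gap, then 10).
DEFAULT_GENERATIONS = (0, 15, 25, 35, 45)
COHORT_YEARS = {"pre1970s": 1955, "1970s": 1975, "1980s": 1985,
                "1990s": 1995, "2000s": 2005}

_POP_MG = {"MG0-I": "I", "MGIII-IV": "III", "MGV+": "V"}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_marker_map(n_markers: int, n_chromosomes: int = 1,
                    mean_spacing_bp: int = 20_000,
                    seed=0) -> pd.DataFrame:
    """Marker map with ``n_markers`` split evenly over chromosomes.

    Positions are cumulative sums of geometric-ish random spacings around
    ``mean_spacing_bp`` (the SoySNP50K chip averages roughly one marker per
    20 kb); indices are 1-based per chromosome.
    """
    rng = _rng(seed)
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    rows = []
    for c, m in enumerate(per, start=1):
        gaps = rng.integers(1, 2 * mean_spacing_bp, size=m)
        pos = np.cumsum(gaps)
        for i in range(m):
            rows.append((f"ss{c}_{i + 1}", f"Gm{c:02d}", int(pos[i]), i + 1,
                         "A/C"))
    return pd.DataFrame(rows, columns=["marker", "chrom", "pos", "index",
                                       "alleles"])


# ---------------------------------------------------------------------------
# Ancestor panels
# ---------------------------------------------------------------------------

@dataclass
class AncestorPanel:
    """Fully homozygous ancestor haplotypes (ancestors x markers, 0/1)."""

    haplotypes: np.ndarray
    names: list[str]
    markers: pd.DataFrame
    duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("ancestor haplotypes must be fully homozygous 0/1")

    @property
    def n_ancestors(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def as_genotype_matrix(self) -> GenotypeMatrix:
        panel = pd.DataFrame({"line_id": self.names})
        return GenotypeMatrix(self.haplotypes.copy(), self.markers, panel)


def generate_ancestor_panel(n_ancestors: int, n_markers: int,
                            maf_spectrum="uniform",
                            near_duplicate_pairs: int = 0,
                            seed=0, *, n_chromosomes: int = 1,
                            near_duplicate_ibs: float = 0.85) -> AncestorPanel:
    """Random homozygous ancestor panel.

    ``maf_spectrum`` sets per-site allele-1 frequencies: a float fixes them,
    ``"uniform"`` draws U(0.05, 0.5), and a callable ``f(rng, size)`` is
    used as-is.  Each near-duplicate pair shares exactly
    ``near_duplicate_ibs`` of its markers, emulating closely related
    ancestor/first-progeny pairs (about 85% identity by state).
    """
    if n_ancestors < 2:
        raise ValueError("need at least 2 ancestors")
    if near_duplicate_pairs > n_ancestors // 2:
        raise ValueError("more near-duplicate pairs than ancestor pairs")
    rng = _rng(seed)
    if callable(maf_spectrum):
        freqs = np.asarray(maf_spectrum(rng, n_markers), dtype=float)
    elif isinstance(maf_spectrum, str):
        if maf_spectrum != "uniform":
            raise ValueError(f"unknown maf spectrum {maf_spectrum!r}")
        freqs = rng.uniform(0.05, 0.5, size=n_markers)
    else:
        freqs = np.full(n_markers, float(maf_spectrum))
    haps = (rng.random((n_ancestors, n_markers)) < freqs).astype(np.int8)
    pairs = []
    for k in range(near_duplicate_pairs):
        i, j = 2 * k, 2 * k + 1
        n_flip = int(round((1.0 - near_duplicate_ibs) * n_markers))
        flip = rng.choice(n_markers, size=n_flip, replace=False)
        haps[j] = haps[i]
        haps[j, flip] = 1 - haps[j, flip]
        pairs.append((i, j))
    names = [f"Anc{i + 1:02d}" for i in range(n_ancestors)]
    markers = make_marker_map(n_markers, n_chromosomes, seed=rng)
    return AncestorPanel(haps, names, markers, pairs)


# ---------------------------------------------------------------------------
# Recombinant-inbred mosaic cohorts
# ---------------------------------------------------------------------------

@dataclass
class TruthAncestry:
    """Ground-truth donor ancestor index per line per marker."""

    donors: np.ndarray          # (lines, markers) int16 ancestor indices
    ancestor_names: list[str]

    def donor_name(self, line: int, marker: int) -> str:
        return self.ancestor_names[self.donors[line, marker]]


def _mosaic(rowA, rowB, chrom_bounds, recomb, rng):
    """Recombine two haplotype-row tuples (calls..., per-row arrays)."""
    M = len(rowA[0])
    switch = rng.random(M) < recomb
    switch[0] = rng.random() < 0.5              # initial donor, chrom 1
    switch[chrom_bounds] = rng.random(len(chrom_bounds)) < 0.5
    which = np.cumsum(switch) % 2                # 0 -> A, 1 -> B
    return [np.where(which == 0, a, b) for a, b in zip(rowA, rowB)]


def simulate_breeding_cohorts(panel: AncestorPanel, contributions,
                              n_lines_per_cohort, *,
                              recomb_per_interval: float = 0.001,
                              selfing_generations: int = 6,
                              seed=0, population: str = "MG0-I",
                              het_rate: float = 0.0,
                              missing_rate: float = 0.0,
                              serial: bool = False,
                              breeding_pop_size: int | None = None,
                              generation_map=None):
    """Simulate decade cohorts of recombinant-inbred mosaic lines.

    Each line is a biparental cross: two parents are drawn with
    replacement, and the line's genome is a crossover mosaic of the two
    parental haplotypes with independent Bernoulli(``recomb_per_interval``)
    switches per marker interval (the chip's ~0.1 cM marker spacing makes
    a uniform per-interval rate a reasonable stand-in; no interference).
    Chromosomes recombine independently.

    With ``serial=False`` (the default) every line's parents are drawn
    directly from the ancestor panel with probability proportional to
    ``contributions``, so expected genome fractions equal the normalized
    weights.  With ``serial=True`` only a founding breeding population is
    built that way; the cohorts then descend from it through rounds of
    random biparental crossing, one round per generation of the effective
    schedule (``generation_map``), in a closed population of
    ``breeding_pop_size`` lines.  Serial mode produces genuine temporal
    drift between cohorts (so the effective population size is finite and
    estimable) while keeping expected ancestor fractions at the weights.

    With ``selfing_generations >= 6`` the output is fully homozygous;
    fewer selfing generations leave residual heterozygosity at rate
    ``0.5**selfing_generations`` at markers where the parents differ.
    ``het_rate``/``missing_rate`` optionally inject technical HET/no-calls.

    Returns ``(GenotypeMatrix, TruthAncestry)``; the truth records the
    donor ancestor of every marker of every line.
    """
    if panel.n_ancestors == 0:
        raise ValueError("empty ancestor panel")
    if isinstance(contributions, dict):
        weights = np.array([float(contributions.get(nm, 0.0))
                            for nm in panel.names])
    else:
        weights = np.asarray(contributions, dtype=float)
        if len(weights) != panel.n_ancestors:
            raise ValueError("contribution weights/ancestor count mismatch")
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    weights = weights / weights.sum()
    if isinstance(n_lines_per_cohort, int):
        n_lines_per_cohort = {c: n_lines_per_cohort for c in COHORT_YEARS}

    rng = _rng(seed)
    M = panel.n_markers
    chrom_bounds = np.flatnonzero(
        panel.markers["chrom"].to_numpy()[1:]
        != panel.markers["chrom"].to_numpy()[:-1]) + 1

    def founder_cross():
        p1, p2 = rng.choice(panel.n_ancestors, size=2, p=weights)
        donors, = _mosaic((np.full(M, p1, dtype=np.int16),),
                          (np.full(M, p2, dtype=np.int16),),
                          chrom_bounds, recomb_per_interval, rng)
        calls = panel.haplotypes[donors, np.arange(M)].astype(np.int8)
        return calls, donors.astype(np.int16), (p1, p2)

    calls_rows, donor_rows, panel_rows = [], [], []
    parent_pairs = []
    i_line = 0

    def emit(calls, donors, pair, cohort):
        nonlocal i_line
        calls = calls.copy()
        if selfing_generations < 6 and pair is not None:
            differ = panel.haplotypes[pair[0]] != panel.haplotypes[pair[1]]
            resid = rng.random(M) < 0.5 ** selfing_generations
            calls[differ & resid] = HET
        if het_rate > 0:
            calls[rng.random(M) < het_rate] = HET
        if missing_rate > 0:
            calls[rng.random(M) < missing_rate] = MISSING
        calls_rows.append(calls)
        donor_rows.append(donors)
        panel_rows.append((f"L{i_line + 1:04d}", _POP_MG[population],
                           COHORT_YEARS[cohort], population, cohort))
        i_line += 1

    if not serial:
        for cohort, n_lines in n_lines_per_cohort.items():
            for _ in range(int(n_lines)):
                calls, donors, pair = founder_cross()
                emit(calls, donors, pair, cohort)
    else:
        gen_map = dict(generation_map or
                       {c: g for c, g in zip(COHORT_YEARS,
                                             DEFAULT_GENERATIONS)})
        B = breeding_pop_size or max(20, 2 * max(n_lines_per_cohort.values()))
        pop = [founder_cross()[:2] for _ in range(B)]
        prev_gen = 0
        for cohort in sorted(n_lines_per_cohort, key=gen_map.get):
            for _ in range(gen_map[cohort] - prev_gen):
                idx = rng.integers(0, B, size=(B, 2))
                pop = [_mosaic(pop[a], pop[b], chrom_bounds,
                               recomb_per_interval, rng)
                       for a, b in idx]
            prev_gen = gen_map[cohort]
            take = rng.choice(B, size=min(int(n_lines_per_cohort[cohort]), B),
                              replace=False)
            for t in take:
                emit(pop[t][0].astype(np.int8), pop[t][1].astype(np.int16),
                     None, cohort)

    sample_panel = pd.DataFrame(panel_rows,
                                columns=["line_id", "maturity_group",
                                         "year_of_release", "population",
                                         "cohort"])
    g = GenotypeMatrix(np.array(calls_rows, dtype=np.int8), panel.markers,
                       sample_panel)
    truth = TruthAncestry(np.array(donor_rows, dtype=np.int16),
                          list(panel.names))
    return g, truth


# ---------------------------------------------------------------------------
# Wright-Fisher trajectories
# ---------------------------------------------------------------------------

@dataclass
class WFTrajectory:
    """Single haploid Wright-Fisher allele-frequency trajectory."""

    p: np.ndarray
    N: int
    s: float
    p0: float


@dataclass
class SamplingSchedule:
    """Timepoints (generations) and per-timepoint sample sizes.

    ``sample_sizes=None`` means census observation: the sample frequency
    equals the population frequency.
    """

    generations: tuple = DEFAULT_GENERATIONS
    sample_sizes: tuple | None = None

    def __post_init__(self):
        g = np.asarray(self.generations)
        if g[0] != 0 or np.any(np.diff(g) <= 0):
            raise ValueError("generations must strictly increase from 0")
        if self.sample_sizes is not None and \
                len(self.sample_sizes) != len(self.generations):
            raise ValueError("sample_sizes length must match generations")


def selection_update(p, s):
    """Deterministic haploid selection update p* = p(1+s)/(1+ps).

    Relative fitness of the favored allele is 1+s against 1.
    """
    p = np.asarray(p, dtype=float)
    return p * (1.0 + s) / (1.0 + p * s)


def wright_fisher_trajectory(N: int, s: float, p0: float, generations: int,
                             seed=0) -> WFTrajectory:
    """One haploid WF trajectory of length ``generations + 1``.

    Each generation applies the deterministic selection update followed by
    binomial(N, p*) reproduction; 0 and 1 are absorbing.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if s <= -1:
        raise ValueError("selection coefficient must be > -1")
    if not 0 <= p0 <= 1:
        raise ValueError("p0 must lie in [0, 1]")
    p = wright_fisher_frequencies(N, s, p0, generations, reps=1, seed=seed)[0]
    return WFTrajectory(p, N, s, p0)


def wright_fisher_frequencies(N: int, s: float, p0, generations: int,
                              reps: int = 1, seed=0) -> np.ndarray:
    """Vectorized WF simulation: (reps, generations+1) frequency array.

    ``p0`` may be a scalar or a (reps,) array of initial frequencies.
    """
    if s <= -1:
        raise ValueError("selection coefficient must be > -1")
    rng = _rng(seed)
    p = np.broadcast_to(np.asarray(p0, dtype=float), (reps,)).copy()
    out = np.empty((reps, generations + 1))
    out[:, 0] = p
    for t in range(1, generations + 1):
        p = selection_update(p, s)
        p = rng.binomial(N, p) / N
        out[:, t] = p
    return out


def sample_observed_counts(traj: WFTrajectory, schedule: SamplingSchedule,
                           seed=0, locus: str = "locus") -> TemporalFrequencySeries:
    """Observe a trajectory through the sampling schedule.

    With sample sizes, observed counts are binomial(n_t, p_t); with census
    observation the population frequency is reported exactly.
    """
    gens = np.asarray(schedule.generations)
    if gens.max() > len(traj.p) - 1:
        raise ValueError("schedule extends beyond trajectory")
    p_true = traj.p[gens]
    if schedule.sample_sizes is None:
        return TemporalFrequencySeries(locus, tuple(gens), p_true.copy(), None)
    rng = _rng(seed)
    n = np.asarray(schedule.sample_sizes, dtype=int)
    counts = rng.binomial(n, p_true)
    return TemporalFrequencySeries(locus, tuple(gens), counts / n, n,
                                   counts=counts)


def observe_frequencies(pop_freqs: np.ndarray, schedule: SamplingSchedule,
                        seed=0, method: str = "binomial",
                        N: int | None = None) -> np.ndarray:
    """Batch observation of (reps, timepoints) population frequencies.

    ``method="binomial"`` draws individuals with replacement;
    ``method="hypergeometric"`` draws distinct lines without replacement
    from the finite population of ``N`` inbred lines (the realistic model
    when each genotyped variety is a distinct member of the breeding
    population).
    """
    if schedule.sample_sizes is None:
        return np.asarray(pop_freqs, dtype=float)
    rng = _rng(seed)
    n = np.asarray(schedule.sample_sizes, dtype=int)
    if method == "binomial":
        return rng.binomial(n[None, :], pop_freqs) / n
    if method != "hypergeometric":
        raise ValueError(f"unknown sampling method {method!r}")
    if N is None:
        raise ValueError("hypergeometric observation needs the population "
                         "size N")
    K = np.rint(np.asarray(pop_freqs) * N).astype(int)
    out = np.empty(np.shape(pop_freqs), dtype=float)
    for t in range(out.shape[1]):
        out[:, t] = rng.hypergeometric(K[:, t], N - K[:, t], n[t]) / n[t]
    return out
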