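"""Window haplotype spectra, identity tracking across cohorts, the
sneak-ratio comparison, and the shared-haplotype-length (H) scan.

A window's haplotype spectrum is the frequency table of the distinct
50-marker call strings among a cohort's lines (lines with a missing or
heterozygous call anywhere in the window drop out of that window's
denominator).  Spectra from an early and a late cohort are matched by
exact string identity: the early cohort's haplotypes get ranks 1..7 by
descending frequency (everything beyond seven lumps into OTHER for
display), late-only strings get fresh identities, and the per-window
maximum haplotype change is the largest |late - early| frequency over all
strings.  H(x) is the average over line pairs of the length of the
maximal identical tract containing marker x (zero when the pair differs
at x itself), a linkage/recent-sharing signal measured in markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import HET, MISSING, GenotypeMatrix
from .diversity import window_table

MAX_RANKED = 7


@dataclass
class WindowSpectrum:
    """Haplotype frequencies of one window in one cohort."""

    window_id: int
    chrom: str
    start_index: int
    frequencies: dict        # haplotype string -> frequency
    n_lines_used: int
    n_excluded: int

    @property
    def empty(self) -> bool:
        return not self.frequencies


def window_haplotype_spectrum(g: GenotypeMatrix, window: int = 50,
                              step: int = 10) -> list[WindowSpectrum]:
    """Spectrum per window for one cohort subset (see module docs)."""
    if g.n_lines == 0:
        raise ValueError("empty cohort")
    wt = window_table(g.markers, window, step)
    out = []
    for k, row in wt.iterrows():
        lo, hi = int(row["_lo"]), int(row["_hi"])
        block = g.calls[:, lo:hi]
        clean = ~np.any((block == HET) | (block == MISSING), axis=1)
        used = block[clean]
        freqs: dict[str, float] = {}
        if len(used):
            strings = ["".join(map(str, r)) for r in used]
            vc = pd.Series(strings).value_counts()
            freqs = {h: c / len(used) for h, c in vc.items()}
        out.append(WindowSpectrum(int(k), str(row["chrom"]),
                                  int(row["start_index"]), freqs,
                                  int(clean.sum()),
                                  int((~clean).sum())))
    return out


@dataclass
class TrackedSpectrum:
    """Identity-matched early/late spectra for one window."""

    window_id: int
    chrom: str
    start_index: int
    ranks: dict              # haplotype -> rank (1..7) or "OTHER"
    early: dict
    late: dict
    max_haplotype_change: float
    changes: dict = field(repr=False, default_factory=dict)


def track_spectra_over_cohorts(early: list[WindowSpectrum],
                               late: list[WindowSpectrum]
                               ) -> list[TrackedSpectrum]:
    """Match spectra window-by-window and score haplotype turnover.

    Identities persist by exact string equality; a haplotype absent from
    one cohort counts as frequency zero there.  Ranks (display colors)
    follow the early cohort's frequency order, lumping ranks beyond 7
    into OTHER; late-only haplotypes rank after all early ones.
    """
    if len(early) != len(late):
        raise ValueError("spectra lists cover different windows")
    out = []
    for e, l in zip(early, late):
        if (e.window_id, e.start_index) != (l.window_id, l.start_index):
            raise ValueError("spectra lists are not window-aligned")
        order = sorted(e.frequencies, key=e.frequencies.get, reverse=True)
        order += [h for h in sorted(l.frequencies, key=l.frequencies.get,
                                    reverse=True) if h not in e.frequencies]
        ranks = {h: (i + 1 if i < MAX_RANKED else "OTHER")
                 for i, h in enumerate(order)}
        changes = {h: l.frequencies.get(h, 0.0) - e.frequencies.get(h, 0.0)
                   for h in order}
        max_change = max((abs(v) for v in changes.values()), default=0.0)
        out.append(TrackedSpectrum(e.window_id, e.chrom, e.start_index,
                                   ranks, e.frequencies, l.frequencies,
                                   max_change, changes))
    return out


@dataclass
class SneakRatioResult:
    """Haplotype-change / allele-change ratio contrast, sneak vs neutral."""

    median_sneak: float
    median_neutral: float
    median_difference: float
    relative_excess: float          # (sneak - neutral) / neutral
    p_value: float
    n_sneak: int
    n_neutral: int
    n_excluded_zero_denominator: int
    n_permutations: int
    seed: int
    method: str = "label permutation of window categories, median difference"


def sneak_ratio_test(categories, max_haplotype_change, max_allele_change,
                     n_permutations: int = 100_000, seed: int = 0
                     ) -> SneakRatioResult:
    """Are sneak windows more 'haplotype-driven' than neutral windows?

    Per window the ratio max-haplotype-change / max-single-allele-change
    is compared between windows called ``sneak`` and ``neutral``; the
    p-value is the one-sided label-permutation probability of a median
    difference at least as large as observed.  Windows with a zero
    allele-change denominator are excluded (count reported).
    """
    cats = np.asarray(categories, dtype=object)
    hap = np.asarray(max_haplotype_change, dtype=float)
    allele = np.asarray(max_allele_change, dtype=float)
    use = np.isin(cats, ("sneak", "neutral")) & np.isfinite(hap) \
        & np.isfinite(allele)
    nz = allele > 0
    excluded = int((use & ~nz).sum())
    use &= nz
    ratio = hap[use] / allele[use]
    is_sneak = cats[use] == "sneak"
    n_s, n_n = int(is_sneak.sum()), int((~is_sneak).sum())
    if n_s < 10 or n_n < 10:
        raise ValueError("need at least 10 windows in each of sneak/neutral")
    med_s = float(np.median(ratio[is_sneak]))
    med_n = float(np.median(ratio[~is_sneak]))
    observed = med_s - med_n
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000
    done = 0
    while done < n_permutations:
        b = min(block, n_permutations - done)
        idx = np.argsort(rng.random((b, len(ratio))), axis=1)
        perm = ratio[idx]
        ms = np.median(perm[:, :n_s], axis=1)
        mn = np.median(perm[:, n_s:], axis=1)
        count += int(np.sum(ms - mn >= observed))
        done += b
    p = (count + 1) / (n_permutations + 1)
    return SneakRatioResult(med_s, med_n, observed,
                            observed / med_n if med_n else np.nan, p,
                            n_s, n_n, excluded, n_permutations, seed)


# ---------------------------------------------------------------------------
# H scan
# ---------------------------------------------------------------------------

def _pair_tracts(agree: np.ndarray) -> np.ndarray:
    """Maximal identical-tract length containing each marker, per row."""
    n = agree.shape[-1]
    idx = np.arange(n)
    last_bad = np.where(~agree, idx, -1)
    left = idx - np.maximum.accumulate(last_bad, axis=-1)
    right = (idx - np.maximum.accumulate(
        np.where(~agree[:, ::-1], idx, -1), axis=-1))[:, ::-1]
    return np.where(agree, left + right - 1, 0)


def h_scan(g: GenotypeMatrix, pair_chunk: int = 256) -> pd.DataFrame:
    """Average pairwise shared-haplotype length H at every marker.

    Agreement uses the same conventions as ancestry tracing: HET is a
    wildcard, MISSING breaks a tract.  H is measured in markers; a pair
    disagreeing at the focal marker contributes zero there.
    """
    if g.n_lines < 2:
        raise ValueError("H requires at least 2 lines")
    ii, jj = np.triu_indices(g.n_lines, k=1)
    M = g.n_markers
    total = np.zeros(M)
    slices = list(g.chromosome_slices().values())
    for c0 in range(0, len(ii), pair_chunk):
        pi_, pj = ii[c0:c0 + pair_chunk], jj[c0:c0 + pair_chunk]
        a, b = g.calls[pi_], g.calls[pj]
        agree = ((a == b) | (a == HET) | (b == HET)) \
            & (a != MISSING) & (b != MISSING)
        for sl in slices:
            total[sl] += _pair_tracts(agree[:, sl]).sum(axis=0)
    out = g.markers[["marker", "chrom", "pos", "index"]].copy()
    out["H"] = total / len(ii)
    return out
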