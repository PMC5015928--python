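"""Sliding-window nucleotide diversity and log2 diversity ratios.

Diversity pi is the average proportion of differing markers between all
line pairs inside a marker window (pairwise differences per marker), with
50-marker windows advanced in 10-marker steps along each chromosome.
Cohort-versus-reference changes are summarized as log2(pi_x / pi_a),
capped at +-8 to match the "<-8" reporting convention for windows whose
focal diversity collapses to zero; windows with zero reference diversity
are masked (the ratio is undefined there).  Contiguous sub-threshold
windows merge into low-diversity regions annotated with the share of
founding ancestors carrying the region's major haplotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import HET, MISSING, GenotypeMatrix

WINDOW = 50
STEP = 10
LOG2_CAP = 8.0
REGION_THRESHOLD = -2.3


def _window_grid(markers: pd.DataFrame, window: int, step: int):
    """Yield (chrom, global start col, window index metadata) per window."""
    out = []
    chroms = markers["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            mc = i - start
            n_win = (mc - window) // step + 1 if mc >= window else 0
            for wjj in range(n_win):
                lo = start + wjj * step
                out.append((chroms[start], lo, lo + window))
            start = i
    return out


def window_table(markers: pd.DataFrame, window: int = WINDOW,
                 step: int = STEP) -> pd.DataFrame:
    """Window index table: chrom, 1-based start/stop marker index, bp span.

    ``midsite`` is the 1-based index of the window's central marker (the
    ``window//2``-th marker of the window), the convention used to label
    low-diversity regions.
    """
    rows = []
    idx = markers["index"].to_numpy()
    pos = markers["pos"].to_numpy()
    for chrom, lo, hi in _window_grid(markers, window, step):
        rows.append((chrom, int(idx[lo]), int(idx[hi - 1]),
                     int(idx[lo]) + window // 2 - 1,
                     int(pos[lo]), int(pos[hi - 1]), lo, hi))
    return pd.DataFrame(rows, columns=["chrom", "start_index", "stop_index",
                                       "midsite", "start_bp", "stop_bp",
                                       "_lo", "_hi"])


def _pair_indices(n: int):
    iu = np.triu_indices(n, k=1)
    return iu[0], iu[1]


def sliding_pi(g: GenotypeMatrix, window: int = WINDOW, step: int = STEP,
               pair_chunk: int = 512) -> pd.DataFrame:
    """Windowed pairwise diversity for a set of lines.

    Per window, pi = mean over line pairs of (differing markers /
    comparable markers), where a heterozygote differs from either
    homozygote by half and missing calls drop out of both counts
    pairwise.  Pairs with no comparable marker in a window are excluded
    from that window's mean.  Returns the window table with a ``pi``
    column; an empty frame if no chromosome holds a full window.
    """
    if g.n_lines < 2:
        raise ValueError("pi requires at least 2 lines")
    wt = window_table(g.markers, window, step)
    if len(wt) == 0:
        return wt.assign(pi=np.array([], dtype=float))
    dose = np.full(g.calls.shape, np.nan)
    dose[g.calls == 0] = 0.0
    dose[g.calls == 1] = 1.0
    dose[g.calls == HET] = 0.5
    valid = (g.calls != MISSING)
    ii, jj = _pair_indices(g.n_lines)
    n_win = len(wt)
    ratio_sum = np.zeros(n_win)
    pair_count = np.zeros(n_win)
    los = wt["_lo"].to_numpy(dtype=int)
    his = wt["_hi"].to_numpy(dtype=int)
    for c0 in range(0, len(ii), pair_chunk):
        pi_, pj = ii[c0:c0 + pair_chunk], jj[c0:c0 + pair_chunk]
        comp = (valid[pi_] & valid[pj]).astype(float)
        diff = np.abs(np.nan_to_num(dose[pi_]) - np.nan_to_num(dose[pj])) * comp
        cdiff = np.concatenate(
            [np.zeros((len(pi_), 1)), np.cumsum(diff, axis=1)], axis=1)
        ccomp = np.concatenate(
            [np.zeros((len(pi_), 1)), np.cumsum(comp, axis=1)], axis=1)
        dsum = cdiff[:, his] - cdiff[:, los]
        csum = ccomp[:, his] - ccomp[:, los]
        ok = csum > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(ok, dsum / np.maximum(csum, 1), 0.0)
        ratio_sum += r.sum(axis=0)
        pair_count += ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(pair_count > 0, ratio_sum / np.maximum(pair_count, 1),
                      np.nan)
    out = wt.copy()
    out["pi"] = pi
    return out


def log2_diversity_ratio(pi_x: pd.DataFrame, pi_a: pd.DataFrame,
                         cap: float = LOG2_CAP) -> pd.DataFrame:
    """log2(pi_x / pi_a) per window, capped at +-``cap``.

    The two series must come from identical window grids.  Windows with
    pi_x = 0 and pi_a > 0 report the cap floor (-cap, printed "<-8"-style);
    windows with pi_a = 0 are masked as NaN.
    """
    for col in ("chrom", "start_index", "stop_index"):
        if not (pi_x[col].to_numpy() == pi_a[col].to_numpy()).all():
            raise ValueError("window grids are not aligned")
    px = pi_x["pi"].to_numpy(dtype=float)
    pa = pi_a["pi"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(px / pa)
    ratio = np.clip(ratio, -cap, cap)
    ratio[(px == 0) & (pa > 0)] = -cap
    ratio[pa == 0] = np.nan
    out = pi_x.copy().rename(columns={"pi": "pi_x"})
    out["pi_a"] = pa
    out["log2_ratio"] = ratio
    return out


def major_window_haplotype(calls: np.ndarray) -> str | None:
    """Most frequent complete haplotype string among rows of ``calls``.

    Rows containing HET or MISSING calls are excluded; ties break on the
    lexically smallest string.  ``None`` when no complete row remains.
    """
    clean = ~np.any((calls == HET) | (calls == MISSING), axis=1)
    if not clean.any():
        return None
    strings = ["".join(map(str, row)) for row in calls[clean]]
    counts = pd.Series(strings).value_counts()
    top = counts[counts == counts.max()]
    return sorted(top.index)[0]


@dataclass
class LowDiversityRegion:
    """A merged run of sub-threshold windows with founder attribution."""

    chrom: str
    midsite: int
    start_bp: int
    stop_bp: int
    log2_ratio: float
    pi_a: float
    percent_founders: float | None


def low_diversity_report(ratios: pd.DataFrame, focal: GenotypeMatrix,
                         founders=None, threshold: float = REGION_THRESHOLD,
                         carry_min_identity: float = 0.9
                         ) -> list[LowDiversityRegion]:
    """Merge sub-threshold windows into regions and attribute founders.

    ``founders`` is an ancestor panel (or genotype matrix) restricted to a
    population's founding ancestors; ``percent_founders`` is the
    percentage of them carrying the focal population's major 50-marker
    haplotype at the region's minimum-ratio window (rounded to the nearest
    percent), or None when no founders are given.  A founder "carries" the
    haplotype when it matches at a fraction of at least
    ``carry_min_identity`` of the window's markers: requiring exact
    50-marker identity would make an all-founders region impossible to
    report, because identical founders leave no reference diversity to
    normalize by.  Regions are sorted by ascending log2 ratio.
    """
    sub = ratios[ratios["log2_ratio"] < threshold]
    if founders is not None and hasattr(founders, "haplotypes"):
        founder_calls = founders.haplotypes
    elif founders is not None:
        founder_calls = founders.calls
    else:
        founder_calls = None
    regions: list[LowDiversityRegion] = []
    for chrom, group in sub.groupby("chrom", sort=False):
        group = group.sort_values("start_index")
        runs: list[list[int]] = []
        prev_stop = None
        for row_idx, row in group.iterrows():
            if prev_stop is not None and row["start_index"] <= prev_stop + 1:
                runs[-1].append(row_idx)
            else:
                runs.append([row_idx])
            prev_stop = row["stop_index"]
        for run in runs:
            block = ratios.loc[run]
            worst = block.loc[block["log2_ratio"].idxmin()]
            pct = None
            if founder_calls is not None and len(founder_calls):
                lo, hi = int(worst["_lo"]), int(worst["_hi"])
                major = major_window_haplotype(focal.calls[:, lo:hi])
                if major is None:
                    pct = None
                else:
                    target = np.array([int(c) for c in major], dtype=np.int8)
                    ident = np.mean(founder_calls[:, lo:hi] == target,
                                    axis=1)
                    pct = round(100.0 * float(np.mean(
                        ident >= carry_min_identity)))
            regions.append(LowDiversityRegion(
                chrom=str(chrom), midsite=int(worst["midsite"]),
                start_bp=int(block["start_bp"].min()),
                stop_bp=int(block["stop_bp"].max()),
                log2_ratio=float(worst["log2_ratio"]),
                pi_a=float(worst["pi_a"]), percent_founders=pct))
    if founders is None:
        warnings.warn("no founders supplied; percent_founders reported "
                      "missing", stacklevel=2)
    regions.sort(key=lambda r: r.log2_ratio)
    return regions


def regions_frame(regions: list[LowDiversityRegion]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in regions])
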