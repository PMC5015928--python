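"""Sweep-mode classification and cross-population candidate alleles.

Each 50-marker window is summarized by two numbers: the mean of its three
largest per-marker |delta f| values (allele-frequency change is noisy at
single markers and diluted when averaged over a whole window; three is
the compromise) and the log2 diversity ratio of the newest cohort against
the oldest.  Population-specific thresholds on the two axes cut the plane
into four modes:

* hard sweep  -- rapid allele change AND strong diversity loss;
* soft sweep  -- rapid allele change without the diversity collapse
  (selection on standing, recombined variation);
* haplotype sneak -- strong diversity loss while every constituent allele
  moves slowly (a haplotype fixing without single-marker signal);
* neutral     -- neither signal.

Diversity thresholds are quoted as positive magnitudes of log2 reduction
(a threshold of 1.9 means windows at or below -1.9).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import window_table

CATEGORIES = ("hard", "soft", "sneak", "neutral")


def window_selection_stats(delta_f: np.ndarray, markers: pd.DataFrame,
                           window: int = 50, step: int = 10,
                           min_markers: int = 3) -> pd.DataFrame:
    """Mean of the top-3 per-marker |delta f| for each window.

    ``delta_f`` aligns with ``markers`` (one value per marker, NaN for
    loci without a usable frequency series).  Windows with fewer than
    ``min_markers`` usable loci are skipped with a warning.
    """
    wt = window_table(markers, window, step)
    vals = np.abs(np.asarray(delta_f, dtype=float))
    top3 = np.full(len(wt), np.nan)
    skipped = 0
    for k, (lo, hi) in enumerate(zip(wt["_lo"], wt["_hi"])):
        w = vals[lo:hi]
        w = w[np.isfinite(w)]
        if len(w) < min_markers:
            skipped += 1
            continue
        top3[k] = float(np.mean(np.sort(w)[-3:]))
    if skipped:
        warnings.warn(f"{skipped} window(s) had fewer than {min_markers} "
                      "usable markers and were skipped", stacklevel=2)
    out = wt.copy()
    out["top3_delta_f"] = top3
    return out


def classify_windows(stats: pd.DataFrame, delta_f_threshold: float,
                     diversity_threshold: float) -> pd.DataFrame:
    """Four-quadrant sweep-mode call per window.

    ``stats`` needs ``top3_delta_f`` and ``log2_ratio`` columns;
    ``diversity_threshold`` is a positive magnitude (windows with
    log2_ratio <= -threshold count as diversity losses).  Returns a copy
    with a ``category`` column; windows with missing inputs get NaN.
    """
    if delta_f_threshold <= 0 or diversity_threshold <= 0:
        raise ValueError("thresholds must be positive")
    top3 = stats["top3_delta_f"].to_numpy(dtype=float)
    ratio = stats["log2_ratio"].to_numpy(dtype=float)
    fast = top3 >= delta_f_threshold
    lost = ratio <= -diversity_threshold
    category = np.select(
        [fast & lost, fast & ~lost, ~fast & lost],
        ["hard", "soft", "sneak"], default="neutral").astype(object)
    category[~np.isfinite(top3) | ~np.isfinite(ratio)] = None
    out = stats.copy()
    out["category"] = category
    out.attrs["delta_f_threshold"] = delta_f_threshold
    out.attrs["diversity_threshold"] = diversity_threshold
    return out


def category_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percent-of-selected per sweep mode (table layout of a
    per-population summary: total windows, thresholds, then one row per
    selected mode with its share of all putatively selected windows)."""
    cats = calls["category"].dropna()
    total = len(cats)
    counts = {c: int((cats == c).sum()) for c in CATEGORIES}
    selected = counts["hard"] + counts["soft"] + counts["sneak"]
    rows = []
    for c in ("sneak", "hard", "soft"):
        pct = 100.0 * counts[c] / selected if selected else np.nan
        rows.append((c, counts[c], pct))
    out = pd.DataFrame(rows, columns=["category", "count",
                                      "percent_of_selected"])
    out.attrs["total_windows"] = total
    out.attrs["neutral"] = counts["neutral"]
    return out


@dataclass
class CrossPopulationCandidate:
    """Marker putatively selected in one population, fixed opposite in
    another."""

    marker: str
    source: str
    sinks: list[str]
    delta_f_x1000: dict      # per population, presentation scale
    final_freq: dict
    beyond_threshold: dict   # asterisk logic: |delta f| > population threshold


def cross_population_candidates(per_pop: dict[str, pd.DataFrame],
                                thresholds: dict[str, float],
                                fixation=(0.05, 0.95)) -> pd.DataFrame:
    """Tabulate selected-here-fixed-there candidate markers.

    ``per_pop`` maps population -> DataFrame with ``marker``, ``delta_f``
    and ``final_freq`` columns, all on a shared marker set and allele
    polarity.  A marker qualifies when some source population's |delta f|
    exceeds its threshold and at least one other population is fixed
    (final frequency outside ``fixation``) on the side opposite to the
    source's direction of change.  Delta f values are reported x1000.
    """
    pops = list(per_pop)
    base = per_pop[pops[0]]["marker"].to_numpy()
    for p in pops[1:]:
        if not np.array_equal(per_pop[p]["marker"].to_numpy(), base):
            raise ValueError("populations use different marker sets "
                             "(polarity cannot be shared)")
    lo, hi = fixation
    rows = []
    for k, marker in enumerate(base):
        df = {p: float(per_pop[p]["delta_f"].iloc[k]) for p in pops}
        ff = {p: float(per_pop[p]["final_freq"].iloc[k]) for p in pops}
        beyond = {p: abs(df[p]) > thresholds[p] for p in pops}
        for src in pops:
            if not beyond[src] or df[src] == 0:
                continue
            rising = df[src] > 0
            sinks = [p for p in pops if p != src
                     and (ff[p] <= lo if rising else ff[p] >= hi)]
            if sinks:
                rows.append(CrossPopulationCandidate(
                    marker=str(marker), source=src, sinks=sinks,
                    delta_f_x1000={p: 1000.0 * df[p] for p in pops},
                    final_freq=ff, beyond_threshold=beyond))
                break        # one candidate row per marker
    recs = []
    for c in rows:
        rec = {"marker": c.marker, "source": c.source,
               "sinks": ",".join(c.sinks)}
        for p in pops:
            star = "*" if c.beyond_threshold[p] else ""
            rec[f"delta_f_x1000_{p}"] = round(c.delta_f_x1000[p], 2)
            rec[f"flag_{p}"] = star
            rec[f"final_freq_{p}"] = c.final_freq[p]
        recs.append(rec)
    return pd.DataFrame(recs)
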