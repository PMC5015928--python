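"""Haplotype-sharing ancestry: trace each marker of each inbred line to
its most likely donor among a panel of ancestor haplotypes.

For a marker m and a candidate ancestor, the match extent is the number of
consecutive agreeing markers ending at m (including m) plus the number of
consecutive agreeing markers immediately to its right, both truncated at
chromosome boundaries.  Heterozygous calls in the line are wildcards (they
are overwhelmingly technical artifacts in selfing species and should not
break an identity tract); missing calls terminate a run.  The marker is
assigned to the ancestor with the longest extent only when that extent
beats the second-best by strictly more than ``margin_threshold`` markers
(default 5); otherwise it is left ambiguous.  Extents are counted in
markers, with a genome-wide constant threshold, which is appropriate for
marker panels laid out at roughly constant genetic spacing (~0.1 cM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import HET, MISSING, GenotypeMatrix

AMBIGUOUS = -1
DEFAULT_MARGIN = 5
FOUNDER_THRESHOLD = 0.03


def _agreement(line_calls: np.ndarray, anc_calls: np.ndarray) -> np.ndarray:
    """(ancestors x markers) boolean agreement with wildcard HET."""
    line = line_calls[None, :]
    agree = (line == anc_calls) | (line == HET) | (anc_calls == HET)
    agree &= (line != MISSING) & (anc_calls != MISSING)
    return agree


def _left_runs(agree: np.ndarray) -> np.ndarray:
    """Per cell: length of the agreement run ending here (including here)."""
    n = agree.shape[-1]
    idx = np.arange(n)
    last_bad = np.where(~agree, idx, -1)
    return idx - np.maximum.accumulate(last_bad, axis=-1)


def match_extents(line_calls: np.ndarray, anc_calls: np.ndarray,
                  chrom_slices) -> np.ndarray:
    """(ancestors x markers) flanking-match extents for one line.

    Extent(m) = run ending at m (counting m once) + run starting at m+1;
    runs never cross chromosome boundaries.
    """
    A, M = anc_calls.shape
    ext = np.zeros((A, M), dtype=np.int32)
    agree = _agreement(line_calls, anc_calls)
    for sl in chrom_slices:
        a = agree[:, sl]
        left = _left_runs(a)
        right_incl = _left_runs(a[:, ::-1])[:, ::-1]
        right_after = np.zeros_like(right_incl)
        right_after[:, :-1] = right_incl[:, 1:]
        ext[:, sl] = left + right_after
    return ext


@dataclass
class AncestryAssignment:
    """Per-line, per-marker donor assignments with margins.

    ``donors`` holds ancestor indices (AMBIGUOUS = -1), ``match_length``
    the winning extent and ``margin`` the winning minus second-best extent.
    """

    donors: np.ndarray
    match_length: np.ndarray
    margin: np.ndarray
    ancestor_names: list[str]
    line_ids: list[str]
    margin_threshold: int = DEFAULT_MARGIN

    @property
    def ambiguous_fraction(self) -> float:
        return float(np.mean(self.donors == AMBIGUOUS))

    def donor_names(self) -> np.ndarray:
        names = np.array(self.ancestor_names + ["AMBIGUOUS"], dtype=object)
        return names[self.donors]


def _panel_calls(ancestors) -> tuple[np.ndarray, list[str]]:
    if hasattr(ancestors, "haplotypes"):       # AncestorPanel
        return ancestors.haplotypes.astype(np.int8), list(ancestors.names)
    return ancestors.calls, ancestors.line_ids  # GenotypeMatrix


def assign_marker_ancestry(g: GenotypeMatrix, ancestors,
                           margin_threshold: int = DEFAULT_MARGIN
                           ) -> AncestryAssignment:
    """Margin-rule donor assignment for every marker of every line.

    ``ancestors`` is an :class:`~temposel.simulate.AncestorPanel` or a
    :class:`~temposel.data.GenotypeMatrix` sharing the marker map.
    """
    anc_calls, anc_names = _panel_calls(ancestors)
    if len(anc_names) == 0:
        raise ValueError("no ancestors supplied")
    if anc_calls.shape[1] != g.n_markers:
        raise ValueError("ancestors and lines use different marker maps")
    if margin_threshold < 0:
        raise ValueError("margin_threshold must be >= 0")
    slices = list(g.chromosome_slices().values())
    L, M = g.calls.shape
    donors = np.full((L, M), AMBIGUOUS, dtype=np.int16)
    best_len = np.zeros((L, M), dtype=np.int32)
    margins = np.zeros((L, M), dtype=np.int32)
    for i in range(L):
        ext = match_extents(g.calls[i], anc_calls, slices)
        order = np.argsort(ext, axis=0)
        best = order[-1]
        ext_best = ext[best, np.arange(M)]
        ext_second = ext[order[-2], np.arange(M)]
        margin = ext_best - ext_second
        ok = margin > margin_threshold
        donors[i, ok] = best[ok]
        best_len[i] = ext_best
        margins[i] = margin
    return AncestryAssignment(donors, best_len, margins, anc_names,
                              g.line_ids, margin_threshold)


@dataclass
class ContributionTable:
    """Fractional genome contribution of each ancestor to a line set."""

    fractions: pd.DataFrame       # ancestor, fraction, founding flag
    ambiguous_fraction: float
    n_lines: int
    all_ambiguous: bool = False

    def founding(self, threshold: float = FOUNDER_THRESHOLD) -> list[str]:
        keep = self.fractions["fraction"] > threshold
        return list(self.fractions.loc[keep, "ancestor"])


def fractional_contribution(assignment: AncestryAssignment,
                            line_mask=None,
                            founder_threshold: float = FOUNDER_THRESHOLD
                            ) -> ContributionTable:
    """Tally assigned markers into per-ancestor genome fractions.

    Markers are pooled over the selected lines; ambiguous markers are
    excluded from the denominator and reported separately.  The output is
    sorted by descending fraction with ancestors above the founding
    threshold flagged.
    """
    donors = assignment.donors
    if line_mask is not None:
        donors = donors[np.asarray(line_mask)]
    if donors.size == 0:
        raise ValueError("no lines selected")
    n_anc = len(assignment.ancestor_names)
    counts = np.bincount(donors[donors != AMBIGUOUS].ravel(),
                         minlength=n_anc).astype(float)
    total = counts.sum()
    ambiguous = float(np.mean(donors == AMBIGUOUS))
    if total == 0:
        frac = np.full(n_anc, np.nan)
        all_amb = True
    else:
        frac = counts / total
        all_amb = False
    table = pd.DataFrame({"ancestor": assignment.ancestor_names,
                          "fraction": frac})
    table["founding"] = table["fraction"] > founder_threshold
    table = table.sort_values("fraction", ascending=False,
                              ignore_index=True)
    return ContributionTable(table, ambiguous, donors.shape[0], all_amb)


def founding_ancestors(table: ContributionTable,
                       threshold: float = FOUNDER_THRESHOLD) -> set[str]:
    """Ancestors contributing strictly more than ``threshold`` (default 3%)."""
    return set(table.founding(threshold))
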