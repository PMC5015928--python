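"""Genotype data model and file I/O for near-inbred SNP panels.

The in-memory containers are deliberately thin: a :class:`GenotypeMatrix`
bundles an ``int8`` call matrix (lines x markers) with a marker map and a
sample panel, both plain :class:`pandas.DataFrame` objects.  Calls are coded

========  =====  ==========================================
code      value  meaning
========  =====  ==========================================
``A0``      0    homozygous for the first listed allele
``A1``      1    homozygous for the second listed allele
``HET``     2    heterozygous (rare in inbred material)
``MISSING`` -1   no call
========  =====  ==========================================

Marker indices are 1-based within each chromosome, ordered by physical
position, matching the "marker index" convention used throughout the
window-based analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

A0 = np.int8(0)
A1 = np.int8(1)
HET = np.int8(2)
MISSING = np.int8(-1)

#: canonical cohort labels in temporal order
COHORTS = ("pre1970s", "1970s", "1980s", "1990s", "2000s")
#: maturity-group populations (MG II lines are excluded from analysis)
POPULATIONS = ("MG0-I", "MGIII-IV", "MGV+")
EXCLUDED = "EXCLUDED"

_MG_TO_POP = {
    "00": "MG0-I", "0": "MG0-I", "I": "MG0-I",
    "II": EXCLUDED,
    "III": "MGIII-IV", "IV": "MGIII-IV",
    "V": "MGV+", "VI": "MGV+", "VII": "MGV+", "VIII": "MGV+",
}

_IUPAC_HET = set("RYSWKM")


class ParseError(ValueError):
    """Malformed genotype-table input."""


def year_to_cohort(year: int) -> str:
    """Decade cohort for a year of release.

    Pre-1970 years (including pre-1940 line selections) fold into
    ``pre1970s``; the final decade is open-ended (post-2009 releases fold
    into ``2000s``).
    """
    year = int(year)
    if year < 1970:
        return "pre1970s"
    if year < 1980:
        return "1970s"
    if year < 1990:
        return "1980s"
    if year < 2000:
        return "1990s"
    return "2000s"


def mg_to_population(mg: str) -> str:
    """Maturity-group label -> analysis population (MG II -> EXCLUDED)."""
    key = str(mg).strip().upper()
    if key not in _MG_TO_POP:
        raise ValueError(f"unknown maturity group label: {mg!r}")
    return _MG_TO_POP[key]


def assign_cohorts_and_populations(panel: pd.DataFrame) -> pd.DataFrame:
    """Attach ``population`` and ``cohort`` columns to a raw sample panel.

    Parameters
    ----------
    panel
        DataFrame with at least ``line_id``, ``maturity_group`` and
        ``year_of_release`` columns.

    Returns
    -------
    A copy with ``population`` (one of ``MG0-I``/``MGIII-IV``/``MGV+``/
    ``EXCLUDED``) and ``cohort`` (``pre1970s`` ... ``2000s``) columns.
    Assignment is a pure function of (maturity group, year).
    """
    required = {"line_id", "maturity_group", "year_of_release"}
    missing_cols = required - set(panel.columns)
    if missing_cols:
        raise ValueError(f"panel missing columns: {sorted(missing_cols)}")
    out = panel.copy()
    bad = []
    pops = []
    for lid, mg in zip(out["line_id"], out["maturity_group"]):
        try:
            pops.append(mg_to_population(mg))
        except ValueError:
            bad.append(str(lid))
            pops.append(None)
    if bad:
        raise ValueError(f"unknown maturity group for line(s): {', '.join(bad)}")
    out["population"] = pops
    out["cohort"] = [year_to_cohort(y) for y in out["year_of_release"]]
    return out


def read_panel_csv(path) -> pd.DataFrame:
    """Read a ``line_id,maturity_group,year_of_release`` CSV and assign
    cohorts/populations."""
    raw = pd.read_csv(path, dtype={"line_id": str, "maturity_group": str})
    return assign_cohorts_and_populations(raw)


def _validate_marker_map(markers: pd.DataFrame) -> None:
    for col in ("marker", "chrom", "pos", "index", "alleles"):
        if col not in markers.columns:
            raise ValueError(f"marker map missing column {col!r}")
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = sub["index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(sub) + 1)):
            raise ValueError(f"marker indices on {chrom} are not consecutive 1..M")
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions on {chrom} not strictly increasing")
    for a in markers["alleles"]:
        parts = str(a).split("/")
        if len(parts) != 2 or parts[0] == parts[1]:
            raise ValueError(f"alleles must be two distinct codes, got {a!r}")


@dataclass
class GenotypeMatrix:
    """Lines x markers biallelic call matrix with marker map and panel.

    ``calls`` is ``int8`` with the codes documented in the module header;
    ``markers`` carries ``marker``, ``chrom``, ``pos``, ``index`` (1-based
    per chromosome) and ``alleles`` ("A/C" style); ``panel`` has one row per
    line (``line_id`` plus any metadata, typically maturity group, year,
    population and cohort).
    """

    calls: np.ndarray
    markers: pd.DataFrame
    panel: pd.DataFrame

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (lines x markers)")
        if self.calls.shape[1] != len(self.markers):
            raise ValueError("calls/marker-map width mismatch")
        if self.calls.shape[0] != len(self.panel):
            raise ValueError("calls/panel length mismatch")
        _validate_marker_map(self.markers)
        self.markers = self.markers.reset_index(drop=True)
        self.panel = self.panel.reset_index(drop=True)
        het_frac = np.mean(self.calls == HET, axis=1)
        worst = float(het_frac.max()) if len(het_frac) else 0.0
        if worst > 0.01:
            warnings.warn(
                f"line {self.panel['line_id'].iloc[int(het_frac.argmax())]} has "
                f"{worst:.1%} heterozygous calls (> 1%)", stacklevel=2)

    # -- convenience -----------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    @property
    def line_ids(self) -> list[str]:
        return [str(x) for x in self.panel["line_id"]]

    def subset_lines(self, mask) -> "GenotypeMatrix":
        """Row subset by boolean mask or integer positions."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(self.calls[idx], self.markers,
                              self.panel.iloc[idx])

    def lines_in(self, *, population: str | None = None,
                 cohort: str | None = None) -> "GenotypeMatrix":
        """Subset to a population and/or cohort (requires assigned panel)."""
        keep = np.ones(self.n_lines, dtype=bool)
        if population is not None:
            keep &= (self.panel["population"] == population).to_numpy()
        if cohort is not None:
            keep &= (self.panel["cohort"] == cohort).to_numpy()
        return self.subset_lines(keep)

    def same_marker_map(self, other: "GenotypeMatrix") -> bool:
        a, b = self.markers, other.markers
        return (len(a) == len(b)
                and (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
                and (a["pos"].to_numpy() == b["pos"].to_numpy()).all())

    def chromosome_slices(self) -> dict[str, slice]:
        """Column slice per chromosome, in file order."""
        out: dict[str, slice] = {}
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out


# ---------------------------------------------------------------------------
# HapMap-style TSV
# ---------------------------------------------------------------------------

def _call_from_diplotype(token: str, a0: str, a1: str, lineno: int) -> int | None:
    """Decode one genotype token; ``None`` flags an allele outside {a0,a1}."""
    t = token.strip().upper()
    if t in ("NN", "N", "--", "-", "./.", ".", ""):
        return int(MISSING)
    if len(t) == 1:
        if t == a0:
            return int(A0)
        if t == a1:
            return int(A1)
        if t in _IUPAC_HET:
            return int(HET)
        return None
    if len(t) == 2:
        if t[0] not in (a0, a1) or t[1] not in (a0, a1):
            return None
        if t[0] == t[1]:
            return int(A0) if t[0] == a0 else int(A1)
        return int(HET)
    raise ParseError(f"line {lineno}: unparseable genotype token {token!r}")


def read_genotype_table(path, format: str = "hapmap_tsv") -> GenotypeMatrix:
    """Read a genotype table into a :class:`GenotypeMatrix`.

    ``format`` is ``"hapmap_tsv"`` (header ``rs chrom pos alleles`` followed
    by one column per line; calls as two-letter diplotypes or single-letter
    IUPAC) or ``"vcf"`` (VCF 4.x, read-only).  Sites with more than two
    alleles are dropped with a warning; markers are sorted by position
    within chromosome (with a warning if the input was unsorted) and
    assigned 1-based per-chromosome indices.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format != "hapmap_tsv":
        raise ValueError(f"unknown format {format!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if len(cols) < 5 or cols[:4] != ["rs", "chrom", "pos", "alleles"]:
            raise ParseError(
                "line 1: expected header starting 'rs\\tchrom\\tpos\\talleles'")
        line_ids = cols[4:]
        records = []          # (marker, chrom, pos, alleles, calls)
        n_dropped = 0
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            parts = raw.split("\t")
            if len(parts) != len(cols):
                raise ParseError(
                    f"line {lineno}: expected {len(cols)} fields, got {len(parts)}")
            rs, chrom, pos, alleles = parts[:4]
            allele_parts = [p.strip().upper() for p in alleles.split("/")]
            if len(allele_parts) != 2:
                n_dropped += 1
                continue
            a0, a1 = allele_parts
            try:
                posi = int(pos)
            except ValueError:
                raise ParseError(f"line {lineno}: bad position {pos!r}") from None
            calls = [_call_from_diplotype(t, a0, a1, lineno) for t in parts[4:]]
            if any(c is None for c in calls):
                n_dropped += 1
                continue
            records.append((rs, chrom, posi, f"{a0}/{a1}", calls))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-biallelic site(s)", stacklevel=2)
    if not records:
        raise ParseError("no usable marker records")
    markers = pd.DataFrame(
        {"marker": [r[0] for r in records],
         "chrom": [r[1] for r in records],
         "pos": [r[2] for r in records],
         "alleles": [r[3] for r in records]})
    calls = np.array([r[4] for r in records], dtype=np.int8).T
    return _finalize(calls, markers, line_ids)


def _finalize(calls: np.ndarray, markers: pd.DataFrame,
              line_ids: list[str]) -> GenotypeMatrix:
    """Sort within chromosome, assign 1-based indices, build the matrix."""
    order = []
    unsorted = False
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            seg = np.arange(start, i)
            seg_pos = pos[seg]
            if np.any(np.diff(seg_pos) < 0):
                unsorted = True
                seg = seg[np.argsort(seg_pos, kind="stable")]
            order.extend(seg.tolist())
            start = i
    if unsorted:
        warnings.warn("marker positions were unsorted; sorted by position "
                      "within chromosome", stacklevel=3)
    markers = markers.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    idx = np.concatenate([np.arange(1, len(sub) + 1)
                          for _, sub in markers.groupby("chrom", sort=False)])
    markers = markers.assign(index=idx)[["marker", "chrom", "pos", "index",
                                         "alleles"]]
    panel = pd.DataFrame({"line_id": line_ids})
    return GenotypeMatrix(calls, markers, panel)


def write_genotype_table(g: GenotypeMatrix, path) -> None:
    """Write the HapMap-style TSV dialect read by :func:`read_genotype_table`.

    Homozygotes are written as doubled-letter diplotypes, heterozygotes as
    the two alleles in map order, missing as ``NN``.
    """
    a0 = np.array([a.split("/")[0] for a in g.markers["alleles"]])
    a1 = np.array([a.split("/")[1] for a in g.markers["alleles"]])
    with open(path, "w") as fh:
        fh.write("\t".join(["rs", "chrom", "pos", "alleles"] + g.line_ids) + "\n")
        for j in range(g.n_markers):
            row = g.markers.iloc[j]
            tokens = []
            for c in g.calls[:, j]:
                if c == A0:
                    tokens.append(a0[j] * 2)
                elif c == A1:
                    tokens.append(a1[j] * 2)
                elif c == HET:
                    tokens.append(a0[j] + a1[j])
                else:
                    tokens.append("NN")
            fh.write("\t".join([str(row["marker"]), str(row["chrom"]),
                                str(row["pos"]), str(row["alleles"])]
                               + tokens) + "\n")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    records = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_dropped += 1
            continue
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        calls = np.full(len(gt), MISSING, dtype=np.int8)
        calls[gt == 0] = A0
        calls[gt == 3] = A1
        calls[gt == 1] = HET
        rid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        records.append((rid, var.CHROM, var.POS,
                        f"{var.REF}/{var.ALT[0]}", calls))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-biallelic-SNP record(s)",
                      stacklevel=3)
    if not records:
        raise ParseError("no usable VCF records")
    markers = pd.DataFrame(
        {"marker": [r[0] for r in records],
         "chrom": [r[1] for r in records],
         "pos": [r[2] for r in records],
         "alleles": [r[3] for r in records]})
    calls = np.stack([r[4] for r in records], axis=1)
    return _finalize(calls, markers, line_ids)


# ---------------------------------------------------------------------------
# Identity-by-state
# ---------------------------------------------------------------------------

@dataclass
class IBSMatrix:
    """Symmetric lines x lines identity-by-state proportions.

    ``values[i, j]`` is the fraction of comparable (pairwise non-missing)
    markers at which lines i and j carry the same call, counting a
    heterozygote against a homozygote as half a match; ``counts`` holds the
    number of comparable markers per pair.  Pairs with no comparable
    markers are NaN.
    """

    values: np.ndarray
    counts: np.ndarray
    line_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids,
                            columns=self.line_ids)

    def write_tsv(self, path) -> None:
        """Square TSV with line-id header row and column."""
        self.to_frame().to_csv(path, sep="\t", index_label="line_id")


def _ibs_channels(calls: np.ndarray):
    c0 = (calls == A0).astype(np.float64)
    c1 = (calls == A1).astype(np.float64)
    ch = (calls == HET).astype(np.float64)
    valid = c0 + c1 + ch
    return c0, c1, ch, valid


def _ibs_cross(calls_a: np.ndarray, calls_b: np.ndarray):
    """(match score, comparable count) between rows of two call matrices."""
    a0, a1, ah, av = _ibs_channels(calls_a)
    b0, b1, bh, bv = _ibs_channels(calls_b)
    matches = (a0 @ b0.T + a1 @ b1.T + ah @ bh.T
               + 0.5 * (a0 @ bh.T + ah @ b0.T + a1 @ bh.T + ah @ b1.T))
    counts = av @ bv.T
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(counts > 0, matches / np.maximum(counts, 1), np.nan)
    return values, counts


def ibs_matrix(g: GenotypeMatrix) -> IBSMatrix:
    """All-pairs IBS among the lines of ``g``.

    HET vs homozygote scores 0.5, HET vs HET scores 1.0; missing calls are
    excluded pairwise from numerator and denominator.  The diagonal is 1 by
    construction (for lines with at least one non-missing call).
    """
    if g.n_lines < 2:
        raise ValueError("IBS requires at least 2 lines")
    values, counts = _ibs_cross(g.calls, g.calls)
    values = (values + values.T) / 2.0  # enforce exact symmetry
    return IBSMatrix(values, counts.astype(np.int64), g.line_ids)


@dataclass
class AncestorIBSSummary:
    """Per-population IBS distributions of lines against each ancestor."""

    per_line: pd.DataFrame   # line_id, population, ancestor, ibs
    summary: pd.DataFrame    # population, ancestor, n, q1, median, q3


def population_ancestor_ibs_summary(g: GenotypeMatrix,
                                    ancestors: GenotypeMatrix) -> AncestorIBSSummary:
    """IBS of every line against every ancestor, grouped by population.

    Populations must already be assigned in ``g.panel``; the ancestor
    matrix must share the marker map.  Empty populations yield empty
    distributions (no rows) rather than errors.
    """
    if not g.same_marker_map(ancestors):
        raise ValueError("line and ancestor matrices have different marker maps")
    values, _ = _ibs_cross(g.calls, ancestors.calls)
    anc_ids = ancestors.line_ids
    rows = []
    pops = g.panel.get("population", pd.Series(["ALL"] * g.n_lines))
    for i, lid in enumerate(g.line_ids):
        for k, aid in enumerate(anc_ids):
            rows.append((lid, pops.iloc[i], aid, values[i, k]))
    per_line = pd.DataFrame(rows, columns=["line_id", "population",
                                           "ancestor", "ibs"])
    grouped = per_line.groupby(["population", "ancestor"])["ibs"]
    summary = grouped.agg(n="count",
                          q1=lambda s: s.quantile(0.25),
                          median="median",
                          q3=lambda s: s.quantile(0.75)).reset_index()
    return AncestorIBSSummary(per_line, summary)
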