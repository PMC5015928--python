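"""Configuration-driven orchestration of the full temporal analysis.

The pipeline runs on real inputs (genotype table + panel CSV + ancestor
table) or on a self-contained synthetic study generated by
:mod:`temposel.simulate`.  Stages mirror the analysis narrative: IBS
structure, ancestry tracing, windowed diversity, temporal Ne, the
selection scan with simulated neutral thresholds, sweep classification,
haplotype spectra, and the power study.  Every output is a TSV with
``#``-prefixed metadata lines naming the parameters and seed that
produced it, so a bundle is reproducible from its own headers.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import data as dm
from . import diversity as dv
from . import ne as ne_mod
from . import power as pw
from . import simulate as sim
from . import spectra as sp
from . import sweeps as sw
from . import temporal as ts

log = logging.getLogger("temposel")

STAGES = ("ibs", "ancestry", "diversity", "ne", "scan", "spectra", "power")

DEFAULT_CONFIG = {
    "window": 50,
    "step": 10,
    "margin_threshold": 5,
    "founding_threshold": 0.03,
    "fixation_bounds": [0.05, 0.95],
    "region_threshold": -2.3,
    "scan_tail": 0.05,
    "scan_n_sim": 10000,
    "ne_bounds": [20, 1000],
    "ne_freq_range": [0.5, 0.6],
    "generation_map": dict(ts.GENERATION_MAP),
    "power": {"reps": 2000, "fpr": 0.05, "N": 200,
              "sample_sizes": list(pw.STUDY_SAMPLE_SIZES)},
    "synthetic": {
        "n_ancestors": 8,
        "n_markers": 1500,
        "n_chromosomes": 3,
        "near_duplicate_pairs": 1,
        "n_lines_per_cohort": 12,
        "recomb_per_interval": 0.001,
        "serial": True,
        "breeding_pop_size": 40,
        "populations": {
            "MG0-I": [4.0, 0.5, 3.0, 0.5, 0.5, 0.5, 0.5, 0.5],
            "MGIII-IV": [6.0, 0.5, 0.5, 0.5, 1.0, 0.5, 0.5, 0.5],
            "MGV+": [0.5, 0.5, 0.5, 3.0, 0.5, 3.0, 2.0, 0.5],
        },
    },
}


def load_config(path=None) -> dict:
    cfg = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_copy(d):
    return yaml.safe_load(yaml.safe_dump(d))


def _deep_update(base, extra):
    for k, v in extra.items():
        # population->weights maps are replaced wholesale, not merged
        if k != "populations" and isinstance(v, dict) \
                and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    """TSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


class Pipeline:
    """One configured analysis run over a genotype panel."""

    def __init__(self, cfg: dict, out_dir, seed: int = 0):
        self.cfg = cfg
        self.seed = int(seed)
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self._meta_base = {"seed": self.seed,
                           "window": cfg["window"], "step": cfg["step"]}
        self.ancestors: sim.AncestorPanel | None = None
        self.g: dm.GenotypeMatrix | None = None
        self.ne_results: dict[str, ne_mod.NeResults] = {}
        self.thresholds: dict[str, float] = {}
        self.scan_delta: dict[str, np.ndarray] = {}

    # -- inputs ----------------------------------------------------------
    def load_inputs(self):
        cfg = self.cfg
        if "genotypes" in cfg:
            fmt = cfg.get("genotype_format", "hapmap_tsv")
            self.g = dm.read_genotype_table(cfg["genotypes"], fmt)
            panel = dm.read_panel_csv(cfg["panel"])
            self.g = dm.GenotypeMatrix(
                self.g.calls, self.g.markers,
                self.g.panel.merge(panel, on="line_id", how="left"))
            anc_g = dm.read_genotype_table(cfg["ancestors"], fmt)
            self.ancestors = sim.AncestorPanel(
                anc_g.calls, anc_g.line_ids, anc_g.markers)
            log.info("loaded %d lines x %d markers", self.g.n_lines,
                     self.g.n_markers)
            return
        syn = cfg["synthetic"]
        rng = np.random.SeedSequence(self.seed).spawn(4)
        self.ancestors = sim.generate_ancestor_panel(
            syn["n_ancestors"], syn["n_markers"],
            near_duplicate_pairs=syn["near_duplicate_pairs"],
            n_chromosomes=syn["n_chromosomes"],
            seed=np.random.default_rng(rng[0]))
        parts = []
        for k, (popname, weights) in enumerate(syn["populations"].items()):
            g, _ = sim.simulate_breeding_cohorts(
                self.ancestors, weights, syn["n_lines_per_cohort"],
                recomb_per_interval=syn["recomb_per_interval"],
                seed=np.random.default_rng(rng[1 + k]),
                population=popname, serial=syn.get("serial", False),
                breeding_pop_size=syn.get("breeding_pop_size"),
                generation_map=cfg["generation_map"])
            parts.append(g)
        calls = np.vstack([g.calls for g in parts])
        panel = pd.concat([g.panel for g in parts], ignore_index=True)
        panel["line_id"] = [f"L{i + 1:04d}" for i in range(len(panel))]
        self.g = dm.GenotypeMatrix(calls, self.ancestors.markers, panel)
        log.info("simulated %d lines x %d markers (%d ancestors)",
                 self.g.n_lines, self.g.n_markers,
                 self.ancestors.n_ancestors)

    def populations(self):
        pops = [p for p in dm.POPULATIONS
                if (self.g.panel["population"] == p).any()]
        return pops

    def _meta(self, **extra):
        meta = dict(self._meta_base)
        meta.update(extra)
        return meta

    # -- stages ----------------------------------------------------------
    def stage_ibs(self):
        ibs = dm.ibs_matrix(self.g)
        ibs.write_tsv(self.out / "ibs_matrix.tsv")
        summ = dm.population_ancestor_ibs_summary(
            self.g, self.ancestors.as_genotype_matrix())
        write_tsv(summ.summary, self.out / "ancestor_ibs_summary.tsv",
                  self._meta(stage="ibs"))

    def stage_ancestry(self):
        cfg = self.cfg
        rows = []
        for pop in self.populations():
            sub = self.g.lines_in(population=pop, cohort="pre1970s")
            assign = anc.assign_marker_ancestry(
                sub, self.ancestors, cfg["margin_threshold"])
            table = anc.fractional_contribution(
                assign, founder_threshold=cfg["founding_threshold"])
            t = table.fractions.copy()
            t.insert(0, "population", pop)
            t["ambiguous_fraction"] = table.ambiguous_fraction
            rows.append(t)
        out = pd.concat(rows, ignore_index=True)
        write_tsv(out, self.out / "contributions.tsv",
                  self._meta(stage="ancestry",
                             margin_threshold=cfg["margin_threshold"],
                             founding_threshold=cfg["founding_threshold"]))
        self.contributions = out

    def stage_diversity(self):
        cfg = self.cfg
        pi_a = dv.sliding_pi(self.ancestors.as_genotype_matrix(),
                             cfg["window"], cfg["step"])
        regions = []
        self.ratios_pre = {}
        for pop in self.populations():
            pre = self.g.lines_in(population=pop, cohort="pre1970s")
            pi_x = dv.sliding_pi(pre, cfg["window"], cfg["step"])
            ratios = dv.log2_diversity_ratio(pi_x, pi_a)
            self.ratios_pre[pop] = ratios
            founders = None
            if hasattr(self, "contributions"):
                names = self.contributions.query(
                    "population == @pop and founding")["ancestor"]
                keep = [i for i, nm in enumerate(self.ancestors.names)
                        if nm in set(names)]
                if keep:
                    founders = sim.AncestorPanel(
                        self.ancestors.haplotypes[keep],
                        [self.ancestors.names[i] for i in keep],
                        self.ancestors.markers)
            regs = dv.low_diversity_report(ratios, pre, founders,
                                           cfg["region_threshold"])
            frame = dv.regions_frame(regs)
            if len(frame):
                frame.insert(0, "population", pop)
                regions.append(frame)
        out = (pd.concat(regions, ignore_index=True) if regions
               else pd.DataFrame(columns=["population"]))
        write_tsv(out, self.out / "low_diversity_regions.tsv",
                  self._meta(stage="diversity",
                             region_threshold=cfg["region_threshold"]))

    def stage_ne(self):
        cfg = self.cfg
        rows = []
        lo, hi = cfg["ne_freq_range"]
        for pop in self.populations():
            series = ts.build_frequency_series(
                self.g, pop, (lo, hi),
                generation_map=cfg["generation_map"])
            if len(series) < 10:
                log.warning("population %s: only %d loci pass the Ne "
                            "filter; skipping", pop, len(series))
                continue
            freqs, sizes, gens = ts.series_matrix(series)
            model = ne_mod.NeModel(freqs, gens, sizes,
                                   tuple(cfg["ne_bounds"]),
                                   initial_prior=(lo, hi))
            res = model.fit()
            self.ne_results[pop] = res
            sizes_str = ",".join(str(int(s)) for s in sizes[0])
            rows.append((pop, sizes_str, len(series), res.ne,
                         f"{res.ci95[0]}-{res.ci95[1]}", res.at_bound))
        out = pd.DataFrame(rows, columns=["population", "lines_per_timepoint",
                                          "n_markers", "ne", "ci95",
                                          "at_bound"])
        write_tsv(out, self.out / "ne_estimates.tsv",
                  self._meta(stage="ne", bounds=tuple(cfg["ne_bounds"]),
                             freq_range=tuple(cfg["ne_freq_range"])))

    def stage_scan(self):
        cfg = self.cfg
        gen_map = cfg["generation_map"]
        gens = tuple(sorted(gen_map.values()))
        thr_rows, call_frames, count_frames = [], [], {}
        per_pop_candidates = {}
        pi_windows = {}
        rng = np.random.SeedSequence([self.seed, 5]).spawn(
            len(self.populations()))
        for k, pop in enumerate(self.populations()):
            # per-marker delta f on the scan filter (< 0.95 initial freq)
            gens_, f1, n, markers = ts.cohort_allele_frequencies(
                self.g, pop, gen_map)
            major_is_1 = f1[:, 0] >= 0.5
            fmaj = np.where(major_is_1[:, None], f1, 1 - f1)
            usable = np.isfinite(fmaj).all(axis=1) & (fmaj[:, 0] < 0.95)
            slopes, _ = ts.delta_f_many(fmaj, gens_,
                                        tuple(cfg["fixation_bounds"]))
            slopes = np.where(usable, slopes, np.nan)
            self.scan_delta[pop] = slopes
            ne_est = self.ne_results.get(pop)
            ne_val = ne_est.ne if ne_est else cfg["power"]["N"]
            spectrum = fmaj[usable, 0]
            sched = sim.SamplingSchedule(
                gens, tuple(int(x) for x in n[0]))
            nt = ts.neutral_thresholds(
                ne_val, spectrum, sched, cfg["scan_tail"],
                cfg["scan_n_sim"],
                seed=int(rng[k].generate_state(1)[0] % 2**31))
            self.thresholds[pop] = nt.threshold
            thr_rows.append((pop, ne_val, nt.threshold, cfg["scan_tail"]))
            # windows: top3 |delta f| + diversity 2000s vs pre1970s
            stats = sw.window_selection_stats(
                slopes, self.g.markers, cfg["window"], cfg["step"])
            pre = self.g.lines_in(population=pop, cohort="pre1970s")
            new = self.g.lines_in(population=pop, cohort="2000s")
            pi_pre = dv.sliding_pi(pre, cfg["window"], cfg["step"])
            pi_new = dv.sliding_pi(new, cfg["window"], cfg["step"])
            ratios = dv.log2_diversity_ratio(pi_new, pi_pre)
            pi_windows[pop] = (pi_pre, pi_new)
            stats["log2_ratio"] = ratios["log2_ratio"].to_numpy()
            calls = sw.classify_windows(stats, nt.threshold,
                                        cfg.get("diversity_threshold", 1.9))
            calls.insert(0, "population", pop)
            call_frames.append(calls)
            count_frames[pop] = sw.category_counts(calls)
            per_pop_candidates[pop] = (f1, n, markers, gens_)
        self.sweep_calls = pd.concat(call_frames, ignore_index=True)
        self.pi_windows = pi_windows
        write_tsv(pd.DataFrame(thr_rows, columns=["population", "ne",
                                                  "delta_f_threshold",
                                                  "tail"]),
                  self.out / "neutral_thresholds.tsv",
                  self._meta(stage="scan", n_sim=cfg["scan_n_sim"]))
        drop = [c for c in ("_lo", "_hi") if c in self.sweep_calls]
        write_tsv(self.sweep_calls.drop(columns=drop),
                  self.out / "sweep_calls.tsv", self._meta(stage="scan"))
        counts = []
        for pop, cf in count_frames.items():
            cf = cf.copy()
            cf.insert(0, "population", pop)
            cf["total_windows"] = cf.attrs.get("total_windows")
            counts.append(cf)
        write_tsv(pd.concat(counts, ignore_index=True),
                  self.out / "category_counts.tsv", self._meta(stage="scan"))
        # cross-population candidates on shared polarity (first population's
        # pre-1970s major allele)
        pops = self.populations()
        if len(pops) >= 2:
            ref_f1 = per_pop_candidates[pops[0]][0]
            ref_major1 = ref_f1[:, 0] >= 0.5
            frames = {}
            for pop in pops:
                f1, n, markers, gens_ = per_pop_candidates[pop]
                fpol = np.where(ref_major1[:, None], f1, 1 - f1)
                slopes, _ = ts.delta_f_many(fpol, gens_,
                                            tuple(cfg["fixation_bounds"]))
                frames[pop] = pd.DataFrame(
                    {"marker": markers, "delta_f": slopes,
                     "final_freq": fpol[:, -1]})
            cands = sw.cross_population_candidates(frames, self.thresholds)
            write_tsv(cands, self.out / "candidates.tsv",
                      self._meta(stage="scan"))

    def stage_spectra(self):
        cfg = self.cfg
        spectra_dir = self.out / "spectra"
        spectra_dir.mkdir(exist_ok=True)
        self.tracked = {}
        for pop in self.populations():
            early = sp.window_haplotype_spectrum(
                self.g.lines_in(population=pop, cohort="pre1970s"),
                cfg["window"], cfg["step"])
            late = sp.window_haplotype_spectrum(
                self.g.lines_in(population=pop, cohort="2000s"),
                cfg["window"], cfg["step"])
            tracked = sp.track_spectra_over_cohorts(early, late)
            self.tracked[pop] = tracked
            h_pre = sp.h_scan(self.g.lines_in(population=pop,
                                              cohort="pre1970s"))
            rows = []
            for t in tracked:
                rows.append((t.chrom, t.start_index,
                             len(t.early), len(t.late),
                             t.max_haplotype_change))
            frame = pd.DataFrame(rows, columns=["chrom", "start_index",
                                                "n_hap_early", "n_hap_late",
                                                "max_haplotype_change"])
            safe = pop.replace("/", "_").replace("+", "plus")
            write_tsv(frame, spectra_dir / f"{safe}_spectra.tsv",
                      self._meta(stage="spectra", population=pop))
            write_tsv(h_pre, spectra_dir / f"{safe}_H_pre1970s.tsv",
                      self._meta(stage="spectra", population=pop,
                                 cohort="pre1970s"))

    def stage_power(self):
        p = self.cfg["power"]
        res = pw.run_power_grid(
            N=p["N"], reps=p["reps"], fpr=p["fpr"],
            sample_sizes=tuple(p["sample_sizes"]),
            seed=int(np.random.SeedSequence([self.seed, 7])
                     .generate_state(1)[0] % 2**31))
        write_tsv(res.table, self.out / "power_grid.tsv",
                  self._meta(stage="power", reps=p["reps"], N=p["N"],
                             fpr=p["fpr"]))

    # -- driver ----------------------------------------------------------
    def run(self, stages=None) -> list[Path]:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        handler = logging.FileHandler(self.out / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s "
                                               "%(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
        try:
            log.info("run start: seed=%d stages=%s", self.seed, stages)
            needs_data = any(s != "power" for s in stages)
            if needs_data:
                self.load_inputs()
            for stage in STAGES:        # fixed order, honoring dependencies
                if stage not in stages:
                    continue
                t0 = time.time()
                getattr(self, f"stage_{stage}")()
                log.info("stage %s done in %.1fs", stage, time.time() - t0)
        finally:
            log.removeHandler(handler)
            handler.close()
        return sorted(p for p in self.out.rglob("*") if p.is_file())


def run_full_analysis(config_path=None, out_dir="temposel_out",
                      seed: int = 0, stages=None) -> list[Path]:
    """Load config, run the requested stages, return written paths."""
    cfg = load_config(config_path)
    return Pipeline(cfg, out_dir, seed).run(stages)
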