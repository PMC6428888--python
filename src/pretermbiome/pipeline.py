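"""End-to-end pipeline: filters -> CST typing -> error model -> risk fits ->
thresholds/FDR -> survival -> immune-modulation analyses.

Configured by :class:`PipelineConfig` (YAML-loadable); every stage writes
its serialized outputs plus a run manifest with sample/taxon accounting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, cst, risk_spline
from .core_data import (
    DEFAULT_CONTAMINANTS,
    TaxaTable,
    absolute_abundance,
    filter_min_reads,
    filter_prevalence,
    filter_studywide_frequency,
    read_taxa_table,
    remove_contaminants,
    shannon_diversity,
    write_taxa_table,
)
from .error_model import fit_error_model
from .synthetic import CohortSpec, generate_bd2, generate_cohort, generate_positive_controls

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures"]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end analysis."""

    # inputs (TSV dialect of core_data); None = must be simulated first
    taxa_path: str | None = None
    meta_path: str | None = None
    counts_path: str | None = None
    controls_path: str | None = None
    out_dir: str = "results"
    # filters
    min_reads: int = 1000
    studywide_freq: float = 1e-5
    prevalence: float = 0.25
    contaminants: list = field(default_factory=lambda: list(DEFAULT_CONTAMINANTS))
    # model
    seed: int = 17
    n_resamples: int = 5
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    max_bins: int = 100
    min_n: int = 50
    effect_floor: float = 0.10
    alpha: float = 0.05
    # strata
    outcome_cutoff: float = 37.0
    strata: list = field(default_factory=lambda: ["all"])  # all | AA | nonAA | visit1 ...
    # limit risk modelling to these taxa (None = all prevalence-passing)
    risk_taxa: list | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def spline_config(self) -> risk_spline.SplineConfig:
        return risk_spline.SplineConfig(
            seed=self.seed,
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            max_bins=self.max_bins,
            min_n=self.min_n,
            effect_floor=self.effect_floor,
        )


def _stratum_mask(meta: pd.DataFrame, stratum: str) -> pd.Series:
    if stratum == "all":
        return pd.Series(True, index=meta.index)
    if stratum in ("AA", "nonAA", "other"):
        return meta["race_group"] == stratum
    if stratum.startswith("visit"):
        return meta["visit"] == int(stratum[-1])
    if stratum == "nulliparous":
        return meta["nulliparous"].astype(bool)
    if stratum == "multiparous":
        return ~meta["nulliparous"].astype(bool)
    raise ValueError(f"unknown stratum {stratum!r}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the results directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed}

    t = read_taxa_table(config.taxa_path, config.meta_path, counts_path=config.counts_path)
    if config.outcome_cutoff != 37.0:
        t = t.with_outcome_cutoff(config.outcome_cutoff)
    manifest["stages"]["input"] = {"samples": t.n_samples, "taxa": t.n_taxa}

    # ---- filters ----------------------------------------------------------
    t, rep_c = remove_contaminants(t, config.contaminants)
    if t.counts is not None:
        t, rep_r = filter_min_reads(t, config.min_reads)
    else:
        rep_r = None
        log.warning("no counts provided; read-depth filter skipped")
    t, rep_f = filter_studywide_frequency(t, config.studywide_freq)
    manifest["stages"]["filtered"] = {
        "samples": t.n_samples,
        "taxa": t.n_taxa,
        "removed_contaminants": len(rep_c.removed_taxa),
        "removed_low_depth_samples": len(rep_r.removed_samples) if rep_r else 0,
        "removed_rare_taxa": len(rep_f.removed_taxa),
    }
    write_taxa_table(t, out / "filtered_taxa.tsv", out / "filtered_meta.tsv")

    # ---- CST typing -------------------------------------------------------
    assignments = cst.assign_csts(t)
    adf = cst.assignments_frame(assignments)
    adf.to_csv(out / "cst_assignments.tsv", sep="\t", index=False)
    freq_tests = pd.concat(
        [cst.cst_frequency_test(assignments, t, visit=v) for v in (1, 2, 3)],
        ignore_index=True,
    )
    freq_tests.to_csv(out / "cst_frequency_tests.tsv", sep="\t", index=False)
    manifest["stages"]["cst"] = adf["cst"].value_counts().to_dict()

    # ---- error model ------------------------------------------------------
    if config.controls_path is None:
        raise ValueError("controls_path is required (replicate positive controls)")
    controls = pd.read_csv(config.controls_path, sep="\t", index_col=0)
    em = fit_error_model(controls)
    em.to_json(out / "error_model.json")
    manifest["stages"]["error_model"] = {
        "replicates": int(controls.shape[0]),
        "taxa_in_fit": int(len(em.diagnostics)),
    }

    # ---- per-taxon risk fits ---------------------------------------------
    eligible = filter_prevalence(t, config.prevalence)
    if config.risk_taxa is not None:
        eligible = [tx for tx in eligible if tx in set(config.risk_taxa)]
    manifest["stages"]["risk_eligible_taxa"] = len(eligible)
    scfg = config.spline_config()
    all_summaries = {}
    fits_by_stratum: dict[str, list] = {}
    for stratum in config.strata:
        mask = _stratum_mask(t.meta, stratum)
        sub = t.subset_samples(list(t.meta.index[mask]))
        y_all = (sub.meta["outcome"] == "sPTB").astype(float)
        fits = []
        for taxon in eligible:
            ra = sub.rel_abund[taxon]
            det = ra > 0
            n_det = int(det.sum())
            if n_det < config.min_n:
                log.info("%s/%s: %d detected (< %d), skipped", stratum, taxon, n_det, config.min_n)
                continue
            x = np.log10(ra[det].to_numpy())
            y = y_all[det].to_numpy()
            fit = risk_spline.fit_with_measurement_error(
                x, y, em, scfg, n_resamples=config.n_resamples, taxon=taxon
            )
            fits.append(fit)
        summary = risk_spline.association_significance(
            fits, alpha=config.alpha, effect_floor=config.effect_floor
        )
        summary.insert(0, "stratum", stratum)
        all_summaries[stratum] = summary
        fits_by_stratum[stratum] = fits
        for fit in fits:
            fit.to_json(out / f"risk_{stratum}_{_slug(fit.taxon)}.json")
    risk_summary = pd.concat(all_summaries.values(), ignore_index=True)
    risk_summary.to_csv(out / "risk_summary.tsv", sep="\t", index=False)
    manifest["stages"]["risk_fits"] = {s: len(f) for s, f in fits_by_stratum.items()}

    # ---- gestational-age trends ------------------------------------------
    div = t.rel_abund.apply(lambda row: shannon_diversity(row.to_numpy()), axis=1)
    trend_div = cohort_stats.fit_gestational_trend(div, t.meta["ga_sample"])
    trends = {"shannon_diversity": {"n_knots": trend_div.n_knots, "aic": trend_div.aic}}
    if "total_16s_copies" in t.meta.columns and t.meta["total_16s_copies"].notna().any():
        ok = t.meta["total_16s_copies"].notna()
        trend_burden = cohort_stats.fit_gestational_trend(
            np.log10(t.meta.loc[ok, "total_16s_copies"]), t.meta.loc[ok, "ga_sample"]
        )
        trends["log10_total_16s"] = {"n_knots": trend_burden.n_knots, "aic": trend_burden.aic}
        abs_ab = absolute_abundance(t)
        abs_ab.to_csv(out / "absolute_abundance.tsv", sep="\t")
    else:
        log.warning("qPCR totals missing; absolute-abundance analyses skipped")
    with open(out / "trends.json", "w") as fh:
        json.dump(trends, fh, indent=2)

    # ---- survival for significant taxa with thresholds -------------------
    surv_rows = []
    base_summary = all_summaries.get("all", risk_summary)
    for _, row in base_summary.iterrows():
        if not row["significant"] or row["threshold"] is None or pd.isna(row["threshold"]):
            continue
        iv = cohort_stats.make_intervals(t, row["taxon"], float(row["threshold"]))
        if len(iv) == 0 or iv["event"].sum() == 0:
            continue
        res = cohort_stats.cox_time_varying(iv)
        surv_rows.append(
            {
                "taxon": row["taxon"],
                "threshold": row["threshold"],
                "hazard_ratio": res.hazard_ratio,
                "ci_lo": res.ci_lo,
                "ci_hi": res.ci_hi,
                "p": res.p,
                "flagged": res.flagged,
            }
        )
    surv = pd.DataFrame(surv_rows)
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    manifest["stages"]["survival_models"] = len(surv)

    # ---- beta-defensin-2 analyses ----------------------------------------
    bd2_results: dict = {}
    v1 = t.meta[t.meta["visit"] == 1]
    has_bd2 = "bd2_pg_ml" in v1.columns and v1["bd2_pg_ml"].notna()
    if has_bd2 is not False and has_bd2.sum() >= 4:
        v1 = v1[has_bd2]
        vals = v1["bd2_pg_ml"].to_numpy(dtype=float)
        grp = v1["outcome"].to_numpy()
        if len(np.unique(grp)) == 2:
            diff, p = cohort_stats.bd2_group_test(vals, grp)
            bd2_results["t_test"] = {"log10_mean_diff": diff, "p": p}
        # quartile modulation per significant taxon
        qm = {}
        for _, row in base_summary.iterrows():
            if not row["significant"]:
                continue
            det = t.rel_abund.loc[v1.index, row["taxon"]] > 0
            if det.sum() < 20:
                continue
            tab, comp = cohort_stats.quartile_modulation(
                vals[det.to_numpy()],
                (v1.loc[det, "outcome"] == "sPTB").astype(int).to_numpy(),
            )
            qm[row["taxon"]] = {
                "quartiles": tab.to_dict(orient="records"),
                "q1_vs_q4_p": comp.p_value_analog,
            }
        bd2_results["quartile_modulation"] = qm
        # 3x3 interaction grid
        from .synthetic import LACTOBACILLUS_SPECIES

        lacto_cols = [c for c in t.taxa if c in LACTOBACILLUS_SPECIES or c.startswith("Lactobacillus")]
        lacto = t.rel_abund.loc[v1.index, lacto_cols].sum(axis=1).to_numpy()
        mc = "Mobiluncus curtisii/mulieris"
        thr_row = base_summary[base_summary["taxon"] == mc]
        thr = (
            float(thr_row["threshold"].iloc[0])
            if len(thr_row) and pd.notna(thr_row["threshold"].iloc[0])
            else None
        )
        csts_v1 = adf.loc[adf.index.intersection(v1.index), "cst"].reindex(v1.index)
        n_base = int(len(v1))
        x_base = int((v1["outcome"] == "sPTB").sum())
        cells = cohort_stats.interaction_grid(
            vals,
            lacto,
            (v1["outcome"] == "sPTB").astype(int).to_numpy(),
            csts=csts_v1.to_numpy(),
            mcurtisii_ra=t.rel_abund.loc[v1.index, mc].to_numpy() if mc in t.taxa else None,
            mcurtisii_threshold=thr,
            baseline_x=x_base,
            baseline_n=n_base,
        )
        cohort_stats.grid_frame(cells).to_csv(out / "interaction_grid.tsv", sep="\t", index=False)
        bd2_results["grid_baseline"] = {"x": x_base, "n": n_base,
                                        "proportion_pct": round(100 * x_base / n_base, 2)}
    else:
        log.warning("insufficient beta-defensin-2 data; modulation analyses skipped")
    with open(out / "bd2_results.json", "w") as fh:
        json.dump(bd2_results, fh, indent=2)

    manifest["accounting_consistent"] = (
        manifest["stages"]["input"]["samples"]
        == manifest["stages"]["filtered"]["samples"]
        + manifest["stages"]["filtered"]["removed_low_depth_samples"]
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name)


def make_fixtures(seed: int, size: str = "small", out_dir: str = "fixtures") -> Path:
    """Write synthetic cohort + controls + truth files for tests/demos.

    ``size='small'`` (~70 subjects, <=200 samples) or 'medium' (~540
    subjects, the study-scale design).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = {"small": 70, "medium": 539}[size]
    spec = CohortSpec(n_subjects=n, seed=seed)
    table, truth = generate_cohort(spec)
    bd2 = generate_bd2(spec, table)
    meta = table.meta.copy()
    meta.loc[bd2.index, "bd2_pg_ml"] = bd2
    table = TaxaTable(table.rel_abund, meta, table.counts, check_row_sums=False)
    write_taxa_table(table, out / "taxa.tsv", out / "meta.tsv", counts_path=out / "counts.tsv")
    controls = generate_positive_controls(spec, n_taxa=40)
    controls.rel_abund.rename_axis("sample_id").to_csv(out / "controls.tsv", sep="\t")
    truth.to_json(out / "truth.json")
    return out
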