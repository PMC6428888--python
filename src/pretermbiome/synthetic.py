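"""Synthetic cohorts with known ground truth.

Emulates the statistical structure the downstream analyses assume:

* community state type (CST) block structure — four *Lactobacillus*-dominated
  profiles (I, II, III, V) and two diverse anaerobic profiles (IV-A with
  BVAB1, IV-B), mixed with race-group-dependent weights;
* bimodal per-taxon log10 relative-abundance distributions, arising from the
  CST mixture plus a detection floor (logistic-normal draws around each
  CST's mean composition);
* a nested 1:4 case:control design (~20% spontaneous preterm cases) with
  three visits and attrition after preterm delivery;
* injectable logistic risk dependence of the birth outcome on chosen taxa
  (log-odds additive across risk taxa, evaluated on visit-1 abundances);
* replicate positive-control tables with abundance-dependent measurement
  error (replicate spread increasing as abundance decreases);
* visit-1 beta-defensin-2 concentrations with outcome/CST-dependent
  location and an assay detection floor.

Every generator is deterministic given ``CohortSpec.seed``; sub-streams are
spawned so cohort, controls and bd2 draws are independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core_data import TaxaTable

__all__ = [
    "TAXON_PANEL",
    "LACTOBACILLUS_SPECIES",
    "RiskCurve",
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_positive_controls",
    "generate_bd2",
    "default_error_sd",
]

#: ~20-taxon panel: four Lactobacillus species, the seven risk-associated
#: anaerobes, BVAB1 (defines CST IV-A) and common vaginal genera.
TAXON_PANEL = (
    "Lactobacillus crispatus",
    "Lactobacillus gasseri",
    "Lactobacillus iners",
    "Lactobacillus jensenii",
    "Gardnerella vaginalis",
    "BVAB1",
    "Atopobium vaginae",
    "g Atopobium",
    "g Megasphaera",
    "Sneathia sanguinegens",
    "Mobiluncus curtisii/mulieris",
    "Mageeibacillus indolicus",
    "Prevotella bivia",
    "Prevotella amnii",
    "g Dialister",
    "Finegoldia magna",
    "Anaerococcus tetradius",
    "Ureaplasma parvum",
    "g Corynebacterium",
    "g Streptococcus",
)

LACTOBACILLUS_SPECIES = TAXON_PANEL[:4]

CSTS = ("I", "II", "III", "IV-A", "IV-B", "V")


def _profile(dominant: dict[str, float], background: float = 1e-4) -> dict[str, float]:
    """Mean composition: named taxa at given proportions, rest share the remainder."""
    rest = [t for t in TAXON_PANEL if t not in dominant]
    left = 1.0 - sum(dominant.values())
    out = dict(dominant)
    for t in rest:
        out[t] = left / len(rest)
    return out


#: Per-CST mean compositions (proportions over TAXON_PANEL).
DEFAULT_CST_PROFILES: dict[str, dict[str, float]] = {
    "I": _profile({"Lactobacillus crispatus": 0.85, "Lactobacillus iners": 0.05}),
    "II": _profile({"Lactobacillus gasseri": 0.80, "Lactobacillus iners": 0.06}),
    "III": _profile({"Lactobacillus iners": 0.82, "Gardnerella vaginalis": 0.06}),
    "IV-A": _profile(
        {
            "BVAB1": 0.30,
            "Gardnerella vaginalis": 0.15,
            "g Megasphaera": 0.10,
            "Sneathia sanguinegens": 0.07,
            "g Atopobium": 0.06,
            "Mobiluncus curtisii/mulieris": 0.05,
            "Mageeibacillus indolicus": 0.05,
            "Lactobacillus iners": 0.05,
        }
    ),
    "IV-B": _profile(
        {
            "Gardnerella vaginalis": 0.28,
            "Atopobium vaginae": 0.15,
            "g Atopobium": 0.08,
            "Prevotella bivia": 0.08,
            "g Megasphaera": 0.06,
            "Mobiluncus curtisii/mulieris": 0.04,
            "Sneathia sanguinegens": 0.04,
            "Lactobacillus iners": 0.08,
        }
    ),
    "V": _profile({"Lactobacillus jensenii": 0.80, "Lactobacillus crispatus": 0.06}),
}

#: Race-group CST weights: Lactobacillus-depauperate states more frequent
#: in the AA stratum, CST I dominating the non-AA stratum.
DEFAULT_CST_WEIGHTS: dict[str, dict[str, float]] = {
    "AA": {"I": 0.20, "II": 0.05, "III": 0.25, "IV-A": 0.20, "IV-B": 0.25, "V": 0.05},
    "nonAA": {"I": 0.50, "II": 0.08, "III": 0.20, "IV-A": 0.07, "IV-B": 0.08, "V": 0.07},
    "other": {"I": 0.45, "II": 0.08, "III": 0.22, "IV-A": 0.08, "IV-B": 0.10, "V": 0.07},
}

#: Race-group marginal frequencies (cohort predominantly African American).
DEFAULT_RACE_WEIGHTS = {"AA": 0.745, "nonAA": 0.215, "other": 0.04}


def default_error_sd(x: np.ndarray) -> np.ndarray:
    """Replicate sd of log10 RA as a function of mean log10 RA.

    Flat 0.05 above 1% abundance, rising linearly to 0.35 at 0.01%
    (spread grows as abundance falls).
    """
    x = np.asarray(x, dtype=float)
    return 0.05 + 0.3 * np.maximum(0.0, -x - 2.0) / 2.0


@dataclass
class RiskCurve:
    """Injected dependence of sPTB risk on one taxon's log10 relative abundance.

    ``kind='logistic'``: r(x) = expit(a + b*(x - x_ref));
    ``kind='step'``: lo below x0, hi at or above x0.
    """

    taxon: str
    kind: str = "logistic"
    a: float = -1.6
    b: float = 1.1
    x_ref: float = -4.0
    x0: float = -2.0
    lo: float = 0.15
    hi: float = 0.55

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "logistic":
            from scipy.special import expit

            return expit(self.a + self.b * (x - self.x_ref))
        if self.kind == "step":
            return np.where(x >= self.x0, self.hi, self.lo)
        raise ValueError(f"unknown risk curve kind {self.kind!r}")


@dataclass
class CohortSpec:
    """Study-condition parameters for the synthetic cohort."""

    n_subjects: int = 539
    case_fraction: float = 0.2
    n_visits: int = 3
    seed: int = 0
    cst_profiles: dict = field(default_factory=lambda: dict(DEFAULT_CST_PROFILES))
    cst_mixture_weights: dict = field(default_factory=lambda: dict(DEFAULT_CST_WEIGHTS))
    race_weights: dict = field(default_factory=lambda: dict(DEFAULT_RACE_WEIGHTS))
    risk_taxa: list = field(
        default_factory=lambda: [RiskCurve("Mobiluncus curtisii/mulieris")]
    )
    #: logistic-normal spread (natural-log scale) around CST profile means
    composition_sigma: float = 1.2
    #: CST persistence probability between consecutive visits
    cst_persistence: float = 0.85
    #: relative abundances below this floor are recorded as undetected (0)
    detection_floor: float = 3e-5
    #: per-visit missingness independent of outcome
    dropout: float = 0.04
    #: mean read depth for simulated counts (lognormal around this)
    mean_reads: float = 40000.0
    #: total 16S copies/swab: log10 ~ Normal(mu, sd)
    log10_total_mu: float = 7.0
    log10_total_sd: float = 0.7
    # beta-defensin-2 (pg/ml): log10 location by outcome; order-of-magnitude
    # guesses, not literature values — adjust per study.
    bd2_log10_loc: float = 3.0
    bd2_log10_scale: float = 0.5
    bd2_case_shift: float = -0.3
    bd2_cst_shift: dict = field(default_factory=dict)
    bd2_detection_limit: float = 15.6
    error_profile: Callable = default_error_sd

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        """Load scalar fields (and optional risk_taxa specs) from YAML.

        The error profile and CST profile tables keep their defaults unless
        overridden programmatically.
        """
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "risk_taxa" in d:
            d["risk_taxa"] = [RiskCurve(**rc) for rc in d["risk_taxa"]]
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown cohort-spec keys: {sorted(unknown)}")
        spec = cls(**known)
        spec.validate()
        return spec

    def to_yaml(self, path) -> None:
        import yaml
        from dataclasses import asdict

        d = {
            k: getattr(self, k)
            for k in (
                "n_subjects", "case_fraction", "n_visits", "seed",
                "composition_sigma", "cst_persistence", "detection_floor",
                "dropout", "mean_reads", "log10_total_mu", "log10_total_sd",
                "bd2_log10_loc", "bd2_log10_scale", "bd2_case_shift",
                "bd2_detection_limit",
            )
        }
        d["risk_taxa"] = [asdict(rc) for rc in self.risk_taxa]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def validate(self) -> None:
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")
        if self.n_subjects < 1 or self.n_visits not in (1, 2, 3):
            raise ValueError("need n_subjects >= 1 and n_visits in {1,2,3}")
        for grp, w in self.cst_mixture_weights.items():
            tot = sum(w.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(f"CST weights for {grp!r} sum to {tot}, not 1")
        for cst, prof in self.cst_profiles.items():
            if abs(sum(prof.values()) - 1.0) > 1e-6:
                raise ValueError(f"profile {cst!r} does not sum to 1")


@dataclass
class SyntheticTruth:
    """Ground truth recorded before noise/censoring is applied."""

    subjects: pd.DataFrame  # subject_id, race_group, cst_v1..v3, p_sptb, outcome
    log10_abund: pd.DataFrame  # per retained sample, true log10 RA (NaN = absent)
    cst_labels: pd.Series  # per retained sample
    risk_truth: dict  # taxon -> {g_eff, threshold, x_grid, r}
    intercept_shift: float

    def to_json(self, path) -> None:
        payload = {
            "subjects": self.subjects.to_dict(orient="list"),
            "log10_abund": {
                "index": list(self.log10_abund.index),
                "columns": list(self.log10_abund.columns),
                "values": np.where(
                    np.isnan(self.log10_abund.to_numpy()), None, self.log10_abund.to_numpy()
                ).tolist(),
            },
            "cst_labels": self.cst_labels.to_dict(),
            "risk_truth": {
                k: {kk: (list(vv) if isinstance(vv, (list, np.ndarray)) else vv)
                    for kk, vv in v.items()}
                for k, v in self.risk_truth.items()
            },
            "intercept_shift": self.intercept_shift,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        la = pd.DataFrame(
            np.array(
                [[np.nan if v is None else v for v in row] for row in d["log10_abund"]["values"]],
                dtype=float,
            ),
            index=d["log10_abund"]["index"],
            columns=d["log10_abund"]["columns"],
        )
        return cls(
            subjects=pd.DataFrame(d["subjects"]),
            log10_abund=la,
            cst_labels=pd.Series(d["cst_labels"]),
            risk_truth=d["risk_truth"],
            intercept_shift=d["intercept_shift"],
        )


# ---------------------------------------------------------------------------


def _draw_composition(rng, profile: np.ndarray, sigma: float, floor: float) -> np.ndarray:
    """Logistic-normal draw around a CST profile, censored at the detection floor."""
    z = np.log(profile) + sigma * rng.standard_normal(profile.size)
    p = np.exp(z - z.max())
    p /= p.sum()
    p[p < floor] = 0.0
    s = p.sum()
    if s == 0:  # pathological floor; keep the dominant taxon
        p[np.argmax(z)] = 1.0
    else:
        p /= s
    return p


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Offset c with mean(expit(eta + c)) = target."""
    from scipy.optimize import brentq
    from scipy.special import expit

    def g(c):
        return float(np.mean(expit(eta + c))) - target

    return brentq(g, -20.0, 20.0, xtol=1e-10)


def generate_cohort(spec: CohortSpec) -> tuple[TaxaTable, SyntheticTruth]:
    """Simulate the nested case-control cohort.

    Outcomes are Bernoulli in the visit-1 latent abundances: the linear
    predictor adds logit(r_t(x_t)) - logit(case_fraction) over detected risk
    taxa, plus an intercept calibrated so the marginal case fraction matches
    ``spec.case_fraction``; the realized (post-calibration) risk curves are
    what :class:`SyntheticTruth` records. Subjects delivering preterm
    contribute no samples after delivery.
    """
    from scipy.special import expit, logit

    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    taxa = list(TAXON_PANEL)
    profiles = {c: np.array([spec.cst_profiles[c][t] for t in taxa]) for c in spec.cst_profiles}
    cst_names = list(spec.cst_profiles)

    races = rng.choice(
        list(spec.race_weights), size=spec.n_subjects, p=list(spec.race_weights.values())
    )

    # CST trajectory and latent compositions for every potential visit
    comp = {}  # (subj, visit) -> composition
    cst_traj = {}
    for i in range(spec.n_subjects):
        w = spec.cst_mixture_weights[races[i]]
        pvec = np.array([w[c] for c in cst_names])
        cst = rng.choice(cst_names, p=pvec)
        for v in range(1, spec.n_visits + 1):
            if v > 1 and rng.random() > spec.cst_persistence:
                cst = rng.choice(cst_names, p=pvec)
            cst_traj[i, v] = cst
            comp[i, v] = _draw_composition(
                rng, profiles[cst], spec.composition_sigma, spec.detection_floor
            )

    # outcome from visit-1 latent abundances, log-odds additive
    base_logit = logit(spec.case_fraction)
    eta = np.full(spec.n_subjects, base_logit)
    idx_of = {t: j for j, t in enumerate(taxa)}
    for rc in spec.risk_taxa:
        j = idx_of[rc.taxon]
        for i in range(spec.n_subjects):
            ra = comp[i, 1][j]
            if ra > 0:
                r = float(np.clip(rc(np.log10(ra)), 1e-6, 1 - 1e-6))
                eta[i] += logit(r) - base_logit
    shift = _solve_intercept(eta, spec.case_fraction) if spec.risk_taxa else 0.0
    p_sptb = expit(eta + shift)
    outcome = rng.random(spec.n_subjects) < p_sptb

    # delivery timing: term ~ N(39.2, 1.1) in [37, 41.5]; sPTB ~ N(33, 4) in [20, 36.9]
    ga_del = np.where(
        outcome,
        np.clip(rng.normal(33.0, 4.0, spec.n_subjects), 20.0, 36.9),
        np.clip(rng.normal(39.2, 1.1, spec.n_subjects), 37.0, 41.5),
    )

    windows = {1: (16.0, 20.0), 2: (20.0, 24.0), 3: (24.0, 28.0)}
    ids, rows, meta_rows, count_rows, truth_rows, cst_rows = [], [], [], [], [], []
    for i in range(spec.n_subjects):
        for v in range(1, spec.n_visits + 1):
            lo, hi = windows[v]
            ga = rng.uniform(lo, hi)
            if ga >= ga_del[i]:  # delivered before this visit
                continue
            if rng.random() < spec.dropout:
                continue
            sid = f"S{i:04d}V{v}"
            p = comp[i, v]
            depth = int(rng.lognormal(np.log(spec.mean_reads), 0.35))
            counts = rng.multinomial(depth, p)
            # observed RA from counts (sequencing realization of the latent mix)
            ids.append(sid)
            rows.append(counts / counts.sum())
            count_rows.append(counts)
            meta_rows.append(
                (
                    sid,
                    f"S{i:04d}",
                    v,
                    races[i],
                    round(ga, 2),
                    round(float(ga_del[i]), 2),
                    "sPTB" if outcome[i] else "term",
                    bool(rng.random() < 0.42),
                    float(10 ** rng.normal(spec.log10_total_mu, spec.log10_total_sd)),
                )
            )
            with np.errstate(divide="ignore"):
                truth_rows.append(np.where(p > 0, np.log10(np.where(p > 0, p, 1.0)), np.nan))
            cst_rows.append((sid, cst_traj[i, v]))

    ra_df = pd.DataFrame(np.vstack(rows), index=ids, columns=taxa)
    counts_df = pd.DataFrame(np.vstack(count_rows), index=ids, columns=taxa)
    meta_df = pd.DataFrame(
        meta_rows,
        columns=[
            "sample_id", "subject_id", "visit", "race_group", "ga_sample",
            "ga_delivery", "outcome", "nulliparous", "total_16s_copies",
        ],
    )
    meta_df["bd2_pg_ml"] = np.nan
    table = TaxaTable(ra_df, meta_df, counts_df)

    # realized risk curves after intercept calibration, over each taxon's
    # detected range in the generated data
    risk_truth = {}
    for rc in spec.risk_taxa:
        det = ra_df[rc.taxon][ra_df[rc.taxon] > 0]
        if len(det) == 0:
            continue
        x = np.log10(det.to_numpy())
        grid = np.linspace(x.min(), x.max(), 201)
        r_real = expit(logit(np.clip(rc(grid), 1e-6, 1 - 1e-6)) + shift)
        g_eff, thr = _curve_effect_and_threshold(grid, r_real)
        risk_truth[rc.taxon] = {
            "g_eff": g_eff,
            "threshold": thr,
            "x_grid": grid,
            "r": r_real,
        }

    truth = SyntheticTruth(
        subjects=pd.DataFrame(
            {
                "subject_id": [f"S{i:04d}" for i in range(spec.n_subjects)],
                "race_group": races,
                "outcome": np.where(outcome, "sPTB", "term"),
                "p_sptb": p_sptb,
                "ga_delivery": ga_del,
                "cst_v1": [cst_traj[i, 1] for i in range(spec.n_subjects)],
            }
        ),
        log10_abund=pd.DataFrame(np.vstack(truth_rows), index=ids, columns=taxa),
        cst_labels=pd.Series(dict(cst_rows)),
        risk_truth=risk_truth,
        intercept_shift=float(shift),
    )
    return table, truth


def _curve_effect_and_threshold(x: np.ndarray, f: np.ndarray, floor: float = 0.10):
    """Signed effect size and risk threshold of a known curve (same rule as
    the estimator applies to fitted curves)."""
    from .risk_spline import signed_effect_size, threshold_from_curve

    g = signed_effect_size(x, f)
    return g, threshold_from_curve(x, f, g, effect_floor=floor)


def generate_positive_controls(
    spec: CohortSpec, n_replicates: int = 14, n_taxa: int | None = None
) -> TaxaTable:
    """Replicate re-sequencings of one pooled control sample.

    Each replicate draws per-taxon log10 RA from Normal(true mean,
    error_profile(true mean)) and re-closes the row; the spread therefore
    grows as true abundance falls.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng = np.random.default_rng(ss[1])
    taxa = list(TAXON_PANEL)
    # pooled-specimen composition: average of CST profiles (a mixture of
    # many donor swabs spans both dominated and diverse communities)
    profiles = np.array([[spec.cst_profiles[c][t] for t in taxa] for c in spec.cst_profiles])
    true = profiles.mean(axis=0)
    true /= true.sum()
    if n_taxa is not None and n_taxa > len(taxa):
        # pad with synthetic low-abundance phylotypes to widen the fit
        # support; a 20-specimen pooled control rarely carries consistently
        # detectable taxa below ~1e-4
        extra = [f"control taxon {k}" for k in range(n_taxa - len(taxa))]
        extra_ra = 10 ** rng.uniform(-4, -1.5, len(extra))
        true = np.concatenate([true, extra_ra])
        true /= true.sum()
        taxa = taxa + extra
    logt = np.log10(true)
    sd = np.asarray(spec.error_profile(logt), dtype=float)
    reps = 10 ** (logt + sd * rng.standard_normal((n_replicates, true.size)))
    reps /= reps.sum(axis=1, keepdims=True)
    ids = [f"CTRL{r + 1:02d}" for r in range(n_replicates)]
    ra = pd.DataFrame(reps, index=ids, columns=taxa)
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "subject_id": "POOLED-CONTROL",
            "visit": 1,
            "race_group": "other",
            "ga_sample": 18.0,
            "ga_delivery": 39.0,
            "outcome": "term",
            "nulliparous": False,
            "total_16s_copies": np.nan,
            "bd2_pg_ml": np.nan,
        }
    )
    return TaxaTable(ra, meta)


def generate_bd2(spec: CohortSpec, table: TaxaTable, cst_labels: pd.Series | None = None) -> pd.Series:
    """Visit-1 beta-defensin-2 concentrations (pg/ml), floored at the assay limit.

    log10 values are normal with location shifted by outcome (cases lower by
    ``bd2_case_shift``) and optionally by CST.
    """
    ss = np.random.SeedSequence(spec.seed).spawn(3)
    rng = np.random.default_rng(ss[2])
    v1 = table.meta[table.meta["visit"] == 1]
    if len(v1) == 0:
        raise ValueError("no visit-1 samples")
    loc = np.full(len(v1), spec.bd2_log10_loc)
    loc += np.where(v1["outcome"] == "sPTB", spec.bd2_case_shift, 0.0)
    if cst_labels is not None and spec.bd2_cst_shift:
        shifts = cst_labels.reindex(v1.index).map(spec.bd2_cst_shift).fillna(0.0)
        loc += shifts.to_numpy()
    vals = 10 ** (loc + spec.bd2_log10_scale * rng.standard_normal(len(v1)))
    vals = np.maximum(vals, spec.bd2_detection_limit)
    return pd.Series(vals, index=v1.index, name="bd2_pg_ml")
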