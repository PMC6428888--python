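"""Community state type (CST) assignment and per-visit frequency tests.

Samples are clustered by Ward-linkage agglomeration on pairwise
Jensen-Shannon divergence between their taxonomic compositions (the
distance actually fed to the linkage is sqrt(JSD), which is a metric) and
cut to six clusters. Clusters are then named from their mean compositions:
clusters dominated by L. crispatus, L. gasseri, L. iners or L. jensenii
become CSTs I, II, III and V respectively; the remaining
Lactobacillus-poor, anaerobe-rich clusters are split into IV-A (the one
with the higher mean BVAB1) and IV-B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_data import TaxaTable

__all__ = [
    "CSTAssignment",
    "jensen_shannon",
    "jsd_matrix",
    "cluster_cst",
    "name_clusters",
    "assign_csts",
    "assign_nearest_centroid",
    "cst_frequency_test",
    "LACTO_CST_MAP",
]

log = logging.getLogger(__name__)

#: Lactobacillus species -> CST label for Lactobacillus-dominated clusters.
LACTO_CST_MAP = {
    "Lactobacillus crispatus": "I",
    "Lactobacillus gasseri": "II",
    "Lactobacillus iners": "III",
    "Lactobacillus jensenii": "V",
}


@dataclass
class CSTAssignment:
    sample_id: str
    cst: str
    cluster_id: int
    dominant_taxon: str
    dominant_fraction: float


def jensen_shannon(p, q) -> float:
    """Jensen-Shannon divergence (base 2) between two proportion vectors.

    JSD = H(m) - (H(p)+H(q))/2 with m = (p+q)/2; symmetric, zero iff p == q,
    bounded in [0, 1] in base 2.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("length mismatch")

    def h(v):
        v = v[v > 0]
        return -(v * np.log2(v)).sum()

    m = (p + q) / 2.0
    return float(max(h(m) - (h(p) + h(q)) / 2.0, 0.0))


def jsd_matrix(ra: np.ndarray) -> np.ndarray:
    """Pairwise JSD (base 2) between rows, vectorised."""
    ra = np.asarray(ra, dtype=float)

    def plogp(v):
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    hp = -plogp(ra).sum(axis=1)  # per-row entropy
    n = ra.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        m = (ra[i] + ra[i + 1 :]) / 2.0
        hm = -plogp(m).sum(axis=1)
        d = hm - (hp[i] + hp[i + 1 :]) / 2.0
        out[i, i + 1 :] = np.maximum(d, 0.0)
    return out + out.T


def cluster_cst(t: TaxaTable, k: int = 6, metric: str = "sqrt_jsd"):
    """Ward-linkage clustering of samples on Jensen-Shannon dissimilarity.

    ``metric='sqrt_jsd'`` (default) feeds sqrt(JSD), a true metric, to the
    linkage; 'jsd' uses the raw divergence for sensitivity analyses.
    Returns (linkage matrix, cluster ids 1..k aligned with sample order).
    """
    n = t.n_samples
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    dm = jsd_matrix(t.rel_abund.to_numpy())
    if metric == "sqrt_jsd":
        dm = np.sqrt(dm)
    elif metric != "jsd":
        raise ValueError(f"unknown metric {metric!r}")
    Z = linkage(squareform(dm, checks=False), method="ward")
    ids = fcluster(Z, t=k, criterion="maxclust")
    return Z, ids


def name_clusters(cluster_ids, t: TaxaTable, lacto_map=None,
                  bvab1_taxon: str = "BVAB1") -> list[CSTAssignment]:
    """Name clusters from their mean compositions.

    A cluster whose mean composition is dominated by one of the four
    Lactobacillus species takes that species' CST label; if two clusters
    claim the same label the one with higher mean dominance keeps it and
    the other joins the IV pool. Among the remaining (Lactobacillus-poor)
    clusters the one with the highest mean BVAB1 is IV-A, the rest IV-B.
    """
    lacto_map = dict(LACTO_CST_MAP if lacto_map is None else lacto_map)
    cluster_ids = np.asarray(cluster_ids)
    ra = t.rel_abund
    cids = np.unique(cluster_ids)
    means = {c: ra[cluster_ids == c].mean(axis=0) for c in cids}

    claims: dict[str, list[tuple[float, int]]] = {}
    for c in cids:
        mean = means[c]
        dom = mean.idxmax()
        if dom in lacto_map:
            claims.setdefault(lacto_map[dom], []).append((float(mean[dom]), int(c)))
    names: dict[int, str] = {}
    iv_pool = [int(c) for c in cids]
    for label, claimants in claims.items():
        claimants.sort(reverse=True)  # highest mean dominance wins
        winner = claimants[0][1]
        names[winner] = label
        iv_pool.remove(winner)
        for _, loser in claimants[1:]:
            log.warning(
                "cluster %d also dominated by CST %s species; demoted to IV pool",
                loser, label,
            )
    if iv_pool:
        if bvab1_taxon in ra.columns:
            bvab = {c: float(means[c].get(bvab1_taxon, 0.0)) for c in iv_pool}
            iva = max(sorted(bvab), key=lambda c: bvab[c])
        else:
            iva = iv_pool[0]
        for c in iv_pool:
            names[c] = "IV-A" if c == iva else "IV-B"

    out = []
    arr = ra.to_numpy()
    dom_idx = arr.argmax(axis=1)
    for i, sid in enumerate(t.sample_ids):
        out.append(
            CSTAssignment(
                sample_id=sid,
                cst=names[int(cluster_ids[i])],
                cluster_id=int(cluster_ids[i]),
                dominant_taxon=ra.columns[dom_idx[i]],
                dominant_fraction=float(arr[i, dom_idx[i]]),
            )
        )
    return out


def assign_csts(t: TaxaTable, k: int = 6, metric: str = "sqrt_jsd") -> list[CSTAssignment]:
    """cluster_cst + name_clusters in one step (joint clustering of all visits)."""
    _, ids = cluster_cst(t, k=k, metric=metric)
    return name_clusters(ids, t)


def assign_nearest_centroid(assignments: list[CSTAssignment], t: TaxaTable,
                            new_ra: pd.DataFrame) -> list[str]:
    """Label new samples by nearest cluster centroid in JSD (out-of-batch)."""
    ids = np.array([a.cluster_id for a in assignments])
    name_of = {a.cluster_id: a.cst for a in assignments}
    centroids = {c: t.rel_abund[ids == c].mean(axis=0).to_numpy() for c in np.unique(ids)}
    labels = []
    for _, row in new_ra.iterrows():
        v = row.to_numpy(dtype=float)
        best = min(centroids, key=lambda c: jensen_shannon(v, centroids[c]))
        labels.append(name_of[best])
    return labels


def assignments_frame(assignments: list[CSTAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "cst": [a.cst for a in assignments],
            "cluster_id": [a.cluster_id for a in assignments],
            "dominant_taxon": [a.dominant_taxon for a in assignments],
            "dominant_fraction": [a.dominant_fraction for a in assignments],
        }
    ).set_index("sample_id", drop=False)


def cst_frequency_test(assignments: list[CSTAssignment], t: TaxaTable,
                       visit: int) -> pd.DataFrame:
    """Per-CST ordinary logistic regression of outcome on CST membership at one visit.

    For each CST, outcome (sPTB=1) is regressed on the CST-membership
    indicator; the table reports the coefficient (log odds ratio), Wald p
    and derived OR. Empty or separated cells are reported as inestimable
    rather than raised.
    """
    import statsmodels.api as sm

    adf = assignments_frame(assignments)
    meta = t.meta[t.meta["visit"] == visit]
    adf = adf.loc[adf.index.intersection(meta.index)]
    y = (meta.loc[adf.index, "outcome"] == "sPTB").astype(float).to_numpy()
    rows = []
    for cst in sorted(adf["cst"].unique()):
        ind = (adf["cst"] == cst).astype(float).to_numpy()
        n_exp = int(ind.sum())
        row = {"visit": visit, "cst": cst, "n_in_cst": n_exp, "n_total": len(ind)}
        tab_ok = 0 < n_exp < len(ind) and 0 < y.sum() < len(y)
        est = None
        if tab_ok:
            try:
                with np.errstate(all="ignore"):
                    model = sm.Logit(y, sm.add_constant(ind)).fit(disp=False, maxiter=100)
                coef = float(model.params[1])
                if abs(coef) < 20:  # separation guard
                    est = {
                        "coef": coef,
                        "odds_ratio": float(np.exp(coef)),
                        "p": float(model.pvalues[1]),
                    }
            except Exception:  # separation / singular -> inestimable
                est = None
        if est is None:
            row.update({"coef": np.nan, "odds_ratio": np.nan, "p": np.nan, "estimable": False})
        else:
            row.update({**est, "estimable": True})
        rows.append(row)
    return pd.DataFrame(rows)
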