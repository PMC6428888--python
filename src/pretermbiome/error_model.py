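"""Abundance-dependent measurement-error model from replicate positive controls.

Amplicon relative abundances are poorly reproducible for rare taxa: across
re-sequencings of the same pooled specimen, the spread of log10 relative
abundance grows as abundance falls. This module fits that spread as a
non-increasing function of mean log10 RA and provides the Gaussian
perturbation sampler the risk model uses to propagate measurement error.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ErrorModel", "fit_error_model", "perturb_abundances"]


@dataclass
class ErrorModel:
    """Replicate sd of log10 RA as a function of mean log10 RA.

    ``grid``/``sd_grid`` define a piecewise-linear sd function, extrapolated
    flat beyond the fitted support; ``diagnostics`` carries the per-taxon
    (mean, sd, n) triples the fit used.
    """

    grid: np.ndarray
    sd_grid: np.ndarray
    diagnostics: pd.DataFrame
    method: str = "isotonic"

    def sd_fn(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.interp(x, self.grid, self.sd_grid)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.grid[0]), float(self.grid[-1])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "grid": self.grid.tolist(),
                    "sd_grid": self.sd_grid.tolist(),
                    "method": self.method,
                    "diagnostics": self.diagnostics.to_dict(orient="list"),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ErrorModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            sd_grid=np.asarray(d["sd_grid"], dtype=float),
            diagnostics=pd.DataFrame(d["diagnostics"]),
            method=d.get("method", "isotonic"),
        )

    @classmethod
    def constant(cls, sd: float) -> "ErrorModel":
        """Fixed-sd model (sd=0 gives the no-noise identity perturbation)."""
        return cls(
            grid=np.array([-9.0, 0.0]),
            sd_grid=np.array([sd, sd], dtype=float),
            diagnostics=pd.DataFrame(columns=["taxon", "mean", "sd", "n"]),
            method="constant",
        )


def fit_error_model(controls, method: str = "isotonic", min_detected: int = 2) -> ErrorModel:
    """Fit the replicate-error profile from a positive-control table.

    Parameters
    ----------
    controls
        TaxaTable (or plain samples x taxa relative-abundance DataFrame)
        whose rows are replicate re-sequencings of one pooled sample.
    method
        'isotonic' (default): non-increasing isotonic regression of
        per-taxon replicate sd on replicate mean log10 RA — the only
        qualitative property asserted of the error process is that spread
        grows at low abundance. 'loglinear': linear fit of sd on mean,
        clipped at 0.
    min_detected
        Taxa detected in fewer replicates are excluded from the fit.

    The fitted curve is evaluated at the observed taxon means and
    extrapolated flat beyond them.
    """
    ra = controls.rel_abund if hasattr(controls, "rel_abund") else controls
    ra = pd.DataFrame(ra)
    if ra.shape[0] < 2:
        raise ValueError("need at least 2 replicate rows to estimate spread")
    means, sds, ns, names = [], [], [], []
    skipped = []
    for taxon in ra.columns:
        col = ra[taxon].to_numpy(dtype=float)
        det = col[col > 0]
        if det.size < min_detected:
            skipped.append(taxon)
            continue
        lg = np.log10(det)
        names.append(taxon)
        means.append(lg.mean())
        sds.append(lg.std(ddof=1))
        ns.append(det.size)
    if len(names) < 3:
        raise ValueError(
            f"only {len(names)} taxa detected in >= {min_detected} replicates; need >= 3"
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} taxa detected in fewer than {min_detected} replicates "
            "were excluded from the error-model fit",
            stacklevel=2,
        )
    diag = pd.DataFrame({"taxon": names, "mean": means, "sd": sds, "n": ns})
    diag = diag.sort_values("mean", kind="mergesort").reset_index(drop=True)
    x = diag["mean"].to_numpy()
    y = diag["sd"].to_numpy()
    if method == "isotonic":
        from sklearn.isotonic import IsotonicRegression

        # pre-smooth the per-taxon sd estimates (each carries sampling noise
        # ~ sd/sqrt(2(n-1)) at replicate count n) before projecting onto the
        # non-increasing cone; raw isotonic is boundary-noisy at 14 replicates
        if len(x) >= 8:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            y_s = lowess(y, x, frac=0.5, it=0, xvals=x)
        else:
            y_s = y
        iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
        fitted = iso.fit_transform(x, y_s)
    elif method == "loglinear":
        b, a = np.polyfit(x, y, 1)
        fitted = np.maximum(a + b * x, 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    # collapse duplicate grid positions for interpolation
    grid, idx = np.unique(x, return_index=True)
    sd_grid = np.maximum(fitted[idx], 0.0)
    return ErrorModel(grid=grid, sd_grid=sd_grid, diagnostics=diag, method=method)


def perturb_abundances(x, em: ErrorModel, seed) -> np.ndarray:
    """Draw x' ~ Normal(x, sd_fn(x)) independently per element.

    ``seed`` may be an int, SeedSequence or Generator; the draw is
    deterministic given it. E[x'] = x, so perturbation preserves ranking in
    expectation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    return x + em.sd_fn(x) * rng.standard_normal(x.shape)
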