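"""Independent oracles used by the test suite.

These deliberately avoid the package's own fitting code paths: a brute-force
grid search of the restricted likelihood, closed-form hand computations, and
the reference R implementation (metafor) driven through Rscript.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from pathlib import Path

import numpy as np


def reml_grid_search(
    y: np.ndarray,
    v: np.ndarray,
    lo: float = 0.0,
    hi: float = 1.0,
    step: float = 1e-6,
    chunk: int = 200_000,
) -> tuple[float, float]:
    """Maximise the intercept-only restricted log-likelihood on a grid.

    Returns (tau2, pooled) at the grid maximiser.  Exhaustive: evaluates
    every grid point, no assumptions about unimodality.
    """
    y = np.asarray(y, float)
    v = np.asarray(v, float)
    grid = np.arange(lo, hi + step / 2, step)
    best_ll = -np.inf
    best_t2 = 0.0
    for start in range(0, len(grid), chunk):
        t2 = grid[start : start + chunk, None]  # (g, 1)
        w = 1.0 / (v[None, :] + t2)  # (g, k)
        sw = w.sum(axis=1)
        swy = (w * y[None, :]).sum(axis=1)
        swy2 = (w * y[None, :] ** 2).sum(axis=1)
        rss = swy2 - swy**2 / sw
        ll = -0.5 * (np.log(v[None, :] + t2).sum(axis=1) + np.log(sw) + rss)
        i = int(np.argmax(ll))
        if ll[i] > best_ll:
            best_ll = float(ll[i])
            best_t2 = float(t2[i, 0])
    w = 1.0 / (v + best_t2)
    pooled = float(np.sum(w * y) / np.sum(w))
    return best_t2, pooled


_METAFOR_SCRIPT = r"""
suppressMessages({library(metafor); library(jsonlite)})
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
f <- rma(yi = d$d, sei = d$se, method = "REML")
fdl <- rma(yi = d$d, sei = d$se, method = "DL")
rt <- regtest(f, model = "rma", predictor = "sei")
out <- list(pooled = unname(f$beta[1]), se_pooled = f$se, tau2 = f$tau2,
            Q = f$QE, Qp = f$QEp, I2 = f$I2,
            ci_low = f$ci.lb, ci_high = f$ci.ub, p = f$pval,
            dl_pooled = unname(fdl$beta[1]), dl_tau2 = fdl$tau2,
            egger_stat = unname(rt$zval))
if ("mod" %in% names(d) && length(unique(d$mod)) > 1) {
  lev <- unique(d$mod)
  ref <- if (!is.null(args[3]) && !is.na(args[3])) args[3] else lev[1]
  mf <- factor(d$mod, levels = c(ref, setdiff(sort(lev), ref)))
  m <- rma(yi = d$d, sei = d$se, mods = ~mf, method = "REML")
  out$QM <- m$QM
  out$QMp <- m$QMp
  out$tau2_resid <- m$tau2
  out$coefs <- unname(as.vector(m$beta))
}
cat(toJSON(out, digits = 12, auto_unbox = TRUE))
"""


def metafor_fit(d: np.ndarray, se: np.ndarray, mod=None, ref: str | None = None) -> dict:
    """Fit the reference R implementation (metafor::rma) on (d, se).

    Optionally includes a single categorical moderator with the given
    reference level.  Returns the parsed JSON result.
    """
    import pandas as pd

    frame = pd.DataFrame({"d": d, "se": se})
    if mod is not None:
        frame["mod"] = list(mod)
    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "data.csv"
        script = Path(tmp) / "oracle.R"
        frame.to_csv(csv, index=False)
        script.write_text(_METAFOR_SCRIPT)
        argv = ["Rscript", "--vanilla", str(script), str(csv), "x", ref or ""]
        res = subprocess.run(argv, capture_output=True, text=True, timeout=300)
        if res.returncode != 0:
            raise RuntimeError(f"metafor oracle failed: {res.stderr[-2000:]}")
        return json.loads(res.stdout)
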