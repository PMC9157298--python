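"""Network-to-outcome analysis: composite scores, Delta connectivity,
Spearman correlation with Benjamini-Hochberg FDR control per family.

Per-subject network dynamics are summarised as Delta = AS - QS, the
difference in mean connectivity over a network's edges between sleep
states. Deltas are correlated (two-tailed Spearman) with clinical
scores; p-values are corrected within declared assessment families
(neurological composites C1/C2 vs the four neurocognitive scores).
"""
from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

NEUROLOGICAL_SCORES = ("C1", "C2")
NEUROCOGNITIVE_SCORES = ("cognitive", "receptive_language",
                         "expressive_language", "fine_motor")


def pca_composites(items: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First principal components of standardized item scores.

    Returns ``(scores, loadings)``: scores have columns C1, C2, ...;
    constant items are dropped with a warning. Component signs are fixed
    so each component's largest-magnitude loading is positive.
    """
    if items.shape[1] < 3 or items.shape[0] < 3:
        raise ValueError("need at least 3 items and 3 subjects")
    X = items.astype(float)
    const = X.std(axis=0, ddof=0) == 0
    if const.any():
        warnings.warn(f"dropping constant items: {list(X.columns[const])}")
        X = X.loc[:, ~const]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z.values)
    loadings = pca.components_
    for k in range(n_components):
        lead = np.argmax(np.abs(loadings[k]))
        if loadings[k, lead] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    names = [f"C{k + 1}" for k in range(n_components)]
    return (pd.DataFrame(scores, index=items.index, columns=names),
            pd.DataFrame(loadings, index=names, columns=Z.columns))


def delta_connectivity(cm_as: ConnectivityMatrix, cm_qs: ConnectivityMatrix,
                       network: list[tuple[int, int]]) -> float:
    """Mean AS - QS connectivity over a network's edges."""
    if not network:
        raise ValueError("empty network")
    edges = sorted({tuple(sorted(e)) for e in network})
    vals = []
    for i, j in edges:
        a, q = cm_as.values[i, j], cm_qs.values[i, j]
        if np.isnan(a) or np.isnan(q):
            raise ValueError(f"edge ({i}, {j}) is masked/absent")
        vals.append(a - q)
    return float(np.mean(vals))


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-tailed exact permutation p for Spearman rho (small n).

    Enumerates all orderings of the y-ranks; ties handled by average
    ranks in both variables.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    count = 0
    total = 0
    obs = abs(rho)
    for perm in permutations(range(n)):
        r = float(rx_c @ ry_c[list(perm)]) / denom
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_test(x, y, exact_max_n: int = 10) -> tuple[float, float, int]:
    """Two-tailed Spearman correlation; exact permutation p for n <= 10.

    Returns (rho, p, n). An all-tied vector gives rho = NaN, p = NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan"), float("nan"), n
    rho, p = stats.spearmanr(x, y)
    if n <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    return float(rho), float(p), n


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    out = np.full(p.shape, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def correlate_outcomes(deltas: pd.DataFrame, outcomes: pd.DataFrame,
                       families: dict[str, list[str]] | None = None,
                       min_pairs: int = 5) -> pd.DataFrame:
    """Spearman correlation of each network's Delta with each score.

    Parameters
    ----------
    deltas
        Subjects x networks table of per-subject Delta values.
    outcomes
        Subjects x scores table (missing values allowed; pairs deleted
        pairwise per test).
    families
        Mapping family -> score names; BH-FDR is applied within each
        family across all networks. Defaults to the neurological
        (C1, C2) and neurocognitive (4 scores) families.

    Returns a tidy frame with columns network, score, family, n, rho,
    p, p_fdr.
    """
    if families is None:
        families = {
            "neurological": [s for s in NEUROLOGICAL_SCORES if s in outcomes],
            "neurocognitive": [s for s in NEUROCOGNITIVE_SCORES if s in outcomes],
        }
    common = deltas.index.intersection(outcomes.index)
    rows = []
    for family, scores in families.items():
        for network in deltas.columns:
            for score in scores:
                x = deltas.loc[common, network].to_numpy(float)
                y = outcomes.loc[common, score].to_numpy(float)
                n_ok = int((~(np.isnan(x) | np.isnan(y))).sum())
                if n_ok < min_pairs:
                    raise ValueError(
                        f"{network} vs {score}: only {n_ok} complete pairs")
                rho, p, n = spearman_test(x, y)
                rows.append(dict(network=network, score=score, family=family,
                                 n=n, rho=rho, p=p))
    report = pd.DataFrame(rows)
    report["p_fdr"] = np.nan
    for family in report["family"].unique():
        sel = report["family"] == family
        report.loc[sel, "p_fdr"] = bh_adjust(report.loc[sel, "p"].to_numpy())
    return report
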