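"""Index of Similarity (IoS) and its inference.

The fitted pattern covariance G is normalized to a correlation matrix
(r_ij = G_ij / sqrt(G_ii G_jj)); the IoS of a condition pair is the absolute
Fisher z-transform |atanh(r)|. Low IoS = low pattern similarity = high
segregation between the two representations. Pairs are grouped into two
families per ROI: (i) movement pairs within each resolution (3 x 3 = 9
values: how segregated are foot/hand/face at a given protocol) and (ii)
resolution pairs within each movement (9 values: how consistent is one body
part's map across protocols). Differences between pair IoS values are tested
with the classical two-correlation Fisher Z statistic and corrected by
Benjamini-Hochberg FDR within each family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FactorialIndex, ValidationError
from .pcm import PCMFit

_R_CLIP = 1.0 - 1e-12


@dataclass
class SimilarityResult:
    """Per-ROI similarity report.

    ``pairs``: one row per condition pair (columns roi, family, pair, cell_a,
    cell_b, r, z_signed, ios). ``tests``: one row per within-family pairwise
    difference (columns roi, family, pair_a, pair_b, Z, p, q, significant).
    """

    roi_name: str
    r: np.ndarray
    ios: np.ndarray
    pairs: pd.DataFrame
    tests: pd.DataFrame
    n_eff: int
    converged: bool = True


def normalize_covariance(G: np.ndarray) -> np.ndarray:
    """Correlation matrix from a covariance: r_ij = G_ij / sqrt(G_ii G_jj).

    Off-diagonal values are clipped to +/-(1 - 1e-12); the diagonal is
    exactly 1.
    """
    G = np.asarray(G, dtype=float)
    d = np.diag(G)
    bad = np.where(d <= 0)[0]
    if bad.size:
        raise ValidationError(f"non-positive variance at cell(s) {bad.tolist()}")
    r = G / np.sqrt(np.outer(d, d))
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    np.fill_diagonal(r, 1.0)
    return r


def ios(r) -> "float | np.ndarray":
    """Index of Similarity: |atanh(r)| (absolute Fisher r-to-z transform)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn("|r| >= 1 clipped before atanh", stacklevel=2)
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    out = np.abs(np.arctanh(r))
    return float(out) if out.ndim == 0 else out


def z_test_pair_difference(z_a: float, z_b: float, n_eff: int) -> tuple[float, float]:
    """Fisher Z-test for the difference of two correlations.

    Inputs are *signed* Fisher-z values (atanh r); the absolute value is a
    reporting convention of the IoS, not part of the null. Z = (z_a - z_b) /
    sqrt(2 / (n_eff - 3)), two-sided normal p.
    """
    if n_eff <= 3:
        raise ValidationError(f"n_eff must exceed 3, got {n_eff}")
    se = np.sqrt(2.0 / (n_eff - 3))
    Z = (z_a - z_b) / se
    p = 2.0 * stats.norm.sf(abs(Z))
    return float(Z), float(p)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, q_adj


def similarity_report(fit: PCMFit, cells: FactorialIndex | None = None,
                      n_eff: int = 100, q: float = 0.05) -> SimilarityResult:
    """Full similarity report for one fitted ROI.

    Emits the 9 within-resolution movement-pair IoS values and the 9
    within-movement resolution-pair IoS values, plus Fisher Z-tests of all
    pairwise IoS differences inside each family with per-family FDR at
    level ``q``. ``n_eff`` is the effective sample size for the Z-test
    (by default the ROI voxel count supplied by the caller).
    """
    cells = cells or FactorialIndex()
    if not fit.converged:
        warnings.warn(f"similarity report on non-converged fit ({fit.roi_name})",
                      stacklevel=2)
    r = normalize_covariance(fit.G_hat)
    z_signed = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    ios_mat = np.abs(z_signed)
    np.fill_diagonal(ios_mat, 0.0)

    families = {
        "within_resolution": cells.within_resolution_pairs(),
        "within_movement": cells.within_movement_pairs(),
    }

    def pair_name(i: int, j: int) -> str:
        mi, ri = cells.cell(i)
        mj, rj = cells.cell(j)
        return f"{mi}@{ri:g}|{mj}@{rj:g}"

    pair_rows = []
    for fam, fam_pairs in families.items():
        for (i, j) in fam_pairs:
            pair_rows.append({
                "roi": fit.roi_name, "family": fam, "pair": pair_name(i, j),
                "cell_a": i, "cell_b": j, "r": r[i, j],
                "z_signed": z_signed[i, j], "ios": ios_mat[i, j],
            })
    pairs = pd.DataFrame(pair_rows)

    test_rows = []
    for fam, fam_pairs in families.items():
        combos = list(combinations(fam_pairs, 2))
        Zs, ps = [], []
        for (a, b) in combos:
            Z, p = z_test_pair_difference(z_signed[a], z_signed[b], n_eff)
            Zs.append(Z)
            ps.append(p)
        if combos:
            rej, qv = fdr_bh(ps, q=q)
        else:
            rej, qv = np.zeros(0, bool), np.zeros(0)
        for (a, b), Z, p, qq, sig in zip(combos, Zs, ps, qv, rej):
            test_rows.append({
                "roi": fit.roi_name, "family": fam,
                "pair_a": pair_name(*a), "pair_b": pair_name(*b),
                "Z": Z, "p": p, "q": qq, "significant": bool(sig),
            })
    tests = pd.DataFrame(test_rows)
    return SimilarityResult(fit.roi_name, r, ios_mat, pairs, tests,
                            n_eff=n_eff, converged=fit.converged)
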