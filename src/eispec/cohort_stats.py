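"""Cohort-level statistics for sex-by-diagnosis analyses of parcel-wise H.

Implements the bespoke human-analysis computations: the behavioral
camouflaging score (principal component of two standardized discrepancy
scores), gene-set enrichment (odds ratio + hypergeometric p against a fixed
background), Fisher's r-to-z comparison of two correlations, and a
contrast-driven partial least squares (PLS) analysis with permutation
p-values and bootstrap ratios.  A seeded synthetic-cohort generator with a
planted sex-by-diagnosis interaction and a female-specific H-camouflage
correlation makes every stage testable without any data download.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CamouflageScores",
    "EnrichmentResult",
    "PLSResult",
    "CohortSpec",
    "camouflage_score",
    "enrichment_test",
    "fisher_rz_compare",
    "pls_group_contrast",
    "generate_synthetic_cohort",
    "DEFAULT_MAX_SCORES",
    "GROUP_ORDER",
]

# maximum attainable instrument scores used for scaling the standardized
# discrepancy components (AQ: 50 items; RMET: 36 items; ADOS-SC: module-4
# social + communication algorithm total)
DEFAULT_MAX_SCORES: Dict[str, float] = {"AQ": 50.0, "ADOS_SC": 22.0, "RMET": 36.0}

# column order of the group design: TD male, autism male, TD female, autism female
GROUP_ORDER: Tuple[str, ...] = ("TD_M", "autism_M", "TD_F", "autism_F")


def _group_label(row) -> str:
    return ("TD" if row["diagnosis"] == "TD" else "autism") + "_" + row["sex"]


# ---------------------------------------------------------------------------
# Camouflaging
# ---------------------------------------------------------------------------

@dataclass
class CamouflageScores:
    table: pd.DataFrame  # per autistic subject: S_AQ, S_ADOS, S_RMET, CF1, CF2, CF
    variance_explained: float
    weights: np.ndarray  # PC1 loadings on (CF1, CF2)


def camouflage_score(
    table: pd.DataFrame,
    max_scores: Optional[Dict[str, float]] = None,
) -> CamouflageScores:
    """Camouflaging index for the autistic subjects of a cohort table.

    Instruments are standardized within the autism sample: mean-centered and
    divided by the maximum possible score, giving S_AQ, S_ADOS and S_RMET.
    CF1 = S_AQ - S_ADOS contrasts self-rated traits with observed behavior;
    CF2 = -S_RMET - S_ADOS contrasts mentalizing performance with observed
    behavior.  The reported CF score is the first principal component of
    (CF1, CF2), sign-oriented so that higher CF = more camouflaging
    (positive correlation with CF1 + CF2).
    """
    max_scores = {**DEFAULT_MAX_SCORES, **(max_scores or {})}
    aut = table[table["diagnosis"] == "autism"].copy()
    if len(aut) < 3:
        raise ValueError("need at least 3 autistic subjects")
    s = {}
    for name, col in (("AQ", "AQ"), ("ADOS", "ADOS_SC"), ("RMET", "RMET")):
        mx = max_scores["ADOS_SC" if name == "ADOS" else name]
        if mx <= 0:
            raise ValueError("max scores must be positive")
        x = aut[col].to_numpy(dtype=float)
        s[name] = (x - x.mean()) / mx
    cf1 = s["AQ"] - s["ADOS"]
    cf2 = -s["RMET"] - s["ADOS"]
    m = np.column_stack([cf1, cf2])
    mc = m - m.mean(axis=0)
    if np.allclose(mc, 0.0):
        raise ValueError("zero variance in CF1 and CF2; camouflaging undefined")
    u, sv, vt = np.linalg.svd(mc, full_matrices=False)
    w = vt[0]
    cf = mc @ w
    if np.dot(w, [1.0, 1.0]) < 0:
        w, cf = -w, -cf
    var_exp = float(sv[0] ** 2 / np.sum(sv**2))
    out = aut[["id"]].copy() if "id" in aut.columns else pd.DataFrame(index=aut.index)
    out["S_AQ"], out["S_ADOS"], out["S_RMET"] = s["AQ"], s["ADOS"], s["RMET"]
    out["CF1"], out["CF2"], out["CF"] = cf1, cf2, cf
    return CamouflageScores(table=out, variance_explained=var_exp, weights=w)


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    overlap: int
    odds_ratio: float
    p_value: float
    table: np.ndarray  # 2x2: [[n11, n12], [n21, n22]]
    infinite_or: bool = False


def enrichment_test(
    set_a: Sequence[str], set_b: Sequence[str], background_n: int
) -> EnrichmentResult:
    """Over-representation of gene set A within gene set B over a fixed
    background: sample odds ratio of the 2x2 membership table and one-tailed
    hypergeometric p-value P(overlap >= observed)."""
    a = {str(x).strip().upper() for x in set_a}
    b = {str(x).strip().upper() for x in set_b}
    a.discard("")
    b.discard("")
    if len(a) > background_n or len(b) > background_n:
        raise ValueError("gene set larger than the background")
    n11 = len(a & b)
    n12 = len(a) - n11
    n21 = len(b) - n11
    n22 = background_n - len(a) - len(b) + n11
    if n22 < 0:
        raise ValueError("background smaller than the union of the sets")
    infinite = False
    if n12 == 0 or n21 == 0:
        odds = np.inf if n11 > 0 else 0.0
        infinite = n11 > 0
    elif n11 == 0:
        odds = 0.0
    else:
        odds = (n11 * n22) / (n12 * n21)
    # hypergeometric: draw |A| from background containing |B| successes
    p = float(stats.hypergeom.sf(n11 - 1, background_n, len(b), len(a)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return EnrichmentResult(
        overlap=n11,
        odds_ratio=float(odds),
        p_value=p,
        table=np.array([[n11, n12], [n21, n22]]),
        infinite_or=infinite,
    )


# ---------------------------------------------------------------------------
# Fisher r-to-z
# ---------------------------------------------------------------------------

def fisher_rz_compare(r1: float, n1: int, r2: float, n2: int) -> Tuple[float, float]:
    """Compare two independent Pearson correlations:
    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-tailed p."""
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each sample must exceed 3 subjects")
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must lie strictly inside (-1, 1)")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Contrast PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSResult:
    singular_values: np.ndarray
    saliences: np.ndarray  # (n_lv, n_parcels), unit-norm rows
    perm_p: np.ndarray
    effect_d: np.ndarray  # standardized effect vs the permutation null
    bootstrap_ratios: np.ndarray  # (n_lv, n_parcels)
    top_mask: np.ndarray  # (n_lv, n_parcels) bool, top 20% by |BSR|
    parcels: List[str]
    kept: np.ndarray  # parcels retained (non-constant)


def _contrast_crossblock(x: np.ndarray, groups: np.ndarray,
                         contrasts: np.ndarray, order: Sequence[str]) -> np.ndarray:
    means = np.stack([
        x[groups == g].mean(axis=0) for g in order
    ])
    centered = means - means.mean(axis=0)
    return contrasts @ centered


def pls_group_contrast(
    h_matrix,
    groups: Sequence[str],
    contrast: Sequence[float] = (1.0, -1.0, -1.0, 1.0),
    n_perm: int = 10000,
    n_boot: int = 10000,
    seed: Optional[int] = None,
    group_order: Sequence[str] = GROUP_ORDER,
    parcel_names: Optional[Sequence[str]] = None,
) -> PLSResult:
    """Contrast-driven (non-rotated) task PLS of parcel-wise H against a
    group design.

    The cross-block matrix between the (grand-mean-centered) group means
    and the contrast(s) is singular-value-decomposed; here, with contrasts
    supplied directly, the parcel saliences are the unit-normalized rows of
    the cross-block matrix.  Significance: permutation of subject group
    labels, counting permuted singular values >= observed (add-one
    estimator).  Reliability: stratified bootstrap over subjects within
    group; BSR = salience / bootstrap SE, and the top 20% of parcels by
    |BSR| form the reported mask.
    """
    x = np.asarray(h_matrix, dtype=float)
    if isinstance(h_matrix, pd.DataFrame):
        parcel_names = list(h_matrix.columns)
    groups = np.asarray(groups)
    if x.ndim != 2 or x.shape[0] != groups.size:
        raise ValueError("h_matrix must be subjects x parcels, matching groups")
    contrasts = np.atleast_2d(np.asarray(contrast, dtype=float))
    if contrasts.shape[1] != len(group_order):
        raise ValueError("contrast length must match the number of groups")
    if not np.allclose(contrasts.sum(axis=1), 0.0):
        raise ValueError("each contrast must sum to zero")
    for g in group_order:
        if (groups == g).sum() < 2:
            raise ValueError(f"need at least 2 subjects in group {g}")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are unstable")

    if parcel_names is None:
        parcel_names = [f"parcel_{i}" for i in range(x.shape[1])]
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant parcel(s)")
    x = x[:, keep]
    names_kept = [n for n, k in zip(parcel_names, keep) if k]

    rng = np.random.default_rng(seed)
    cross = _contrast_crossblock(x, groups, contrasts, group_order)
    sv = np.linalg.norm(cross, axis=1)
    sal = cross / np.where(sv > 0, sv, 1.0)[:, None]

    # permutation null for the singular values
    perm_ge = np.zeros(sv.size)
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        c = _contrast_crossblock(x, perm, contrasts, group_order)
        perm_ge += np.linalg.norm(c, axis=1) >= sv
    perm_p = (perm_ge + 1.0) / (n_perm + 1.0)

    null_sv = np.empty((min(n_perm, 1000), sv.size))
    for i in range(null_sv.shape[0]):
        perm = rng.permutation(groups)
        null_sv[i] = np.linalg.norm(
            _contrast_crossblock(x, perm, contrasts, group_order), axis=1
        )
    null_sd = null_sv.std(axis=0)
    effect_d = (sv - null_sv.mean(axis=0)) / np.where(null_sd > 0, null_sd, 1.0)

    # stratified bootstrap for salience stability
    idx_by_group = {g: np.nonzero(groups == g)[0] for g in group_order}
    boot_sal = np.empty((n_boot, sal.shape[0], sal.shape[1]))
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_by_group[g], size=idx_by_group[g].size, replace=True)
            for g in group_order
        ])
        xb = x[take]
        gb = groups[take]
        cb = _contrast_crossblock(xb, gb, contrasts, group_order)
        svb = np.linalg.norm(cb, axis=1)
        sb = cb / np.where(svb > 0, svb, 1.0)[:, None]
        # sign-align each bootstrap LV with the original
        flip = np.sign(np.sum(sb * sal, axis=1))
        flip[flip == 0] = 1.0
        boot_sal[b] = sb * flip[:, None]
    se = boot_sal.std(axis=0)
    bsr = np.where(se > 0, sal / np.where(se > 0, se, 1.0), 0.0)

    n_top = int(np.ceil(0.2 * bsr.shape[1]))
    top_mask = np.zeros_like(bsr, dtype=bool)
    for i in range(bsr.shape[0]):
        top = np.argsort(np.abs(bsr[i]))[::-1][:n_top]
        top_mask[i, top] = True

    return PLSResult(
        singular_values=sv,
        saliences=sal,
        perm_p=perm_p,
        effect_d=effect_d,
        bootstrap_ratios=bsr,
        top_mask=top_mask,
        parcels=names_kept,
        kept=keep,
    )


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Generator settings for a 4-group (diagnosis x sex) synthetic cohort.

    ``male_d`` is the TD-minus-autism standardized effect in affected
    parcels for males (positive = H reduced in autistic males); ``female_d``
    likewise for females (the planted interaction is their difference).
    ``female_r`` is the target correlation between affected-parcel H and the
    latent camouflaging trait within autistic females.
    """

    n_per_group: Dict[str, int] = field(
        default_factory=lambda: {"TD_M": 29, "autism_M": 23, "TD_F": 33, "autism_F": 25}
    )
    n_parcels: int = 180
    affected: Sequence[int] = (0,)
    male_d: float = 1.30
    female_d: float = -0.27
    h_mean: float = 0.90
    h_sd: float = 0.10
    female_r: float = 0.60
    male_r: float = -0.10


def generate_synthetic_cohort(
    spec: Optional[CohortSpec] = None, seed: Optional[int] = None
) -> pd.DataFrame:
    """Synthetic cohort table: parcel-wise H with a planted sex-by-diagnosis
    interaction, behavioral scores with a female-specific H-camouflage
    correlation, and nuisance covariates.

    Parcel H values are Gaussian (h_mean, h_sd), with autistic subjects'
    affected parcels shifted by -d * h_sd (d per sex).  For autistic
    subjects a latent camouflaging trait c is drawn with the requested
    correlation to the mean affected-parcel H (z-scored), and AQ, ADOS-SC
    and RMET are generated from c with independent noise so that the
    derived CF score inherits an H correlation close to the target.
    """
    spec = spec or CohortSpec()
    if any(n < 4 for n in spec.n_per_group.values()):
        raise ValueError("need at least 4 subjects per group")
    if not all(0 <= p < spec.n_parcels for p in spec.affected):
        raise ValueError("affected parcel index out of range")
    for r in (spec.female_r, spec.male_r):
        if not abs(r) < 1:
            raise ValueError("requested correlations must lie inside (-1, 1)")
    rng = np.random.default_rng(seed)
    affected = np.asarray(spec.affected, dtype=int)
    rows = []
    h_blocks = []
    for grp in GROUP_ORDER:
        n = spec.n_per_group[grp]
        diag, sex = grp.split("_")
        h = rng.normal(spec.h_mean, spec.h_sd, size=(n, spec.n_parcels))
        if diag == "autism":
            d = spec.male_d if sex == "M" else spec.female_d
            h[:, affected] -= d * spec.h_sd
        h_blocks.append(h)
        for i in range(n):
            rows.append({"diagnosis": diag, "sex": sex})
    table = pd.DataFrame(rows)
    table.insert(0, "id", [f"sub-{i:03d}" for i in range(len(table))])
    h_all = np.vstack(h_blocks)

    # behavioral scores
    aq = np.empty(len(table))
    ados = np.empty(len(table))
    rmet = np.empty(len(table))
    is_aut = (table["diagnosis"] == "autism").to_numpy()
    is_f = (table["sex"] == "F").to_numpy()
    # TD: no ADOS administered -> NaN; AQ/RMET in normative ranges
    aq[~is_aut] = rng.normal(14.0, 5.0, (~is_aut).sum())
    rmet[~is_aut] = rng.normal(28.0, 3.0, (~is_aut).sum())
    ados[~is_aut] = np.nan
    for female in (False, True):
        m = is_aut & (is_f == female)
        n = int(m.sum())
        h_roi = h_all[m][:, affected].mean(axis=1)
        z = (h_roi - h_roi.mean()) / (h_roi.std() or 1.0)
        r = spec.female_r if female else spec.male_r
        c = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
        # camouflaging = high self-reported traits + intact mentalizing
        # relative to low observed symptoms; loadings/noise balanced so the
        # derived CF score carries ~the requested H correlation
        aq[m] = 35.0 + 5.0 * (0.95 * c + 0.32 * rng.standard_normal(n))
        ados[m] = np.clip(8.0 - 2.5 * c + 0.8 * rng.standard_normal(n), 0, None)
        rmet[m] = np.clip(22.0 + 4.0 * (0.95 * c + 0.32 * rng.standard_normal(n)), 0, 36)
    table["AQ"] = np.round(np.clip(aq, 0, 50), 0)
    table["ADOS_SC"] = np.round(np.clip(ados, 0, 22), 0)
    table["RMET"] = np.round(np.clip(rmet, 0, 36), 0)
    table["meanFD"] = rng.gamma(8.0, 0.02, len(table))
    table["FIQ"] = rng.normal(115.0, 12.0, len(table))
    parcels = [f"parcel_{i:03d}" for i in range(spec.n_parcels)]
    table = pd.concat(
        [table, pd.DataFrame(h_all, columns=parcels, index=table.index)], axis=1
    )
    return table
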