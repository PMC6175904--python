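"""Group-level inference: t-maps, TFCE, permutation nulls, conjunctions, ROIs.

Subject-level searchlight coefficients are combined with a one-sample t-test
per voxel.  Because pairwise distances violate independence assumptions,
significance comes from a nonparametric max-statistic permutation scheme:
within each participant the assignment of neural patterns to trials is
randomly permuted (breaking the brain-behavior link while preserving the
neural distance structure), the whole searchlight + group t + TFCE pipeline
is recomputed, and the maximum and minimum TFCE values over all spheres are
recorded per permutation.  The 97.5th percentile of the max values and the
2.5th percentile of the min values threshold the observed TFCE map — a
two-tailed familywise test at p = 0.05.

Threshold-free cluster enhancement (TFCE) integrates cluster support over
all heights:  TFCE(v) = sum_h e(h)^E h^H dh, with extent e(h) the size of
the cluster containing v at threshold h.  Defaults are the canonical
E = 0.5, H = 2, 26-connectivity, dh = max|t|/100.

The vivid-only conjunction takes min(t_Hamm, -t_HammxVivid) voxelwise,
enhances it with TFCE, and tests one-tailed at the 95th percentile of the
permuted max — significant only where content structure is present for
vivid pairs *and* reliably weaker for less vivid pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .searchlight_rsa import (
    BetaVolume,
    ModelSpec,
    SubjectSearchlight,
    _condensed_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StatMap",
    "PermutationNull",
    "RoiResult",
    "group_tmap",
    "tfce",
    "permutation_null",
    "threshold_two_tailed",
    "threshold_one_tailed",
    "conjunction_map",
    "infer_term",
    "infer_conjunction",
    "roi_tests",
]

TFCE_E = 0.5
TFCE_H = 2.0
TFCE_STEPS = 100  # dh = max|t| / TFCE_STEPS unless dh given explicitly


# ---------------------------------------------------------------------------
# group t
# ---------------------------------------------------------------------------


def _tstat(stack: np.ndarray) -> np.ndarray:
    """One-sample t vs 0 along axis 0; NaN where any subject is undefined.

    Voxels with zero variance across subjects get a signed-infinity sentinel
    (0 if the common value is 0) so they stay identifiable downstream.
    """
    n = stack.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & np.isfinite(mean)
    with np.errstate(invalid="ignore"):
        t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[zero_var & (mean == 0)] = 0.0
    return t


def group_tmap(maps: Sequence, term: str | None = None) -> np.ndarray:
    """Voxelwise one-sample t across subjects' coefficient maps.

    ``maps`` are per-subject 3-D arrays, or
    :class:`~lifelog_rsa.searchlight_rsa.CoefficientMaps` with ``term``
    naming the coefficient to extract.
    """
    vols = []
    for m in maps:
        vol = m[term] if term is not None and hasattr(m, "maps") else m
        vols.append(np.asarray(vol, dtype=float))
    return _tstat(np.stack(vols))


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def _tfce_one_sided(
    t: np.ndarray, E: float, H: float, dh: float, structure: np.ndarray
) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    tmax = float(t.max(initial=0.0))
    if tmax <= 0 or dh <= 0:
        return out
    h = dh
    while h <= tmax + 1e-12:
        supra = t >= h
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            extent = np.bincount(labels.ravel())
            contrib = (extent[labels] ** E) * (h**H) * dh
            out[supra] += contrib[supra]
        h += dh
    return out


def tfce(
    t: np.ndarray,
    E: float = TFCE_E,
    H: float = TFCE_H,
    dh: float | None = None,
    connectivity: int = 26,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed statistic volume.

    The positive and negative tails are enhanced symmetrically (the negative
    tail by enhancing ``-t``), so the output carries the sign of ``t``.
    Non-finite voxels (undefined or zero-variance sentinels) take no part in
    any cluster and come back NaN.
    """
    if E <= 0 or H <= 0:
        raise ValueError("E and H must be positive")
    t = np.asarray(t, dtype=float)
    finite = np.isfinite(t)
    tt = np.where(finite, t, 0.0)
    if dh is None:
        peak = float(np.abs(tt).max(initial=0.0))
        dh = peak / TFCE_STEPS if peak > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    structure = _connectivity_structure(connectivity)
    out = _tfce_one_sided(tt, E, H, dh, structure) - _tfce_one_sided(
        -tt, E, H, dh, structure
    )
    out[~finite] = np.nan
    return out


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Max/min TFCE null distributions from trial-label permutations."""

    null_max: np.ndarray
    null_min: np.ndarray
    n_perm: int
    seed: int
    statistic: str  # "term" or "conjunction"


@dataclass
class StatMap:
    """Observed group statistic with its permutation null and thresholds."""

    t: np.ndarray
    tfce: np.ndarray
    null: PermutationNull
    thresholds: dict[str, float] = field(default_factory=dict)
    sig_mask: np.ndarray | None = None
    alpha: float = 0.05
    tails: int = 2
    term: str = ""


def _stat_volume(
    subjects: Sequence[SubjectSearchlight],
    perms: Sequence[np.ndarray] | None,
    term: str,
    term_neg: str | None,
    tfce_kwargs: dict,
) -> tuple[np.ndarray, np.ndarray]:
    """(t volume, tfce volume) for one (possibly permuted) dataset."""
    shape = subjects[0].shape
    nvox = int(np.prod(shape))

    def term_stack(name: str) -> np.ndarray:
        k = subjects[0].spec.names.index(name)
        stack = np.full((len(subjects), nvox), np.nan)
        for s_idx, s in enumerate(subjects):
            if s.shape != shape:
                raise ValueError("subjects must share one volume grid")
            coefs = s.coef_matrix(None if perms is None else perms[s_idx])
            flat = np.full(nvox, np.nan, dtype=float)
            lin = np.ravel_multi_index(tuple(s.centers.T), shape)
            flat[lin] = coefs[k]
            stack[s_idx] = flat
        return stack

    # coef_matrix is the expensive call; fetch both terms from one pass
    if term_neg is None:
        t = _tstat(term_stack(term))
    else:
        # cache coefficient matrices once per subject, then form both stacks
        k_pos = subjects[0].spec.names.index(term)
        k_neg = subjects[0].spec.names.index(term_neg)
        stack_pos = np.full((len(subjects), nvox), np.nan)
        stack_neg = np.full((len(subjects), nvox), np.nan)
        for s_idx, s in enumerate(subjects):
            coefs = s.coef_matrix(None if perms is None else perms[s_idx])
            lin = np.ravel_multi_index(tuple(s.centers.T), shape)
            flat = np.full(nvox, np.nan)
            flat[lin] = coefs[k_pos]
            stack_pos[s_idx] = flat
            flat = np.full(nvox, np.nan)
            flat[lin] = coefs[k_neg]
            stack_neg[s_idx] = flat
        t = conjunction_map(
            _tstat(stack_pos).reshape(shape), _tstat(stack_neg).reshape(shape)
        ).ravel()
    t = t.reshape(shape)
    return t, tfce(t, **tfce_kwargs)


def permutation_null(
    subjects: Sequence[SubjectSearchlight],
    term: str,
    n_perm: int,
    seed: int,
    term_neg: str | None = None,
    **tfce_kwargs,
) -> PermutationNull:
    """Trial-label permutation null of the max/min TFCE statistic.

    Each permutation draws one independent trial-index permutation per
    participant, applies it to the neural side of every pair (the same draw
    for every sphere, as required for a valid max-statistic correction),
    refits all subject GLMs, recomputes the group t and TFCE volumes, and
    records the extrema over defined voxels.  With ``term_neg`` the statistic
    is the conjunction min(t_term, -t_term_neg) instead of t_term.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    null_min = np.empty(n_perm)
    for p in range(n_perm):
        perms = [rng.permutation(s.n_trials) for s in subjects]
        _, enh = _stat_volume(subjects, perms, term, term_neg, tfce_kwargs)
        finite = np.isfinite(enh)
        if not finite.any():
            raise ValueError("permutation produced no defined voxels")
        null_max[p] = enh[finite].max()
        null_min[p] = enh[finite].min()
    return PermutationNull(
        null_max=null_max,
        null_min=null_min,
        n_perm=n_perm,
        seed=seed,
        statistic="term" if term_neg is None else "conjunction",
    )


def threshold_two_tailed(stat: StatMap, alpha: float = 0.05) -> np.ndarray:
    """Flag voxels beyond the two-tailed max/min-TFCE permutation thresholds.

    hi is the (1 - alpha/2) quantile of the permutation max TFCE values and
    lo the alpha/2 quantile of the min values; flagged voxels have observed
    TFCE above hi or below lo.
    """
    hi = float(np.quantile(stat.null.null_max, 1 - alpha / 2))
    lo = float(np.quantile(stat.null.null_min, alpha / 2))
    finite = np.isfinite(stat.tfce)
    sig = np.zeros(stat.tfce.shape, dtype=bool)
    sig[finite] = (stat.tfce[finite] > hi) | (stat.tfce[finite] < lo)
    stat.thresholds = {"hi": hi, "lo": lo}
    stat.sig_mask = sig
    stat.alpha = alpha
    stat.tails = 2
    return sig


def threshold_one_tailed(stat: StatMap, alpha: float = 0.05) -> np.ndarray:
    """One-tailed (positive, directional) max-TFCE threshold."""
    hi = float(np.quantile(stat.null.null_max, 1 - alpha))
    finite = np.isfinite(stat.tfce)
    sig = np.zeros(stat.tfce.shape, dtype=bool)
    sig[finite] = stat.tfce[finite] > hi
    stat.thresholds = {"hi": hi}
    stat.sig_mask = sig
    stat.alpha = alpha
    stat.tails = 1
    return sig


def conjunction_map(t_pos: np.ndarray, t_neg: np.ndarray) -> np.ndarray:
    """Voxelwise min(t_pos, -t_neg); both maps must share one grid."""
    t_pos = np.asarray(t_pos, dtype=float)
    t_neg = np.asarray(t_neg, dtype=float)
    if t_pos.shape != t_neg.shape:
        raise ValueError(
            f"grid mismatch: {t_pos.shape} vs {t_neg.shape}"
        )
    return np.minimum(t_pos, -t_neg)


def infer_term(
    subjects: Sequence[SubjectSearchlight],
    term: str = "Hamm",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    **tfce_kwargs,
) -> StatMap:
    """Observed group t + TFCE for one term with a two-tailed permutation test."""
    t, enh = _stat_volume(subjects, None, term, None, tfce_kwargs)
    null = permutation_null(subjects, term, n_perm, seed, **tfce_kwargs)
    stat = StatMap(t=t, tfce=enh, null=null, term=term)
    threshold_two_tailed(stat, alpha)
    return stat


def infer_conjunction(
    subjects: Sequence[SubjectSearchlight],
    term_pos: str = "Hamm",
    term_neg: str = "Hamm:Vivid",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    **tfce_kwargs,
) -> StatMap:
    """Conjunction min(t_pos, -t_neg), one-tailed max-TFCE permutation test."""
    t, enh = _stat_volume(subjects, None, term_pos, term_neg, tfce_kwargs)
    null = permutation_null(
        subjects, term_pos, n_perm, seed, term_neg=term_neg, **tfce_kwargs
    )
    stat = StatMap(
        t=t, tfce=enh, null=null, term=f"min({term_pos}, -{term_neg})"
    )
    threshold_one_tailed(stat, alpha)
    return stat


# ---------------------------------------------------------------------------
# ROI analysis
# ---------------------------------------------------------------------------


@dataclass
class RoiResult:
    roi: str
    model: tuple[str, ...]
    term: str
    t: float
    p_perm: float
    corrected_alpha: float
    significant: bool


class _RoiEngine:
    """All-trial-pair distances for one subject x ROI (one pooled 'sphere')."""

    def __init__(self, betas: BetaVolume, roi_mask: np.ndarray, pairs: pd.DataFrame):
        vox = np.argwhere(np.asarray(roi_mask, dtype=bool) & betas.mask)
        if len(vox) == 0:
            raise ValueError("empty ROI after intersecting the data mask")
        P = betas.data[vox[:, 0], vox[:, 1], vox[:, 2], :].astype(float)
        n = P.shape[1]
        Z = P - P.mean(axis=0, keepdims=True)
        sd = Z.std(axis=0)
        good = sd > 0
        Zn = np.zeros_like(Z)
        Zn[:, good] = Z[:, good] / (sd[good] * np.sqrt(P.shape[0]))
        corr = Zn.T @ Zn
        if not good.all():
            corr[~good, :] = np.nan
            corr[:, ~good] = np.nan
        iu = np.triu_indices(n, 1)
        self.D_full = 1.0 - corr[iu]
        self.n_trials = n
        inc = pairs[pairs["included"]]
        self.inc_i = inc["i"].to_numpy(dtype=np.int64)
        self.inc_j = inc["j"].to_numpy(dtype=np.int64)

    def distances(self, perm: np.ndarray | None) -> np.ndarray:
        if perm is None:
            a, b = self.inc_i, self.inc_j
        else:
            a, b = perm[self.inc_i], perm[self.inc_j]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        y = self.D_full[_condensed_index(lo, hi, self.n_trials)]
        sd = np.nanstd(y)
        return (y - np.nanmean(y)) / sd


def roi_tests(
    rois: Mapping[str, np.ndarray],
    subject_data: Sequence[tuple[BetaVolume, pd.DataFrame]],
    models: Sequence[ModelSpec],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation t-tests of ROI-pooled GLM betas, Bonferroni corrected.

    Each ROI's voxels form a single pooled neighborhood: distances are
    computed over all ROI voxels, z-scored, and fit with every model; the
    per-term betas are t-tested across subjects against zero, with a
    within-participant trial-permutation p-value (two-tailed, add-one
    estimator) and Bonferroni correction over all ROI x model x term tests.
    """
    engines = {
        roi: [_RoiEngine(bv, mask, pairs) for bv, pairs in subject_data]
        for roi, mask in rois.items()
    }
    designs = {
        id(m): [np.linalg.pinv(m.design_matrix(pairs)) for _, pairs in subject_data]
        for m in models
    }

    def stats_for(perms: Sequence[np.ndarray] | None) -> dict:
        out = {}
        for roi, engs in engines.items():
            ys = [
                e.distances(None if perms is None else perms[si])
                for si, e in enumerate(engs)
            ]
            for m in models:
                betas_sub = np.array(
                    [designs[id(m)][si] @ y for si, y in enumerate(ys)]
                )  # (n_subj, n_coef)
                tvals = _tstat(betas_sub)
                for k, name in enumerate(m.names):
                    if name == "intercept":
                        continue
                    out[(roi, m.terms, name)] = tvals[k]
        return out

    observed = stats_for(None)
    rng = np.random.default_rng(seed)
    exceed = {key: 0 for key in observed}
    for _ in range(n_perm):
        perms = [rng.permutation(e.n_trials) for e in engines[next(iter(engines))]]
        perm_stats = stats_for(perms)
        for key, t_obs in observed.items():
            if abs(perm_stats[key]) >= abs(t_obs):
                exceed[key] += 1

    n_tests = len(observed)
    corrected_alpha = alpha / n_tests
    rows = []
    for (roi, terms, name), t_obs in observed.items():
        p = (1 + exceed[(roi, terms, name)]) / (n_perm + 1)
        rows.append(
            RoiResult(
                roi=roi,
                model=terms,
                term=name,
                t=float(t_obs),
                p_perm=float(p),
                corrected_alpha=corrected_alpha,
                significant=bool(p < corrected_alpha),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
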