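"""Spherical-searchlight pair-level GLMs over single-trial beta volumes.

For each participant, a sphere (default radius 7.5 mm) is centered on every
gray-matter voxel; within the sphere, the neural distance between every
included stimulus pair is 1 minus the Pearson correlation of the two trials'
voxel patterns, z-scored across the participant's included pairs.  An
ordinary-least-squares model then relates the distances to the pair
covariates, e.g.

    neuraldistance = a + b_Hamm Hamm + b_VisSim VisSim
                       + b_scanner log10(scannertime) + e

optionally with Vivid and the Hamm x Vivid interaction (and space / time /
space x time for region-of-interest follow-ups).  The per-term coefficient
maps across participants are the input to group inference.

The heavy lifting lives in :class:`SubjectSearchlight`, which caches the raw
pairwise distance for *every* trial pair per sphere so that within-
participant trial-relabeling permutations only re-index and refit, never
re-correlate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BetaVolume",
    "ModelSpec",
    "PairGlmFit",
    "CoefficientMaps",
    "SubjectSearchlight",
    "sphere_neighborhoods",
    "sphere_offsets",
    "fit_pair_glm",
    "searchlight_map",
    "CONTENT_MODEL",
    "VIVIDNESS_MODEL",
    "CONTENT_SPACETIME_MODEL",
    "VIVIDNESS_SPACETIME_MODEL",
]

#: searchlight sphere radius in mm
DEFAULT_RADIUS_MM = 7.5

#: spheres with fewer in-mask voxels than this are skipped
MIN_SPHERE_VOXELS = 10

#: pair-table column(s) behind each model term; tuples are multiplied
_TERM_COLUMNS: dict[str, tuple[str, ...]] = {
    "Hamm": ("hamm",),
    "VisSim": ("vis_sim",),
    "log10_scanner": ("log10_scanner",),
    "Vivid": ("vivid_code",),
    "Hamm:Vivid": ("hamm", "vivid_code"),
    "space": ("space_m",),
    "time": ("time_s",),
    "space:time": ("space_m", "time_s"),
}

_INTERACTION_PARENTS = {
    "Hamm:Vivid": ("Hamm", "Vivid"),
    "space:time": ("space", "time"),
}


@dataclass
class BetaVolume:
    """4-D grid of single-trial activity estimates plus an analysis mask."""

    data: np.ndarray  # (x, y, z, trial)
    voxel_size_mm: np.ndarray  # (3,)
    mask: np.ndarray  # 3-D boolean
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise ValueError("beta data must be 4-D (x, y, z, trial)")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial grid")
        self.voxel_size_mm = np.broadcast_to(
            np.asarray(self.voxel_size_mm, dtype=float), (3,)
        ).copy()
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])

    @property
    def n_trials(self) -> int:
        return self.data.shape[3]

    @classmethod
    def from_nifti(cls, data_path: str | Path, mask_path: str | Path) -> "BetaVolume":
        img = nib.load(str(data_path))
        mask_img = nib.load(str(mask_path))
        zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
        return cls(
            data=np.asarray(img.dataobj, dtype=np.float32),
            voxel_size_mm=zooms,
            mask=np.asarray(mask_img.dataobj) > 0,
            affine=np.asarray(img.affine),
        )

    def to_nifti(self, data_path: str | Path, mask_path: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(self.data, self.affine), str(data_path))
        if mask_path is not None:
            nib.save(
                nib.Nifti1Image(self.mask.astype(np.uint8), self.affine),
                str(mask_path),
            )


@dataclass(frozen=True)
class ModelSpec:
    """Ordered list of pair-level regression terms (intercept implicit).

    The term order fixes the coefficient order of every fit and map, keeping
    outputs byte-stable across runs.
    """

    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        for t in self.terms:
            if t not in _TERM_COLUMNS:
                raise ValueError(
                    f"unknown term {t!r}; known: {sorted(_TERM_COLUMNS)}"
                )
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model")
        for t, parents in _INTERACTION_PARENTS.items():
            if t in self.terms and not all(p in self.terms for p in parents):
                raise ValueError(f"{t} requires main effects {parents}")

    @property
    def names(self) -> tuple[str, ...]:
        """Coefficient names, intercept first."""
        return ("intercept", *self.terms)

    def design_matrix(self, pairs: pd.DataFrame) -> np.ndarray:
        """Design matrix over the *included* rows of a pair table."""
        inc = pairs[pairs["included"]]
        cols = [np.ones(len(inc))]
        for t in self.terms:
            x = np.ones(len(inc))
            for c in _TERM_COLUMNS[t]:
                x = x * inc[c].to_numpy(dtype=float)
            cols.append(x)
        X = np.column_stack(cols)
        if not np.all(np.isfinite(X)):
            bad = [
                name
                for name, col in zip(self.names, X.T)
                if not np.all(np.isfinite(col))
            ]
            raise ValueError(f"non-finite covariates for terms: {bad}")
        return X


CONTENT_MODEL = ModelSpec(("Hamm", "VisSim", "log10_scanner"))
VIVIDNESS_MODEL = ModelSpec(
    ("Hamm", "Vivid", "Hamm:Vivid", "VisSim", "log10_scanner")
)
CONTENT_SPACETIME_MODEL = ModelSpec(
    ("Hamm", "VisSim", "log10_scanner", "space", "time", "space:time")
)
VIVIDNESS_SPACETIME_MODEL = ModelSpec(
    ("Hamm", "Vivid", "Hamm:Vivid", "VisSim", "log10_scanner", "space", "time", "space:time")
)


@dataclass
class PairGlmFit:
    """OLS result of one pair-level GLM."""

    spec: ModelSpec
    coef: np.ndarray  # aligned with spec.names
    residuals: np.ndarray
    y: np.ndarray
    X: np.ndarray
    pair_index: np.ndarray  # pair-table row labels entering the fit

    def __getitem__(self, term: str) -> float:
        return float(self.coef[self.spec.names.index(term)])


def fit_pair_glm(y, pairs: pd.DataFrame, spec: ModelSpec) -> PairGlmFit:
    """Ordinary least squares of neural distances on the pair covariates.

    ``y`` may be a plain vector aligned with the included pairs, or a
    :class:`~lifelog_rsa.pair_builder.NeuralDistanceVector` (whose
    ``pair_index`` then selects the design rows, so pairs dropped for
    zero-variance patterns are handled).
    """
    inc = pairs[pairs["included"]]
    pair_index = getattr(y, "pair_index", None)
    y_arr = np.asarray(getattr(y, "values", y), dtype=float)
    if pair_index is not None:
        sub = pairs.loc[pair_index].copy()
        X = spec.design_matrix(sub)
        used_index = np.asarray(pair_index)
    else:
        if len(y_arr) != len(inc):
            raise ValueError(
                f"y has {len(y_arr)} values for {len(inc)} included pairs"
            )
        X = spec.design_matrix(pairs)
        used_index = inc.index.to_numpy()
    p = X.shape[1]
    if X.shape[0] < p + 1:
        raise ValueError(
            f"need at least {p + 1} included pairs to fit {p} coefficients"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = sorted(spec.names[k] for k in piv[np.abs(np.diag(r)) <= tol])
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")
    coef, *_ = np.linalg.lstsq(X, y_arr, rcond=None)
    resid = y_arr - X @ coef
    return PairGlmFit(spec, coef, resid, y_arr, X, used_index)


# ---------------------------------------------------------------------------
# sphere geometry
# ---------------------------------------------------------------------------


def sphere_offsets(radius_mm: float, voxel_size_mm) -> np.ndarray:
    """Integer voxel offsets whose mm distance from the origin is <= radius.

    The boundary is inclusive; with 7.5 mm radius on a 2.5 mm isotropic grid
    this yields 123 offsets (the interior searchlight sphere size).
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    ext = [int(np.floor(radius_mm / v)) for v in vs]
    rng = [np.arange(-e, e + 1) for e in ext]
    gx, gy, gz = np.meshgrid(*rng, indexing="ij")
    off = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d2 = ((off * vs) ** 2).sum(axis=1)
    return off[d2 <= radius_mm**2 + 1e-9]


def sphere_neighborhoods(
    mask: np.ndarray, radius_mm: float, voxel_size_mm
) -> dict[tuple[int, int, int], np.ndarray]:
    """In-mask sphere membership for every in-mask center voxel.

    Returns a mapping center -> (k, 3) array of in-mask voxel coordinates
    within ``radius_mm`` of the center (center included).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    off = sphere_offsets(radius_mm, voxel_size_mm)
    shape = np.asarray(mask.shape)
    out: dict[tuple[int, int, int], np.ndarray] = {}
    for center in np.argwhere(mask):
        coords = center + off
        ok = np.all((coords >= 0) & (coords < shape), axis=1)
        coords = coords[ok]
        coords = coords[mask[coords[:, 0], coords[:, 1], coords[:, 2]]]
        out[tuple(int(c) for c in center)] = coords
    return out


def _condensed_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Index of unordered pair (i < j) in the upper-triangle flattening."""
    return (n * i - (i * (i + 1)) // 2 + (j - i - 1)).astype(np.int64)


# ---------------------------------------------------------------------------
# per-subject engine
# ---------------------------------------------------------------------------


class SubjectSearchlight:
    """Precomputed searchlight state for one participant.

    On construction this computes, for every retained sphere center, the raw
    correlation distance between **all** trial pairs (not only included
    ones).  A within-participant permutation of trial labels then amounts to
    re-indexing columns of that matrix, re-z-scoring, and re-projecting onto
    the (fixed) design pseudoinverse — no correlations are recomputed.
    """

    def __init__(
        self,
        betas: BetaVolume,
        pairs: pd.DataFrame,
        spec: ModelSpec,
        radius_mm: float = DEFAULT_RADIUS_MM,
        min_voxels: int = MIN_SPHERE_VOXELS,
        zscore_scope: str = "sphere",
    ) -> None:
        if zscore_scope not in ("sphere", "participant"):
            raise ValueError("zscore_scope must be 'sphere' or 'participant'")
        self.betas = betas
        self.pairs = pairs
        self.spec = spec
        self.radius_mm = float(radius_mm)
        self.min_voxels = int(min_voxels)
        self.zscore_scope = zscore_scope
        self.shape = betas.mask.shape
        n = betas.n_trials

        inc = pairs[pairs["included"]]
        if inc.empty:
            raise ValueError("no included pairs")
        self._inc_i = inc["i"].to_numpy(dtype=np.int64)
        self._inc_j = inc["j"].to_numpy(dtype=np.int64)
        if self._inc_i.max() >= n or self._inc_j.max() >= n:
            raise ValueError("pair trial indices exceed the beta trial axis")
        X = spec.design_matrix(pairs)
        p = X.shape[1]
        if X.shape[0] < p + 1:
            raise ValueError("not enough included pairs for the model")
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("rank-deficient design matrix")
        self.X = X
        self._pinvX = np.linalg.pinv(X).astype(np.float32)  # (p, n_inc)
        self._pinv_ones = self._pinvX @ np.ones(X.shape[0], dtype=np.float32)

        off = sphere_offsets(radius_mm, betas.voxel_size_mm)
        all_centers = np.argwhere(betas.mask)
        flat = betas.data.reshape(-1, n)
        mask_flat = betas.mask.ravel()
        strides = np.array(
            [self.shape[1] * self.shape[2], self.shape[2], 1], dtype=np.int64
        )
        iu = np.triu_indices(n, 1)
        self._iu = iu
        n_pairs_full = len(iu[0])

        centers, rows, skipped = [], [], 0
        shape_arr = np.asarray(self.shape)
        for center in all_centers:
            coords = center + off
            ok = np.all((coords >= 0) & (coords < shape_arr), axis=1)
            lin = coords[ok] @ strides
            lin = lin[mask_flat[lin]]
            if len(lin) < self.min_voxels:
                skipped += 1
                continue
            P = flat[lin]  # (vox, trials)
            Z = P - P.mean(axis=0, keepdims=True)
            sd = Z.std(axis=0)
            good = sd > 0
            Zn = np.zeros_like(Z)
            Zn[:, good] = Z[:, good] / (sd[good] * np.sqrt(len(lin)))
            corr = Zn.T @ Zn
            if not good.all():
                corr[~good, :] = np.nan
                corr[:, ~good] = np.nan
            centers.append(center)
            rows.append((1.0 - corr[iu]).astype(np.float32))
        if skipped:
            logger.info(
                "skipped %d spheres below %d voxels", skipped, self.min_voxels
            )
        if not centers:
            raise ValueError("no sphere met the minimum voxel count")
        self.n_skipped = skipped
        self.centers = np.asarray(centers)
        # pair-major layout: permutation gathers then read contiguous rows
        self._DT = np.ascontiguousarray(np.vstack(rows).T)
        self.n_trials = n
        self._identity_idx = _condensed_index(self._inc_i, self._inc_j, n)

    @property
    def D_full(self) -> np.ndarray:
        """(n_centers, n_trial_pairs) raw distances for every trial pair."""
        return self._DT.T

    # -- fitting ------------------------------------------------------------

    def _gather(self, perm: np.ndarray | None) -> np.ndarray:
        """(n_included, n_centers) raw distances under a trial relabeling."""
        if perm is None:
            idx = self._identity_idx
        else:
            perm = np.asarray(perm, dtype=np.int64)
            a = perm[self._inc_i]
            b = perm[self._inc_j]
            lo = np.minimum(a, b)
            hi = np.maximum(a, b)
            idx = _condensed_index(lo, hi, self.n_trials)
        return self._DT[idx]

    def distance_matrix(self, perm: np.ndarray | None = None) -> np.ndarray:
        """(n_centers, n_included) z-scored neural distances."""
        Y = self._gather(perm).astype(np.float32)
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.zscore_scope == "sphere":
                mu = Y.mean(axis=0, keepdims=True)
                sd = Y.std(axis=0, keepdims=True)
            else:  # one scale per participant, pooled over spheres
                mu = np.float32(np.nanmean(Y))
                sd = np.float32(np.nanstd(Y))
            Z = (Y - mu) / sd
        return Z.T

    def coef_matrix(self, perm: np.ndarray | None = None) -> np.ndarray:
        """(n_coef, n_centers) OLS coefficients; NaN where undefined.

        ``perm`` is a trial-index permutation applied to the neural side (the
        distance of behavioral pair (i, j) is read from neural pair
        (perm[i], perm[j])); None fits the observed assignment.

        Z-scoring the distances commutes with the projection: with the
        intercept in the design, subtracting the mean only shifts the
        intercept coefficient (pinv(X) @ 1 is the intercept unit vector) and
        dividing by the sd rescales all coefficients, so the fit runs on the
        raw gathered distances and the normalization is applied to the
        coefficients — identical to fitting the z-scored distances, without
        materializing them.
        """
        Yt = self._gather(perm)  # (n_inc, n_centers)
        n_inc = Yt.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            if self.zscore_scope == "sphere":
                mu = Yt.mean(axis=0)
                var = np.einsum("ij,ij->j", Yt, Yt) / n_inc - mu**2
                sd = np.sqrt(np.maximum(var, 0.0))
                sd[var <= 0] = np.nan  # constant distances: undefined z-score
            else:  # one scale per participant, pooled over spheres
                mu = np.full(Yt.shape[1], np.nanmean(Yt), dtype=np.float32)
                sd = np.full(Yt.shape[1], np.nanstd(Yt), dtype=np.float32)
            G = self._pinvX @ Yt  # (p, n_centers)
            B = (G - np.outer(self._pinv_ones, mu)) / sd[None, :]
        return B

    def coefficient_maps(self, perm: np.ndarray | None = None) -> "CoefficientMaps":
        coefs = self.coef_matrix(perm)
        vols: dict[str, np.ndarray] = {}
        for k, name in enumerate(self.spec.names):
            vol = np.full(self.shape, np.nan, dtype=np.float32)
            vol[tuple(self.centers.T)] = coefs[k]
            vols[name] = vol
        return CoefficientMaps(
            maps=vols,
            spec=self.spec,
            sphere_radius_mm=self.radius_mm,
            n_skipped=self.n_skipped,
            affine=self.betas.affine,
        )


@dataclass
class CoefficientMaps:
    """Per-term coefficient volumes at sphere centers for one participant."""

    maps: Mapping[str, np.ndarray]
    spec: ModelSpec
    sphere_radius_mm: float
    n_skipped: int = 0
    affine: np.ndarray | None = None

    def __getitem__(self, term: str) -> np.ndarray:
        return self.maps[term]

    def to_nifti(self, out_dir: str | Path, prefix: str = "beta") -> list[Path]:
        """One NIfTI per term, plus a JSON sidecar with the run settings."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        affine = self.affine if self.affine is not None else np.eye(4)
        written = []
        for term, vol in self.maps.items():
            safe = term.replace(":", "_x_")
            path = out_dir / f"{prefix}_{safe}.nii"
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))
            written.append(path)
        sidecar = out_dir / f"{prefix}_searchlight.json"
        sidecar.write_text(
            json.dumps(
                {
                    "sphere_radius_mm": self.sphere_radius_mm,
                    "terms": list(self.spec.names),
                    "n_skipped_spheres": self.n_skipped,
                },
                indent=2,
            )
        )
        return written


def searchlight_map(
    betas: BetaVolume,
    pairs: pd.DataFrame,
    spec: ModelSpec,
    radius_mm: float = DEFAULT_RADIUS_MM,
    min_voxels: int = MIN_SPHERE_VOXELS,
    zscore_scope: str = "sphere",
) -> CoefficientMaps:
    """Whole-volume searchlight GLM for one participant.

    Fits the pair-level model in the sphere around every in-mask voxel and
    returns one coefficient volume per term (NaN at skipped or undefined
    centers).  A sphere whose data defeat the fit (e.g. constant patterns)
    yields NaN at that center rather than failing the whole map.
    """
    engine = SubjectSearchlight(
        betas, pairs, spec, radius_mm=radius_mm, min_voxels=min_voxels,
        zscore_scope=zscore_scope,
    )
    return engine.coefficient_maps()
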