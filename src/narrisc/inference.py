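"""Group inference on pairwise ISC by sign-flip permutation and TFCE.

The one-sample question "is mean pairwise r positive here?" is answered
non-parametrically: under the null each pairwise correlation is symmetric
around zero, so surrogate datasets are built by flipping the sign of each
pairwise r.  Because every subject contributes to many pairs, two flipping
schemes are provided:

* ``pair_independent`` — each pair's sign flipped i.i.d. (the standard
  scheme, which treats pairwise values as exchangeable units);
* ``subject_blocks`` — one sign per subject, a pair flips by the product of
  its two subjects' signs, so all pairs sharing a subject flip coherently.
  This is a concrete realization of subject-level exchangeability blocks
  for pairwise data.

Statistic maps are enhanced with threshold-free cluster enhancement (TFCE)
and family-wise error is controlled with the permutation distribution of
the image-wide maximum.  Only the positive tail is enhanced by default
(ISC hypotheses are one-sided); a two-tailed option exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .dataio import DataError, PValueMap, StatMap
from .isc import PairwiseISCMatrix, mean_isc_map

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TFCEParams:
    """TFCE settings: extent exponent E, height exponent H, number of
    integration steps and 3D neighbourhood connectivity."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E < 0 or self.H < 0:
            raise DataError("TFCE exponents must be non-negative")
        if self.n_steps < 1:
            raise DataError("TFCE needs at least one integration step")
        if self.connectivity not in (6, 18, 26):
            raise DataError("connectivity must be 6, 18 or 26")


@dataclass(frozen=True)
class PermutationScheme:
    """How surrogate sign patterns are drawn."""

    mode: str = "pair_independent"   # or "subject_blocks"
    n_perm: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("pair_independent", "subject_blocks"):
            raise DataError(f"unknown permutation mode {self.mode!r}")
        if self.n_perm < 1:
            raise DataError("n_perm must be >= 1")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def sign_flip_stat(matrix: PairwiseISCMatrix, signs: np.ndarray) -> StatMap:
    """Mean over valid pairs of sign * r per voxel."""
    signs = np.asarray(signs, dtype=np.float64)
    if signs.shape != (matrix.n_pairs,):
        raise DataError(f"signs must have length n_pairs={matrix.n_pairs}")
    flipped = PairwiseISCMatrix(pairs=matrix.pairs,
                                values=matrix.values * signs[:, None],
                                kind=matrix.kind, mask=matrix.mask,
                                conditions=matrix.conditions,
                                subjects=matrix.subjects)
    m = mean_isc_map(flipped)
    m.statistic_name = "sign_flip_mean_isc"
    return m


def tfce_array(values: np.ndarray, params: TFCEParams = TFCEParams()) -> np.ndarray:
    """TFCE enhancement of a non-negative 3D array (NaN and negatives -> 0).

    score(p) = sum over thresholds h = dh, 2dh, ..., max of
    e(h, p)^E * h^H * dh, where e(h, p) is the voxel count of the connected
    supra-threshold component containing p at height h.
    """
    v = np.nan_to_num(np.asarray(values, dtype=np.float64), nan=0.0)
    np.maximum(v, 0.0, out=v)
    out = np.zeros_like(v)
    vmax = v.max()
    if vmax <= 0:
        return out
    structure = _STRUCTURES[params.connectivity]
    dh = vmax / params.n_steps
    for k in range(1, params.n_steps + 1):
        h = k * dh
        supra = v >= h
        labels, n_comp = ndimage.label(supra, structure=structure)
        if n_comp == 0:
            break
        sizes = np.bincount(labels.ravel())
        extent = sizes[labels]           # component size at each voxel
        contrib = (extent.astype(np.float64) ** params.E) * (h ** params.H) * dh
        out[supra] += contrib[supra]
    return out


def tfce(stat_map: StatMap, params: TFCEParams = TFCEParams()) -> StatMap:
    """TFCE of a statistic map (positive tail)."""
    enhanced = tfce_array(stat_map.data, params)
    enhanced[~np.isfinite(stat_map.data)] = np.nan
    return StatMap(data=enhanced, statistic_name="tfce",
                   metadata={**stat_map.metadata,
                             "tfce": {"E": params.E, "H": params.H,
                                      "n_steps": params.n_steps,
                                      "connectivity": params.connectivity}},
                   affine=stat_map.affine)


def _draw_signs(matrix: PairwiseISCMatrix, scheme: PermutationScheme,
                rng: np.random.Generator) -> np.ndarray:
    if scheme.mode == "pair_independent":
        return rng.choice([-1.0, 1.0], size=matrix.n_pairs)
    # subject_blocks: one sign per subject; pair sign = product of the two
    subjects = matrix.subjects or sorted({p[0] for p in matrix.pairs}
                                         | {p[1] for p in matrix.pairs})
    subj_sign = dict(zip(subjects, rng.choice([-1.0, 1.0], size=len(subjects))))
    return np.array([subj_sign[si] * subj_sign[sj] for si, sj, _, _ in matrix.pairs])


def _masked_mean_maps(matrix: PairwiseISCMatrix,
                      signs_matrix: np.ndarray) -> np.ndarray:
    """Mean over valid pairs of sign*r for many sign vectors at once.

    signs_matrix is (n_perm, n_pairs); returns (n_perm, n_voxels).
    """
    vals = matrix.values
    valid = np.isfinite(vals)
    filled = np.where(valid, vals, 0.0)
    counts = valid.sum(axis=0).astype(np.float64)
    counts[counts == 0] = np.nan
    return (signs_matrix @ filled) / counts[None, :]


def permutation_test(matrix: PairwiseISCMatrix,
                     tfce_params: TFCEParams = TFCEParams(),
                     scheme: PermutationScheme = PermutationScheme(),
                     alpha: float = 0.05,
                     two_tailed: bool = False) -> tuple[StatMap, PValueMap]:
    """Sign-flip one-sample permutation test with TFCE and max-stat FWE.

    Returns the observed TFCE map and the FWE-corrected p-value map; the
    uncorrected per-voxel p is stored in the p-map metadata.
    """
    if 1.0 / (scheme.n_perm + 1) > alpha:
        logger.warning("n_perm=%d cannot reach alpha=%g (min p=%g)",
                       scheme.n_perm, alpha, 1.0 / (scheme.n_perm + 1))
    rng = np.random.default_rng(scheme.seed)
    mask = matrix.mask.data

    observed_mean = _masked_mean_maps(matrix, np.ones((1, matrix.n_pairs)))[0]

    def enhance(vec: np.ndarray) -> np.ndarray:
        grid = matrix.to_map(vec, fill=0.0)
        grid = np.nan_to_num(grid, nan=0.0)
        enhanced = tfce_array(grid, tfce_params)
        if two_tailed:
            enhanced_neg = tfce_array(-grid, tfce_params)
            enhanced = np.maximum(enhanced, enhanced_neg)
        return enhanced[mask]

    obs_tfce = enhance(observed_mean)

    exceed_max = np.zeros(matrix.n_voxels)
    exceed_vox = np.zeros(matrix.n_voxels)
    for _ in range(scheme.n_perm):
        signs = _draw_signs(matrix, scheme, rng)
        perm_mean = _masked_mean_maps(matrix, signs[None, :])[0]
        perm_tfce = enhance(perm_mean)
        perm_max = np.nanmax(perm_tfce) if perm_tfce.size else 0.0
        exceed_max += perm_max >= obs_tfce
        exceed_vox += perm_tfce >= obs_tfce

    p_fwe = (1.0 + exceed_max) / (1.0 + scheme.n_perm)
    p_unc = (1.0 + exceed_vox) / (1.0 + scheme.n_perm)

    obs_map = StatMap(data=matrix.to_map(obs_tfce), statistic_name="tfce",
                      metadata={"kind": matrix.kind,
                                "conditions": list(matrix.conditions),
                                "n_pairs": matrix.n_pairs,
                                "scheme": scheme.mode, "n_perm": scheme.n_perm},
                      affine=matrix.mask.affine)
    p_map = PValueMap(data=matrix.to_map(p_fwe), corrected=True,
                      n_perm=scheme.n_perm,
                      metadata={"scheme": scheme.mode, "seed": scheme.seed,
                                "uncorrected_p": matrix.to_map(p_unc)},
                      affine=matrix.mask.affine)
    return obs_map, p_map


def conjunction_min(p_maps: list[PValueMap], alpha: float = 0.05) -> np.ndarray:
    """Minimum-statistic conjunction: voxel true iff significant in every map.

    Equivalent to thresholding the voxelwise maximum p (minimum statistic)
    at alpha.  Returns a boolean 3D array.
    """
    if len(p_maps) < 2:
        raise DataError("conjunction needs at least 2 maps")
    shape = p_maps[0].data.shape
    for m in p_maps[1:]:
        if m.data.shape != shape:
            raise DataError(f"grid mismatch in conjunction: {m.data.shape} vs {shape}")
    out = np.ones(shape, dtype=bool)
    for m in p_maps:
        with np.errstate(invalid="ignore"):
            out &= m.data < alpha
    return out
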