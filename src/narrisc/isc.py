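"""Per-voxel pairwise inter-subject correlation (ISC).

Within one condition, every unordered subject pair (i < j) contributes one
Pearson r per voxel; for N subjects that is N(N-1)/2 pairs (406 for N=29).
Between two conditions, ordered pairs (i in c1, j in c2, i != j) are kept,
N(N-1) of them, matching the double-sum definition of the between-condition
average r; the mean is unchanged versus unordered averaging but the pair
bookkeeping reflects that r(s_i,c1, s_j,c2) and r(s_j,c1, s_i,c2) are
distinct observations.

Averaging uses raw r (the between-condition average statistic is defined as
the arithmetic mean of the pairwise correlations); a Fisher-z option exists
but is off by default.  Zero-variance time courses yield invalid (NaN)
entries which are excluded and counted, never averaged in as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import BrainMask, CohortDataset, DataError, StatMap

Pair = tuple[str, str, str, str]  # (subject_i, subject_j, condition_i, condition_j)


@dataclass
class PairwiseISCMatrix:
    """n_pairs x n_voxels matrix of pairwise Pearson r on the masked voxels."""

    pairs: list[Pair]
    values: np.ndarray
    kind: str                    # "within" | "between"
    mask: BrainMask
    conditions: tuple[str, ...]
    subjects: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[0] != len(self.pairs):
            raise DataError("pair bookkeeping does not match value rows")
        if self.kind not in ("within", "between"):
            raise DataError(f"unknown matrix kind {self.kind!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def to_map(self, vector: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter an n_voxels vector back onto the 3D grid (NaN outside mask)."""
        grid = np.full(self.mask.shape, fill, dtype=np.float64)
        grid[self.mask.data] = vector
        return grid


def _zscore_columns(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize (T, V) columns to zero mean / unit population SD.

    Returns (z, valid) where invalid marks zero-variance columns; their z
    columns are set to 0 so products vanish and are masked afterwards.
    """
    centered = series - series.mean(axis=0, keepdims=True)
    sd = centered.std(axis=0)
    valid = sd > 0
    sd_safe = np.where(valid, sd, 1.0)
    return centered / sd_safe, valid


def _pair_correlations(cohort: CohortDataset, pairs_idx: list[tuple[int, int]],
                       cond_a: str, cond_b: str, subjects: list[str],
                       block_size: int) -> np.ndarray:
    """Pearson r for (subjects[i] in cond_a, subjects[j] in cond_b) pairs.

    Voxels are processed in blocks so memory stays bounded by
    block_size x n_subjects regardless of mask size.
    """
    n_vox = cohort.mask.n_voxels
    T = cohort.n_timepoints(cond_a)
    out = np.empty((len(pairs_idx), n_vox))
    ia = np.array([i for i, _ in pairs_idx])
    jb = np.array([j for _, j in pairs_idx])
    for start in range(0, n_vox, block_size):
        stop = min(start + block_size, n_vox)
        za, zb, va, vb = [], [], [], []
        for subj in subjects:
            sa = cohort.masked_series(subj, cond_a)[:, start:stop]
            z, v = _zscore_columns(sa)
            za.append(z); va.append(v)
            if cond_b == cond_a:
                zb.append(z); vb.append(v)
            else:
                sb = cohort.masked_series(subj, cond_b)[:, start:stop]
                z2, v2 = _zscore_columns(sb)
                zb.append(z2); vb.append(v2)
        ZA = np.stack(za)   # (N, T, v)
        ZB = np.stack(zb)
        VA = np.stack(va)
        VB = np.stack(vb)
        r = np.einsum("ptv,ptv->pv", ZA[ia], ZB[jb]) / T
        invalid = ~(VA[ia] & VB[jb])
        r[invalid] = np.nan
        out[:, start:stop] = r
    return np.clip(out, -1.0, 1.0, out=out, where=np.isfinite(out))


def pairwise_within_isc(cohort: CohortDataset, condition: str,
                        block_size: int = 20000) -> PairwiseISCMatrix:
    """All unordered-pair Pearson correlations within one condition."""
    if condition not in cohort.conditions:
        raise DataError(f"condition {condition!r} not in cohort")
    N = cohort.n_subjects
    if N < 2:
        raise DataError("within-condition ISC needs at least 2 subjects")
    if cohort.n_timepoints(condition) < 3:
        raise DataError("within-condition ISC needs T >= 3")
    subjects = cohort.subjects
    pairs_idx = [(i, j) for i in range(N) for j in range(i + 1, N)]
    values = _pair_correlations(cohort, pairs_idx, condition, condition,
                                subjects, block_size)
    pairs = [(subjects[i], subjects[j], condition, condition) for i, j in pairs_idx]
    return PairwiseISCMatrix(pairs=pairs, values=values, kind="within",
                             mask=cohort.mask, conditions=(condition,),
                             subjects=list(subjects))


def pairwise_between_isc(cohort: CohortDataset, c1: str, c2: str,
                         block_size: int = 20000) -> PairwiseISCMatrix:
    """Ordered-pair correlations r(s_i in c1, s_j in c2), i != j."""
    for c in (c1, c2):
        if c not in cohort.conditions:
            raise DataError(f"condition {c!r} not in cohort")
    if cohort.n_timepoints(c1) != cohort.n_timepoints(c2):
        raise DataError(
            f"conditions {c1!r} (T={cohort.n_timepoints(c1)}) and {c2!r} "
            f"(T={cohort.n_timepoints(c2)}) have mismatched T")
    N = cohort.n_subjects
    if N < 2:
        raise DataError("between-condition ISC needs at least 2 subjects")
    subjects = cohort.subjects
    pairs_idx = [(i, j) for i in range(N) for j in range(N) if i != j]
    values = _pair_correlations(cohort, pairs_idx, c1, c2, subjects, block_size)
    pairs = [(subjects[i], subjects[j], c1, c2) for i, j in pairs_idx]
    return PairwiseISCMatrix(pairs=pairs, values=values, kind="between",
                             mask=cohort.mask, conditions=(c1, c2),
                             subjects=list(subjects))


def mean_isc_map(matrix: PairwiseISCMatrix, fisher_z: bool = False) -> StatMap:
    """Per-voxel mean of pairwise r over valid pairs (NaN where none valid)."""
    vals = matrix.values
    n_invalid = np.isnan(vals).sum(axis=0)
    n_valid = vals.shape[0] - n_invalid
    if fisher_z:
        vals = np.arctanh(np.clip(vals, -1 + 1e-15, 1 - 1e-15))
    # summing in sorted order makes the mean independent of pair bookkeeping
    # order, so permuting subject order reproduces the map bit-identically
    vals = np.sort(vals, axis=0)  # NaN sort to the end
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_vec = np.where(n_valid > 0,
                            np.nansum(vals, axis=0) / np.maximum(n_valid, 1),
                            np.nan)
    if fisher_z:
        mean_vec = np.tanh(mean_vec)
    grid = matrix.to_map(mean_vec)
    return StatMap(
        data=grid,
        statistic_name="mean_isc",
        metadata={
            "kind": matrix.kind,
            "conditions": list(matrix.conditions),
            "n_pairs": matrix.n_pairs,
            "n_invalid_total": int(n_invalid.sum()),
            "fisher_z": fisher_z,
        },
        affine=matrix.mask.affine,
    )
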