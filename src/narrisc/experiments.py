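"""Repeatable simulation experiments: recovery, calibration and power.

These drivers run the full pipeline on synthetic cohorts and summarize the
outcome; the validation suite and the analysis scripts both call them.
Problem sizes are scaled to desk hardware: calibration runs use a
10x10x10 grid with short runs (T=200) and 99 permutations per test, which
keeps each Monte-Carlo repeat under a second while leaving the statistics'
validity untouched (a permutation p-value is exact at any statistic
resolution, so the TFCE integration ladder is coarsened to 25 steps here).
"""

from __future__ import annotations

import numpy as np

from .association import mantel_association
from .inference import PermutationScheme, TFCEParams, permutation_test
from .isc import mean_isc_map, pairwise_between_isc, pairwise_within_isc
from .synthetic import SimulationConfig, generate_cohort

#: coarse ladder for Monte-Carlo experiments (validity is unaffected)
MC_TFCE = TFCEParams(n_steps=25)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-repeat seeds below 2**31 derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)


def isc_recovery(fractions=(0.0, 0.25, 0.5, 1.0), n_subjects: int = 20,
                 T: int = 1000, shape=(3, 3, 3), seed: int = 0) -> dict:
    """Recover the shared fraction f from the within-condition mean ISC map.

    Under the generative model E[r] = f, so the pair-averaged map should sit
    within 0.05 of f.
    """
    out = {}
    for f, s in zip(fractions, _child_seeds(seed, len(fractions))):
        cfg = SimulationConfig(n_subjects=n_subjects, shape=shape,
                               n_timepoints=T, conditions=("listen",),
                               shared_fraction_within=f,
                               shared_fraction_between=0.0, seed=int(s))
        cohort, *_ = generate_cohort(cfg)
        m = mean_isc_map(pairwise_within_isc(cohort, "listen"))
        out[f] = float(np.nanmean(m.data))
    return out


def between_isc_recovery(b: float = 0.25, f: float = 0.5, n_subjects: int = 20,
                         T: int = 1000, shape=(3, 3, 3), seed: int = 0) -> float:
    """Recover the between-condition shared fraction b from the ordered-pair
    mean ISC between two conditions."""
    cfg = SimulationConfig(n_subjects=n_subjects, shape=shape, n_timepoints=T,
                           conditions=("lipread", "listen"),
                           shared_fraction_within=f,
                           shared_fraction_between=b, seed=seed)
    cohort, *_ = generate_cohort(cfg)
    m = mean_isc_map(pairwise_between_isc(cohort, "lipread", "listen"))
    return float(np.nanmean(m.data))


def fwe_calibration(n_repeats: int = 200, n_subjects: int = 10,
                    shape=(10, 10, 10), T: int = 200, n_perm: int = 99,
                    alpha: float = 0.05, seed: int = 0,
                    mode: str = "subject_blocks",
                    tfce_params: TFCEParams = MC_TFCE) -> dict:
    """Family-wise false-positive rate of the sign-flip/TFCE test on null
    cohorts (no shared signal anywhere).

    Each repeat generates an independent null cohort, runs the corrected
    one-sample test, and records whether ANY voxel is declared significant.
    A calibrated test keeps this rate near alpha.

    The default flipping scheme is subject_blocks: under the null, negating
    one subject's time series is an exact distributional invariance and flips
    every pair containing that subject coherently, so the block scheme yields
    exact FWE control.  Independent per-pair flips ignore the dependence of
    pairs sharing a subject and are anti-conservative at small n (the
    pair_independent mode is kept for measuring exactly that inflation).
    """
    hits = 0
    for s in _child_seeds(seed, n_repeats):
        cfg = SimulationConfig(n_subjects=n_subjects, shape=shape,
                               n_timepoints=T, conditions=("listen",),
                               shared_fraction_within=0.0,
                               shared_fraction_between=0.0, seed=int(s))
        cohort, *_ = generate_cohort(cfg)
        matrix = pairwise_within_isc(cohort, "listen")
        _, pmap = permutation_test(
            matrix, tfce_params,
            PermutationScheme(mode=mode, n_perm=n_perm,
                              seed=int(s) % (2 ** 31 - 1)),
            alpha=alpha)
        hits += bool(np.nanmin(pmap.data) < alpha)
    return {"rate": hits / n_repeats, "n_repeats": n_repeats,
            "n_subjects": n_subjects, "n_perm": n_perm, "mode": mode}


def _skill_region_config(n_subjects: int, T: int, shape, region,
                         f_region: float, b_region: float, seed: int,
                         skill_linked: bool) -> SimulationConfig:
    region = np.asarray(region, dtype=bool)
    f = np.where(region, f_region, 0.3)
    b = np.where(region, b_region, 0.15)
    return SimulationConfig(n_subjects=n_subjects, shape=shape, n_timepoints=T,
                            conditions=("lipread", "listen"),
                            shared_fraction_within=f,
                            shared_fraction_between=b,
                            skill_region=region if skill_linked else None,
                            seed=seed)


def default_region(shape=(6, 6, 6)) -> np.ndarray:
    region = np.zeros(shape, dtype=bool)
    region[1:4, 1:4, 1:4] = True
    return region


def mantel_null_calibration(n_repeats: int = 100, n_subjects: int = 15,
                            shape=(10, 10, 10), T: int = 200,
                            n_perm: int = 99, alpha: float = 0.05,
                            seed: int = 0) -> dict:
    """Mantel detections under a zero-slope skill model.

    Cohorts carry real between-condition signal but no skill modulation, so
    the skill predictor is unrelated to ISC; detections anywhere should stay
    at the FWE level.
    """
    hits = 0
    for s in _child_seeds(seed, n_repeats):
        cfg = SimulationConfig(n_subjects=n_subjects, shape=shape,
                               n_timepoints=T,
                               conditions=("lipread", "listen"),
                               shared_fraction_within=0.3,
                               shared_fraction_between=0.15, seed=int(s))
        cohort, behavior, *_ = generate_cohort(cfg)
        matrix = pairwise_between_isc(cohort, "lipread", "listen")
        res = mantel_association(
            matrix, behavior, source="lip_score",
            scheme=PermutationScheme(n_perm=n_perm,
                                     seed=int(s) % (2 ** 31 - 1)),
            tfce_params=MC_TFCE)
        hits += bool(np.nanmin(res.p_map.data) < alpha)
    return {"rate": hits / n_repeats, "n_repeats": n_repeats,
            "n_subjects": n_subjects, "n_perm": n_perm}


def mantel_power(n_repeats: int = 20, n_subjects: int = 20, T: int = 300,
                 shape=(6, 6, 6), n_perm: int = 199, alpha: float = 0.05,
                 f_region: float = 0.6, b_region: float = 0.5,
                 seed: int = 0) -> dict:
    """Recovery of a planted skill-modulated region by the Mantel test.

    In the region, each subject's loading on the cross-condition component
    scales with skill/100, so pairwise ISC there covaries with the lipread
    member's skill score.  A repeat counts as a detection when at least one
    region voxel reaches corrected p < alpha; voxelwise sensitivity inside
    the region is also tracked.
    """
    region = default_region(shape)
    detected = 0
    sens = []
    for s in _child_seeds(seed, n_repeats):
        cfg = _skill_region_config(n_subjects, T, shape, region, f_region,
                                   b_region, int(s), skill_linked=True)
        cohort, behavior, *_ = generate_cohort(cfg)
        matrix = pairwise_between_isc(cohort, "lipread", "listen")
        res = mantel_association(
            matrix, behavior, source="lip_score",
            scheme=PermutationScheme(n_perm=n_perm,
                                     seed=int(s) % (2 ** 31 - 1)),
            tfce_params=MC_TFCE)
        sig = res.p_map.data < alpha
        detected += bool(sig[region].any())
        sens.append(sig[region].mean())
    return {"rate": detected / n_repeats, "sensitivity": float(np.mean(sens)),
            "n_repeats": n_repeats, "n_subjects": n_subjects, "n_perm": n_perm}


def signflip_power_single(n_subjects: int = 15, T: int = 300, shape=(8, 8, 8),
                          n_perm: int = 199, alpha: float = 0.05,
                          f: float = 0.3, seed: int = 0) -> dict:
    """One-sample sign-flip power on a single cohort with an f-shared region.

    Returns the fraction of region voxels reaching corrected significance and
    the number of significant voxels among those at least 2 voxels away from
    the region (TFCE spills into immediately adjacent voxels by design, so
    the specificity count excludes the one-voxel border).
    """
    from scipy import ndimage
    region = np.zeros(shape, dtype=bool)
    region[2:5, 2:5, 2:5] = True
    cfg = SimulationConfig(n_subjects=n_subjects, shape=shape, n_timepoints=T,
                           conditions=("listen",),
                           shared_fraction_within=np.where(region, f, 0.0),
                           shared_fraction_between=0.0, seed=seed)
    cohort, *_ = generate_cohort(cfg)
    matrix = pairwise_within_isc(cohort, "listen")
    _, pmap = permutation_test(matrix, MC_TFCE,
                               PermutationScheme(n_perm=n_perm, seed=seed))
    sig = pmap.data < alpha
    border = ndimage.binary_dilation(region, iterations=1)
    return {"region_sensitivity": float(sig[region].mean()),
            "far_false_positives": int(sig[~border].sum()),
            "n_region": int(region.sum())}
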