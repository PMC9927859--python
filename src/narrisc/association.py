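"""Association of pairwise between-condition ISC with behavior (Mantel test).

Each between-condition pair (i lipreading, j listening) carries the
behavioral value of the pair member in the lipreading role; the per-voxel
statistic is the Pearson correlation across pairs between ISC values and
that predictor (for a single predictor this is equivalent, up to a monotone
transform, to the simple-regression slope test of regressing ISC on the
predictor).  Significance follows the Mantel convention: subject labels in
the behavioral table are shuffled, the pair predictor rebuilt, and the
statistic map recomputed each permutation, which preserves the pair
dependence structure of ISC values under the null.  TFCE and max-statistic
FWE correction are applied as for the one-sample inference.

Presentation-order control subtracts order-group means: per-pair ISC values
and the pair predictor are grouped by the lipreading-condition member's
order group.
"""

from __future__ import annotations

import numpy as np

from .behavior import center_by_group
from .dataio import BehavioralTable, DataError, PValueMap, StatMap
from .inference import PermutationScheme, TFCEParams, tfce_array
from .isc import PairwiseISCMatrix


class PairPredictor:
    """Per-pair behavioral predictor aligned with a pair matrix."""

    def __init__(self, values: np.ndarray, source: str, assignment_rule: str,
                 lipread_members: list[str], degenerate: bool = False):
        self.values = np.asarray(values, dtype=np.float64)
        self.source = source
        self.assignment_rule = assignment_rule
        self.lipread_members = lipread_members
        self.degenerate = degenerate


SOURCE_COLUMNS = {"lip_score": "lip_score_pct", "mean_rating": "mean_rating"}


def _lipread_member_index(matrix: PairwiseISCMatrix,
                          lipread_condition: str) -> list[int]:
    """For each pair, 0 or 1: which member is in the lipreading condition."""
    if matrix.kind != "between":
        raise DataError("pair predictor is defined for between-condition "
                        "matrices only (the rule needs a lipreading role)")
    c1, c2 = matrix.conditions
    if lipread_condition not in (c1, c2):
        raise DataError(f"neither condition of {matrix.conditions} is the "
                        f"lipreading condition {lipread_condition!r}")
    if c1 == c2:
        raise DataError("between-condition matrix has identical condition roles")
    return [0 if c1 == lipread_condition else 1] * matrix.n_pairs


def build_pair_predictor(matrix: PairwiseISCMatrix, table: BehavioralTable,
                         source: str = "lip_score",
                         lipread_condition: str = "lipread") -> PairPredictor:
    """Predictor = behavioral value of the pair member in the lipreading role."""
    if source not in SOURCE_COLUMNS:
        raise DataError(f"unknown predictor source {source!r}")
    column = SOURCE_COLUMNS[source]
    which = _lipread_member_index(matrix, lipread_condition)
    members = [pair[w] for pair, w in zip(matrix.pairs, which)]
    values = np.array([table.value(m, column) for m in members])
    degenerate = bool(np.all(values == values[0]))
    return PairPredictor(values=values, source=source,
                         assignment_rule=f"value of member in {lipread_condition!r}",
                         lipread_members=members, degenerate=degenerate)


def remove_order_effects(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Group-mean centering (per-subject or per-pair vectors)."""
    return center_by_group(np.asarray(values, dtype=float), np.asarray(groups))


class AssociationResult:
    def __init__(self, stat_map: StatMap, p_map: PValueMap,
                 scheme: PermutationScheme, n_perm: int):
        self.stat_map = stat_map
        self.p_map = p_map
        self.scheme = scheme
        self.n_perm = n_perm


def _corr_with_columns(pred: np.ndarray, values_centered: np.ndarray,
                       col_norms: np.ndarray) -> np.ndarray:
    """Pearson r of pred against every column of a pre-centered matrix."""
    pc = pred - pred.mean()
    denom = np.linalg.norm(pc) * col_norms
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (pc @ values_centered) / denom
    return r


def mantel_association(matrix: PairwiseISCMatrix, table: BehavioralTable,
                       source: str = "lip_score",
                       lipread_condition: str = "lipread",
                       scheme: PermutationScheme = PermutationScheme(),
                       tfce_params: TFCEParams = TFCEParams(),
                       control_order: bool = False,
                       extra_sources: tuple[str, ...] = ()
                       ) -> AssociationResult:
    """Mantel-type permutation test of pairwise ISC against behavior.

    extra_sources enables a joint multi-predictor mode in which the
    statistic is the multiple correlation of ISC on all predictors; the
    default is a single predictor per run.
    """
    if scheme.n_perm < 1:
        raise DataError("n_perm must be >= 1")
    predictor = build_pair_predictor(matrix, table, source, lipread_condition)
    if predictor.degenerate:
        raise DataError("constant behavioral predictor: association undefined")
    sources = (source,) + tuple(extra_sources)

    which = _lipread_member_index(matrix, lipread_condition)
    members = predictor.lipread_members
    subjects = matrix.subjects or sorted({p[0] for p in matrix.pairs}
                                         | {p[1] for p in matrix.pairs})
    member_idx = np.array([subjects.index(m) for m in members])

    # behavioral values indexed by subject position, one row per source
    beh = np.stack([table.aligned(subjects, SOURCE_COLUMNS[s]) for s in sources])
    pair_groups = None
    if control_order:
        subj_groups = table.aligned(subjects, "order_group").astype(int)
        pair_groups = subj_groups[member_idx]

    vals = matrix.values
    valid_cols = np.all(np.isfinite(vals), axis=0)
    V = vals.copy()
    V[:, ~valid_cols] = 0.0
    if control_order:
        V = np.stack([center_by_group(V[:, j], pair_groups)
                      for j in range(V.shape[1])], axis=1)
    Vc = V - V.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Vc, axis=0)
    norms[norms == 0] = np.nan

    def stat_vector(perm: np.ndarray) -> np.ndarray:
        """Association statistic per voxel for a subject-label permutation."""
        preds = beh[:, perm][:, member_idx]          # (k, n_pairs)
        if control_order:
            preds = np.stack([center_by_group(p, pair_groups) for p in preds])
        if preds.shape[0] == 1:
            return _corr_with_columns(preds[0], Vc, norms)
        # multiple correlation R for the joint mode
        X = np.column_stack([np.ones(preds.shape[1]), preds.T])
        beta, *_ = np.linalg.lstsq(X, Vc, rcond=None)
        fitted = X @ beta
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.linalg.norm(fitted - fitted.mean(axis=0), axis=0) / norms

    rng = np.random.default_rng(scheme.seed)
    identity = np.arange(len(subjects))
    obs_stat = stat_vector(identity)

    mask = matrix.mask.data

    def enhance(vec: np.ndarray) -> np.ndarray:
        grid = matrix.to_map(vec, fill=0.0)
        return tfce_array(np.nan_to_num(grid, nan=0.0), tfce_params)[mask]

    obs_tfce = enhance(obs_stat)
    exceed_max = np.zeros(matrix.n_voxels)
    exceed_vox = np.zeros(matrix.n_voxels)
    # the Mantel shuffle already permutes whole subjects, so subject-level
    # exchangeability blocks are respected by construction in either mode
    for _ in range(scheme.n_perm):
        perm = rng.permutation(len(subjects))
        perm_tfce = enhance(stat_vector(perm))
        exceed_max += np.nanmax(perm_tfce) >= obs_tfce
        exceed_vox += perm_tfce >= obs_tfce

    p_fwe = (1.0 + exceed_max) / (1.0 + scheme.n_perm)
    p_unc = (1.0 + exceed_vox) / (1.0 + scheme.n_perm)

    meta = {"source": sources, "scheme": scheme.mode, "n_perm": scheme.n_perm,
            "control_order": control_order, "conditions": list(matrix.conditions)}
    stat_map = StatMap(data=matrix.to_map(obs_stat),
                       statistic_name="pair_correlation", metadata=meta,
                       affine=matrix.mask.affine)
    p_map = PValueMap(data=matrix.to_map(p_fwe), corrected=True,
                      n_perm=scheme.n_perm,
                      metadata={**meta, "uncorrected_p": matrix.to_map(p_unc),
                                "observed_tfce": matrix.to_map(obs_tfce)},
                      affine=matrix.mask.affine)
    return AssociationResult(stat_map=stat_map, p_map=p_map, scheme=scheme,
                             n_perm=scheme.n_perm)
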