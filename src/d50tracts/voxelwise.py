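"""Mass-univariate GLM with permutation/TFCE inference on skeleton maps.

Implements the statistical core of a tract-based spatial statistics (TBSS)
style analysis: an ordinary-least-squares general linear model fitted
independently at every skeleton voxel, threshold-free cluster enhancement
(TFCE) of the resulting t-map, and family-wise error (FWE) control through
the permutation distribution of the image-wide maximum TFCE statistic.
Nuisance covariates are handled with the Freedman-Lane permutation scheme.

Only positive statistic values are enhanced; the opposite direction of a
contrast is tested by a separate run on the negated contrast, mirroring how
increases and decreases are reported separately in TBSS practice.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonDataset",
    "DesignMatrix",
    "StatMap",
    "TFCEParams",
    "PermutationResult",
    "PermutationTFCE",
    "build_design",
    "glm_tstat",
    "tfce_enhance",
    "permutation_maxtfce",
    "threshold_report",
    "tbss_tfce_params",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class SkeletonDataset:
    """Subjects x skeleton-voxel matrix for one DTI metric.

    ``values`` holds one row per subject over the ``mask.sum()`` skeleton
    voxels (FA dimensionless; MD/AD/RD in mm^2/s).
    """

    mask: np.ndarray
    values: np.ndarray
    metric_tag: str = "FA"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x voxels matrix")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError(
                f"values has {self.values.shape[1]} columns but mask has "
                f"{int(self.mask.sum())} skeleton voxels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.subject_ids is not None and len(self.subject_ids) != len(self.values):
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def select_subjects(self, index: np.ndarray) -> "SkeletonDataset":
        ids = None
        if self.subject_ids is not None:
            ids = [self.subject_ids[i] for i in np.atleast_1d(index)]
        return SkeletonDataset(
            mask=self.mask,
            values=self.values[index],
            metric_tag=self.metric_tag,
            affine=self.affine,
            subject_ids=ids,
        )


@dataclass
class DesignMatrix:
    """Named-column design with attached contrast vectors.

    Group factors are coded as one indicator column per level (cell-means
    coding); continuous covariates are mean-centred by default at build time.
    """

    matrix: np.ndarray
    columns: list[str]
    contrasts: dict[str, np.ndarray]
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.columns):
            raise ValueError("column names do not match matrix width")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")
        for name, c in self.contrasts.items():
            c = np.asarray(c, dtype=float)
            if c.size != self.matrix.shape[1]:
                raise ValueError(f"contrast '{name}' length mismatch")
            self.contrasts[name] = c

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


@dataclass
class StatMap:
    """Per-skeleton-voxel t statistics with their residual degrees of freedom."""

    values: np.ndarray
    df: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic map contains non-finite values")


@dataclass(frozen=True)
class TFCEParams:
    """TFCE integration parameters.

    ``E`` and ``H`` are the extent and height exponents; ``dh`` the threshold
    step in statistic units (``None`` = 1/100 of the observed map maximum);
    ``connectivity`` the 3-D neighbourhood (6, 18 or 26).
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


def tbss_tfce_params(dh: float | None = None) -> TFCEParams:
    """Skeleton-optimised TFCE variant (E=1, H=2, 26-connectivity)."""
    return TFCEParams(E=1.0, H=2.0, dh=dh, connectivity=26)


@dataclass
class PermutationResult:
    """Observed TFCE map with its permutation null and FWE-corrected p-values."""

    observed_t: StatMap
    observed_tfce: np.ndarray
    null_max: np.ndarray
    p_fwe: np.ndarray
    n_perm: int
    seed: int | None
    exhaustive: bool = False


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def build_design(
    table: pd.DataFrame,
    group: str | None = None,
    regressor: str | None = None,
    covariates: tuple[str, ...] = (),
    demean: bool = True,
    subject_col: str = "patient_id",
) -> DesignMatrix:
    """Build a GLM design from a per-subject covariate table.

    Exactly one of ``group`` (two-level factor, cell-means coded, contrast
    ``level1 - level2``) or ``regressor`` (continuous variable of interest,
    intercept included, contrast on its slope) must be given.  String-valued
    covariates are indicator-coded; continuous ones mean-centred when
    ``demean``.
    """
    if (group is None) == (regressor is None):
        raise ValueError("specify exactly one of group= or regressor=")
    if subject_col in table.columns and table[subject_col].duplicated().any():
        dups = table.loc[table[subject_col].duplicated(), subject_col].tolist()
        raise ValueError(f"duplicate subject rows: {dups}")

    needed = [c for c in (group, regressor, *covariates) if c is not None]
    for col in needed:
        if col not in table.columns:
            raise ValueError(f"covariate column '{col}' missing from table")
        if table[col].isna().any():
            bad = table.loc[table[col].isna()]
            who = (
                bad[subject_col].tolist()
                if subject_col in table.columns
                else bad.index.tolist()
            )
            raise ValueError(f"missing values in column '{col}' for subjects {who}")

    cols: list[np.ndarray] = []
    names: list[str] = []

    def add_continuous(name: str) -> None:
        x = table[name].to_numpy(dtype=float)
        cols.append(x - x.mean() if demean else x)
        names.append(name)

    def add_factor(name: str, drop_first: bool) -> list[str]:
        levels = sorted(pd.unique(table[name].astype(str)))
        used = levels[1:] if drop_first else levels
        for lev in used:
            cols.append((table[name].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{name}[{lev}]")
        return used

    contrasts: dict[str, np.ndarray] = {}
    if group is not None:
        levels = sorted(pd.unique(table[group].astype(str)))
        if len(levels) != 2:
            raise ValueError(f"group column '{group}' must have two levels, got {levels}")
        add_factor(group, drop_first=False)
        interest = np.zeros(2)
    else:
        cols.append(np.ones(len(table)))
        names.append("intercept")
        add_continuous(regressor)

    for cov in covariates:
        if table[cov].dtype == object or str(table[cov].dtype) == "category":
            add_factor(cov, drop_first=True)
        else:
            add_continuous(cov)

    matrix = np.column_stack(cols)
    ncol = matrix.shape[1]
    if group is not None:
        c = np.zeros(ncol)
        c[0], c[1] = 1.0, -1.0
        contrasts[f"{group}:{sorted(pd.unique(table[group].astype(str)))[0]}>"
                  f"{sorted(pd.unique(table[group].astype(str)))[1]}"] = c
    else:
        c = np.zeros(ncol)
        c[names.index(regressor)] = 1.0
        contrasts[f"{regressor}:positive"] = c

    ids = table[subject_col].astype(str).tolist() if subject_col in table.columns else None
    return DesignMatrix(matrix=matrix, columns=names, contrasts=contrasts, subject_ids=ids)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------


def _tstat_matrix(
    Y: np.ndarray, X: np.ndarray, c: np.ndarray, pinvX: np.ndarray, cXXc: float, df: int
) -> np.ndarray:
    beta = pinvX @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    denom = np.sqrt(sigma2 * cXXc)
    num = c @ beta
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def glm_tstat(
    data: SkeletonDataset | np.ndarray, design: DesignMatrix, contrast: np.ndarray | str
) -> StatMap:
    """Per-voxel OLS t-statistic for one contrast.

    ``t = c' b / sqrt(s^2 c' (X'X)^-1 c)`` with ``s^2`` the residual variance
    on ``n - rank(X)`` degrees of freedom.  Voxels with zero residual
    variance get t = 0 (logged).
    """
    Y = data.values.copy() if isinstance(data, SkeletonDataset) else np.asarray(data, float)
    X = design.matrix
    if isinstance(contrast, str):
        contrast = design.contrasts[contrast]
    c = np.asarray(contrast, dtype=float)
    n, p = X.shape
    if Y.shape[0] != n:
        raise ValueError("data and design have different subject counts")
    df = n - design.rank
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    XtX_inv = np.linalg.inv(X.T @ X)
    pinvX = XtX_inv @ X.T
    cXXc = float(c @ XtX_inv @ c)
    t = _tstat_matrix(Y, X, c, pinvX, cXXc, df)
    n_degenerate = int(np.sum(~np.isfinite(t)))
    if n_degenerate:
        logger.warning("%d degenerate voxels set to t=0", n_degenerate)
        t = np.nan_to_num(t)
    zero_var = np.einsum("ij,ij->j", Y - X @ (pinvX @ Y), Y - X @ (pinvX @ Y)) == 0
    if zero_var.any():
        logger.warning("%d zero-variance voxels set to t=0", int(zero_var.sum()))
        t[zero_var] = 0.0
    return StatMap(values=t, df=df)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------


def _embed(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vol = np.zeros(mask.shape, dtype=float)
    vol[mask] = values
    return vol


def tfce_enhance(
    stat: StatMap | np.ndarray,
    params: TFCEParams | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    For every voxel v, sums ``e_v(h)^E * h^H * dh`` over thresholds
    ``h = dh, 2dh, ... <= max(stat)``, where ``e_v(h)`` is the voxel count of
    the connected suprathreshold (``stat >= h``) component containing v.
    Negative statistic values contribute nothing; enhance the negated map to
    test the opposite direction.  Returns values over the mask voxels when a
    mask is given, else a full 3-D map.
    """
    params = params or TFCEParams()
    values = stat.values if isinstance(stat, StatMap) else np.asarray(stat, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("statistic map contains non-finite values")
    masked_input = mask is not None and values.ndim == 1
    if masked_input:
        vol = _embed(values, mask)
    else:
        vol = np.asarray(values, dtype=float)
        if vol.ndim != 3:
            raise ValueError("unmasked input must be a 3-D volume")

    pos = np.where(vol > 0, vol, 0.0)
    vmax = float(pos.max())
    out = np.zeros_like(vol)
    if vmax > 0:
        dh = params.dh if params.dh is not None else vmax / 100.0
        structure = params.structure()
        # crop to the positive bounding box: labelling cost dominates
        idx = np.nonzero(pos > 0)
        lo = [int(i.min()) for i in idx]
        hi = [int(i.max()) + 1 for i in idx]
        sub = pos[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        acc = np.zeros_like(sub)
        n_steps = int(math.floor(vmax / dh + 1e-9))
        for k in range(1, n_steps + 1):
            h = k * dh
            sup = sub >= h
            labels, n_comp = ndimage.label(sup, structure=structure)
            if n_comp == 0:
                continue
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            acc[sup] += (sizes.astype(float) ** params.E)[labels[sup]] * h**params.H * dh
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = acc
    if masked_input:
        return out[mask]
    return out


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------


def _exhaustive_group_perms(group_rows: np.ndarray) -> list[np.ndarray] | None:
    """All distinct relabelings for a pure two-group design, as row orders.

    Returns None when the design is not a pure two-level indicator layout.
    """
    patterns, inverse = np.unique(group_rows, axis=0, return_inverse=True)
    if len(patterns) != 2:
        return None
    n = len(inverse)
    pos_a = np.nonzero(inverse == 0)[0]
    pos_b = np.nonzero(inverse == 1)[0]
    if math.comb(n, len(pos_a)) > 100000:
        return None
    orders = []
    all_idx = np.arange(n)
    for new_a in itertools.combinations(range(n), len(pos_a)):
        new_a = np.array(new_a)
        order = np.empty(n, dtype=int)
        # design rows labelled A receive the data of the newly-assigned A set
        order[pos_a] = new_a
        order[pos_b] = np.setdiff1d(all_idx, new_a)
        orders.append(order)
    return orders


def permutation_maxtfce(
    data: SkeletonDataset,
    design: DesignMatrix,
    contrast: np.ndarray | str,
    params: TFCEParams | None = None,
    n_perm: int = 5000,
    seed: int | None = 0,
) -> PermutationResult:
    """Permutation test with TFCE and max-statistic FWE correction.

    Uses the Freedman-Lane scheme: the data are residualised against the
    nuisance part of the design (columns with zero contrast weight), the
    residual rows are permuted, the nuisance signal is added back, and the
    full model is refit.  Per permutation the image-wide maximum TFCE value
    is collected; ``p_fwe(v) = (1 + #{null_max >= tfce(v)}) / (n_perm + 1)``.

    When the requested number of permutations reaches the number of distinct
    relabelings, an exhaustive enumeration replaces random sampling (logged).
    """
    params = params or TFCEParams()
    if isinstance(contrast, str):
        contrast = design.contrasts[contrast]
    c = np.asarray(contrast, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = design.matrix
    Y = data.values
    n = X.shape[0]

    obs_t = glm_tstat(data, design, c)
    obs_tfce = tfce_enhance(obs_t, params, data.mask)
    # the observed map's integration step is reused for every permutation so
    # all maxima live on the same enhancement scale
    if params.dh is None and obs_tfce.max() > 0:
        vmax = float(np.maximum(obs_t.values, 0).max())
        params = TFCEParams(E=params.E, H=params.H, dh=vmax / 100.0,
                            connectivity=params.connectivity)

    nuisance = np.abs(c) == 0
    Z = X[:, nuisance]
    if Z.shape[1] > 0:
        Hz = Z @ np.linalg.pinv(Z)
        fitted_z = Hz @ Y
        resid_z = Y - fitted_z
    else:
        fitted_z = np.zeros_like(Y)
        resid_z = Y

    orders: list[np.ndarray] | None = None
    exhaustive = False
    if Z.shape[1] == 0:
        group_orders = _exhaustive_group_perms(X[:, ~nuisance])
        if group_orders is not None and len(group_orders) - 1 <= n_perm:
            orders = [o for o in group_orders if not np.array_equal(o, np.arange(n))]
            exhaustive = True
    if orders is None and math.factorial(n) - 1 <= n_perm:
        orders = [
            np.array(p)
            for p in itertools.permutations(range(n))
            if not np.array_equal(p, np.arange(n))
        ]
        exhaustive = True
    if exhaustive:
        logger.info("exhaustive enumeration: %d distinct relabelings", len(orders) + 1)

    XtX_inv = np.linalg.inv(X.T @ X)
    pinvX = XtX_inv @ X.T
    cXXc = float(c @ XtX_inv @ c)
    df = n - design.rank

    rng = np.random.default_rng(seed)
    if orders is None:
        orders = [rng.permutation(n) for _ in range(n_perm)]

    null_max = np.empty(len(orders), dtype=float)
    for i, order in enumerate(orders):
        Ystar = fitted_z + resid_z[order]
        t_perm = _tstat_matrix(Ystar, X, c, pinvX, cXXc, df)
        t_perm = np.nan_to_num(t_perm)
        null_max[i] = tfce_enhance(t_perm, params, data.mask).max()

    n_eff = len(orders)
    exceed = (null_max[None, :] >= obs_tfce[:, None]).sum(axis=1)
    p_fwe = (1.0 + exceed) / (n_eff + 1.0)
    return PermutationResult(
        observed_t=obs_t,
        observed_tfce=obs_tfce,
        null_max=null_max,
        p_fwe=p_fwe,
        n_perm=n_eff,
        seed=seed,
        exhaustive=exhaustive,
    )


class PermutationTFCE(BaseEstimator):
    """Estimator wrapper around :func:`permutation_maxtfce`.

    Construct with a design, contrast and TFCE/permutation settings; ``fit``
    takes the subjects x voxels matrix (or a :class:`SkeletonDataset`) and
    exposes ``tstat_``, ``tfce_``, ``null_max_`` and ``p_fwe_``.
    """

    def __init__(
        self,
        design: DesignMatrix | None = None,
        contrast: np.ndarray | str | None = None,
        params: TFCEParams | None = None,
        n_perm: int = 5000,
        seed: int | None = 0,
        mask: np.ndarray | None = None,
    ) -> None:
        self.design = design
        self.contrast = contrast
        self.params = params
        self.n_perm = n_perm
        self.seed = seed
        self.mask = mask

    def fit(self, X, y=None) -> "PermutationTFCE":
        if isinstance(X, SkeletonDataset):
            data = X
        else:
            X = np.asarray(X, dtype=float)
            mask = self.mask
            if mask is None:  # treat columns as a flat 1 x v x 1 grid
                mask = np.ones((1, X.shape[1], 1), dtype=bool)
            data = SkeletonDataset(mask=mask, values=X)
        result = permutation_maxtfce(
            data, self.design, self.contrast,
            params=self.params, n_perm=self.n_perm, seed=self.seed,
        )
        self.result_ = result
        self.tstat_ = result.observed_t.values
        self.tfce_ = result.observed_tfce
        self.null_max_ = result.null_max
        self.p_fwe_ = result.p_fwe
        return self


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def threshold_report(
    result: PermutationResult,
    alpha: float,
    mask: np.ndarray | None = None,
    p_levels: tuple[float, ...] = (0.001, 0.01, 0.05),
    connectivity: int = 26,
) -> dict:
    """Summary of FWE-suprathreshold voxels at level ``alpha``.

    Returns total suprathreshold count, a by-p-level histogram over the
    disjoint bins formed by ``p_levels`` (restricted to levels <= alpha) and,
    when a mask is given, the connected components of significant voxels with
    sizes, peak TFCE values and peak voxel coordinates.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    sig = result.p_fwe < alpha
    levels = sorted([lv for lv in p_levels if lv <= alpha] + [alpha])
    edges = [0.0] + levels
    hist_rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        count = int(np.sum((result.p_fwe >= lo) & (result.p_fwe < hi)))
        hist_rows.append({"p_low": lo, "p_high": hi, "n_voxels": count})
    histogram = pd.DataFrame(hist_rows)

    components: list[dict] = []
    if mask is not None and sig.any():
        vol = np.zeros(mask.shape, dtype=bool)
        vol[mask] = sig
        structure = TFCEParams(connectivity=connectivity).structure()
        labels, n_comp = ndimage.label(vol, structure=structure)
        tf_vol = np.zeros(mask.shape, dtype=float)
        tf_vol[mask] = result.observed_tfce
        for k in range(1, n_comp + 1):
            comp = labels == k
            peak_flat = int(np.argmax(np.where(comp, tf_vol, -np.inf)))
            peak = np.unravel_index(peak_flat, mask.shape)
            components.append(
                {
                    "size": int(comp.sum()),
                    "peak_tfce": float(tf_vol[peak]),
                    "peak_voxel": tuple(int(i) for i in peak),
                    "min_p_fwe": float(result.p_fwe[comp[mask]].min()),
                }
            )
        components.sort(key=lambda d: -d["size"])

    return {
        "alpha": alpha,
        "n_significant": int(sig.sum()),
        "significant": sig,
        "histogram": histogram,
        "components": components,
    }
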