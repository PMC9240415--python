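"""Voxel-wise lesion-symptom mapping with permutation inference.

Two complementary analyses relate per-voxel lesion status to a behavioural
score (composite discourse coherence) across patients:

* **VBCM** (voxel-based correlational methodology): mass-univariate — at each
  voxel, behaviour is regressed on the continuous abnormality value plus
  covariates (age, months post-onset, optionally lesion volume); the t
  statistic of the voxel coefficient forms the map.
* **SVR-LSM**: multivariate — an epsilon-SVR with a linear kernel is fit from
  all binary lesion voxels jointly to behaviour (residualized for
  covariates); the back-projected weight per voxel forms the map.

Both use permutation of the behaviour vector for inference: voxel-wise p
values from the permutation (or analytic t) distribution, and cluster-level
family-wise error control from the permutation distribution of the maximum
suprathreshold cluster size. Covariates are handled by Freedman-Lane
residual permutation. Cluster correction is permutation-based throughout
(distribution-free), rather than random-field theory.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "LesionImage",
    "LesionDataset",
    "StatMap",
    "Cluster",
    "ClusterSet",
    "fwhm_to_sigma",
    "smooth",
    "binarize",
    "lesion_volume",
    "vbcm",
    "vbcm_multi",
    "svr_lsm",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class LesionImage:
    """One patient's lesion image on a common grid.

    ``values`` is a 3D array of continuous abnormality in [0, 1] or a binary
    mask; ``voxel_size`` is in mm (isotropic or per-axis); ``affine`` is
    carried opaquely from input to output.
    """

    values: np.ndarray
    voxel_size: float | tuple[float, float, float] = 2.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("lesion image must be 3D")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 1:
            raise ValueError("lesion values must lie in [0, 1]")

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())

    def sigma_voxels(self, fwhm_mm: float) -> np.ndarray:
        vs = np.broadcast_to(np.asarray(self.voxel_size, dtype=float), (3,))
        return fwhm_to_sigma(fwhm_mm) / vs


@dataclass
class LesionDataset:
    """Aligned stack of lesion images + behaviour + covariates.

    ``images``: (n_patients, nx, ny, nz) array; ``behaviour``: length-n
    vector; ``covariates``: DataFrame with named columns (may be empty);
    ``mask``: boolean analysis mask (default: voxels nonzero in >=1 patient).
    """

    images: np.ndarray
    behaviour: np.ndarray
    covariates: pd.DataFrame
    mask: np.ndarray | None = None
    voxel_size: float | tuple[float, float, float] = 2.0
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.behaviour = np.asarray(self.behaviour, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("images must be (n_patients, nx, ny, nz)")
        n = self.images.shape[0]
        if len(self.behaviour) != n or len(self.covariates) != n:
            raise ValueError("images, behaviour and covariates disagree on n")
        if self.mask is None:
            self.mask = self.images.any(axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid_shape:
            raise ValueError("mask shape differs from image grid")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.images.shape[1:]

    def voxel_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_patients, n_mask_voxels) matrix of within-mask voxel values."""
        m = self.mask if mask is None else mask
        return self.images[:, m]

    def lesion_volumes(self) -> np.ndarray:
        """Per-patient lesioned voxel count (binary) or abnormality mass."""
        return self.images.reshape(self.n, -1).sum(axis=1)


@dataclass
class StatMap:
    """Voxel-wise statistic and p-value volumes (NaN outside the mask)."""

    statistic: np.ndarray
    p_voxel: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class Cluster:
    voxels: np.ndarray            # (size, 3) integer voxel coordinates
    size: int
    peak_statistic: float
    peak_coordinate: tuple[int, int, int]
    p_fwe: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    null_max_sizes: np.ndarray    # permutation distribution of max cluster size
    meta: dict = field(default_factory=dict)

    def significant(self, cluster_p: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_fwe <= cluster_p]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"size": c.size, "peak_statistic": c.peak_statistic,
              "peak_x": c.peak_coordinate[0], "peak_y": c.peak_coordinate[1],
              "peak_z": c.peak_coordinate[2], "p_fwe": c.p_fwe}
             for c in self.clusters]
        )


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth(image: LesionImage, fwhm_mm: float) -> LesionImage:
    """Gaussian-smooth a lesion image; ``fwhm_mm = 0`` is the identity.

    Sigma per axis is fwhm/(2*sqrt(2 ln 2)) converted from mm to voxels.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if image.voxel_size is None:
        raise ValueError("unknown voxel size")
    if fwhm_mm == 0:
        return image
    out = ndimage.gaussian_filter(image.values, sigma=image.sigma_voxels(fwhm_mm))
    return LesionImage(np.clip(out, 0.0, 1.0), image.voxel_size, image.affine)


def binarize(image: LesionImage, u: float = 0.5) -> LesionImage:
    """Threshold a continuous abnormality image: voxel = 1 iff value > u."""
    out = (image.values > u).astype(float)
    if not out.any():
        logger.warning("binarize: no voxel exceeds u=%g; empty mask", u)
    return LesionImage(out, image.voxel_size, image.affine)


def lesion_volume(image: LesionImage) -> int:
    """Number of lesioned voxels in a binary image."""
    if not image.is_binary:
        raise ValueError("lesion_volume requires a binary image")
    return int(image.values.sum())


# ---------------------------------------------------------------------------
# shared permutation-cluster machinery
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of y on columns of Z. ``y`` is (n,) or (n, m) with
    variables in columns."""
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return y - Z @ beta

def _covariate_matrix(covariates: pd.DataFrame, n: int) -> np.ndarray:
    Z = np.column_stack([np.ones(n)] + [covariates[c].to_numpy(dtype=float)
                                        for c in covariates.columns])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear covariates")
    return Z


def _label_clusters(supra: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    return ndimage.label(supra, structure=structure)


def _extract_clusters(
    stat3d: np.ndarray,
    supra: np.ndarray,
    null_max: np.ndarray,
    connectivity: int,
) -> list[Cluster]:
    labels, n_clusters = _label_clusters(supra, connectivity)
    clusters = []
    n_perm = len(null_max)
    for lab in range(1, n_clusters + 1):
        vox = np.argwhere(labels == lab)
        size = len(vox)
        vals = stat3d[labels == lab]
        peak_i = int(np.argmax(np.abs(vals)))
        p_fwe = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        clusters.append(
            Cluster(voxels=vox, size=size, peak_statistic=float(vals[peak_i]),
                    peak_coordinate=tuple(int(x) for x in vox[peak_i]),
                    p_fwe=float(p_fwe))
        )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def _max_cluster_size(supra: np.ndarray, connectivity: int) -> int:
    labels, n = _label_clusters(supra, connectivity)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _sign_select(stat_flat: np.ndarray, passing: np.ndarray, sign: str) -> np.ndarray:
    if sign == "negative":
        return passing & (stat_flat < 0)
    if sign == "positive":
        return passing & (stat_flat > 0)
    return passing


# ---------------------------------------------------------------------------
# VBCM
# ---------------------------------------------------------------------------

def vbcm(
    data: LesionDataset,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    n_perm: int = 10000,
    connectivity: int = 26,
    cluster_sign: str = "negative",
    control_volume: bool = False,
    seed: int | None = None,
) -> tuple[StatMap, ClusterSet]:
    """Mass-univariate voxel-based correlational mapping.

    At each within-mask voxel, behaviour is regressed on the continuous
    voxel value plus covariates; the voxel coefficient's t statistic is
    stored with a two-tailed analytic p. The sign convention follows the
    damage-deficit direction: negative t means more abnormality goes with
    lower behaviour, and clusters are formed on that sign by default
    (``cluster_sign`` in {"negative", "positive", "both"}).

    Cluster-level FWE comes from the permutation distribution of the maximum
    suprathreshold cluster size under Freedman-Lane permutation of the
    behaviour residuals (covariates respected).
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    covs = data.covariates.copy()
    if control_volume:
        covs = covs.assign(lesion_volume=data.lesion_volumes())
    n = data.n
    n_cov = covs.shape[1]
    if n < n_cov + 3:
        raise ValueError("need at least (number of covariates + 3) patients")
    Z = _covariate_matrix(covs, n)

    mask = data.mask.copy()
    V = data.voxel_matrix(mask)
    var = V.var(axis=0)
    nz = var > 0
    if (~nz).any():
        logger.info("vbcm: excluding %d zero-variance voxel(s)", int((~nz).sum()))
        flat_idx = np.flatnonzero(mask.ravel())[~nz]
        mask = mask.copy().ravel()
        mask[flat_idx] = False
        mask = mask.reshape(data.grid_shape)
        V = V[:, nz]
    if not mask.any():
        raise ValueError("empty analysis mask")

    # Frisch-Waugh-Lovell: residualize both sides on covariates, then the
    # partial correlation t equals the full-model voxel-coefficient t.
    Ry = _residualize(data.behaviour, Z)
    RV = _residualize(V, Z)                           # (n, p)
    df = n - 2 - n_cov
    RVn = RV / np.linalg.norm(RV, axis=0)
    y_std = Ry / np.linalg.norm(Ry)
    r = y_std @ RVn
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df)

    t_crit = stats.t.isf(voxel_p / 2, df)
    # |t| > t_crit is equivalent to |r| > r_crit; thresholding on r avoids
    # transforming the full permutation matrix
    r_crit = t_crit / np.sqrt(df + t_crit**2)
    passing = np.abs(r) > r_crit
    supra_flat = _sign_select(t, passing, cluster_sign)

    # Freedman-Lane: permute behaviour residuals, re-residualize on Z
    E = np.stack([rng.permutation(Ry) for _ in range(n_perm)])   # (n_perm, n)
    E = _residualize(E.T, Z).T
    E /= np.linalg.norm(E, axis=1, keepdims=True)
    R_perm = E.astype(np.float32) @ RVn.astype(np.float32)      # (n_perm, p)
    rc = np.float32(r_crit)
    if cluster_sign == "negative":
        PAS = R_perm < -rc
    elif cluster_sign == "positive":
        PAS = R_perm > rc
    else:
        PAS = (R_perm < -rc) | (R_perm > rc)

    null_max = np.empty(n_perm, dtype=int)
    supra3 = np.zeros(data.grid_shape, dtype=bool)
    for i in range(n_perm):
        supra3[:] = False
        supra3[mask] = PAS[i]
        null_max[i] = _max_cluster_size(supra3, connectivity)

    stat3 = np.full(data.grid_shape, np.nan)
    p3 = np.full(data.grid_shape, np.nan)
    stat3[mask] = t
    p3[mask] = p
    supra3 = np.zeros(data.grid_shape, dtype=bool)
    supra3[mask] = supra_flat

    meta = {"method": "vbcm", "voxel_p": voxel_p, "cluster_p": cluster_p,
            "n_perm": n_perm, "connectivity": connectivity,
            "cluster_sign": cluster_sign, "df": df,
            "control_volume": control_volume}
    stat_map = StatMap(stat3, p3, mask, meta)
    clusters = _extract_clusters(stat3, supra3, null_max, connectivity)
    return stat_map, ClusterSet(clusters, null_max, meta)


def vbcm_multi(
    data: LesionDataset,
    extra_regressors: dict[str, np.ndarray],
    **kwargs,
) -> dict[str, tuple[StatMap, ClusterSet]]:
    """VBCM with several behavioural regressors of interest.

    Each named regressor's unique effect is mapped with all other regressors
    (plus the dataset covariates) treated as nuisance. The dataset behaviour
    vector is included under the name ``"behaviour"``.
    """
    regs = {"behaviour": np.asarray(data.behaviour, dtype=float)}
    for name, v in extra_regressors.items():
        regs[name] = np.asarray(v, dtype=float)
    R = np.column_stack(list(regs.values()))
    if np.linalg.matrix_rank(np.column_stack([np.ones(data.n), R])) < R.shape[1] + 1:
        raise ValueError("collinear regressors of interest")
    out = {}
    for name in regs:
        others = {k: v for k, v in regs.items() if k != name}
        covs = data.covariates.copy()
        for k, v in others.items():
            covs[f"reg_{k}"] = v
        ds = LesionDataset(
            images=data.images, behaviour=regs[name], covariates=covs,
            mask=data.mask, voxel_size=data.voxel_size, affine=data.affine,
        )
        out[name] = vbcm(ds, **kwargs)
    return out


# ---------------------------------------------------------------------------
# SVR-LSM
# ---------------------------------------------------------------------------

def _optimize_svr(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                  n_candidates: int = 20, n_folds: int = 5) -> tuple[float, float]:
    """Seeded random search over log-uniform C and epsilon, 5-fold CV MSE."""
    log_c = rng.uniform(np.log(1e-2), np.log(1e3), n_candidates)
    log_e = rng.uniform(np.log(1e-3), np.log(1.0), n_candidates)
    best, best_mse = (1.0, 0.1), np.inf
    kf = KFold(n_splits=min(n_folds, len(y)), shuffle=True,
               random_state=int(rng.integers(2**31)))
    for C, eps in zip(np.exp(log_c), np.exp(log_e)):
        mse = 0.0
        for tr, te in kf.split(X):
            m = SVR(kernel="linear", C=C, epsilon=eps).fit(X[tr], y[tr])
            mse += float(np.mean((m.predict(X[te]) - y[te]) ** 2))
        if mse < best_mse:
            best_mse, best = mse, (float(C), float(eps))
    return best


def svr_lsm(
    data: LesionDataset,
    lesion_threshold: int = 4,
    voxel_p: float = 0.005,
    cluster_p: float = 0.05,
    n_perm: int = 10000,
    connectivity: int = 26,
    cluster_sign: str = "negative",
    control_volume: bool = False,
    hyperparameters: tuple[float, float] | None = None,
    seed: int | None = None,
) -> tuple[StatMap, ClusterSet]:
    """Multivariate support-vector-regression lesion-symptom mapping.

    Binary lesion voxels lesioned in at least ``lesion_threshold`` patients
    form the feature matrix; behaviour is residualized for the dataset
    covariates before fitting. With ``control_volume``, lesion volume is
    additionally regressed out of every retained voxel column AND out of
    behaviour. An epsilon-SVR with a linear kernel is fit; its
    back-projected weight per voxel is the beta map.

    Hyper-parameters (C, epsilon) are chosen once on the observed data by
    seeded random search with 5-fold cross-validation (log-uniform
    C in [1e-2, 1e3], epsilon in [1e-3, 1]) unless given explicitly; the
    same values are reused in every permutation refit.

    Voxel-wise p values are two-tailed permutation tail probabilities of
    |beta| under behaviour permutations; clusters are formed at ``voxel_p``
    on the deficit-direction sign (negative beta by default) and corrected
    by the permutation max-cluster-size distribution.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives very coarse p-values", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = data.n
    binary = data.images
    if not np.isin(binary, (0.0, 1.0)).all():
        raise ValueError("svr_lsm requires binary lesion images")
    y = np.asarray(data.behaviour, dtype=float)
    if np.var(y) == 0:
        raise ValueError("degenerate behaviour: constant across patients")

    coverage = binary.sum(axis=0)
    feat_mask = (coverage >= lesion_threshold) & data.mask
    p_feat = int(feat_mask.sum())
    if p_feat < 1:
        raise ValueError("empty feature set")
    X = binary[:, feat_mask]                           # (n, p_feat)

    Z = _covariate_matrix(data.covariates, n)
    y = _residualize(y, Z)
    if control_volume:
        vol = data.lesion_volumes()
        Zv = np.column_stack([np.ones(n), vol])
        y = _residualize(y, Zv)
        X = _residualize(X, Zv)

    if hyperparameters is None:
        C, eps = _optimize_svr(X, y, rng)
    else:
        C, eps = hyperparameters

    # linear-kernel fits via the precomputed Gram matrix: solving in the dual
    # costs O(n^2) per permutation instead of O(n^2 p); the weight map is
    # back-projected from the support vectors afterwards
    G = X @ X.T

    def _fit_beta(target: np.ndarray) -> np.ndarray:
        m = SVR(kernel="precomputed", C=C, epsilon=eps).fit(G, target)
        return (m.dual_coef_ @ X[m.support_]).ravel()

    beta = _fit_beta(y).astype(float)
    # each weight map is normalized to unit L2 norm before the voxel-wise
    # comparison: the permutation test then asks where weight *concentrates*,
    # not how large the map is overall (overall magnitude varies with the
    # permuted target and carries no spatial information)
    def _unit(w: np.ndarray) -> np.ndarray:
        nrm = np.linalg.norm(w)
        return w / nrm if nrm > 0 else w

    beta_n = _unit(beta)
    W = np.empty((n_perm, p_feat), dtype=np.float32)
    for i in range(n_perm):
        W[i] = _unit(_fit_beta(rng.permutation(y)))

    absW = np.abs(W)
    p_vox = (1 + (absW >= np.abs(beta_n)).sum(axis=0)) / (n_perm + 1)
    # per-voxel threshold at the voxel_p tail of the permutation null,
    # used consistently for the observed map and every permutation map
    thresh = np.quantile(absW, 1 - voxel_p, axis=0)
    passing = np.abs(beta_n) > thresh
    supra_flat = _sign_select(beta, passing, cluster_sign)

    null_max = np.empty(n_perm, dtype=int)
    supra3 = np.zeros(data.grid_shape, dtype=bool)
    for i in range(n_perm):
        pas = _sign_select(W[i], absW[i] > thresh, cluster_sign)
        supra3[:] = False
        supra3[feat_mask] = pas
        null_max[i] = _max_cluster_size(supra3, connectivity)

    stat3 = np.full(data.grid_shape, np.nan)
    p3 = np.full(data.grid_shape, np.nan)
    stat3[feat_mask] = beta
    p3[feat_mask] = p_vox
    supra3 = np.zeros(data.grid_shape, dtype=bool)
    supra3[feat_mask] = supra_flat

    meta = {"method": "svr_lsm", "voxel_p": voxel_p, "cluster_p": cluster_p,
            "n_perm": n_perm, "connectivity": connectivity,
            "cluster_sign": cluster_sign, "lesion_threshold": lesion_threshold,
            "C": C, "epsilon": eps, "control_volume": control_volume,
            "n_features": p_feat}
    stat_map = StatMap(stat3, p3, feat_mask, meta)
    clusters = _extract_clusters(stat3, supra3, null_max, connectivity)
    return stat_map, ClusterSet(clusters, null_max, meta)
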