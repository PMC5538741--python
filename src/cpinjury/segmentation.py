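"""EM/MRF tissue segmentation with explicit lesion classes.

A bivariate (T1, T2) Gaussian mixture with spatially varying tissue priors
is fitted by expectation-maximisation; spatial coherence is imposed by a
mean-field Potts smoothing of the posteriors (6-neighbourhood, coupling
``beta``) folded into each E-step.  Lesions are handled as-outliers: two
extra mixture components are seeded at the T2-hyperintense tail of white
matter and the outlier tail of grey matter, each with a small uniform
spatial prior inside its parent tissue's support, so that voxels poorly
explained by healthy tissue migrate into a lesion class during EM.

The estimator follows scikit-learn conventions (constructor parameters,
``fit``, fitted attributes with a trailing underscore) but consumes image
volumes rather than tabular data, in the manner of image maskers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .phantom import GroundTruth
from .preprocess import BrainMask
from .volume import ImageVolume, Label, RegionAtlas, RegionClass

__all__ = [
    "EMMRFSegmenter",
    "SegmentationResult",
    "make_tissue_priors",
    "fit_em_mrf",
    "detect_lesions",
    "regional_lesion_volumes",
    "TISSUE_CLASSES",
    "LESION_CLASSES",
]

TISSUE_CLASSES = ("CSF", "GM", "WM")
LESION_CLASSES = ("WM-lesion", "GM-lesion")
PARENT_OF = {"WM-lesion": "WM", "GM-lesion": "GM"}


@dataclass
class SegmentationResult:
    """Per-class posterior maps plus the argmax hard labelling."""

    class_names: tuple[str, ...]
    posteriors: np.ndarray  # (K, nx, ny, nz) float32, zero outside mask
    mask: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def hard_labels(self) -> np.ndarray:
        """Argmax class index per in-mask voxel; -1 outside the mask."""
        lab = np.argmax(self.posteriors, axis=0).astype(np.int16)
        lab[~self.mask] = -1
        return lab

    def class_mask(self, name: str) -> np.ndarray:
        """Hard-label mask for a class; all-false if the class is absent."""
        if name not in self.class_names:
            return np.zeros(self.mask.shape, dtype=bool)
        k = self.class_names.index(name)
        return (self.hard_labels == k) & self.mask

    def posterior(self, name: str) -> np.ndarray:
        return self.posteriors[self.class_names.index(name)]


def make_tissue_priors(
    base: GroundTruth, fwhm_mm: float = 4.0, ventricle_halo_mm: float = 10.0
) -> dict[str, np.ndarray]:
    """Tissue probability maps from a control anatomy.

    Binary tissue masks (ventricles folded into CSF) are Gaussian-smoothed
    and renormalised, emulating atlas tissue probability maps registered to
    the subject.  CSF keeps a moderate prior inside a halo around the
    ventricles so that pathological ventricular enlargement into
    periventricular white matter can be claimed by the CSF class — the
    accommodation a segmentation tailored to severe injury needs.
    """
    sigma_vox = fwhm_mm / 2.355 / np.asarray(base.spacing)
    masks = {
        "CSF": base.tissue_mask(Label.CSF, Label.VENTRICLE),
        "GM": base.tissue_mask(Label.GM),
        "WM": base.tissue_mask(Label.WM),
    }
    priors = {
        name: ndimage.gaussian_filter(m.astype(np.float32), sigma_vox)
        for name, m in masks.items()
    }
    if ventricle_halo_mm > 0:
        vent = base.tissue_mask(Label.VENTRICLE)
        if vent.any():
            halo = ndimage.distance_transform_edt(~vent, sampling=base.spacing) <= ventricle_halo_mm
            priors["CSF"] = np.maximum(priors["CSF"], np.where(halo, 0.15, 0.0)).astype(np.float32)
    total = sum(priors.values())
    floor = 1e-4  # a small floor keeps all classes reachable everywhere
    for name in priors:
        priors[name] = (priors[name] + floor) / (total + len(priors) * floor)
    return priors


def _log_gauss2(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log-density of a bivariate (or univariate) Gaussian, closed form."""
    d = x.shape[1]
    diff = x - mean
    if d == 1:
        var = cov[0, 0]
        return -0.5 * (np.log(2 * np.pi * var) + diff[:, 0] ** 2 / var)
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    inv00, inv11 = cov[1, 1] / det, cov[0, 0] / det
    inv01 = -cov[0, 1] / det
    q = (
        inv00 * diff[:, 0] ** 2
        + 2 * inv01 * diff[:, 0] * diff[:, 1]
        + inv11 * diff[:, 1] ** 2
    )
    return -0.5 * (d * np.log(2 * np.pi) + np.log(det) + q)


def _regularize_cov(cov: np.ndarray, ridge: float, scale: float = 1.0) -> np.ndarray:
    """Ensure a well-conditioned covariance; the floor is tied to the
    global intensity scale so collapsed components cannot produce
    degenerate likelihoods."""
    tr = np.trace(cov)
    floor = max(ridge * tr, 1e-6 * scale)
    try:
        np.linalg.cholesky(cov)
        ok = np.linalg.cond(cov) < 1e8
    except np.linalg.LinAlgError:
        ok = False
    if not ok:
        warnings.warn("singular class covariance: applying ridge regularisation")
        cov = cov + np.eye(cov.shape[0]) * floor
    return cov


class EMMRFSegmenter(BaseEstimator):
    """EM/MRF mixture segmentation with optional lesion-as-outlier classes.

    Parameters
    ----------
    beta : MRF coupling of the mean-field Potts smoothing; 0 disables it.
    max_iter, tol : EM stopping rule (mean absolute posterior change).
    lesion_classes : add WM-lesion and GM-lesion outlier components.
    lesion_prior_eps : uniform spatial prior mass given to each lesion
        class inside its parent tissue's support.
    min_lesion_voxels : lesion components claiming fewer voxels are
        dissolved back into the parent tissue.
    mahalanobis_threshold : distance beyond which in-tissue voxels are
        flagged as unexplained outliers (diagnostic flag only).

    Attributes (after fit)
    ----------------------
    means_, covariances_ : per-class intensity model.
    result_ : the :class:`SegmentationResult`.
    converged_, n_iter_, loglik_path_ : convergence log.
    bivariate_ : whether both modalities were available.
    """

    def __init__(
        self,
        beta: float = 0.5,
        max_iter: int = 50,
        tol: float = 1e-4,
        lesion_classes: bool = True,
        lesion_prior_eps: float = 0.02,
        min_lesion_voxels: int = 5,
        ridge: float = 1e-6,
        mahalanobis_threshold: float = 3.0,
    ):
        self.beta = beta
        self.max_iter = max_iter
        self.tol = tol
        self.lesion_classes = lesion_classes
        self.lesion_prior_eps = lesion_prior_eps
        self.min_lesion_voxels = min_lesion_voxels
        self.ridge = ridge
        self.mahalanobis_threshold = mahalanobis_threshold

    # ------------------------------------------------------------------
    def fit(
        self,
        t1: ImageVolume,
        t2: ImageVolume | None,
        mask: BrainMask,
        priors: dict[str, np.ndarray],
    ) -> "EMMRFSegmenter":
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        m = np.asarray(mask.data, dtype=bool)
        if not m.any():
            raise ValueError("empty mask")
        missing = [c for c in TISSUE_CLASSES if c not in priors]
        if missing:
            raise ValueError(f"priors missing tissue classes {missing}")

        self.bivariate_ = t2 is not None
        channels = [np.asarray(t1.data, dtype=np.float64)[m]]
        if self.bivariate_:
            if not t1.same_grid(t2):
                raise ValueError("T1 and T2 must share a grid")
            channels.append(np.asarray(t2.data, dtype=np.float64)[m])
        x = np.stack(channels, axis=1)
        self._scale = float(np.var(x))  # global intensity scale for cov floors

        names = list(TISSUE_CLASSES)
        prior_mask = np.stack([priors[c][m] for c in TISSUE_CLASSES]).astype(np.float64)
        prior_mask /= prior_mask.sum(axis=0, keepdims=True)

        # initial healthy-tissue moments from the priors
        means, covs = [], []
        for k, name in enumerate(TISSUE_CLASSES):
            w = prior_mask[k]
            mu = (w[:, None] * x).sum(0) / w.sum()
            diff = x - mu
            cov = (w[:, None, None] * (diff[:, :, None] * diff[:, None, :])).sum(0) / w.sum()
            means.append(mu)
            covs.append(_regularize_cov(cov, self.ridge, self._scale))
        means = np.stack(means)
        covs = np.stack(covs)

        # phase 1: healthy tissues only
        q, means, covs, loglik_path, converged, n_iter = self._em_loop(
            x, m, prior_mask, means, covs, self.max_iter, frozen=()
        )

        if self.lesion_classes:
            # phase 2: seed lesion components at the outlier tail of each
            # parent tissue (T2-hyperintense for WM) and let EM refine them
            prior_mask, means, covs, names, seeds = self._add_lesion_components(
                x, q, prior_mask, means, covs, names
            )
            if seeds:
                q2, means, covs, path2, conv2, it2 = self._em_loop(
                    x, m, prior_mask, means, covs, max(self.max_iter // 3, 10),
                    frozen=(),
                )
                q, loglik_path = q2, loglik_path + path2
                converged, n_iter = conv2, n_iter + it2
            else:  # no outliers anywhere: lesion classes stay empty
                q = np.concatenate([q, np.zeros((2, q.shape[1]))], axis=0)

        if not converged:
            warnings.warn(f"EM did not converge in {self.max_iter} iterations")

        # dissolve tiny lesion components into their parents
        K = len(names)
        hard = np.argmax(q, axis=0)
        if self.lesion_classes:
            for lname in LESION_CLASSES:
                k = names.index(lname)
                if int((hard == k).sum()) < self.min_lesion_voxels:
                    pk = names.index(PARENT_OF[lname])
                    q[pk] += q[k]
                    q[k] = 0.0

        post_full = np.zeros((K,) + m.shape, dtype=np.float32)
        for k in range(K):
            post_full[k][m] = q[k]

        self.class_names_ = tuple(names)
        self.means_ = means
        self.covariances_ = covs
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.loglik_path_ = loglik_path
        self.result_ = SegmentationResult(
            class_names=tuple(names),
            posteriors=post_full,
            mask=m,
            spacing=t1.spacing,
        )
        self.outlier_flag_ = self._mahalanobis_flag(x, m)
        return self

    def _em_loop(self, x, m, prior_mask, means, covs, max_iter, frozen=()):
        """Mean-field EM iterations; returns posteriors and updated moments."""
        K = prior_mask.shape[0]
        q = prior_mask.copy()
        struct = ndimage.generate_binary_structure(3, 1).astype(np.float32)
        struct[1, 1, 1] = 0.0
        loglik_path = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # E-step with mean-field MRF prior adjustment
            log_prior = np.log(np.maximum(prior_mask, 1e-30))
            if self.beta > 0:
                neigh = np.empty_like(q)
                for k in range(K):
                    full = np.zeros(m.shape, dtype=np.float32)
                    full[m] = q[k]
                    conv = ndimage.correlate(full, struct, mode="constant")
                    neigh[k] = conv[m]
                log_prior = log_prior + self.beta * neigh
            log_like = np.stack([_log_gauss2(x, means[k], covs[k]) for k in range(K)])
            log_post = log_prior + log_like
            top = log_post.max(axis=0, keepdims=True)
            post = np.exp(log_post - top)
            norm = post.sum(axis=0, keepdims=True)
            # observed-data mixture log-likelihood: the quantity EM is
            # guaranteed to not decrease at beta=0 (pseudo-likelihood when
            # the MRF term is active)
            loglik_path.append(float((top + np.log(norm)).sum()))
            post /= norm
            delta = float(np.mean(np.abs(post - q)))
            q = post

            # M-step
            for k in range(K):
                if k in frozen:
                    continue
                w = q[k]
                sw = w.sum()
                if sw < 1e-9:
                    continue
                mu = (w[:, None] * x).sum(0) / sw
                diff = x - mu
                cov = (w[:, None, None] * (diff[:, :, None] * diff[:, None, :])).sum(0) / sw
                means[k] = mu
                covs[k] = _regularize_cov(cov, self.ridge, self._scale)

            if delta < self.tol:
                converged = True
                break
        return q, means, covs, loglik_path, converged, n_iter

    def _add_lesion_components(self, x, q, prior_mask, means, covs, names):
        """Append outlier-seeded lesion components to the converged model.

        Candidate voxels lie in the parent tissue's prior support but are
        Mahalanobis outliers to every healthy class; WM lesions must
        additionally be T2-hyperintense relative to WM (the tail the
        component is meant to capture).  Components are seeded from the
        candidates' own moments, falling back to the parent mean + 2 sd on
        the last channel when no candidates exist.
        """
        d2 = []
        for k in range(len(TISSUE_CLASSES)):
            diff = x - means[k]
            inv = np.linalg.inv(covs[k])
            d2.append(np.einsum("ni,ij,nj->n", diff, inv, diff))
        outlier = np.min(d2, axis=0) > self.mahalanobis_threshold**2

        names = list(names)
        eps = self.lesion_prior_eps
        seeds = []
        new_means = list(means)
        new_covs = list(covs)
        for lname in LESION_CLASSES:
            parent = PARENT_OF[lname]
            pk = TISSUE_CLASSES.index(parent)
            # gate on the parent-tissue core: voxels near tissue borders
            # (mixed priors, interface blur) are outliers to every class
            # but are not lesions
            # support (and candidate) region is the parent-tissue core:
            # interface shells blurred toward other tissues stay excluded;
            # the threshold adapts to thin structures whose smoothed prior
            # never reaches the nominal core level
            core_level = min(0.8, 0.9 * float(prior_mask[pk].max()))
            support = prior_mask[pk] > core_level
            cand = outlier & support
            if x.shape[1] > 1:
                sd_t2 = np.sqrt(covs[pk][-1, -1])
                cand = cand & (x[:, -1] > means[pk][-1] + 2.0 * sd_t2)  # T2 tail
            lp = np.where(support, eps, 0.0)
            prior_mask[pk] = np.where(support, prior_mask[pk] * (1 - eps), prior_mask[pk])
            prior_mask = np.concatenate([prior_mask, lp[None]], axis=0)
            names.append(lname)
            if int(cand.sum()) >= self.min_lesion_voxels:
                xc = x[cand]
                mu = xc.mean(axis=0)
                diff = xc - mu
                cov = diff.T @ diff / len(xc)
                seeds.append(lname)
            else:
                mu = means[pk].copy()
                sd = np.sqrt(np.diag(covs[pk]))
                mu[-1] = mu[-1] + 2.0 * sd[-1]
                cov = covs[pk].copy()
            new_means.append(mu)
            new_covs.append(_regularize_cov(np.atleast_2d(cov), self.ridge, self._scale))
        prior_mask /= prior_mask.sum(axis=0, keepdims=True)
        return prior_mask, np.stack(new_means), np.stack(new_covs), names, seeds

    def _mahalanobis_flag(self, x: np.ndarray, m: np.ndarray) -> np.ndarray:
        """Voxels farther than the threshold from every healthy tissue."""
        d2 = []
        for name in TISSUE_CLASSES:
            k = self.class_names_.index(name)
            cov = self.covariances_[k]
            diff = x - self.means_[k]
            inv = np.linalg.inv(cov)
            d2.append(np.einsum("ni,ij,nj->n", diff, inv, diff))
        flag = np.min(d2, axis=0) > self.mahalanobis_threshold**2
        out = np.zeros(m.shape, dtype=bool)
        out[m] = flag
        return out


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_em_mrf(
    t1: ImageVolume,
    t2: ImageVolume | None,
    mask: BrainMask,
    priors: dict[str, np.ndarray],
    beta: float = 0.5,
    max_iter: int = 50,
    **kwargs,
) -> tuple[EMMRFSegmenter, SegmentationResult]:
    """Fit the EM/MRF mixture; returns the fitted model and its result."""
    model = EMMRFSegmenter(beta=beta, max_iter=max_iter, **kwargs).fit(t1, t2, mask, priors)
    return model, model.result_


def detect_lesions(model: EMMRFSegmenter) -> dict[str, np.ndarray]:
    """Final lesion masks: voxels whose argmax posterior is a lesion class."""
    res = model.result_
    out = {}
    for lname in LESION_CLASSES:
        if lname in res.class_names:
            out[lname] = res.class_mask(lname)
        else:
            out[lname] = np.zeros(res.mask.shape, dtype=bool)
    return out


def regional_lesion_volumes(
    lesion_masks: dict[str, np.ndarray],
    atlas: RegionAtlas,
    spacing: tuple[float, float, float],
) -> pd.DataFrame:
    """Per-region lesion volumes in mL.

    GM-lesion volumes are reported against cortical and deep-grey regions,
    WM-lesion volumes against white-matter regions; lesion voxels falling
    on other atlas labels are reported under region 0 so per-region volumes
    always sum exactly to the total lesion volume.
    """
    for mask in lesion_masks.values():
        if mask.shape != atlas.labels.shape:
            raise ValueError("lesion mask and atlas grids differ")
    vox_ml = float(np.prod(spacing)) / 1000.0
    allowed = {
        "GM-lesion": set(atlas.ids_of_class(RegionClass.CORTICAL))
        | set(atlas.ids_of_class(RegionClass.DEEP_GREY)),
        "WM-lesion": set(atlas.ids_of_class(RegionClass.WHITE_MATTER)),
    }
    rows = []
    for lname, mask in lesion_masks.items():
        if not mask.any():
            continue
        ids, counts = np.unique(atlas.labels[mask], return_counts=True)
        keep = allowed.get(lname, set())
        for rid, n in zip(ids, counts):
            rid = int(rid) if int(rid) in keep else 0
            rows.append((rid, lname, float(n) * vox_ml))
    df = pd.DataFrame(rows, columns=["region_id", "lesion_class", "volume_mL"])
    if df.empty:
        return df.astype({"region_id": int, "lesion_class": str, "volume_mL": float})
    return df.groupby(["region_id", "lesion_class"], as_index=False)["volume_mL"].sum()
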