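"""Behavioral partial least squares correlation (PLSC).

Singular value decomposition of the cross-block covariance between a
z-scored imaging block X (subjects x features) and behavioral block Y
(subjects x measures):

    R = Yz' Xz = U  diag(s)  V'

Left singular vectors are behavioral saliences, right singular vectors
imaging saliences.  Component significance is assessed by permuting the
rows of Y (add-one permutation p-values); feature stability by bootstrap
salience / SE ratios (BSR) thresholded at |BSR| >= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import DegenerateModelError, ValidationError


@dataclass(frozen=True)
class CohortMatrices:
    """Paired imaging / behavioral blocks with group labels."""

    X: np.ndarray
    Y: np.ndarray
    subject_ids: tuple[str, ...]
    group: tuple[str, ...]
    feature_names: tuple[str, ...]
    measure_names: tuple[str, ...]
    # planted ground truth, populated by the synthetic generator only
    latent: np.ndarray | None = None
    salience_img: np.ndarray | None = None
    salience_beh: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValidationError("X and Y must be 2-D matrices")
        if X.shape[0] != Y.shape[0]:
            raise ValidationError(
                f"X and Y must share the subject dimension "
                f"({X.shape[0]} vs {Y.shape[0]})")
        n = X.shape[0]
        for name, seq, expect in (
                ("subject_ids", self.subject_ids, n),
                ("group", self.group, n),
                ("feature_names", self.feature_names, X.shape[1]),
                ("measure_names", self.measure_names, Y.shape[1])):
            if len(seq) != expect:
                raise ValidationError(f"{name} must have length {expect}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class PLSCModel:
    """Decomposition of the cross-block covariance plus inference results.

    U: measures x components (behavioral saliences), V: features x
    components (imaging saliences), unit-norm columns; singular values
    non-increasing; cov_explained sums to 1.
    """

    U: np.ndarray
    V: np.ndarray
    singular_values: np.ndarray
    cov_explained: np.ndarray
    perm_p: np.ndarray | None = None
    bsr_img: np.ndarray | None = None
    bsr_beh: np.ndarray | None = None
    stable_img: np.ndarray | None = None
    stable_beh: np.ndarray | None = None
    bsr_threshold: float | None = None
    loadings_img: np.ndarray | None = None
    loadings_beh: np.ndarray | None = None
    scores_img: np.ndarray | None = None
    scores_beh: np.ndarray | None = None
    n_boot_redrawn: int = 0

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def to_dict(self) -> dict:
        """JSON-serializable summary of every populated field."""
        def conv(value):
            if value is None:
                return None
            arr = np.asarray(value)
            return arr.tolist()

        return {
            "singular_values": conv(self.singular_values),
            "cov_explained": conv(self.cov_explained),
            "behavioral_saliences": conv(self.U),
            "imaging_saliences": conv(self.V),
            "perm_p": conv(self.perm_p),
            "bsr_img": conv(self.bsr_img),
            "bsr_beh": conv(self.bsr_beh),
            "stable_img": conv(self.stable_img),
            "stable_beh": conv(self.stable_beh),
            "bsr_threshold": self.bsr_threshold,
            "loadings_img": conv(self.loadings_img),
            "loadings_beh": conv(self.loadings_beh),
            "n_boot_redrawn": self.n_boot_redrawn,
        }


def preprocess(X: np.ndarray, Y: np.ndarray,
               block_names: tuple[str, ...] | None = None,
               measure_names: tuple[str, ...] | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise z-scoring (mean 0, sample SD 1) of both blocks."""
    Xz = _zscore_block(np.asarray(X, dtype=float), block_names, "X")
    Yz = _zscore_block(np.asarray(Y, dtype=float), measure_names, "Y")
    if Xz.shape[0] != Yz.shape[0]:
        raise ValidationError("X and Y must share the subject dimension")
    return Xz, Yz


def _zscore_block(M: np.ndarray, names, block: str) -> np.ndarray:
    if M.ndim != 2:
        raise ValidationError(f"{block} must be 2-D")
    if M.shape[0] < 3:
        raise ValidationError("need at least 3 subjects to standardize")
    if not np.all(np.isfinite(M)):
        raise ValidationError(f"{block} contains missing/non-finite values")
    sd = M.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = ([names[j] for j in bad] if names is not None
                  else bad.tolist())
        raise ValidationError(f"constant column(s) in {block}: {labels}")
    return (M - M.mean(axis=0)) / sd


def _apply_sign_convention(U: np.ndarray, V: np.ndarray):
    # flip each component so the largest-|entry| of its V column is positive
    for comp in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, comp])))
        if V[j, comp] < 0:
            V[:, comp] *= -1
            U[:, comp] *= -1
    return U, V


def fit_plsc(Xz: np.ndarray, Yz: np.ndarray) -> PLSCModel:
    """SVD of R = Yz' Xz with a deterministic sign convention."""
    R = Yz.T @ Xz
    if not np.any(R):
        raise DegenerateModelError("cross-block covariance is identically 0")
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    U, V = _apply_sign_convention(U.copy(), V.copy())
    total = float(np.sum(s**2))
    return PLSCModel(U=U, V=V, singular_values=s,
                     cov_explained=s**2 / total)


def permutation_test(Xz: np.ndarray, Y: np.ndarray, n_perm: int = 1000,
                     seed: int | None = None) -> np.ndarray:
    """Permutation p-value per component.

    Rows of Y are shuffled relative to Xz; the permuted block is
    re-standardized and refit, and p_l = (1 + #{s_perm_l >= s_obs_l}) /
    (1 + n_perm).
    """
    if n_perm < 100:
        raise ValidationError("n_perm < 100 gives unstable p-values")
    Y = np.asarray(Y, dtype=float)
    Yz = _zscore_block(Y, None, "Y")
    observed = fit_plsc(Xz, Yz).singular_values
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    n = Y.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yzp = _zscore_block(Y[perm], None, "Y")
        s_perm = np.linalg.svd(Yzp.T @ Xz, compute_uv=False)
        exceed += s_perm >= observed
    return (1.0 + exceed) / (1.0 + n_perm)


def bootstrap_stability(X: np.ndarray, Y: np.ndarray, n_boot: int = 500,
                        seed: int | None = None, threshold: float = 2.0
                        ) -> dict:
    """Bootstrap stability ratios for every salience element.

    Subjects are resampled with replacement; each resample is
    re-standardized and refit, components are sign-aligned to the original
    saliences, and BSR = original salience / bootstrap SE.  Resamples that
    produce a constant column are redrawn (counted).
    """
    if n_boot < 100:
        raise ValidationError("n_boot < 100 gives unstable ratios")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xz, Yz = preprocess(X, Y)
    model = fit_plsc(Xz, Yz)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    boot_U = np.empty((n_boot,) + model.U.shape)
    boot_V = np.empty((n_boot,) + model.V.shape)
    redrawn = 0
    for b in range(n_boot):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            try:
                Xb, Yb = preprocess(X[idx], Y[idx])
            except ValidationError:
                redrawn += 1
                continue
            break
        else:
            raise ValidationError(
                "could not draw a non-degenerate bootstrap resample")
        mb = fit_plsc(Xb, Yb)
        signs = np.sign(np.sum(model.V * mb.V, axis=0))
        signs[signs == 0] = 1.0
        boot_U[b] = mb.U * signs
        boot_V[b] = mb.V * signs
    if redrawn:
        warnings.warn(f"redrew {redrawn} degenerate bootstrap resamples",
                      RuntimeWarning, stacklevel=2)
    se_U = boot_U.std(axis=0, ddof=1)
    se_V = boot_V.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr_beh = np.where(se_U > 0, model.U / se_U, np.inf * np.sign(model.U))
        bsr_img = np.where(se_V > 0, model.V / se_V, np.inf * np.sign(model.V))
    return {
        "bsr_img": bsr_img,
        "bsr_beh": bsr_beh,
        "stable_img": np.abs(bsr_img) >= threshold,
        "stable_beh": np.abs(bsr_beh) >= threshold,
        "n_redrawn": redrawn,
    }


def scores_and_loadings(model: PLSCModel, Xz: np.ndarray, Yz: np.ndarray,
                        X_raw: np.ndarray, Y_raw: np.ndarray) -> PLSCModel:
    """Composite scores (projections on the saliences) and loadings
    (correlation of each raw column with its composite score)."""
    scores_img = Xz @ model.V
    scores_beh = Yz @ model.U
    loadings_img = _column_correlations(np.asarray(X_raw, float), scores_img)
    loadings_beh = _column_correlations(np.asarray(Y_raw, float), scores_beh)
    return replace(model, scores_img=scores_img, scores_beh=scores_beh,
                   loadings_img=loadings_img, loadings_beh=loadings_beh)


def _column_correlations(M: np.ndarray, scores: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    denom = np.outer(np.sqrt(np.sum(Mc**2, axis=0)),
                     np.sqrt(np.sum(Sc**2, axis=0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (Mc.T @ Sc) / denom
    return np.clip(corr, -1.0, 1.0)


def plsc_analysis(cohort: CohortMatrices, n_perm: int = 1000,
                  n_boot: int = 500, seed: int | None = None,
                  bsr_threshold: float = 2.0) -> PLSCModel:
    """Full behavioral PLSC: decomposition, permutation p-values,
    bootstrap stability, scores and loadings, pooling all subjects."""
    root = np.random.SeedSequence(seed)
    perm_seed, boot_seed = root.spawn(2)
    Xz, Yz = preprocess(cohort.X, cohort.Y, cohort.feature_names,
                        cohort.measure_names)
    model = fit_plsc(Xz, Yz)
    perm_p = permutation_test(Xz, cohort.Y, n_perm=n_perm, seed=perm_seed)
    boot = bootstrap_stability(cohort.X, cohort.Y, n_boot=n_boot,
                               seed=boot_seed, threshold=bsr_threshold)
    model = replace(model, perm_p=perm_p, bsr_img=boot["bsr_img"],
                    bsr_beh=boot["bsr_beh"], stable_img=boot["stable_img"],
                    stable_beh=boot["stable_beh"],
                    bsr_threshold=bsr_threshold,
                    n_boot_redrawn=boot["n_redrawn"])
    return scores_and_loadings(model, Xz, Yz, cohort.X, cohort.Y)
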