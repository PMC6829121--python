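"""Prediction-accuracy estimators and their predictands.

True accuracy is the Pearson correlation between a prediction and the
simulated genetic values. In real data the truth is unavailable, so accuracy
must be estimated against a proxy predictand; this module implements the
estimators compared in this package:

* naive: correlation with the test lines' own focal phenotypes ``y_n1``,
  rescaled by 1/h to undo the extra residual variance of phenotypes. For
  CV2-style predictors this estimator is biased whenever the traits share
  residual covariance, because the secondary phenotype used for prediction
  and the focal phenotype used for validation carry correlated residuals.
* full-data EBV predictand: BLUPs from a fit to the complete data, kept here
  to demonstrate that reusing training data in the predictand grossly
  inflates estimated accuracy.
* parametric: selection-index theory; refit the bivariate model to
  (prediction, phenotype) on the validation lines only and report the
  genetic correlation times the index's accuracy scaling sqrt(h2_I).
* semi-parametric: subtract an analytic estimate of the residual-covariance
  bias from the naive correlation before rescaling.
* CV2*: validate against focal phenotypes of clones or nearest relatives of
  the test lines, severing the shared-residual channel entirely.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .mixedmodel import BivariateFit, fit_bivariate_reml
from .relatedness import GRM, ConditionalBlocks, Partition

logger = logging.getLogger(__name__)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        logger.warning("zero variance input; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _h_factor(h1_sq: float, correction: str = "h") -> float:
    """The 1/h (default) or 1/h^2 rescaling of phenotype-validated correlations."""
    if not 0.0 < h1_sq <= 1.0:
        raise ValueError("h1_sq must be in (0, 1]")
    if correction == "h":
        return math.sqrt(h1_sq)
    if correction == "h2":
        return h1_sq
    raise ValueError(f"unknown correction {correction!r}")


def true_accuracy(u_hat: np.ndarray, u_true: np.ndarray) -> float:
    """Pearson correlation between predictions and true genetic values."""
    return _pearson(u_hat, u_true)


def naive_accuracy(u_hat: np.ndarray, y_n1: np.ndarray, h1_sq: float,
                   correction: str = "h") -> float:
    """Phenotype-validated accuracy, ``cor(u_hat, y_n1) / sqrt(h1_sq)``.

    Under the model ``cor(u_hat, y) = cor(u_hat, u) * h``, so dividing by
    ``h = sqrt(h1_sq)`` puts the estimate on the genetic-accuracy scale (the
    corrected value may exceed 1). The same factor must be applied to every
    method being compared.
    """
    return _pearson(u_hat, y_n1) / _h_factor(h1_sq, correction)


def full_data_ebv_predictand(Y_all: np.ndarray, grm: GRM,
                             partition: Partition | None = None) -> np.ndarray:
    """Focal-trait BLUPs from a bivariate fit to the COMPLETE data.

    Validating against these estimated genetic values reuses the training
    phenotypes inside the predictand and dramatically overestimates accuracy;
    the function exists so that failure mode can be demonstrated and tested,
    not for actual model evaluation.
    """
    fit = fit_bivariate_reml(np.asarray(Y_all, dtype=float), grm.values)
    u_tilde = fit.u_hat_o[:, 0]
    if partition is None:
        return u_tilde
    return u_tilde[grm.index_of(partition.test_ids)]


def parametric_accuracy(u_hat: np.ndarray, y_n1: np.ndarray, K_nn: np.ndarray,
                        eig: tuple[np.ndarray, np.ndarray] | None = None,
                        correction: str = "h_index") -> float:
    """Selection-index accuracy estimate from validation-partition data only.

    Treats the prediction as an index I and fits the bivariate model to
    (I, y) on the validation lines with their GRM block; the accuracy of an
    index is its genetic correlation with the target times sqrt of the index
    heritability (``correction="h2_index"`` multiplies by h2_I instead).
    Returns NaN when the validation fit fails.
    """
    u_hat = np.asarray(u_hat, dtype=float)
    y_n1 = np.asarray(y_n1, dtype=float)
    if np.var(u_hat) == 0 or np.var(y_n1) == 0:
        return float("nan")
    try:
        fit = fit_bivariate_reml(np.column_stack([u_hat, y_n1]), K_nn, eig=eig)
    except Exception as e:  # noqa: BLE001 - any fit failure is a missing value
        logger.warning("parametric validation fit failed: %s", e)
        return float("nan")
    if not fit.converged:
        logger.warning("parametric validation fit did not converge")
        return float("nan")
    g, r = fit.G_hat, fit.R_hat
    var_i = g[0, 0] + r[0, 0]
    if g[0, 0] <= 1e-8 * var_i or g[1, 1] <= 1e-12:
        return 0.0  # index carries no detectable genetic signal
    rho_g = g[0, 1] / math.sqrt(g[0, 0] * g[1, 1])
    rho_g = float(np.clip(rho_g, -1.0, 1.0))
    h2_i = g[0, 0] / var_i
    scale = math.sqrt(h2_i) if correction == "h_index" else h2_i
    return rho_g * scale


@dataclass(frozen=True)
class BiasCorrection:
    """Analytic bias of the naive estimator for a CV2-style predictor.

    ``bias_cov`` is the expected excess of the sample covariance between the
    CV2 prediction and ``y_n1`` caused by residual covariance between traits:
    ``g12 * r12 * tr(S Sc Vc^-1) / (n - 1)`` with centering
    ``S = I - 11'/n``. ``bias_hat`` is the same quantity on the correlation
    scale (divided by the sample standard deviations). Zero exactly when
    either ``g12`` or ``r12`` is zero.
    """

    bias_hat: float
    bias_cov: float
    g12: float
    r12: float
    trace_term: float
    var_u_hat: float
    var_y: float
    n: int


def semiparametric_bias(fit: BivariateFit, blocks: ConditionalBlocks,
                        u_hat3: np.ndarray, y_n1: np.ndarray) -> BiasCorrection:
    """Estimate the residual-covariance bias of ``cor(u_hat3, y_n1)``.

    The CV2 predictor's second term regresses on ``y_n2``, whose residual
    covaries with the validation residual ``e_n1`` (covariance ``r12`` per
    line). Propagating that through the predictor gives the cross-covariance
    ``g12 * r12 * Sc Vc^-1``; centering and averaging yields ``bias_cov``
    above. Components are taken from the training fit (true matrices may be
    supplied via a fixed-component fit for oracle use).
    """
    u_hat3 = np.asarray(u_hat3, dtype=float)
    y_n1 = np.asarray(y_n1, dtype=float)
    n = u_hat3.size
    if n < 3 or y_n1.size != n:
        raise ValueError("need matching vectors of length >= 3")
    g12 = float(fit.G_hat[0, 1])
    r12 = float(fit.R_hat[0, 1])
    g22 = float(fit.G_hat[1, 1])
    r22 = float(fit.R_hat[1, 1])
    Sc = blocks.schur
    Vc = g22 * Sc + r22 * np.eye(n)
    Vc = 0.5 * (Vc + Vc.T)
    cho = linalg.cho_factor(Vc, lower=True)
    B = linalg.cho_solve(cho, Sc)            # Vc^-1 Sc
    ones = np.ones(n)
    trace_term = float(np.trace(B)) - float(Sc @ ones @ linalg.cho_solve(cho, ones)) / n
    bias_cov = g12 * r12 * trace_term / (n - 1)
    var_u = float(np.var(u_hat3, ddof=1))
    var_y = float(np.var(y_n1, ddof=1))
    if var_u <= 0 or var_y <= 0:
        bias_hat = float("nan")
    else:
        bias_hat = bias_cov / math.sqrt(var_u * var_y)
    return BiasCorrection(bias_hat=bias_hat, bias_cov=bias_cov, g12=g12, r12=r12,
                          trace_term=trace_term, var_u_hat=var_u, var_y=var_y, n=n)


def semiparametric_accuracy(naive_cor: float, bias: BiasCorrection, h1_sq: float,
                            correction: str = "h") -> float:
    """Bias-corrected phenotype-validated accuracy.

    ``naive_cor`` is the *raw* correlation ``cor(u_hat3, y_n1)``; the bias is
    subtracted before the 1/h rescaling.
    """
    return (naive_cor - bias.bias_hat) / _h_factor(h1_sq, correction)


def cv2star_accuracy(u_hat3: np.ndarray, y_x1: np.ndarray, h1_sq: float,
                     design: str, r11: float | None = None) -> float:
    """CV2* accuracy: validate against relatives' focal phenotypes.

    ``design="clone"``: ``y_x1`` comes from an independently raised clone of
    each test line, with residual variance ``2 * r11`` (each clone copy
    carries half the data of a line mean), so the rescaling factor is
    ``sqrt(h1_sq / (h1_sq + 2 r11))``. ``design="relative"``: ``y_x1`` is the
    ordinary phenotype of the nearest relative, factor ``sqrt(h1_sq)`` (unit
    phenotypic variance). Score every competing method against the same
    ``y_x1`` with the same factor so the comparison is unaffected.
    """
    u_hat3 = np.asarray(u_hat3, dtype=float)
    y_x1 = np.asarray(y_x1, dtype=float)
    if u_hat3.shape != y_x1.shape:
        raise ValueError("prediction and surrogate phenotype lengths differ")
    if r11 is None:
        r11 = 1.0 - h1_sq
    if design == "clone":
        factor = math.sqrt(h1_sq / (h1_sq + 2.0 * r11))
    elif design == "relative":
        factor = math.sqrt(h1_sq / (h1_sq + r11))
    else:
        raise ValueError(f"unknown CV2* design {design!r}")
    return _pearson(u_hat3, y_x1) / factor
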