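"""Genetic-value predictors for the test partition.

Three predictors of the focal-trait genetic values ``u_n1`` of the test
("n") lines, all built from training-partition fits:

* single-trait: ``Kno Koo^-1 u_hat_o1`` with univariate-fit BLUPs;
* CV1 (multi-trait, no test phenotypes): the same projection applied to the
  focal-trait BLUPs of the bivariate fit;
* CV2 (multi-trait, using the test lines' own secondary-trait phenotypes
  ``y_n2``): a two-step predictor that adds the conditional regression of
  ``u_n1`` on ``y_n2`` given the training BLUPs,

  ``Kno Koo^-1 u_hat_o1 + g12 * Sc Vc^-1 (y_n2 - mu2 - Kno Koo^-1 u_hat_o2)``

  with ``Sc`` the Schur complement of the partitioned GRM and
  ``Vc = g22 * Sc + r22 * I`` the conditional phenotypic covariance of
  ``y_n2``. No data from the test lines enter the training stage.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .mixedmodel import BivariateFit, MixedModelError, UnivariateFit
from .relatedness import ConditionalBlocks


def _check_dims(u_hat_o: np.ndarray, blocks: ConditionalBlocks) -> None:
    if blocks.projection.shape[1] != u_hat_o.shape[0]:
        raise MixedModelError(
            f"projection expects {blocks.projection.shape[1]} training BLUPs, "
            f"got {u_hat_o.shape[0]}"
        )


def predict_single(fit: UnivariateFit, blocks: ConditionalBlocks) -> np.ndarray:
    """Single-trait GBLUP prediction ``Kno Koo^-1 u_hat_o1``."""
    _check_dims(fit.u_hat_o, blocks)
    return blocks.projection @ fit.u_hat_o


def predict_cv1(fit: BivariateFit, blocks: ConditionalBlocks) -> np.ndarray:
    """CV1 multi-trait prediction: same projection, bivariate-fit BLUPs."""
    _check_dims(fit.u_hat_o, blocks)
    return blocks.projection @ fit.u_hat_o[:, 0]


def predict_cv2(fit: BivariateFit, blocks: ConditionalBlocks,
                y_n2: np.ndarray) -> np.ndarray:
    """Two-step CV2 prediction using the test lines' secondary phenotypes."""
    _check_dims(fit.u_hat_o, blocks)
    y_n2 = np.asarray(y_n2, dtype=float)
    n_test = blocks.projection.shape[0]
    if y_n2.shape != (n_test,):
        raise MixedModelError(f"y_n2 must have length {n_test}")
    g12 = fit.G_hat[0, 1]
    g22 = fit.G_hat[1, 1]
    r22 = fit.R_hat[1, 1]
    if r22 <= 0:
        raise MixedModelError("r22 <= 0 makes the conditional covariance singular")
    Sc = blocks.schur
    Vc = g22 * Sc + r22 * np.eye(n_test)
    Vc = 0.5 * (Vc + Vc.T)
    resid = y_n2 - fit.mu_hat[1] - blocks.projection @ fit.u_hat_o[:, 1]
    cho = linalg.cho_factor(Vc, lower=True)
    adj = g12 * (Sc @ linalg.cho_solve(cho, resid))
    return blocks.projection @ fit.u_hat_o[:, 0] + adj


def write_predictions(predictions: dict[str, np.ndarray], ids, path: str | Path,
                      delimiter: str = "\t") -> None:
    """Tidy prediction table: one row per (id, method)."""
    rows = [
        {"id": lid, "method": method, "u_hat": float(val)}
        for method, vec in predictions.items()
        for lid, val in zip(ids, vec)
    ]
    pd.DataFrame(rows).to_csv(Path(path), sep=delimiter, index=False,
                              float_format="%.17g")
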