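"""Feature-combination x regularization-multiplier grid search with AICc.

The default grid crosses six feature combinations (L, LQ, LQH, H, LQHP,
LQHPT) with regularization multipliers 0.5 to 4.0 in steps of 0.5 — 48
candidate models.  Each candidate is fitted on the full presence set with a
shared background sample; AICc is computed from the presence likelihood
under the raw output standardized over all valid study cells, with k = the
number of non-zero coefficients.  The candidate with delta.AICc = 0 is
selected; ties break toward smaller k, then larger RM, then grid order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import auc, split_presences
from .grid_io import GridLayer
from .maxent_core import (
    FeatureSpec,
    MaxEntModel,
    compute_scaling,
    expand_features,
    feature_info,
    fit_maxent,
    predict_logistic,
    sample_background,
)
from .occurrences import OccurrenceSet
from .stack import occurrence_cells, predictor_matrix, values_at_cells

__all__ = ["TuningResult", "aicc", "tune_grid", "DEFAULT_FCS", "DEFAULT_RMS"]

logger = logging.getLogger(__name__)

DEFAULT_FCS = ("L", "LQ", "LQH", "H", "LQHP", "LQHPT")
DEFAULT_RMS = tuple(np.arange(0.5, 4.01, 0.5))


@dataclass
class TuningRow:
    fc: str
    rm: float
    aicc: float          # NaN when undefined
    delta_aicc: float
    k: int
    mean_test_auc: float
    converged: bool


@dataclass
class TuningResult:
    rows: list[TuningRow]
    selected: tuple[str, float]
    selected_model: MaxEntModel | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "FC": r.fc,
                    "RM": r.rm,
                    "AICc": r.aicc,
                    "delta.AICc": r.delta_aicc,
                    "k": r.k,
                    "mean_test_AUC": r.mean_test_auc,
                    "converged": r.converged,
                }
                for r in self.rows
            ]
        )

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def aicc(model: MaxEntModel, presence_values: np.ndarray, study_values: np.ndarray) -> float:
    """Small-sample-corrected AIC of a fitted model.

    The raw output is standardized to sum to one over all valid study
    cells; ln L is the sum of log standardized raw at the presence cells;
    AICc = 2k - 2 ln L + 2k(k+1)/(n-k-1) with k non-zero coefficients and
    n presences.  Returns NaN (undefined) when k = 0 or k >= n-1.
    """
    from .maxent_core import predict_raw

    n = np.atleast_2d(presence_values).shape[0]
    k = model.k_nonzero
    if k == 0 or k >= n - 1:
        return float("nan")
    raw_study = predict_raw(model, study_values)
    raw_pres = predict_raw(model, presence_values)
    total = raw_study.sum()
    if total <= 0:
        return float("nan")
    ll = float(np.log(raw_pres / total).sum())
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)


def tune_grid(
    occ: OccurrenceSet,
    env: list[GridLayer],
    fcs: tuple[str, ...] = DEFAULT_FCS,
    rms: tuple[float, ...] = DEFAULT_RMS,
    seed: int | None = None,
    mask: GridLayer | None = None,
    n_background: int = 10000,
    hinge_knots: int = 50,
    threshold_knots: int = 50,
    eval_split: bool = True,
) -> TuningResult:
    """Fit every (FC, RM) candidate and select the delta.AICc = 0 row.

    All candidates share one background sample and seed.  The full LQHPT
    expansion is computed once and sliced per feature combination.  When
    ``eval_split`` is set, a single 75/25 split model per candidate supplies
    a test AUC for reporting (selection itself uses only AICc).
    """
    if mask is None:
        mask = env[0].copy_with(
            np.where(np.isfinite(env[0].values), 1.0, np.nan), kind="binary"
        )
    names = [lyr.name or f"var{i}" for i, lyr in enumerate(env)]
    X_study, _, _ = predictor_matrix(env)
    bg_cells = sample_background(mask, n_background, seed=seed)
    pres_cells = occurrence_cells(occ, mask, unique=False)
    bg_cells = np.unique(np.vstack([bg_cells, pres_cells]), axis=0)
    Xb = values_at_cells(env, bg_cells)
    Xb = Xb[np.isfinite(Xb).all(axis=1)]
    Xp = values_at_cells(env, pres_cells)
    Xp = Xp[np.isfinite(Xp).all(axis=1)]
    if len(Xp) < 2:
        raise ValueError("fewer than 2 presences fall on valid cells")
    scaling = compute_scaling(Xb)

    full_spec = FeatureSpec("LQHPT", hinge_knots, threshold_knots)
    _, full_classes = feature_info(names, full_spec)
    full_classes = np.array(full_classes)
    Fp_full = expand_features(Xp, full_spec, scaling)
    Fb_full = expand_features(Xb, full_spec, scaling)
    Fstudy_full = expand_features(X_study, full_spec, scaling)

    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(0, 2**31 - 1))
    if eval_split:
        train, test = split_presences(occ, 0.25, seed=split_seed)
        tr_cells = occurrence_cells(train, mask, unique=False)
        te_cells = occurrence_cells(test, mask, unique=False)
        Xtr = values_at_cells(env, tr_cells)
        Xte = values_at_cells(env, te_cells)
        Xtr = Xtr[np.isfinite(Xtr).all(axis=1)]
        Xte = Xte[np.isfinite(Xte).all(axis=1)]

    rows: list[TuningRow] = []
    models: dict[tuple[str, float], MaxEntModel] = {}
    for fc in fcs:
        spec = FeatureSpec(fc, hinge_knots, threshold_knots)
        cols = np.isin(full_classes, list(spec.classes))
        classes_fc = full_classes[cols].tolist()
        for rm in rms:
            model = fit_maxent(
                Fp_full[:, cols], Fb_full[:, cols], spec, rm,
                feature_classes=classes_fc, variable_names=names, scaling=scaling,
            )
            a = _aicc_from_features(model, Fp_full[:, cols], Fstudy_full[:, cols])
            test_auc = float("nan")
            if eval_split and len(Xte):
                split_model = fit_maxent(
                    expand_features(Xtr, spec, scaling),
                    Fb_full[:, cols],
                    spec, rm, feature_classes=classes_fc,
                    variable_names=names, scaling=scaling,
                )
                test_auc = auc(
                    predict_logistic(split_model, Xte),
                    predict_logistic(split_model, Xb),
                )
            rows.append(TuningRow(fc, float(rm), a, float("nan"),
                                  model.k_nonzero, test_auc, model.converged))
            models[(fc, float(rm))] = model

    defined = [r for r in rows if np.isfinite(r.aicc)]
    if not defined:
        raise ValueError(
            "AICc undefined for every candidate (k = 0 or k >= n-1 everywhere); "
            "more presences are needed"
        )
    best = min(r.aicc for r in defined)
    for r in rows:
        r.delta_aicc = r.aicc - best if np.isfinite(r.aicc) else float("nan")
    zero_rows = [r for r in rows if np.isfinite(r.delta_aicc) and r.delta_aicc == 0.0]
    # tie-break: smaller k, then larger rm, then FC grid order
    fc_order = {fc: i for i, fc in enumerate(fcs)}
    zero_rows.sort(key=lambda r: (r.k, -r.rm, fc_order[r.fc]))
    sel = zero_rows[0]
    return TuningResult(rows=rows, selected=(sel.fc, sel.rm),
                        selected_model=models[(sel.fc, sel.rm)])


def _aicc_from_features(model: MaxEntModel, Fp: np.ndarray, Fstudy: np.ndarray) -> float:
    """AICc computed directly from pre-expanded feature matrices."""
    n = Fp.shape[0]
    k = model.k_nonzero
    if k == 0 or k >= n - 1:
        return float("nan")
    eta_study = Fstudy @ model.coefficients
    eta_pres = Fp @ model.coefficients
    from scipy.special import logsumexp

    log_total = logsumexp(eta_study)
    ll = float((eta_pres - log_total).sum())
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)
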