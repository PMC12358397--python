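"""Model evaluation: train/test splits, AUC, replicates, variable importance.

AUC is the presence-background rank-sum statistic (background points act as
pseudo-absences): the fraction of (presence, background) score pairs where
the presence scores higher, ties counted one half.  Percent contribution is
implemented as normalized permutation importance — the mean AUC drop when
one variable is shuffled across the evaluation cells — because it is well
defined for any fitted model and independent of the optimization path.
Jackknife importance refits the model with each variable alone and with
each variable left out, reporting regularized training gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .grid_io import GridLayer
from .maxent_core import (
    FeatureSpec,
    MaxEntModel,
    predict_logistic,
    sample_background,
    train_maxent,
)
from .occurrences import OccurrenceSet
from .stack import layer_from_valid, occurrence_cells, predictor_matrix, values_at_cells

__all__ = [
    "EvaluationReport",
    "split_presences",
    "auc",
    "replicate_fit",
    "permutation_importance",
    "jackknife_gains",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Replicate AUCs, contribution percentages and jackknife gains."""

    replicate_aucs: list[tuple[float, float]] = field(default_factory=list)  # (train, test)
    mean_test_auc: float = float("nan")
    sd_test_auc: float = float("nan")
    contributions: dict[str, float] = field(default_factory=dict)
    jackknife: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary_text(self) -> str:
        lines = [
            f"n_replicates: {len(self.replicate_aucs)}",
            f"mean_test_auc: {self.mean_test_auc:.3f} ± {self.sd_test_auc:.3f} (sd)",
        ]
        for name, pct in sorted(self.contributions.items(), key=lambda kv: -kv[1]):
            lines.append(f"contribution[{name}]: {pct:.1f}%")
        for name, (alone, without) in self.jackknife.items():
            lines.append(f"jackknife[{name}]: alone={alone:.4f} without={without:.4f}")
        return "\n".join(lines)


def split_presences(
    occ: OccurrenceSet, test_fraction: float = 0.25, seed: int | None = None
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint train/test partition; test size = floor(n * fraction)."""
    n = len(occ)
    if n < 4:
        raise ValueError("need at least 4 presences to split")
    n_test = int(np.floor(n * test_fraction))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [r for i, r in enumerate(occ.records) if i not in test_idx]
    test = [r for i, r in enumerate(occ.records) if i in test_idx]
    return (
        OccurrenceSet(occ.species, train),
        OccurrenceSet(occ.species, test),
    )


def auc(presence_scores, background_scores) -> float:
    """Rank-sum (Mann-Whitney) AUC; ties count one half.

    Equals the fraction of (presence, background) pairs where the presence
    score exceeds the background score.  Returns 0.5 when all scores are
    identical.
    """
    pres = np.asarray(presence_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or bg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([pres, bg]))
    r_pres = ranks[: pres.size].sum()
    u = r_pres - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * bg.size))


def _fit_once(
    train_occ: OccurrenceSet,
    env: list[GridLayer],
    mask: GridLayer,
    spec: FeatureSpec,
    rm: float,
    n_background: int,
    seed: int,
    include_presences_in_background: bool = True,
) -> tuple[MaxEntModel, np.ndarray, np.ndarray]:
    """Fit one model; returns (model, presence values, background values)."""
    bg_cells = sample_background(mask, n_background, seed=seed)
    pres_cells = occurrence_cells(train_occ, mask, unique=False)
    if include_presences_in_background:
        bg_cells = np.unique(np.vstack([bg_cells, pres_cells]), axis=0)
    Xb = values_at_cells(env, bg_cells)
    Xp = values_at_cells(env, pres_cells)
    ok_b = np.isfinite(Xb).all(axis=1)
    ok_p = np.isfinite(Xp).all(axis=1)
    if not ok_p.all():
        logger.warning("dropped %d presences in nodata cells", (~ok_p).sum())
    names = [lyr.name or f"var{i}" for i, lyr in enumerate(env)]
    model = train_maxent(Xp[ok_p], Xb[ok_b], names, spec, rm)
    return model, Xp[ok_p], Xb[ok_b]


def replicate_fit(
    occ: OccurrenceSet,
    env: list[GridLayer],
    spec: FeatureSpec,
    rm: float,
    n_replicates: int = 10,
    seed: int | None = None,
    mask: GridLayer | None = None,
    n_background: int = 10000,
    test_fraction: float = 0.25,
    compute_contributions: bool = True,
) -> tuple[EvaluationReport, GridLayer]:
    """Run replicate split/fit cycles; return the report and the cell-wise
    mean logistic suitability layer (the working suitability index P).

    Each replicate draws its own train/test split and background sample
    from seeds derived from the master seed.
    """
    if mask is None:
        mask = env[0].copy_with(
            np.where(np.isfinite(env[0].values), 1.0, np.nan), kind="binary"
        )
    X_all, cells_all, names = predictor_matrix(env)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=2 * n_replicates)
    report = EvaluationReport()
    mean_vals = np.zeros(X_all.shape[0])
    contrib_acc = np.zeros(len(env))
    for r in range(n_replicates):
        train, test = split_presences(occ, test_fraction, seed=int(sub_seeds[2 * r]))
        model, Xp_train, Xb = _fit_once(
            train, env, mask, spec, rm, n_background, seed=int(sub_seeds[2 * r + 1])
        )
        bg_scores = predict_logistic(model, Xb)
        train_auc = auc(predict_logistic(model, Xp_train), bg_scores)
        Xp_test = values_at_cells(env, occurrence_cells(test, mask, unique=False))
        Xp_test = Xp_test[np.isfinite(Xp_test).all(axis=1)]
        test_auc = auc(predict_logistic(model, Xp_test), bg_scores) if len(Xp_test) else float("nan")
        report.replicate_aucs.append((train_auc, test_auc))
        mean_vals += predict_logistic(model, X_all)
        if compute_contributions:
            contrib = permutation_importance(
                model, Xp_test if len(Xp_test) else Xp_train, Xb,
                seed=int(sub_seeds[2 * r + 1]), normalize=False,
            )
            contrib_acc += np.array([contrib[n] for n in names])
    mean_vals /= n_replicates
    tests = np.array([t for _, t in report.replicate_aucs if np.isfinite(t)])
    report.mean_test_auc = float(tests.mean()) if tests.size else float("nan")
    report.sd_test_auc = float(tests.std(ddof=1)) if tests.size > 1 else 0.0
    if compute_contributions:
        total = contrib_acc.sum()
        if total > 0:
            report.contributions = dict(zip(names, 100.0 * contrib_acc / total))
        else:
            report.contributions = {n: 100.0 / len(names) for n in names}
    mean_layer = layer_from_valid(env[0], cells_all, mean_vals, kind="continuous",
                                  name=f"{occ.species}_suitability")
    return report, mean_layer


def permutation_importance(
    model: MaxEntModel,
    presence_values: np.ndarray,
    background_values: np.ndarray,
    seed: int | None = None,
    n_perm: int = 10,
    normalize: bool = True,
) -> dict[str, float]:
    """Per-variable mean AUC drop under permutation, optionally normalized
    to percentages summing to 100."""
    rng = np.random.default_rng(seed)
    Xp = np.atleast_2d(presence_values)
    Xb = np.atleast_2d(background_values)
    base = auc(predict_logistic(model, Xp), predict_logistic(model, Xb))
    names = model.variable_names
    drops = np.zeros(len(names))
    n_p = Xp.shape[0]
    X_all = np.vstack([Xp, Xb])
    for v in range(len(names)):
        acc = 0.0
        for _ in range(n_perm):
            Xperm = X_all.copy()
            Xperm[:, v] = rng.permutation(Xperm[:, v])
            scores = predict_logistic(model, Xperm)
            acc += auc(scores[:n_p], scores[n_p:])
        drops[v] = max(0.0, base - acc / n_perm)
    if not normalize:
        return dict(zip(names, drops))
    total = drops.sum()
    if total <= 0:
        return {n: 100.0 / len(names) for n in names}
    return dict(zip(names, 100.0 * drops / total))


def jackknife_gains(
    occ: OccurrenceSet,
    env: list[GridLayer],
    spec: FeatureSpec,
    rm: float,
    seed: int | None = None,
    mask: GridLayer | None = None,
    n_background: int = 10000,
) -> dict[str, tuple[float, float]]:
    """Regularized training gain with each variable alone / left out.

    The gain of a model is (1/m) sum lambda.f(x) - log Z + log n_background;
    the null model has gain exactly 0.
    """
    if len(env) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    if mask is None:
        mask = env[0].copy_with(
            np.where(np.isfinite(env[0].values), 1.0, np.nan), kind="binary"
        )
    names = [lyr.name or f"var{i}" for i, lyr in enumerate(env)]
    out: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(names):
        alone_model, _, _ = _fit_once(occ, [env[i]], mask, spec, rm, n_background, seed or 0)
        rest = [lyr for j, lyr in enumerate(env) if j != i]
        without_model, _, _ = _fit_once(occ, rest, mask, spec, rm, n_background, seed or 0)
        out[name] = (alone_model.training_gain, without_model.training_gain)
    return out
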