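"""Maximum-entropy presence-background distribution model.

The model estimates a Gibbs distribution over landscape cells,

    raw(x) = exp(lambda . f(x)) / Z,

where ``f`` expands the raw predictor values into feature transforms
(linear, quadratic, product, hinge, threshold) and ``Z`` normalizes over a
background sample.  The coefficients maximize the penalized log-likelihood
of the presence cells,

    (1/m) sum_presence lambda.f(x)  -  log sum_background exp(lambda.f(b))
                                    -  sum_j beta_j |lambda_j|,

an L1-regularized concave problem.  ``beta_j`` scales linearly with the
regularization multiplier (RM) and follows per-feature-class default
schedules against the presence count, so larger RM values produce sparser,
smoother models.  The optimization uses the lambda = lambda+ - lambda-
bound-constrained split solved with L-BFGS-B.

The "logistic" output rescales raw to a [0, 1] suitability index using the
entropy of the fitted background distribution: p = e^H raw / (1 + e^H raw).
Under the null model every cell gets p = 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grid_io import GridLayer

__all__ = [
    "FeatureSpec",
    "MaxEntModel",
    "sample_background",
    "compute_scaling",
    "expand_features",
    "feature_info",
    "fit_maxent",
    "train_maxent",
    "predict_raw",
    "predict_logistic",
]

FC_ORDER = "LQHPT"

#: |lambda| above this counts as a non-zero coefficient (feeds AICc's k).
NONZERO_TOL = 1e-7


@dataclass(frozen=True)
class FeatureSpec:
    """Which feature classes to expand, and knot counts for H and T.

    ``classes`` is any subset of "LQHPT": Linear, Quadratic, Hinge,
    Product (pairwise), Threshold.  Hinge features come in forward and
    reverse directions at a uniform interior knot grid; threshold features
    are strict step indicators 1[u > t].
    """

    classes: str = "LQ"
    hinge_knots: int = 50
    threshold_knots: int = 50

    def __post_init__(self) -> None:
        cls = "".join(c for c in FC_ORDER if c in self.classes.upper())
        if not cls:
            raise ValueError(f"no valid feature classes in {self.classes!r}")
        if set(self.classes.upper()) - set(FC_ORDER):
            raise ValueError(f"unknown feature classes in {self.classes!r}")
        object.__setattr__(self, "classes", cls)
        if self.hinge_knots < 2 or self.threshold_knots < 2:
            raise ValueError("knot counts must be >= 2")

    @property
    def label(self) -> str:
        return self.classes


def _knots(n: int) -> np.ndarray:
    # interior knots: avoids degenerate hinges at t=0 / t=1
    return np.linspace(0.0, 1.0, n + 2)[1:-1]


def compute_scaling(background_values: np.ndarray) -> np.ndarray:
    """Per-variable (min, max) over the background sample, shape (p, 2)."""
    bg = np.asarray(background_values, dtype=float)
    return np.column_stack([np.nanmin(bg, axis=0), np.nanmax(bg, axis=0)])


def _unit_scale(values: np.ndarray, scaling: np.ndarray) -> np.ndarray:
    """Scale each variable to [0, 1] by its training range, clamped."""
    lo, hi = scaling[:, 0], scaling[:, 1]
    span = hi - lo
    degenerate = span <= 0
    span = np.where(degenerate, 1.0, span)
    u = (values - lo) / span
    u[:, degenerate] = 0.5  # constant variable: flagged by caller
    return np.clip(u, 0.0, 1.0)


def feature_info(variable_names: list[str], spec: FeatureSpec) -> tuple[list[str], list[str]]:
    """Feature names and their class letter, in expansion column order."""
    names: list[str] = []
    classes: list[str] = []
    p = len(variable_names)
    if "L" in spec.classes:
        for v in variable_names:
            names.append(f"L({v})")
            classes.append("L")
    if "Q" in spec.classes:
        for v in variable_names:
            names.append(f"Q({v})")
            classes.append("Q")
    if "H" in spec.classes:
        for v in variable_names:
            for t in _knots(spec.hinge_knots):
                names.append(f"Hf({v},{t:.4f})")
                classes.append("H")
            for t in _knots(spec.hinge_knots):
                names.append(f"Hr({v},{t:.4f})")
                classes.append("H")
    if "P" in spec.classes:
        for a in range(p):
            for b in range(a + 1, p):
                names.append(f"P({variable_names[a]},{variable_names[b]})")
                classes.append("P")
    if "T" in spec.classes:
        for v in variable_names:
            for t in _knots(spec.threshold_knots):
                names.append(f"T({v},{t:.4f})")
                classes.append("T")
    return names, classes


def expand_features(values: np.ndarray, spec: FeatureSpec, scaling: np.ndarray) -> np.ndarray:
    """Expand raw variable values (n, p) into the feature matrix (n, K).

    Variables are scaled to u = (v - min)/(max - min), clamped to [0, 1].
    Column order matches :func:`feature_info`: L, Q, H (forward then
    reverse per variable), P, T.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    u = _unit_scale(values, np.asarray(scaling, dtype=float))
    n, p = u.shape
    blocks: list[np.ndarray] = []
    if "L" in spec.classes:
        blocks.append(u)
    if "Q" in spec.classes:
        blocks.append(u ** 2)
    if "H" in spec.classes:
        t = _knots(spec.hinge_knots)
        fwd = np.maximum(0.0, (u[:, :, None] - t) / (1.0 - t))
        rev = np.maximum(0.0, (t - u[:, :, None]) / t)
        hinge = np.concatenate([fwd, rev], axis=2)  # (n, p, 2k)
        blocks.append(hinge.reshape(n, -1))
    if "P" in spec.classes:
        iu, ju = np.triu_indices(p, k=1)
        blocks.append(u[:, iu] * u[:, ju])
    if "T" in spec.classes:
        t = _knots(spec.threshold_knots)
        blocks.append((u[:, :, None] > t).astype(float).reshape(n, -1))
    return np.concatenate(blocks, axis=1) if blocks else np.empty((n, 0))


# -- regularization schedule -------------------------------------------------
# Default per-class penalty widths, interpolated piecewise-linearly against
# the presence count m, then scaled by RM and the per-feature presence s.d.
_BASE_SCHEDULE: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "L": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "Q": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "P": ((0, 10, 17), (2.6, 1.6, 0.5)),
    "H": ((0, 1), (0.5, 0.5)),
    "T": ((0, 100), (2.0, 1.0)),
}


def regularization_weights(
    presence_features: np.ndarray,
    feature_classes: list[str],
    rm: float,
    m: int | None = None,
) -> np.ndarray:
    """Per-feature L1 penalty beta_j = RM * base(class, m) * sd_j / sqrt(m).

    ``sd_j`` is the standard deviation of feature j over the presences,
    floored at 1/sqrt(m) so constant or near-constant features still carry
    a finite penalty.
    """
    X = np.asarray(presence_features, dtype=float)
    if m is None:
        m = X.shape[0]
    m = max(m, 2)
    sd = X.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1.0 / np.sqrt(m))
    base = np.empty(len(feature_classes))
    for cls, (xs, ys) in _BASE_SCHEDULE.items():
        mask = np.array([c == cls for c in feature_classes])
        if mask.any():
            base[mask] = np.interp(m, xs, ys)
    return rm * base * sd / np.sqrt(m)


@dataclass
class MaxEntModel:
    """A fitted Gibbs model with everything needed to project it."""

    spec: FeatureSpec
    rm: float
    variable_names: list[str]
    scaling: np.ndarray              # (p, 2) background (min, max)
    coefficients: np.ndarray         # lambda over expanded features
    log_normalizer: float            # log Z over the training background
    entropy: float                   # H of the fitted background distribution
    n_presence: int
    n_background: int
    converged: bool = True
    feature_names: list[str] = field(default_factory=list)
    training_gain: float = 0.0

    @property
    def k_nonzero(self) -> int:
        return int((np.abs(self.coefficients) > NONZERO_TOL).sum())

    # -- plain-text serialization ------------------------------------------

    def to_text(self) -> str:
        payload = {
            "format": "parasdm-maxent-model",
            "version": 1,
            "feature_classes": self.spec.classes,
            "hinge_knots": self.spec.hinge_knots,
            "threshold_knots": self.spec.threshold_knots,
            "rm": self.rm,
            "variable_names": self.variable_names,
            "scaling": self.scaling.tolist(),
            "coefficients": self.coefficients.tolist(),
            "log_normalizer": self.log_normalizer,
            "entropy": self.entropy,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "converged": self.converged,
            "training_gain": self.training_gain,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_text(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        if d.get("format") != "parasdm-maxent-model":
            raise ValueError("not a serialized model")
        spec = FeatureSpec(d["feature_classes"], d["hinge_knots"], d["threshold_knots"])
        names, _ = feature_info(d["variable_names"], spec)
        return cls(
            spec=spec,
            rm=d["rm"],
            variable_names=d["variable_names"],
            scaling=np.asarray(d["scaling"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            log_normalizer=d["log_normalizer"],
            entropy=d["entropy"],
            n_presence=d["n_presence"],
            n_background=d["n_background"],
            converged=d["converged"],
            feature_names=names,
            training_gain=d.get("training_gain", 0.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "MaxEntModel":
        with open(path) as fh:
            return cls.from_text(fh.read())


def sample_background(mask: GridLayer, n: int = 10000, seed: int | None = None) -> np.ndarray:
    """Uniform sample of cell (row, col) indices without replacement.

    Cells with mask value 1 are eligible; if fewer than ``n`` exist all of
    them are returned.  Reproducible under ``seed``.
    """
    if mask.kind != "binary":
        raise ValueError("background mask must be binary")
    rows, cols = np.nonzero(mask.values == 1.0)
    total = rows.size
    if total == 0:
        raise ValueError("mask has no valid cells")
    rng = np.random.default_rng(seed)
    if n >= total:
        return np.column_stack([rows, cols])
    pick = rng.choice(total, size=n, replace=False)
    return np.column_stack([rows[pick], cols[pick]])


def _objective_and_grad(z, F_pres_mean, F_bg, beta):
    K = beta.size
    lam = z[:K] - z[K:]
    s = F_bg @ lam
    lse = logsumexp(s)
    q = np.exp(s - lse)
    neg_ll = lse - F_pres_mean @ lam
    g = F_pres_mean - q @ F_bg            # gradient of the (concave) log-lik
    val = neg_ll + beta @ (z[:K] + z[K:])
    grad = np.concatenate([-g + beta, g + beta])
    return val, grad


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    spec: FeatureSpec,
    rm: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 10000,
    feature_classes: list[str] | None = None,
    variable_names: list[str] | None = None,
    scaling: np.ndarray | None = None,
    feature_names: list[str] | None = None,
) -> MaxEntModel:
    """Fit the penalized Gibbs model on pre-expanded feature matrices.

    ``presence_features`` (m, K) and ``background_features`` (n, K) must be
    expansions under the same spec/scaling.  Returns the model with
    ``converged`` False (and a warning logged) if the optimizer hits
    ``max_iter``.
    """
    Fp = np.atleast_2d(np.asarray(presence_features, dtype=float))
    Fb = np.atleast_2d(np.asarray(background_features, dtype=float))
    m, K = Fp.shape
    if m < 2:
        raise ValueError("need at least 2 presences")
    if Fb.shape[0] < 1 or Fb.shape[1] != K:
        raise ValueError("background features empty or mismatched")
    if feature_classes is None:
        if variable_names is None:
            raise ValueError("feature_classes or variable_names required")
        _, feature_classes = feature_info(variable_names, spec)
    beta = regularization_weights(Fp, feature_classes, rm, m)
    Fp_mean = Fp.mean(axis=0)

    res = minimize(
        _objective_and_grad,
        x0=np.zeros(2 * K),
        args=(Fp_mean, Fb, beta),
        method="L-BFGS-B",
        jac=True,
        bounds=[(0.0, None)] * (2 * K),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-9, "maxcor": 20},
    )
    lam = res.x[:K] - res.x[K:]
    lam[np.abs(lam) <= NONZERO_TOL] = 0.0
    s = Fb @ lam
    log_z = float(logsumexp(s))
    q = np.exp(s - log_z)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    n_bg = Fb.shape[0]
    gain = float(Fp_mean @ lam - log_z + np.log(n_bg))
    if variable_names is not None and feature_names is None:
        feature_names, _ = feature_info(variable_names, spec)
    return MaxEntModel(
        spec=spec,
        rm=rm,
        variable_names=variable_names or [],
        scaling=np.asarray(scaling, dtype=float) if scaling is not None else np.empty((0, 2)),
        coefficients=lam,
        log_normalizer=log_z,
        entropy=entropy,
        n_presence=m,
        n_background=n_bg,
        converged=bool(res.success),
        feature_names=feature_names or [],
        training_gain=gain,
    )


def train_maxent(
    presence_values: np.ndarray,
    background_values: np.ndarray,
    variable_names: list[str],
    spec: FeatureSpec,
    rm: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 10000,
) -> MaxEntModel:
    """Scale, expand and fit from raw variable values (convenience path)."""
    scaling = compute_scaling(background_values)
    Fp = expand_features(presence_values, spec, scaling)
    Fb = expand_features(background_values, spec, scaling)
    _, classes = feature_info(variable_names, spec)
    return fit_maxent(
        Fp, Fb, spec, rm, tol, max_iter,
        feature_classes=classes, variable_names=variable_names, scaling=scaling,
    )


def predict_raw(model: MaxEntModel, values: np.ndarray) -> np.ndarray:
    """Raw Gibbs output e^{lambda.f(x)}/Z for raw variable values (n, p).

    Features are clamped to the training [0, 1] range; the output sums to 1
    over the training background.
    """
    F = expand_features(values, model.spec, model.scaling)
    return np.exp(F @ model.coefficients - model.log_normalizer)


def predict_logistic(model: MaxEntModel, values: np.ndarray) -> np.ndarray:
    """Logistic suitability index p = e^H raw / (1 + e^H raw), in (0, 1)."""
    F = expand_features(values, model.spec, model.scaling)
    eta = model.entropy + F @ model.coefficients - model.log_normalizer
    # numerically stable sigmoid
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ez = np.exp(eta[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
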