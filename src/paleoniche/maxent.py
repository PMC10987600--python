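"""Presence-background Maxent, implemented from scratch.

Maxent estimates a Gibbs density over background cells,
``P(x) = exp(eta(x)) / Z`` with ``eta`` a sparse linear combination of
feature transforms of the climate covariates, by maximizing the penalized
presence log-likelihood

    (1/n_p) * sum_presences eta(x_i)  -  log( mean_background exp(eta(x_j)) )
    -  sum_features lambda_j * |beta_j|

The lasso penalties follow the published Maxent defaults: per-feature-class
base weights interpolated against the presence sample size, scaled by each
feature's standard deviation over the presences and by 1/sqrt(n_p), all
multiplied by a global regularization multiplier (RM).

Fitting is by monotone proximal-gradient descent (ISTA with backtracking),
which decreases the objective at every iteration and terminates on the lasso
KKT conditions.  Feature classes are linear (L), quadratic (Q) and forward
hinge (H), combined as L / LQ / LQH / H; covariates are min-max scaled on
the combined presence + background training sample.

Model selection follows the standard ENM tuning workflow: a grid over RM and
feature classes is scored by ten-fold cross-validation (random presence
folds, background shared), candidates are screened by delta-AICc < 2, then
minimum mean test omission, then maximum mean test AUC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import rankdata

FEATURE_CLASSES = ("L", "LQ", "LQH", "H")


class FittingError(RuntimeError):
    pass


@dataclass(frozen=True)
class FeatureSpec:
    """Feature-class set, hinge-knot count and regularization multiplier."""

    feature_class: str = "LQ"
    hinge_knots: int = 15
    rm: float = 1.0

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"feature_class must be one of {FEATURE_CLASSES}")
        if self.rm <= 0:
            raise ValueError("regularization multiplier must be positive")
        if "H" in self.feature_class and self.hinge_knots < 2:
            raise ValueError("hinge classes need at least 2 knots")

    @property
    def kinds(self) -> list[str]:
        return {"L": ["L"], "LQ": ["L", "Q"], "LQH": ["L", "Q", "H"], "H": ["H"]}[
            self.feature_class
        ]


@dataclass(frozen=True)
class Feature:
    variable: str
    kind: str           # "L", "Q" or "H"
    knot: float = 0.0   # hinge knot on the [0, 1] scaled axis


def _scaled(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (x - lo) / (hi - lo)


def build_features(
    data: pd.DataFrame,
    variables: Sequence[str],
    spec: FeatureSpec,
    normalization: dict[str, tuple[float, float]],
) -> tuple[np.ndarray, list[Feature]]:
    """Design matrix and feature metadata for records of the given variables.

    Covariates are min-max scaled by the supplied normalization (computed on
    the training sample); L is the scaled covariate, Q its square, H the
    forward hinges ``max(0, (z - knot) / (1 - knot))`` at evenly spaced knots
    on [0, 1).  Zero-variance variables are skipped with a warning.
    """
    cols: list[np.ndarray] = []
    meta: list[Feature] = []
    for v in variables:
        lo, hi = normalization[v]
        if hi <= lo:
            warnings.warn(f"variable {v!r} has zero variance on the training sample; skipped")
            continue
        z = _scaled(np.asarray(data[v], dtype=float), lo, hi)
        for kind in spec.kinds:
            if kind == "L":
                cols.append(z)
                meta.append(Feature(v, "L"))
            elif kind == "Q":
                cols.append(z**2)
                meta.append(Feature(v, "Q"))
            elif kind == "H":
                knots = np.arange(spec.hinge_knots) / spec.hinge_knots
                for kn in knots:
                    cols.append(np.maximum(0.0, (z - kn) / (1.0 - kn)))
                    meta.append(Feature(v, "H", float(kn)))
    if not cols:
        raise FittingError("no usable features (all variables zero-variance?)")
    return np.column_stack(cols), meta


def _interp_base(n: float, sizes, betas) -> float:
    return float(np.interp(n, sizes, betas))


def regularization_weights(
    features_presence: np.ndarray, meta: Sequence[Feature], rm: float
) -> np.ndarray:
    """Per-feature lasso weights following the published Maxent defaults.

    base(class, n_p) is interpolated from the Maxent default tables (linear:
    1.0/0.2/0.05 at 10/30/100 presences; quadratic: 1.3..0.05 at 0..100;
    hinge: 0.5), then scaled by the feature's sd over the presences and by
    1/sqrt(n_p), and finally by the regularization multiplier.
    """
    n = features_presence.shape[0]
    sd = features_presence.std(axis=0, ddof=1) if n > 1 else np.ones(features_presence.shape[1])
    sd = np.maximum(sd, 1e-3)
    base = np.empty(len(meta))
    for j, f in enumerate(meta):
        if f.kind == "L":
            base[j] = _interp_base(n, (10, 30, 100), (1.0, 0.2, 0.05))
        elif f.kind == "Q":
            base[j] = _interp_base(n, (0, 10, 17, 30, 100), (1.3, 0.8, 0.5, 0.25, 0.05))
        else:
            base[j] = 0.5
    return rm * base * sd / np.sqrt(max(n, 1))


@dataclass
class MaxentModel:
    """A fitted Maxent model: features, coefficients and output transforms."""

    spec: FeatureSpec
    variables: list[str]
    normalization: dict[str, tuple[float, float]]
    training_means: dict[str, float]
    meta: list[Feature]
    coef: np.ndarray
    reg: np.ndarray
    log_norm: float        # log sum of exp(eta) over the training background
    entropy: float         # Shannon entropy of the fitted background density
    n_presence: int
    n_background: int
    n_iter: int = 0
    objective: float = float("nan")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))

    def linear_score(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [v for v in self.variables if v not in rows.columns]
        if missing:
            raise KeyError(f"rows are missing model variables: {missing}")
        X, _ = build_features(rows, self.variables, self.spec, self.normalization)
        return X @ self.coef

    def to_json(self) -> str:
        payload = {
            "spec": {
                "feature_class": self.spec.feature_class,
                "hinge_knots": self.spec.hinge_knots,
                "rm": self.spec.rm,
            },
            "variables": self.variables,
            "normalization": {v: list(map(float, mm)) for v, mm in self.normalization.items()},
            "training_means": {v: float(m) for v, m in self.training_means.items()},
            "meta": [[f.variable, f.kind, f.knot] for f in self.meta],
            "coef": [float(c) for c in self.coef],
            "reg": [float(r) for r in self.reg],
            "log_norm": float(self.log_norm),
            "entropy": float(self.entropy),
            "n_presence": self.n_presence,
            "n_background": self.n_background,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        d = json.loads(text)
        return cls(
            spec=FeatureSpec(**d["spec"]),
            variables=list(d["variables"]),
            normalization={v: tuple(mm) for v, mm in d["normalization"].items()},
            training_means=dict(d["training_means"]),
            meta=[Feature(v, k, kn) for v, k, kn in d["meta"]],
            coef=np.asarray(d["coef"], dtype=float),
            reg=np.asarray(d["reg"], dtype=float),
            log_norm=float(d["log_norm"]),
            entropy=float(d["entropy"]),
            n_presence=int(d["n_presence"]),
            n_background=int(d["n_background"]),
        )


def maxent_objective(
    beta: np.ndarray, Xp: np.ndarray, Xb: np.ndarray, reg: np.ndarray
) -> float:
    """The penalized negative presence log-likelihood being minimized."""
    eta_p = Xp @ beta
    eta_b = Xb @ beta
    smooth = -float(eta_p.mean()) + float(logsumexp(eta_b) - np.log(len(eta_b)))
    return smooth + float(reg @ np.abs(beta))


def _smooth_value_grad(beta, Xp, Xb):
    eta_p = Xp @ beta
    eta_b = Xb @ beta
    lse = logsumexp(eta_b)
    q = np.exp(eta_b - lse)
    value = -float(eta_p.mean()) + float(lse - np.log(len(eta_b)))
    grad = -Xp.mean(axis=0) + q @ Xb
    return value, grad, q


def _smooth_value(beta, Xp, Xb):
    return -float((Xp @ beta).mean()) + float(logsumexp(Xb @ beta) - np.log(Xb.shape[0]))


def _prox_step(point, f_point, g_point, step, reg, Xp, Xb):
    """One backtracked proximal-gradient step from ``point``."""
    while True:
        cand = np.sign(point - step * g_point) * np.maximum(
            np.abs(point - step * g_point) - step * reg, 0.0
        )
        delta = cand - point
        f_cand = _smooth_value(cand, Xp, Xb)
        if f_cand <= f_point + g_point @ delta + 0.5 * (delta @ delta) / step + 1e-12:
            return cand, f_cand, step
        step *= 0.5
        if step < 1e-15:
            raise FittingError("proximal line search collapsed")


def _kkt_violation(grad, beta, reg):
    viol_zero = np.maximum(np.abs(grad) - reg, 0.0)[beta == 0]
    viol_active = np.abs(grad + reg * np.sign(beta))[beta != 0]
    return max(viol_zero.max(initial=0.0), viol_active.max(initial=0.0))


def _mfista(beta0, Xp, Xb, reg, max_iter, kkt_tol):
    """Monotone FISTA: accelerated proximal gradient with an ISTA safeguard.

    The safeguard takes a plain proximal step from the incumbent whenever the
    accelerated candidate would raise the objective, so the objective value
    is nonincreasing across iterations; termination is on the lasso KKT
    conditions.
    """
    x = beta0
    y = x.copy()
    obj_x = _smooth_value(x, Xp, Xb) + float(reg @ np.abs(x))
    t_mom = 1.0
    step = 1.0
    worst = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        f_y, g_y, _ = _smooth_value_grad(y, Xp, Xb)
        z, f_z, step = _prox_step(y, f_y, g_y, step, reg, Xp, Xb)
        obj_z = f_z + float(reg @ np.abs(z))
        if obj_z <= obj_x:
            x_new, obj_new = z, obj_z
        else:
            f_x, g_x, _ = _smooth_value_grad(x, Xp, Xb)
            z2, f_z2, step = _prox_step(x, f_x, g_x, step, reg, Xp, Xb)
            x_new, obj_new = z2, f_z2 + float(reg @ np.abs(z2))
            if obj_new > obj_x + 1e-15:
                x_new, obj_new = x, obj_x  # cannot improve: stay put
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        y = x_new + ((t_mom - 1.0) / t_new) * (x_new - x)
        x, obj_x, t_mom = x_new, obj_new, t_new
        step *= 1.2

        if n_iter % 5 == 0 or n_iter == max_iter:
            _, g, _ = _smooth_value_grad(x, Xp, Xb)
            worst = _kkt_violation(g, x, reg)
            if worst <= kkt_tol:
                break
    x, obj_x = _active_set_polish(x, Xp, Xb, reg, obj_x)
    _, g, _ = _smooth_value_grad(x, Xp, Xb)
    worst = _kkt_violation(g, x, reg)
    return x, obj_x, n_iter, worst


def _active_set_polish(beta, Xp, Xb, reg, obj, max_newton=30):
    """Newton refinement on the active coordinates with signs held fixed.

    Proximal gradient identifies the active set and signs quickly but closes
    the last distance to the optimum slowly when features are correlated
    (hinge bases especially).  On the fixed orthant the problem is smooth, so
    a few damped Newton steps reach machine precision; steps that would flip
    a sign or raise the objective are rejected, keeping the overall descent
    monotone.
    """
    active = np.nonzero(beta)[0]
    if len(active) == 0:
        return beta, obj
    signs = np.sign(beta[active])
    Xpa, Xba = Xp[:, active], Xb[:, active]
    rega = reg[active]
    b = beta[active].copy()
    for _ in range(max_newton):
        eta_b = Xba @ b
        lse = logsumexp(eta_b)
        q = np.exp(eta_b - lse)
        grad = -Xpa.mean(axis=0) + q @ Xba + rega * signs
        mu = q @ Xba
        H = (Xba * q[:, None]).T @ Xba - np.outer(mu, mu)
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        f0 = -float((Xpa @ b).mean()) + float(lse - np.log(len(eta_b))) + float(rega @ (signs * b))
        improved = False
        while t > 1e-6:
            cand = b - t * step
            if np.any(np.sign(cand) * signs < 0):  # sign flip: shrink
                t *= 0.5
                continue
            fc = (
                -float((Xpa @ cand).mean())
                + float(logsumexp(Xba @ cand) - np.log(Xba.shape[0]))
                + float(rega @ (signs * cand))
            )
            if fc <= f0 + 1e-15:
                b, improved = cand, True
                break
            t *= 0.5
        if not improved or np.max(np.abs(t * step)) < 1e-14:
            break
    out = beta.copy()
    out[active] = b
    new_obj = maxent_objective(out, Xp, Xb, reg)
    if new_obj <= obj + 1e-15:
        return out, new_obj
    return beta, obj


def fit_maxent(
    presence: pd.DataFrame,
    background: pd.DataFrame,
    spec: FeatureSpec = FeatureSpec(),
    variables: Sequence[str] | None = None,
    max_iter: int = 20_000,
    kkt_tol: float = 1e-7,
    min_presence_warn: int = 10,
    add_samples_to_background: bool = True,
) -> MaxentModel:
    """Fit the penalized Maxent model to presence and background rows.

    ``presence`` and ``background`` are DataFrames carrying one column per
    covariate; ``variables`` defaults to every shared numeric column.
    Normalization constants come from the combined training sample.  By the
    reference Maxent convention the presence samples are added to the
    background for the density's normalization (this also keeps the
    penalized objective bounded when a feature fully separates the classes).
    The optimizer is monotone accelerated proximal gradient; convergence is
    declared when the lasso KKT conditions hold within ``kkt_tol``.
    """
    if len(background) == 0:
        raise FittingError("no background rows")
    if len(presence) == 0:
        raise FittingError("no presence rows")
    if variables is None:
        bookkeeping = {"label", "year_bp", "row", "col", "lon", "lat", "context_id"}
        variables = [
            c
            for c in presence.columns
            if c not in bookkeeping
            and c in background.columns
            and np.issubdtype(presence[c].dtype, np.number)
        ]
    variables = list(variables)
    if len(presence) < min_presence_warn:
        warnings.warn(f"only {len(presence)} presences; Maxent fits may be unstable")

    combined = pd.concat([presence[variables], background[variables]], ignore_index=True)
    normalization = {
        v: (float(combined[v].min()), float(combined[v].max())) for v in variables
    }
    training_means = {v: float(combined[v].mean()) for v in variables}

    Xp, meta = build_features(presence, variables, spec, normalization)
    Xb, _ = build_features(background, variables, spec, normalization)
    if add_samples_to_background:
        Xb = np.vstack([Xb, Xp])
    reg = regularization_weights(Xp, meta, spec.rm)

    beta, obj, n_iter, worst = _mfista(
        np.zeros(Xp.shape[1]), Xp, Xb, reg, max_iter=max_iter, kkt_tol=kkt_tol
    )
    if worst > kkt_tol:
        warnings.warn(
            f"Maxent fit reached max_iter={max_iter} with KKT violation {worst:.2e}"
        )

    eta_b = Xb @ beta
    log_norm = float(logsumexp(eta_b))
    q = np.exp(eta_b - log_norm)
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return MaxentModel(
        spec=spec,
        variables=variables,
        normalization=normalization,
        training_means=training_means,
        meta=meta,
        coef=beta,
        reg=reg,
        log_norm=log_norm,
        entropy=entropy,
        n_presence=len(presence),
        n_background=Xb.shape[0],  # size of the normalization set
        n_iter=n_iter,
        objective=obj,
    )


def predict(model: MaxentModel, rows: pd.DataFrame, transform: str = "logistic") -> np.ndarray:
    """Model output for new rows: ``raw``, ``logistic`` or ``cloglog``.

    Raw values are the Gibbs density normalized over the training background
    (they sum to 1 there).  The logistic and cloglog transforms use the
    training-entropy convention with default prevalence 0.5, so a null model
    scores 0.5 everywhere under the logistic transform.
    """
    eta = model.linear_score(rows)
    log_raw = eta - model.log_norm
    if transform == "raw":
        return np.exp(log_raw)
    s = np.exp(np.minimum(model.entropy + log_raw, 700.0))  # e^H * raw
    if transform == "logistic":
        return s / (1.0 + s)
    if transform == "cloglog":
        return 1.0 - np.exp(-s)
    raise ValueError(f"unknown transform {transform!r}")


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    auc: float
    tss: float
    kappa: float
    omission: float
    aicc: float
    n_nonzero: int
    threshold: float


def auc_score(pres_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outscores random background)."""
    pres_scores = np.asarray(pres_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    n1, n0 = len(pres_scores), len(bg_scores)
    if n1 == 0 or n0 == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([pres_scores, bg_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def confusion_rates(
    pres_scores: np.ndarray, bg_scores: np.ndarray, threshold: float
) -> tuple[float, float, float, float]:
    """(TP, FN, TN, FP) counts at a threshold (score >= threshold = presence)."""
    tp = float(np.sum(pres_scores >= threshold))
    fn = float(len(pres_scores) - tp)
    tn = float(np.sum(bg_scores < threshold))
    fp = float(len(bg_scores) - tn)
    return tp, fn, tn, fp


def tss_kappa(tp: float, fn: float, tn: float, fp: float) -> tuple[float, float]:
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    tss = tpr + tnr - 1.0
    n = tp + fn + tn + fp
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    return tss, kappa


def youden_threshold(pres_scores: np.ndarray, bg_scores: np.ndarray) -> float:
    """Observed-score threshold maximizing TPR + TNR; ties break low."""
    cands = np.unique(np.concatenate([pres_scores, bg_scores]))
    best_t, best_j = float(cands[0]), -np.inf
    for t in cands:
        tp, fn, tn, fp = confusion_rates(pres_scores, bg_scores, t)
        tss, _ = tss_kappa(tp, fn, tn, fp)
        if tss > best_j + 1e-12:
            best_j, best_t = tss, float(t)
    return best_t


def omission_threshold(train_pres_scores: np.ndarray, rule: str = "or10p") -> float:
    """Training-presence threshold: 10th percentile (or10p) or minimum (mtp)."""
    scores = np.asarray(train_pres_scores, dtype=float)
    if rule == "or10p":
        return float(np.quantile(scores, 0.10))
    if rule == "mtp":
        return float(scores.min())
    raise ValueError(f"unknown omission rule {rule!r}")


def aicc_score(model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame) -> float:
    """Small-sample AIC from the presence likelihood of the raw density.

    lnL sums log(raw) at the presences with raw normalized over the full
    background; K counts nonzero coefficients; n is the presence count.
    Undefined (NaN) when n <= K + 1.
    """
    K = model.n_nonzero
    n = len(presence)
    if n - K - 1 <= 0:
        return float("nan")
    eta_p = model.linear_score(presence)
    eta_b = model.linear_score(background)
    lnl = float(np.sum(eta_p - logsumexp(eta_b)))
    return -2.0 * lnl + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def evaluate(
    pres_scores: np.ndarray,
    bg_scores: np.ndarray,
    threshold: float | None = None,
    omit_threshold: float | None = None,
    aicc: float = float("nan"),
    n_nonzero: int = 0,
) -> EvalMetrics:
    """Threshold-dependent and threshold-free metrics for one score split.

    ``threshold`` defaults to the Youden-optimal cut over the observed
    scores; ``omit_threshold`` (the training-derived omission cut) defaults
    to the same threshold when not supplied.
    """
    pres_scores = np.asarray(pres_scores, dtype=float)
    bg_scores = np.asarray(bg_scores, dtype=float)
    if threshold is None:
        threshold = youden_threshold(pres_scores, bg_scores)
    tp, fn, tn, fp = confusion_rates(pres_scores, bg_scores, threshold)
    tss, kappa = tss_kappa(tp, fn, tn, fp)
    cut = threshold if omit_threshold is None else omit_threshold
    omission = float(np.mean(pres_scores < cut))
    return EvalMetrics(
        auc=auc_score(pres_scores, bg_scores),
        tss=tss,
        kappa=kappa,
        omission=omission,
        aicc=aicc,
        n_nonzero=n_nonzero,
        threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# tuning-grid cross-validation and selection
# ---------------------------------------------------------------------------

def default_tuning_grid(rms: Sequence[float] = (1, 2, 3, 4, 5),
                        classes: Sequence[str] = FEATURE_CLASSES,
                        hinge_knots: int = 15) -> list[FeatureSpec]:
    return [FeatureSpec(feature_class=c, hinge_knots=hinge_knots, rm=float(r))
            for r in rms for c in classes]


@dataclass
class SelectionResult:
    grid: pd.DataFrame            # one row per candidate with fold-mean metrics
    selected: FeatureSpec
    model: MaxentModel            # full-data refit of the winner
    trace: list[str] = field(default_factory=list)
    omission_rule: str = "or10p"


def cross_validate_select(
    table: pd.DataFrame,
    grid: Sequence[FeatureSpec] | None = None,
    folds: int = 10,
    seed: int = 0,
    variables: Sequence[str] | None = None,
    omission_rule: str = "or10p",
) -> SelectionResult:
    """Score a tuning grid by k-fold CV and select the final model.

    Presences are partitioned into random folds (background shared by all
    folds).  Per candidate: AICc from the full-data fit; mean test AUC and
    mean test omission (at the training or10p threshold) across folds.
    Selection: candidates with delta-AICc < 2, then lowest mean omission,
    then highest mean AUC; residual ties go to the lower RM and the simpler
    feature class.
    """
    from .sampling import split_presence_background

    if grid is None:
        grid = default_tuning_grid()
    grid = list(grid)
    if not grid:
        raise ValueError("empty tuning grid")
    pres, bg = split_presence_background(table)
    if variables is None:
        skip = {"label", "year_bp", "row", "col", "lon", "lat", "context_id"}
        variables = [c for c in table.columns
                     if c not in skip and np.issubdtype(table[c].dtype, np.number)]
    variables = list(variables)
    n_pres = len(pres)
    if n_pres < folds:
        raise ValueError(f"{n_pres} presences cannot be split into {folds} folds")

    rng = np.random.default_rng(seed)
    fold_id = rng.permutation(np.arange(n_pres) % folds)

    rows = []
    full_models = {}
    for ci, spec in enumerate(grid):
        full = fit_maxent(pres, bg, spec, variables=variables, kkt_tol=1e-6)
        full_models[ci] = full
        aicc = aicc_score(full, pres, bg)

        fold_auc, fold_om = [], []
        for f in range(folds):
            train = pres[fold_id != f]
            test = pres[fold_id == f]
            if len(test) == 0 or len(train) == 0:
                continue
            m = fit_maxent(train, bg, spec, variables=variables, kkt_tol=1e-5,
                           min_presence_warn=0)
            bg_scores = predict(m, bg, "raw")
            test_scores = predict(m, test, "raw")
            train_scores = predict(m, train, "raw")
            cut = omission_threshold(train_scores, omission_rule)
            fold_auc.append(auc_score(test_scores, bg_scores))
            fold_om.append(float(np.mean(test_scores < cut)))
        rows.append({
            "candidate": ci,
            "rm": spec.rm,
            "feature_class": spec.feature_class,
            "aicc": aicc,
            "mean_auc": float(np.mean(fold_auc)),
            "sd_auc": float(np.std(fold_auc, ddof=1)) if len(fold_auc) > 1 else 0.0,
            "mean_omission": float(np.mean(fold_om)),
            "n_nonzero": full.n_nonzero,
        })
    res = pd.DataFrame(rows)
    finite = res["aicc"].dropna()
    best_aicc = float(finite.min()) if len(finite) else float("nan")
    res["delta_aicc"] = res["aicc"] - best_aicc

    trace = []
    pool = res[res["delta_aicc"] < 2.0]
    if pool.empty:  # every AICc undefined: fall back to the whole grid
        pool = res
        trace.append("AICc screen: no candidate with finite AICc; screen skipped")
    else:
        trace.append(
            f"AICc screen: {len(pool)}/{len(res)} candidates with delta-AICc < 2"
        )
    min_om = pool["mean_omission"].min()
    pool = pool[np.isclose(pool["mean_omission"], min_om)]
    trace.append(f"omission screen: {len(pool)} candidate(s) at mean omission {min_om:.4f}")
    max_auc = pool["mean_auc"].max()
    pool = pool[np.isclose(pool["mean_auc"], max_auc)]
    trace.append(f"AUC tie-break: {len(pool)} candidate(s) at mean AUC {max_auc:.4f}")
    class_order = {c: i for i, c in enumerate(FEATURE_CLASSES)}
    pool = pool.assign(_c=pool["feature_class"].map(class_order)).sort_values(["rm", "_c"])
    winner = int(pool.iloc[0]["candidate"])
    spec = grid[winner]
    trace.append(f"selected: RM={spec.rm:g}, features={spec.feature_class}")

    return SelectionResult(
        grid=res.drop(columns=["candidate"]),
        selected=spec,
        model=full_models[winner],
        trace=trace,
        omission_rule=omission_rule,
    )


# ---------------------------------------------------------------------------
# interpretation: contributions, response curves, niche envelope
# ---------------------------------------------------------------------------

def training_gain(model: MaxentModel, presence: pd.DataFrame, background: pd.DataFrame,
                  coef: np.ndarray | None = None) -> float:
    """Mean presence log-likelihood gain over the uniform null model."""
    beta = model.coef if coef is None else coef
    Xp, _ = build_features(presence, model.variables, model.spec, model.normalization)
    Xb, _ = build_features(background, model.variables, model.spec, model.normalization)
    return float((Xp @ beta).mean() - (logsumexp(Xb @ beta) - np.log(len(Xb))))


def variable_contribution(
    model: MaxentModel,
    table: pd.DataFrame,
    method: str = "both",
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-variable importance, normalized to sum to 100 percent.

    ``permutation``: mean AUC drop when a variable's column is shuffled;
    ``drop``: training-gain loss when the variable's coefficients are zeroed.
    Both are surrogates for the path-gain "percent contribution" heuristic of
    the reference Maxent GUI, whose bookkeeping is not reconstructible from
    the fitted coefficients.
    """
    from .sampling import split_presence_background

    pres, bg = split_presence_background(table)
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"variable": model.variables})

    if method in ("drop", "both"):
        g_full = training_gain(model, pres, bg)
        losses = []
        for v in model.variables:
            beta = model.coef.copy()
            for j, f in enumerate(model.meta):
                if f.variable == v:
                    beta[j] = 0.0
            losses.append(max(g_full - training_gain(model, pres, bg, coef=beta), 0.0))
        losses = np.asarray(losses)
        total = losses.sum()
        out["drop_pct"] = 100.0 * losses / total if total > 0 else 100.0 / len(losses)

    if method in ("permutation", "both"):
        base_auc = auc_score(predict(model, pres, "raw"), predict(model, bg, "raw"))
        drops = []
        for v in model.variables:
            accum = 0.0
            both = pd.concat([pres, bg], ignore_index=True)
            n_p = len(pres)
            for _ in range(n_permutations):
                perm = both.copy()
                perm[v] = rng.permutation(perm[v].values)
                scores = predict(model, perm, "raw")
                accum += base_auc - auc_score(scores[:n_p], scores[n_p:])
            drops.append(max(accum / n_permutations, 0.0))
        drops = np.asarray(drops)
        total = drops.sum()
        out["permutation_pct"] = 100.0 * drops / total if total > 0 else 100.0 / len(drops)
    return out


def response_curve(
    model: MaxentModel,
    variable: str,
    others_at: str = "mean",
    grid: int = 100,
    transform: str = "logistic",
) -> pd.DataFrame:
    """Suitability along one variable's training range, others held constant."""
    if variable not in model.variables:
        raise KeyError(f"{variable!r} is not a model variable")
    lo, hi = model.normalization[variable]
    xs = np.linspace(lo, hi, grid)
    rows = {}
    for v in model.variables:
        if v == variable:
            rows[v] = xs
        elif others_at == "mean":
            rows[v] = np.full(grid, model.training_means[v])
        elif others_at == "median":
            vlo, vhi = model.normalization[v]
            rows[v] = np.full(grid, 0.5 * (vlo + vhi))
        else:
            raise ValueError("others_at must be 'mean' or 'median'")
    df = pd.DataFrame(rows)
    df["suitability"] = predict(model, df, transform)
    return df[[variable, "suitability"]]


def niche_envelope(
    model: MaxentModel,
    cut: float = 0.5,
    grid: int = 512,
    others_at: str = "mean",
    transform: str = "logistic",
    pair_grid: int = 60,
) -> dict:
    """Fundamental-niche characterization at a suitability cut.

    For each variable: the interval(s) of its response curve exceeding
    ``cut`` (empty list if the response never reaches it), with endpoints
    linearly interpolated at the crossings.  For each variable pair: a 2-D
    suitability surface with the remaining variables at their training means.
    """
    intervals: dict[str, list[tuple[float, float]]] = {}
    for v in model.variables:
        curve = response_curve(model, v, others_at=others_at, grid=grid, transform=transform)
        x = curve[v].values
        y = curve["suitability"].values
        above = y >= cut
        segs: list[tuple[float, float]] = []
        i = 0
        while i < len(x):
            if above[i]:
                j = i
                while j + 1 < len(x) and above[j + 1]:
                    j += 1
                lo = x[i]
                if i > 0:
                    lo = float(np.interp(cut, [y[i - 1], y[i]], [x[i - 1], x[i]]))
                hi = x[j]
                if j + 1 < len(x):
                    hi = float(np.interp(cut, [y[j + 1], y[j]], [x[j + 1], x[j]]))
                segs.append((float(lo), float(hi)))
                i = j + 1
            else:
                i += 1
        intervals[v] = segs

    surfaces = {}
    for a in range(len(model.variables)):
        for b in range(a + 1, len(model.variables)):
            va, vb = model.variables[a], model.variables[b]
            la, ha = model.normalization[va]
            lb, hb = model.normalization[vb]
            xa = np.linspace(la, ha, pair_grid)
            xb = np.linspace(lb, hb, pair_grid)
            A, B = np.meshgrid(xa, xb, indexing="ij")
            rows = {va: A.ravel(), vb: B.ravel()}
            for v in model.variables:
                if v not in (va, vb):
                    rows[v] = np.full(A.size, model.training_means[v])
            z = predict(model, pd.DataFrame(rows), transform).reshape(pair_grid, pair_grid)
            surfaces[(va, vb)] = {"x": xa, "y": xb, "suitability": z}
    return {"cut": cut, "intervals": intervals, "surfaces": surfaces}
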