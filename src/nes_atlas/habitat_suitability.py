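"""Presence-background maximum-entropy habitat modelling for species groups.

The model assigns every cell x a probability p(x) proportional to
exp(lambda . f(x)), where f are features derived from the environmental
covariates (linear and quadratic terms of each continuous covariate scaled
to [0, 1] over the background, one indicator per substrate class, and
optional hinge terms).  The weights maximise the L1-regularised
log-likelihood of the presence cells against the background

    L(lambda) = mean_presence(lambda . f) - log Z(lambda) - sum_j beta_j |lambda_j|

which is the maximum-entropy distribution subject to the constraint that
model feature means stay within beta_j of the presence-sample means.  The
optimiser is cyclic coordinate ascent with proximal (soft-threshold)
updates and backtracking, which makes the per-covariate objective gains
available for the percent-contribution diagnostic.

The logistic output rescales the raw probabilities with a default
prevalence tau = 0.5 so that a completely uninformative model scores 0.5
everywhere: logistic = tau e^H p / (1 - tau + tau e^H p), with H the
entropy of the raw distribution over the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.metrics import roc_auc_score

from .environment import GEOLOGY_NAMES, EnvLayerStack
from .grids import GridSpec, Raster
from .hotspot_grid import HotspotGrid

__all__ = [
    "MaxentParams",
    "MaxentFeatures",
    "MaxentModel",
    "covariate_table",
    "presence_cells",
    "split_presences",
    "sample_background",
    "fit_maxent",
    "fit_group_model",
    "model_auc",
    "predict_surface",
    "evaluate_auc",
    "variable_importance",
    "marginal_response",
    "compare_hotspots_to_suitability",
]

CONTINUOUS_COVARIATES = ("elevation", "slope", "rainfall", "temperature")


@dataclass(frozen=True)
class MaxentParams:
    """Fitting defaults mirror the standard desktop configuration: at most
    10000 background cells, iteration cap 500, convergence 1e-5, an L1
    regularisation multiplier of 1, prevalence 0.5."""

    beta_multiplier: float = 1.0
    tau: float = 0.5
    max_iter: int = 500
    tol: float = 1e-5
    n_background: int = 10000
    test_fraction: float = 0.25
    hinge: bool = False
    n_hinge_knots: int = 5
    seed: int = 0


# ---------------------------------------------------------------------------
# Covariate and feature construction


def covariate_table(stack: EnvLayerStack, cells: np.ndarray) -> pd.DataFrame:
    """Covariate values for an array of (ix, iy) cell indices."""
    cells = np.asarray(cells, dtype=int)
    out = {"ix": cells[:, 0], "iy": cells[:, 1]}
    for name, layer in stack.layers().items():
        out[name] = layer.values[cells[:, 1], cells[:, 0]].astype(float)
    return pd.DataFrame(out)


def land_cells(stack: EnvLayerStack) -> np.ndarray:
    """(n, 2) array of (ix, iy) for cells valid in every layer."""
    valid = np.ones(stack.grid.shape, dtype=bool)
    for layer in stack.layers().values():
        valid &= layer.mask_valid()
    iy, ix = np.nonzero(valid)
    return np.column_stack([ix, iy])


def presence_cells(records: pd.DataFrame, grid: GridSpec, binary: bool = False) -> np.ndarray:
    """Map records to grid cells.

    Default mode keeps one entry per (species, cell) — cells rich in species
    appear once per species, weighting the model toward multi-species cells.
    ``binary=True`` collapses to simple presence/absence per cell, the
    sensitivity mode that removes that weighting.
    """
    ix, iy = grid.cell_index(records["x"].to_numpy(), records["y"].to_numpy())
    inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
    df = pd.DataFrame(
        {"species_id": records["species_id"].to_numpy()[inside], "ix": ix[inside], "iy": iy[inside]}
    )
    subset = ["ix", "iy"] if binary else ["species_id", "ix", "iy"]
    df = df.sort_values(subset, kind="mergesort").drop_duplicates(subset=subset)
    return df[["ix", "iy"]].to_numpy()


def split_presences(cells: np.ndarray, test_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random train/test split of presence cells."""
    rng = np.random.default_rng(seed)
    n = len(cells)
    n_test = int(round(n * test_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError("test split would be empty; adjust test_fraction or sample size")
    perm = rng.permutation(n)
    return cells[perm[n_test:]], cells[perm[:n_test]]


def sample_background(stack: EnvLayerStack, n: int, seed: int) -> np.ndarray:
    """Random background sample of land cells, without replacement, capped at n."""
    cand = land_cells(stack)
    if len(cand) <= n:
        return cand
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(cand), size=n, replace=False)
    return cand[np.sort(pick)]


@dataclass
class MaxentFeatures:
    """Feature expansion fit on the background covariate table.

    Continuous covariates are min-max scaled over the background (and
    clamped to [0, 1] at prediction time); each contributes a linear and a
    quadratic feature, plus optional left-hinge features at background
    quantile knots.  The substrate covariate contributes one indicator per
    class seen in the background.  Constant covariates are dropped.
    """

    lo: dict = field(default_factory=dict)
    hi: dict = field(default_factory=dict)
    geo_classes: list = field(default_factory=list)
    hinge_knots: dict = field(default_factory=dict)
    names: list = field(default_factory=list)
    covariate_of: list = field(default_factory=list)
    dropped: list = field(default_factory=list)

    @classmethod
    def fit(cls, background: pd.DataFrame, hinge: bool = False, n_hinge_knots: int = 5):
        self = cls()
        for cov in CONTINUOUS_COVARIATES:
            v = background[cov].to_numpy(dtype=float)
            lo, hi = float(v.min()), float(v.max())
            if hi - lo <= 0:
                self.dropped.append(cov)
                continue
            self.lo[cov], self.hi[cov] = lo, hi
            self.names += [f"{cov}:linear", f"{cov}:quadratic"]
            self.covariate_of += [cov, cov]
            if hinge:
                knots = np.quantile(v, np.linspace(0.1, 0.9, n_hinge_knots))
                self.hinge_knots[cov] = [(k - lo) / (hi - lo) for k in knots]
                for i in range(len(knots)):
                    self.names.append(f"{cov}:hinge{i}")
                    self.covariate_of.append(cov)
        geo = background["geology"].to_numpy()
        self.geo_classes = sorted(np.unique(geo).tolist())
        if len(self.geo_classes) > 1:
            for c in self.geo_classes:
                self.names.append(f"geology:is_{GEOLOGY_NAMES.get(c, c)}")
                self.covariate_of.append("geology")
        else:
            self.geo_classes = []
            self.dropped.append("geology")
        return self

    @property
    def covariates(self) -> list[str]:
        seen = []
        for c in self.covariate_of:
            if c not in seen:
                seen.append(c)
        return seen

    def transform(self, table: pd.DataFrame, clamp_report: dict | None = None) -> np.ndarray:
        cols = []
        for cov in CONTINUOUS_COVARIATES:
            if cov not in self.lo:
                continue
            v = table[cov].to_numpy(dtype=float)
            s = (v - self.lo[cov]) / (self.hi[cov] - self.lo[cov])
            if clamp_report is not None:
                clamp_report[cov] = int(((s < 0) | (s > 1)).sum())
            s = np.clip(s, 0.0, 1.0)
            cols += [s, s**2]
            for knot in self.hinge_knots.get(cov, []):
                denom = max(1.0 - knot, 1e-9)
                cols.append(np.clip((s - knot) / denom, 0.0, 1.0))
        if self.geo_classes:
            geo = table["geology"].to_numpy()
            for c in self.geo_classes:
                cols.append((geo == c).astype(float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class MaxentModel:
    features: MaxentFeatures
    lam: np.ndarray
    params: MaxentParams
    log_z: float            # log sum of exp(eta) over the background sample
    entropy: float          # entropy of the raw distribution over the background
    presence_mean: np.ndarray
    beta: np.ndarray
    n_presence: int
    n_background: int
    objective_trace: list = field(default_factory=list)
    gain_by_covariate: dict = field(default_factory=dict)
    n_iter: int = 0
    converged: bool = False

    def eta(self, X: np.ndarray) -> np.ndarray:
        return X @ self.lam

    def raw(self, X: np.ndarray) -> np.ndarray:
        """Raw output: exp(eta) normalised by the background partition sum."""
        return np.exp(self.eta(X) - self.log_z)

    def logistic(self, X: np.ndarray) -> np.ndarray:
        tau = self.params.tau
        q = np.exp(self.entropy + self.eta(X) - self.log_z)
        return tau * q / (1.0 - tau + tau * q)

    def percent_contribution(self) -> dict:
        total = sum(max(g, 0.0) for g in self.gain_by_covariate.values())
        if total <= 0:
            return {c: 0.0 for c in self.gain_by_covariate}
        return {c: 100.0 * max(g, 0.0) / total for c, g in self.gain_by_covariate.items()}


def _objective(lam, Xp_mean, Xb, beta):
    eta_b = Xb @ lam
    return float(Xp_mean @ lam - logsumexp(eta_b) + np.log(len(Xb)) - beta @ np.abs(lam))


def fit_maxent(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    features: MaxentFeatures,
    params: MaxentParams = MaxentParams(),
) -> MaxentModel:
    """Maximise the L1-penalised presence log-likelihood by cyclic proximal
    coordinate ascent.

    One iteration sweeps every feature once: the coordinate gradient is the
    gap between the presence mean and the current model mean of that
    feature, the curvature is the model variance, and the L1 penalty enters
    through soft-thresholding, with step backtracking to guarantee the
    objective never decreases.  Stops when an entire sweep improves the
    objective by less than ``params.tol``.
    """
    m, J = X_presence.shape
    if m < 1:
        raise ValueError("no presence cells")
    Xb = np.asarray(X_background, dtype=float)
    Xp_mean = X_presence.mean(axis=0)
    pres_var = X_presence.var(axis=0)
    beta = params.beta_multiplier * np.sqrt(np.maximum(pres_var, 1e-6) / m)

    lam = np.zeros(J)
    eta_b = Xb @ lam
    obj = _objective(lam, Xp_mean, Xb, beta)
    if not np.isfinite(obj):
        raise FloatingPointError("non-finite objective at initialisation")
    trace = [obj]
    gain: dict[str, float] = {c: 0.0 for c in features.covariates}
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        sweep_start = obj
        for j in range(J):
            w = np.exp(eta_b - logsumexp(eta_b))
            fj = Xb[:, j]
            ef = float(w @ fj)
            grad = Xp_mean[j] - ef
            var = max(float(w @ fj**2) - ef**2, 1e-8)
            step = lam[j] + grad / var
            thr = beta[j] / var
            new = np.sign(step) * max(abs(step) - thr, 0.0)
            delta = new - lam[j]
            if delta == 0.0:
                continue
            # backtrack until the penalised objective does not decrease
            for _ in range(30):
                cand = lam[j] + delta
                cand_eta = eta_b + delta * fj
                cand_obj = (
                    Xp_mean @ lam + Xp_mean[j] * delta
                    - logsumexp(cand_eta) + np.log(len(Xb))
                    - beta @ np.abs(lam) + beta[j] * (abs(lam[j]) - abs(cand))
                )
                if cand_obj >= obj - 1e-12:
                    break
                delta *= 0.5
            else:
                continue
            if cand_obj < obj:
                continue
            if not np.isfinite(cand_obj):
                raise FloatingPointError(f"non-finite objective updating feature {features.names[j]}")
            lam[j] = cand
            eta_b = cand_eta
            gain[features.covariate_of[j]] += cand_obj - obj
            obj = float(cand_obj)
        trace.append(obj)
        if obj - sweep_start < params.tol:
            converged = True
            break
    log_z = float(logsumexp(eta_b))
    p = np.exp(eta_b - log_z)
    entropy = float(-(p * np.log(np.maximum(p, 1e-300))).sum())
    return MaxentModel(
        features=features,
        lam=lam,
        params=params,
        log_z=log_z,
        entropy=entropy,
        presence_mean=Xp_mean,
        beta=beta,
        n_presence=m,
        n_background=len(Xb),
        objective_trace=trace,
        gain_by_covariate=gain,
        n_iter=it,
        converged=converged,
    )


def fit_group_model(
    stack: EnvLayerStack,
    records: pd.DataFrame,
    params: MaxentParams = MaxentParams(),
    binary: bool = False,
):
    """Convenience pipeline: presence cells -> split -> background -> fit.

    Returns (model, info) where info carries the cell sets and feature
    matrices needed for evaluation.
    """
    cells = presence_cells(records, stack.grid, binary=binary)
    if len(cells) < 10:
        raise ValueError("need at least 10 presence cells")
    train, test = split_presences(cells, params.test_fraction, params.seed)
    bg = sample_background(stack, params.n_background, params.seed + 1)
    feats = MaxentFeatures.fit(covariate_table(stack, bg), params.hinge, params.n_hinge_knots)
    cov_train = covariate_table(stack, train)
    cov_test = covariate_table(stack, test)
    cov_bg = covariate_table(stack, bg)
    Xp = feats.transform(cov_train)
    Xb = feats.transform(cov_bg)
    model = fit_maxent(Xp, Xb, feats, params)
    info = {
        "train_cells": train, "test_cells": test, "background_cells": bg,
        "cov_train": cov_train, "cov_test": cov_test, "cov_bg": cov_bg,
        "X_train": Xp, "X_test": feats.transform(cov_test), "X_bg": Xb,
    }
    return model, info


# ---------------------------------------------------------------------------
# Prediction and evaluation


def predict_surface(model: MaxentModel, stack: EnvLayerStack, cutoff: float = 0.75):
    """Logistic suitability surface on the stack grid.

    Covariates outside the training range are clamped to it and counted in
    the clamping report.  Returns (raster, high_mask_raster, clamp_report).
    """
    cells = land_cells(stack)
    table = covariate_table(stack, cells)
    clamp_report: dict = {}
    X = model.features.transform(table, clamp_report=clamp_report)
    suit = model.logistic(X)
    vals = np.full(stack.grid.shape, np.nan)
    vals[cells[:, 1], cells[:, 0]] = suit
    surface = Raster(vals, stack.grid, nodata=np.nan)
    mask = np.zeros(stack.grid.shape, dtype=float)
    mask[cells[:, 1], cells[:, 0]] = (suit > cutoff).astype(float)
    return surface, Raster(mask, stack.grid, nodata=-1.0), clamp_report


def evaluate_auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank AUC of presence scores against background scores (ties at 0.5)."""
    if len(scores_presence) == 0:
        raise ValueError("empty presence score set")
    y = np.concatenate([np.ones(len(scores_presence)), np.zeros(len(scores_background))])
    s = np.concatenate([scores_presence, scores_background])
    return float(roc_auc_score(y, s))


def model_auc(model: MaxentModel, X_presence: np.ndarray, X_background: np.ndarray) -> float:
    return evaluate_auc(model.eta(X_presence), model.eta(X_background))


def variable_importance(
    model: MaxentModel,
    cov_presence: pd.DataFrame,
    cov_background: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent contribution and permutation importance per covariate.

    Permutation importance permutes a covariate's values jointly across the
    pooled presence + background table, rebuilds features, and measures the
    drop in training AUC (averaged over seeded permutations, normalised to
    sum to 100 over covariates)."""
    feats = model.features
    rng = np.random.default_rng(seed)
    X_p = feats.transform(cov_presence)
    X_b = feats.transform(cov_background)
    auc0 = evaluate_auc(model.eta(X_p), model.eta(X_b))
    n_p = len(cov_presence)
    drops = {}
    for cov in feats.covariates:
        dd = []
        for _ in range(n_permutations):
            pooled = np.concatenate(
                [cov_presence[cov].to_numpy(), cov_background[cov].to_numpy()]
            )
            pooled = pooled[rng.permutation(len(pooled))]
            cp = cov_presence.copy()
            cb = cov_background.copy()
            cp[cov] = pooled[:n_p]
            cb[cov] = pooled[n_p:]
            auc = evaluate_auc(model.eta(feats.transform(cp)), model.eta(feats.transform(cb)))
            dd.append(max(auc0 - auc, 0.0))
        drops[cov] = float(np.mean(dd))
    total = sum(drops.values())
    contrib = model.percent_contribution()
    rows = []
    for cov in feats.covariates:
        rows.append(
            {
                "covariate": cov,
                "percent_contribution": contrib.get(cov, 0.0),
                "auc_drop": drops[cov],
                "permutation_importance": 100.0 * drops[cov] / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def marginal_response(
    cov_presence: pd.DataFrame,
    cov_background: pd.DataFrame,
    covariate: str,
    params: MaxentParams = MaxentParams(),
    n_grid: int = 101,
) -> dict:
    """Single-covariate response: refit using only that covariate's features.

    Returns the suitability curve over the covariate's background range and
    a direction label (increasing / decreasing / bimodal / flat) from the
    sign changes of the smoothed derivative.
    """
    feats = MaxentFeatures.fit(cov_background, hinge=params.hinge, n_hinge_knots=params.n_hinge_knots)
    keep = [j for j, c in enumerate(feats.covariate_of) if c == covariate]
    if not keep:
        raise ValueError(f"covariate {covariate!r} has no features (constant over background?)")
    Xp = feats.transform(cov_presence)[:, keep]
    Xb = feats.transform(cov_background)[:, keep]
    sub = MaxentFeatures()
    sub.names = [feats.names[j] for j in keep]
    sub.covariate_of = [covariate] * len(keep)
    sub.lo, sub.hi = dict(feats.lo), dict(feats.hi)
    sub.geo_classes = feats.geo_classes if covariate == "geology" else []
    sub.hinge_knots = {covariate: feats.hinge_knots.get(covariate, [])} if covariate in feats.hinge_knots else {}
    model = fit_maxent(Xp, Xb, sub, params)
    if covariate == "geology":
        grid_vals = np.array(feats.geo_classes, dtype=float)
        table = pd.DataFrame({"geology": grid_vals})
        for c in CONTINUOUS_COVARIATES:
            table[c] = 0.0
    else:
        grid_vals = np.linspace(feats.lo[covariate], feats.hi[covariate], n_grid)
        table = pd.DataFrame({covariate: grid_vals})
        for c in CONTINUOUS_COVARIATES:
            if c != covariate:
                table[c] = 0.0
        table["geology"] = feats.geo_classes[0] if feats.geo_classes else 0.0
    Xg = feats.transform(table)[:, keep]
    curve = model.logistic(Xg)
    if covariate == "geology":
        direction = "categorical"
    else:
        k = max(n_grid // 10, 1)
        kern = np.ones(k) / k
        smooth = np.convolve(curve, kern, mode="valid")
        dv = np.diff(smooth)
        eps = 1e-4
        sign = np.sign(dv) * (np.abs(dv) > eps)
        sign = sign[sign != 0]
        changes = int((np.diff(sign) != 0).sum()) if len(sign) else 0
        if curve.max() - curve.min() < 0.05:
            direction = "flat"
        elif changes == 0:
            direction = "increasing" if (len(sign) and sign[0] > 0) else "decreasing"
        elif changes == 1 and len(sign) and sign[0] > 0:
            direction = "unimodal"
        else:
            direction = "bimodal"
    return {"grid": grid_vals, "suitability": curve, "direction": direction, "model": model}


def compare_hotspots_to_suitability(
    surface: Raster, hg: HotspotGrid, cutoff: float = 0.75
) -> pd.DataFrame:
    """Cross-classify hotspot cells against high-suitability habitat.

    The suitability surface is resampled to the hotspot grid by the mean of
    the fine cells under each hotspot cell; every hotspot-grid cell then
    falls in one of four classes.  The 'high-suitability only' class is the
    candidate set of under-sampled sites worth new field work.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValueError("cutoff must be in (0, 1)")
    from .grids import resample_to

    if surface.grid.cell != hg.grid.cell:
        nodata = -9999.0
        vals = np.where(np.isfinite(surface.values), surface.values, nodata)
        coarse = resample_to(Raster(vals, surface.grid, nodata=nodata), hg.grid.cell)
    else:
        coarse = surface
    rows = []
    for iy in range(hg.grid.ny):
        for ix in range(hg.grid.nx):
            if ix >= coarse.grid.nx or iy >= coarse.grid.ny:
                continue
            s = coarse.values[iy, ix]
            if not np.isfinite(s) or s == coarse.nodata:
                continue
            hot = bool(hg.hpne_flags[iy, ix])
            high = bool(s > cutoff)
            cls = (
                "hotspot_and_suitable" if hot and high
                else "hotspot_only" if hot
                else "suitable_only" if high
                else "neither"
            )
            rows.append({"ix": ix, "iy": iy, "suitability": float(s), "hotspot": hot,
                         "high_suitability": high, "class": cls})
    return pd.DataFrame(rows)
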