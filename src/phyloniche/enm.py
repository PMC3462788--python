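"""Minimal maximum-entropy ecological niche model over gridded environments.

The engine is a transparent exponential-family (Gibbs) model: per retained
layer a standardized linear and quadratic feature, a coefficient vector fit by
maximizing the regularized log-likelihood

    mean_presences(lambda . f)  -  log mean_background(exp(lambda . f))  -  beta ||lambda||_1

which is convex; the raw prediction is the normalized density exp(lambda . f)
over unmasked cells (sums to 1) and the logistic form is the usual monotone
transform  tau e^H q / (1 + tau e^H q)  with tau = 0.5 and H the entropy of
the raw distribution.  Hinge/threshold features, clamping and the replicate
scheduling of full Maxent are deliberately not reproduced — the goal is a
fast, refittable suitability surface for overlap randomization tests.

``MaxentModel`` follows the scikit-learn estimator protocol (``fit``,
``predict``, ``get_params``/``set_params``, trailing-underscore fitted
attributes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from ._errors import DegenerateInputError, ValidationError

__all__ = [
    "EnvStack",
    "OccurrenceSet",
    "SuitabilitySurface",
    "MaxentModel",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_occurrences",
    "write_occurrences",
    "thin_occurrences",
    "prune_correlated_layers",
    "fit_enm",
    "predict_suitability",
    "auc_from_scores",
    "evaluate_auc",
    "train_test_split",
    "lpt_threshold",
    "replicate_auc",
    "jackknife_importance",
    "read_env_stack",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class EnvStack:
    """Multi-layer gridded environment sharing one geotransform and mask.

    ``grids`` has shape (n_layers, nrows, ncols); row 0 is the *northern* edge
    (raster convention).  ``mask`` is True on valid (non-nodata) cells.
    """

    names: list[str]
    grids: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    mask: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 3 or self.grids.shape[0] != len(self.names):
            raise ValidationError("grids must be (n_layers, nrows, ncols)")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grids.shape[1:]:
            raise ValidationError("mask shape mismatch")
        if self.cellsize <= 0:
            raise ValidationError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.grids.shape[1]

    @property
    def ncols(self) -> int:
        return self.grids.shape[2]

    def layer(self, name: str) -> np.ndarray:
        return self.grids[self.names.index(name)]

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise ValidationError(f"missing layers: {missing}")
        idx = [self.names.index(n) for n in names]
        return EnvStack(list(names), self.grids[idx], self.xllcorner,
                        self.yllcorner, self.cellsize, self.mask, self.nodata)

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) for a point; None if off-grid.  Boundary points go to
        the higher-index cell (floor rule on the geotransform)."""
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((lat - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xllcorner + (col + 0.5) * self.cellsize
        lat = self.yllcorner + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    @classmethod
    def from_layers(cls, layers: dict[str, np.ndarray], xllcorner=0.0,
                    yllcorner=0.0, cellsize=1.0, mask=None, nodata=-9999.0):
        names = list(layers)
        grids = np.stack([np.asarray(layers[n], dtype=float) for n in names])
        if mask is None:
            mask = np.ones(grids.shape[1:], dtype=bool)
        return cls(names, grids, xllcorner, yllcorner, cellsize, mask, nodata)


@dataclass
class OccurrenceSet:
    """Presence points as (lon, lat) decimal degrees."""

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SuitabilitySurface:
    """Per-cell suitability; ``form`` is 'raw' (sums to 1) or 'logistic'."""

    values: np.ndarray
    mask: np.ndarray
    form: str = "raw"

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def as_density(self) -> "SuitabilitySurface":
        """Renormalize over unmasked cells to sum 1 (identity on raw form)."""
        v = np.where(self.mask, np.clip(self.values, 0.0, None), 0.0)
        total = v[self.mask].sum()
        if total <= 0:
            raise DegenerateInputError("surface has zero total suitability")
        out = np.zeros_like(v)
        out[self.mask] = v[self.mask] / total
        return SuitabilitySurface(out, self.mask, "raw")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read one ESRI ASCII grid.  Returns (values, header dict); nodata cells
    are NaN in the returned array."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValidationError(f"ASCII grid header missing '{key}' in {path}")
    nodata = header.get("nodata_value", -9999.0)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    for line in lines[i:]:
        if not line.strip():
            continue
        vals = [float(v) for v in line.split()]
        rows.append(vals)
    if len(rows) != nrows:
        raise ValidationError(
            f"{path}: expected {nrows} data rows, found {len(rows)}"
        )
    for r, vals in enumerate(rows):
        if len(vals) != ncols:
            raise ValidationError(
                f"{path}: row {r + 1} has {len(vals)} values, expected {ncols}"
            )
    arr = np.asarray(rows, dtype=float)
    arr[arr == nodata] = np.nan
    header["nodata_value"] = nodata
    return arr, header


def write_ascii_grid(path, values: np.ndarray, xllcorner: float, yllcorner: float,
                     cellsize: float, nodata: float = -9999.0) -> None:
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        out = np.where(np.isnan(values), nodata, values)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_env_stack(paths: dict[str, str]) -> EnvStack:
    """Read several ASCII grids (name -> path) into one EnvStack; all must
    share shape and geotransform; the mask is the intersection of valid cells
    (required identical across layers up to shared nodata)."""
    names, arrays, headers = [], [], []
    for name, path in paths.items():
        arr, hdr = read_ascii_grid(path)
        names.append(name)
        arrays.append(arr)
        headers.append(hdr)
    ref = headers[0]
    for name, hdr in zip(names, headers):
        for key in _HEADER_KEYS:
            if not np.isclose(hdr[key], ref[key]):
                raise ValidationError(f"layer '{name}' disagrees on header '{key}'")
    grids = np.stack(arrays)
    mask = ~np.any(np.isnan(grids), axis=0)
    grids = np.where(np.isnan(grids), 0.0, grids)
    return EnvStack(names, grids, ref["xllcorner"], ref["yllcorner"],
                    ref["cellsize"], mask, ref.get("nodata_value", -9999.0))


def read_occurrences(path, source: str = "") -> OccurrenceSet:
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "lon" not in cols or "lat" not in cols:
        raise ValidationError(f"{path}: occurrence CSV must have 'lon,lat' header")
    df.columns = cols
    return OccurrenceSet(df[["lon", "lat"]].to_numpy(), source or str(path))


def write_occurrences(occ: OccurrenceSet, path) -> None:
    pd.DataFrame(occ.points, columns=["lon", "lat"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# preprocessing


def thin_occurrences(occ: OccurrenceSet, min_sep: float = 0.1) -> OccurrenceSet:
    """Greedy spatial thinning in input order: keep a point iff it lies at
    least ``min_sep`` degrees (Euclidean) from every already-kept point."""
    if min_sep < 0:
        raise ValidationError("min_sep must be non-negative")
    kept: list[np.ndarray] = []
    # small tolerance so points at exactly min_sep survive float round-off
    eps = 1e-9 * max(min_sep, 1.0)
    for p in occ.points:
        if all(np.hypot(*(p - q)) >= min_sep - eps for q in kept):
            kept.append(p)
    return OccurrenceSet(np.array(kept).reshape(-1, 2), occ.source)


def prune_correlated_layers(
    env: EnvStack,
    r_threshold: float = 0.8,
    priority: list[str] | None = None,
) -> tuple[EnvStack, list[tuple[str, str, float]]]:
    """Iteratively drop one layer of every pair with |Pearson r| > threshold.

    ``priority`` lists layers from most to least preferred (default: input
    order); for each offending pair the lower-priority layer is dropped.
    Returns (pruned stack, [(kept, dropped, r), ...]).  Constant layers have
    undefined r and are treated as uncorrelated (with a warning).
    """
    if len(env.names) == 0:
        raise ValidationError("empty stack")
    priority = list(priority) if priority is not None else list(env.names)
    rank = {n: priority.index(n) if n in priority else len(priority) for n in env.names}
    active = list(env.names)
    dropped: list[tuple[str, str, float]] = []
    data = {n: env.layer(n)[env.mask] for n in env.names}
    for n, v in data.items():
        if np.std(v) == 0:
            warnings.warn(f"layer '{n}' is constant; correlation undefined, kept")
    while True:
        best = None
        for i in range(len(active)):
            for j in range(i + 1, len(active)):
                a, b = active[i], active[j]
                if np.std(data[a]) == 0 or np.std(data[b]) == 0:
                    continue
                r = float(np.corrcoef(data[a], data[b])[0, 1])
                if abs(r) > r_threshold and (best is None or abs(r) > abs(best[2])):
                    best = (a, b, r)
        if best is None:
            break
        a, b, r = best
        loser = a if rank[a] > rank[b] else b
        keeper = b if loser == a else a
        active.remove(loser)
        dropped.append((keeper, loser, r))
    return env.subset(active), dropped


# ---------------------------------------------------------------------------
# the estimator


class MaxentModel:
    """Exponential-family niche model with standardized linear+quadratic
    features and L1 regularization.

    Parameters
    ----------
    n_background : number of background cells sampled uniformly without
        replacement from the unmasked grid (all cells if fewer available).
    reg : L1 penalty weight beta (>= 0).
    tol : convergence tolerance on the objective.
    max_iter : optimizer iteration cap.
    min_presences : minimum distinct presence points required on the grid.
    include_presences_in_background : add presence cells to the background
        sample (full-Maxent behaviour); off by default.
    seed : RNG seed for the background sample.
    """

    def __init__(self, n_background: int = 10_000, reg: float = 0.1,
                 tol: float = 1e-5, max_iter: int = 500, min_presences: int = 5,
                 include_presences_in_background: bool = False,
                 seed: int | None = None):
        self.n_background = n_background
        self.reg = reg
        self.tol = tol
        self.max_iter = max_iter
        self.min_presences = min_presences
        self.include_presences_in_background = include_presences_in_background
        self.seed = seed

    # -- sklearn protocol ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_background": self.n_background, "reg": self.reg, "tol": self.tol,
            "max_iter": self.max_iter, "min_presences": self.min_presences,
            "include_presences_in_background": self.include_presences_in_background,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "MaxentModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- features -----------------------------------------------------------
    @staticmethod
    def _raw_features(env: EnvStack, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return env.grids[:, rows, cols].T  # (n_points, n_layers)

    def _featurize(self, raw: np.ndarray) -> np.ndarray:
        z = (raw - self.feature_means_) / self.feature_stds_
        return np.concatenate([z, z**2], axis=1)

    # -- fitting ------------------------------------------------------------
    def fit(self, occ: OccurrenceSet, env: EnvStack,
            background_rc: np.ndarray | None = None) -> "MaxentModel":
        """Fit to presence points over an environment stack.

        ``background_rc`` optionally fixes the background sample as an
        (n, 2) array of (row, col) — used by the randomization tests so the
        null replicates share the observed fit's background.
        """
        rows, cols, n_dropped = rasterize_presences(occ, env)
        if n_dropped:
            warnings.warn(f"{n_dropped} presence point(s) off-grid or masked; dropped")
        if len(rows) < self.min_presences:
            raise DegenerateInputError(
                f"only {len(rows)} usable presences (< {self.min_presences})"
            )
        rng = np.random.default_rng(self.seed)
        if background_rc is None:
            valid = np.argwhere(env.mask)
            k = min(self.n_background, len(valid))
            background_rc = valid[rng.choice(len(valid), size=k, replace=False)]
        background_rc = np.asarray(background_rc)
        if self.include_presences_in_background:
            background_rc = np.concatenate(
                [background_rc, np.column_stack([rows, cols])]
            )

        self.layer_names_ = list(env.names)
        bg_raw = self._raw_features(env, background_rc[:, 0], background_rc[:, 1])
        self.feature_means_ = bg_raw.mean(axis=0)
        stds = bg_raw.std(axis=0)
        self.feature_stds_ = np.where(stds > 0, stds, 1.0)
        self.background_rc_ = background_rc

        F_bg = self._featurize(bg_raw)
        F_pres = self._featurize(self._raw_features(env, rows, cols))
        self.presence_rc_ = np.column_stack([rows, cols])

        coef, info = _fit_gibbs(F_pres, F_bg, self.reg, self.tol, self.max_iter)
        self.coef_ = coef
        self.n_iter_ = info["nit"]
        self.converged_ = info["converged"]
        if not self.converged_:
            warnings.warn(
                f"optimizer hit max_iter={self.max_iter}; "
                f"final gradient norm {info['grad_norm']:.3g}"
            )
        # entropy of the raw distribution over the background sample
        s = F_bg @ coef
        logp = s - logsumexp(s)
        self.entropy_ = float(-np.sum(np.exp(logp) * logp))
        return self

    # -- prediction ---------------------------------------------------------
    def predict(self, env: EnvStack, form: str = "logistic") -> SuitabilitySurface:
        """Suitability over an environment stack with the same layer names."""
        missing = [n for n in self.layer_names_ if n not in env.names]
        if missing:
            raise ValidationError(f"environment missing layer(s): {missing}")
        env = env.subset(self.layer_names_)
        rows, cols = np.nonzero(env.mask)
        F = self._featurize(self._raw_features(env, rows, cols))
        s = F @ self.coef_
        log_raw = s - logsumexp(s)
        raw = np.exp(log_raw)
        grid = np.zeros(env.mask.shape)
        if form == "raw":
            grid[rows, cols] = raw
            return SuitabilitySurface(grid, env.mask.copy(), "raw")
        if form == "logistic":
            scaled = 0.5 * np.exp(self.entropy_) * raw
            grid[rows, cols] = scaled / (1.0 + scaled)
            return SuitabilitySurface(grid, env.mask.copy(), "logistic")
        raise ValueError(f"unknown form: {form!r}")

    def score_points(self, env: EnvStack, rc: np.ndarray) -> np.ndarray:
        """Unnormalized log-suitability lambda.f at (row, col) points —
        rank-equivalent to both raw and logistic outputs."""
        env = env.subset(self.layer_names_)
        F = self._featurize(self._raw_features(env, rc[:, 0], rc[:, 1]))
        return F @ self.coef_

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({
            "params": self.get_params(),
            "layer_names": self.layer_names_,
            "coef": self.coef_.tolist(),
            "feature_means": self.feature_means_.tolist(),
            "feature_stds": self.feature_stds_.tolist(),
            "entropy": self.entropy_,
            "background_rc": self.background_rc_.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "MaxentModel":
        blob = json.loads(text)
        model = cls(**blob["params"])
        model.layer_names_ = list(blob["layer_names"])
        model.coef_ = np.asarray(blob["coef"])
        model.feature_means_ = np.asarray(blob["feature_means"])
        model.feature_stds_ = np.asarray(blob["feature_stds"])
        model.entropy_ = blob["entropy"]
        model.background_rc_ = np.asarray(blob["background_rc"])
        model.converged_ = True
        return model


def _fit_gibbs(F_pres: np.ndarray, F_bg: np.ndarray, reg: float,
               tol: float, max_iter: int) -> tuple[np.ndarray, dict]:
    """Maximize mean(F_pres @ l) - log mean(exp(F_bg @ l)) - reg*||l||_1 via
    the positive/negative split trick (keeps the problem smooth for L-BFGS)."""
    d = F_pres.shape[1]
    mean_pres = F_pres.mean(axis=0)
    log_nbg = np.log(len(F_bg))

    def negloglik_grad(lam: np.ndarray) -> tuple[float, np.ndarray]:
        s = F_bg @ lam
        lse = logsumexp(s)
        w = np.exp(s - lse)
        nll = -(mean_pres @ lam) + (lse - log_nbg)
        grad = -mean_pres + w @ F_bg
        return nll, grad

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = x[:d], x[d:]
        lam = u - v
        nll, g = negloglik_grad(lam)
        val = nll + reg * (u.sum() + v.sum())
        return val, np.concatenate([g + reg, -g + reg])

    x0 = np.zeros(2 * d)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=[(0.0, None)] * (2 * d),
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    lam = res.x[:d] - res.x[d:]
    _, g = negloglik_grad(lam)
    return lam, {"nit": res.nit, "converged": bool(res.success),
                 "grad_norm": float(np.linalg.norm(g))}


def rasterize_presences(occ: OccurrenceSet, env: EnvStack) -> tuple[np.ndarray, np.ndarray, int]:
    """Map points to unmasked (row, col); returns (rows, cols, n_dropped)."""
    rows, cols, dropped = [], [], 0
    for lon, lat in occ.points:
        rc = env.cell_of(lon, lat)
        if rc is None or not env.mask[rc]:
            dropped += 1
            continue
        rows.append(rc[0])
        cols.append(rc[1])
    return np.asarray(rows, dtype=int), np.asarray(cols, dtype=int), dropped


# ---------------------------------------------------------------------------
# functional wrappers and evaluation


def fit_enm(occ: OccurrenceSet, env: EnvStack, n_background: int = 10_000,
            reg: float = 0.1, max_iter: int = 500, tol: float = 1e-5,
            seed: int | None = None, **kw) -> MaxentModel:
    return MaxentModel(n_background=n_background, reg=reg, tol=tol,
                       max_iter=max_iter, seed=seed, **kw).fit(occ, env)


def predict_suitability(model: MaxentModel, env: EnvStack,
                        form: str = "logistic") -> SuitabilitySurface:
    return model.predict(env, form)


def auc_from_scores(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 0.5."""
    pos = np.asarray(presence_scores, dtype=float)
    neg = np.asarray(background_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("need at least one presence and one background score")
    if np.ptp(np.concatenate([pos, neg])) == 0:
        warnings.warn("constant predictions; AUC degenerates to 0.5")
        return 0.5
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def evaluate_auc(model: MaxentModel, env: EnvStack, occ_test: OccurrenceSet,
                 background_rc: np.ndarray | None = None) -> float:
    """Test AUC of the model: presences vs background cells (the model's own
    background sample by default)."""
    rows, cols, dropped = rasterize_presences(occ_test, env)
    if dropped:
        warnings.warn(f"{dropped} test point(s) off-grid; dropped")
    if len(rows) == 0:
        raise ValidationError("no usable test presences")
    if background_rc is None:
        background_rc = model.background_rc_
    pos = model.score_points(env, np.column_stack([rows, cols]))
    neg = model.score_points(env, np.asarray(background_rc))
    return auc_from_scores(pos, neg)


def train_test_split(occ: OccurrenceSet, train_fraction: float = 0.25,
                     seed: int | None = None) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random partition into (train, test) at the stated training fraction."""
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must lie in (0, 1)")
    n = len(occ)
    if n < 2:
        raise ValidationError("need at least 2 points to split")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValidationError(
            f"train_fraction={train_fraction} leaves an empty partition for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (OccurrenceSet(occ.points[perm[:n_train]], occ.source),
            OccurrenceSet(occ.points[perm[n_train:]], occ.source))


def lpt_threshold(surface: SuitabilitySurface, env: EnvStack,
                  occ_train: OccurrenceSet) -> tuple[float, np.ndarray]:
    """Lowest-presence-threshold binarization.

    threshold = min predicted value over training presences; a cell is
    'suitable' iff value >= threshold, so every training presence is suitable.
    Returns (threshold, boolean suitable map over the grid)."""
    rows, cols, _ = rasterize_presences(occ_train, env)
    if len(rows) == 0:
        raise ValidationError("no training presences on the grid")
    thr = float(surface.values[rows, cols].min())
    suitable = (surface.values >= thr) & surface.mask
    return thr, suitable


def replicate_auc(occ: OccurrenceSet, env: EnvStack, k: int = 10,
                  train_fraction: float = 0.25, seed: int | None = None,
                  **fit_settings) -> tuple[float, list[float]]:
    """Mean test AUC over k fits with different random train/test splits
    (the usual replicate-averaged model evaluation).  Returns
    (mean AUC, per-replicate AUCs)."""
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(k):
        train, test = train_test_split(occ, train_fraction,
                                       seed=int(rng.integers(2**31)))
        model = MaxentModel(**{**fit_settings, "seed": int(rng.integers(2**31))})
        model.fit(train, env)
        aucs.append(evaluate_auc(model, env, test))
    return float(np.mean(aucs)), aucs


def jackknife_importance(occ: OccurrenceSet, env: EnvStack,
                         train_fraction: float = 0.25, seed: int | None = None,
                         **fit_settings) -> dict[str, dict[str, float | None]]:
    """Leave-one-out / only-one variable importance on a fixed split and
    background: {layer: {'only': AUC, 'without': AUC}} (None on fit failure).
    """
    if len(env.names) < 2:
        raise ValidationError("jackknife needs at least 2 layers")
    rng = np.random.default_rng(seed)
    train, test = train_test_split(occ, train_fraction, seed=int(rng.integers(2**31)))
    valid = np.argwhere(env.mask)
    n_bg = min(fit_settings.get("n_background", 10_000), len(valid))
    background_rc = valid[rng.choice(len(valid), size=n_bg, replace=False)]

    def _auc(layer_names: list[str]) -> float | None:
        sub = env.subset(layer_names)
        try:
            model = MaxentModel(**{**fit_settings, "seed": int(rng.integers(2**31))})
            model.fit(train, sub, background_rc=background_rc)
            return evaluate_auc(model, sub, test, background_rc)
        except Exception as exc:
            warnings.warn(f"jackknife fit failed for {layer_names}: {exc}")
            return None

    out: dict[str, dict[str, float | None]] = {}
    for name in env.names:
        out[name] = {
            "only": _auc([name]),
            "without": _auc([n for n in env.names if n != name]),
        }
    return out
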