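"""Niche-overlap metrics and the identity / background randomization tests.

Overlap between two suitability surfaces p and q (normalized to sum 1 over the
shared unmasked region) is measured by

* Schoener's D  = 1 - 1/2 * sum_i |p_i - q_i|
* Hellinger  I  = 1 - 1/2 * sum_i (sqrt(p_i) - sqrt(q_i))^2

both in [0, 1], equal to 1 iff p == q and 0 on disjoint supports.

The identity test pools the two occurrence sets, randomly repartitions them
into the original sample sizes, refits both niche models and recomputes D and
I per pseudoreplicate; the null hypothesis of niche identity is rejected when
the observed overlap is *lower* than the null distribution (one-tailed).  The
background test instead redraws one taxon's points uniformly from that
taxon's accessible region and asks whether the observed overlap is higher or
lower than expected from the available environment (two-tailed).  All refits
share the observed fits' background sample and optimizer settings so that
null variation reflects only the point assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._errors import DegenerateInputError, ValidationError
from .enm import (
    EnvStack,
    MaxentModel,
    OccurrenceSet,
    SuitabilitySurface,
    rasterize_presences,
)

__all__ = [
    "OverlapResult",
    "schoener_D",
    "hellinger_I",
    "empirical_p",
    "identity_test",
    "background_test",
    "background_test_pair",
    "background_region_mask",
]


@dataclass
class OverlapResult:
    observed_D: float
    observed_I: float
    null_D: np.ndarray
    null_I: np.ndarray
    p_D: float
    p_I: float
    tail: str
    direction: str = ""
    n_retries: int = 0


def _shared_densities(pX: SuitabilitySurface, pY: SuitabilitySurface):
    if pX.values.shape != pY.values.shape:
        raise ValidationError("surfaces have different grid shapes")
    shared = pX.mask & pY.mask
    if not shared.any():
        raise ValidationError("surfaces share no unmasked cells")
    if not (np.array_equal(pX.mask, shared) and np.array_equal(pY.mask, shared)):
        warnings.warn("masks differ; overlap computed on their intersection")

    def _norm(s: SuitabilitySurface) -> np.ndarray:
        v = np.clip(s.values[shared], 0.0, None)
        total = v.sum()
        if total <= 0:
            raise DegenerateInputError("surface has zero suitability on shared region")
        return v / total

    return _norm(pX), _norm(pY)


def schoener_D(pX: SuitabilitySurface, pY: SuitabilitySurface) -> float:
    """D = 1 - 1/2 sum |p - q| over the shared unmasked region."""
    p, q = _shared_densities(pX, pY)
    return float(1.0 - 0.5 * np.abs(p - q).sum())


def hellinger_I(pX: SuitabilitySurface, pY: SuitabilitySurface) -> float:
    """I = 1 - 1/2 sum (sqrt p - sqrt q)^2 over the shared unmasked region."""
    p, q = _shared_densities(pX, pY)
    return float(1.0 - 0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def empirical_p(observed: float, null_values, tail: str = "lower") -> float:
    """Add-one-rank empirical p-value.

    lower: Pr(null <= observed); upper: Pr(null >= observed);
    two: 2 * min(lower, upper), capped at 1.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    n = null.size
    lower = (np.sum(null <= observed + 1e-12) + 1.0) / (n + 1.0)
    upper = (np.sum(null >= observed - 1e-12) + 1.0) / (n + 1.0)
    if tail == "lower":
        return float(min(lower, 1.0))
    if tail == "upper":
        return float(min(upper, 1.0))
    if tail == "two":
        return float(min(2.0 * min(lower, upper), 1.0))
    raise ValueError(f"unknown tail: {tail!r}")


def _fit_and_density(points: np.ndarray, env: EnvStack, background_rc: np.ndarray,
                     fit_settings: dict, seed: int) -> SuitabilitySurface:
    model = MaxentModel(**{**fit_settings, "seed": seed})
    model.fit(OccurrenceSet(points), env, background_rc=background_rc)
    return model.predict(env, form="raw")


def _shared_background(env: EnvStack, fit_settings: dict, rng) -> np.ndarray:
    valid = np.argwhere(env.mask)
    k = min(fit_settings.get("n_background", 10_000), len(valid))
    return valid[rng.choice(len(valid), size=k, replace=False)]


def identity_test(
    occA: OccurrenceSet,
    occB: OccurrenceSet,
    env: EnvStack,
    fit_settings: dict | None = None,
    n_reps: int = 100,
    seed: int | None = None,
    max_retries: int = 3,
) -> OverlapResult:
    """Niche-identity (equivalency) randomization test.

    Pools both occurrence sets; each pseudoreplicate randomly reassigns the
    pooled points into groups of the original sizes, refits both models on
    the same background, and recomputes D and I.  One-tailed: identity is
    rejected when the observed overlap falls below the null distribution.
    """
    fit_settings = dict(fit_settings or {})
    rng = np.random.default_rng(seed)
    for name, occ in (("A", occA), ("B", occB)):
        rows, _, _ = rasterize_presences(occ, env)
        if len(rows) == 0:
            raise ValidationError(f"occurrence set {name} has no usable points")

    background_rc = _shared_background(env, fit_settings, rng)
    sA = _fit_and_density(occA.points, env, background_rc, fit_settings,
                          int(rng.integers(2**31)))
    sB = _fit_and_density(occB.points, env, background_rc, fit_settings,
                          int(rng.integers(2**31)))
    obs_D, obs_I = schoener_D(sA, sB), hellinger_I(sA, sB)

    pooled = np.concatenate([occA.points, occB.points])
    nA = len(occA.points)
    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)
    retries = 0
    for r in range(n_reps):
        for attempt in range(max_retries + 1):
            perm = rng.permutation(len(pooled))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    s1 = _fit_and_density(pooled[perm[:nA]], env, background_rc,
                                          fit_settings, int(rng.integers(2**31)))
                    s2 = _fit_and_density(pooled[perm[nA:]], env, background_rc,
                                          fit_settings, int(rng.integers(2**31)))
                null_D[r], null_I[r] = schoener_D(s1, s2), hellinger_I(s1, s2)
                break
            except (DegenerateInputError, ValidationError):
                retries += 1
                if attempt == max_retries:
                    raise
    return OverlapResult(
        observed_D=obs_D, observed_I=obs_I, null_D=null_D, null_I=null_I,
        p_D=empirical_p(obs_D, null_D, "lower"),
        p_I=empirical_p(obs_I, null_I, "lower"),
        tail="lower", direction="identity", n_retries=retries,
    )


def background_region_mask(
    occ: OccurrenceSet, env: EnvStack, margin: float = 1.0,
    rectangle: tuple[float, float, float, float] | None = None,
    region_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of the 'accessible region' for background draws.

    Priority: explicit ``region_mask``; else ``rectangle`` =
    (lonmin, lonmax, latmin, latmax); else the bounding rectangle of the
    points buffered by ``margin`` degrees.  Always intersected with the grid
    mask."""
    if region_mask is not None:
        region = np.asarray(region_mask, dtype=bool)
        if region.shape != env.mask.shape:
            raise ValidationError("region mask shape mismatch")
        out = region & env.mask
    else:
        if rectangle is None:
            lons, lats = occ.points[:, 0], occ.points[:, 1]
            rectangle = (lons.min() - margin, lons.max() + margin,
                         lats.min() - margin, lats.max() + margin)
        lonmin, lonmax, latmin, latmax = rectangle
        rows, cols = np.indices(env.mask.shape)
        lon = env.xllcorner + (cols + 0.5) * env.cellsize
        lat = env.yllcorner + (env.nrows - rows - 0.5) * env.cellsize
        out = (env.mask & (lon >= lonmin) & (lon <= lonmax)
               & (lat >= latmin) & (lat <= latmax))
    if not out.any():
        raise ValidationError("background region contains no unmasked cells")
    return out


def background_test(
    occA: OccurrenceSet,
    occB: OccurrenceSet,
    env: EnvStack,
    fit_settings: dict | None = None,
    n_reps: int = 100,
    seed: int | None = None,
    margin: float = 1.0,
    rectangle: tuple[float, float, float, float] | None = None,
    region_mask: np.ndarray | None = None,
) -> OverlapResult:
    """Background randomization test (direction: A's model vs B's background).

    The observed overlap of ENM(A) and ENM(B) is compared with overlaps of
    ENM(A) against models fit to |B| points drawn uniformly from B's
    accessible region; two-tailed (both 'more similar than expected' and
    'more divergent' are meaningful outcomes).
    """
    fit_settings = dict(fit_settings or {})
    rng = np.random.default_rng(seed)
    region = background_region_mask(occB, env, margin, rectangle, region_mask)
    region_cells = np.argwhere(region)
    nB_rows, _, _ = rasterize_presences(occB, env)
    nB = len(nB_rows)
    if nB == 0:
        raise ValidationError("occurrence set B has no usable points")
    if len(region_cells) < nB:
        raise ValidationError(
            f"background region ({len(region_cells)} cells) smaller than |B| = {nB}"
        )

    background_rc = _shared_background(env, fit_settings, rng)
    sA = _fit_and_density(occA.points, env, background_rc, fit_settings,
                          int(rng.integers(2**31)))
    sB = _fit_and_density(occB.points, env, background_rc, fit_settings,
                          int(rng.integers(2**31)))
    obs_D, obs_I = schoener_D(sA, sB), hellinger_I(sA, sB)

    null_D = np.empty(n_reps)
    null_I = np.empty(n_reps)
    for r in range(n_reps):
        cells = region_cells[rng.choice(len(region_cells), size=nB, replace=True)]
        jitter = rng.uniform(0, 1, size=(nB, 2))
        lon = env.xllcorner + (cells[:, 1] + jitter[:, 0]) * env.cellsize
        lat = env.yllcorner + (env.nrows - cells[:, 0] - jitter[:, 1]) * env.cellsize
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_rand = _fit_and_density(np.column_stack([lon, lat]), env,
                                      background_rc, fit_settings,
                                      int(rng.integers(2**31)))
        null_D[r] = schoener_D(sA, s_rand)
        null_I[r] = hellinger_I(sA, s_rand)
    return OverlapResult(
        observed_D=obs_D, observed_I=obs_I, null_D=null_D, null_I=null_I,
        p_D=empirical_p(obs_D, null_D, "two"),
        p_I=empirical_p(obs_I, null_I, "two"),
        tail="two", direction="A_vs_background_of_B",
    )


def background_test_pair(
    occA: OccurrenceSet, occB: OccurrenceSet, env: EnvStack,
    fit_settings: dict | None = None, n_reps: int = 100,
    seed: int | None = None, margin: float = 1.0,
) -> tuple[OverlapResult, OverlapResult]:
    """Run the background test in both directions (A vs B's background, then
    B vs A's background), as two null distributions per comparison."""
    rng = np.random.default_rng(seed)
    ab = background_test(occA, occB, env, fit_settings, n_reps,
                         int(rng.integers(2**31)), margin)
    ba = background_test(occB, occA, env, fit_settings, n_reps,
                         int(rng.integers(2**31)), margin)
    ba.direction = "B_vs_background_of_A"
    return ab, ba
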