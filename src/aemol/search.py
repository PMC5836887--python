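"""Latent-space search: GP Bayesian optimization and the similarity probe.

Bayesian optimization maximizes an objective over a latent box: a Gaussian
process surrogate (squared-exponential kernel, hyperparameters by marginal
likelihood) is fit to the evaluated points, the expected-improvement
acquisition is maximized to pick the next point, and the loop repeats.  The
default budget follows common practice for this task: 100 random starting
points followed by 500 guided iterations.

The similarity probe quantifies latent smoothness around a query molecule:
points are drawn on spheres of growing radius around the query's latent
vector, decoded repeatedly, and the median ECFP6 Tanimoto similarity of the
valid decodes to the query is recorded per distance bin, together with the
fraction of valid decodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel

from . import codec
from .generate import generate
from .qsar import ecfp_fingerprint, tanimoto


def expected_improvement(mu, sigma, best):
    """EI = (mu - best) * Phi(u) + sigma * phi(u), u = (mu - best) / sigma.

    Degenerates to max(mu - best, 0) when sigma = 0.  Vectorized over mu and
    sigma.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    improve = mu - best
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sigma > 0, improve / np.where(sigma > 0, sigma, 1.0), 0.0)
    ei = np.where(
        sigma > 0,
        improve * norm.cdf(u) + sigma * norm.pdf(u),
        np.maximum(improve, 0.0),
    )
    return ei if ei.ndim else float(ei)


@dataclass
class BOTrace:
    """Every evaluated point of one Bayesian-optimization run, in order."""

    points: np.ndarray  # (n_init + n_iter, d)
    scores: np.ndarray  # (n_init + n_iter,)
    n_init: int
    extras: list = field(default_factory=list)  # per-point payloads (if any)

    @property
    def best_score(self) -> float:
        return float(np.max(self.scores))

    @property
    def best_point(self) -> np.ndarray:
        return self.points[int(np.argmax(self.scores))]

    @property
    def cumulative_best(self) -> np.ndarray:
        return np.maximum.accumulate(self.scores)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "iteration": np.arange(len(self.scores)),
                "phase": ["init"] * self.n_init
                + ["bo"] * (len(self.scores) - self.n_init),
                "score": self.scores,
                "best_so_far": self.cumulative_best,
            }
        )
        if self.extras:
            df["payload"] = self.extras
        return df


def _fit_gp(X: np.ndarray, y: np.ndarray, jitter: float) -> GaussianProcessRegressor:
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e2))
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=jitter, normalize_y=True, n_restarts_optimizer=1,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(X, y)
    return gp


def _maximize_ei(gp, best: float, bounds: np.ndarray,
                 rng: np.random.Generator, n_candidates: int = 512,
                 n_refine: int = 3) -> np.ndarray:
    d = bounds.shape[0]
    cand = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_candidates, d))
    mu, sigma = gp.predict(cand, return_std=True)
    ei = expected_improvement(mu, sigma, best)
    order = np.argsort(ei)[::-1]

    def neg_ei(x):
        m, s = gp.predict(x.reshape(1, -1), return_std=True)
        return -float(expected_improvement(m[0], s[0], best))

    best_x = cand[order[0]]
    best_val = -ei[order[0]]
    for start in cand[order[:n_refine]]:
        res = minimize(neg_ei, start, method="L-BFGS-B",
                       bounds=[tuple(b) for b in bounds])
        if res.fun < best_val:
            best_val = res.fun
            best_x = res.x
    return np.clip(best_x, bounds[:, 0], bounds[:, 1])


def bo_search(objective, bounds, n_init: int = 100, n_iter: int = 500,
              rng: np.random.Generator | None = None,
              jitter: float = 1e-6) -> BOTrace:
    """Maximize ``objective`` over a box via GP + expected improvement.

    ``objective(z) -> float`` or ``(float, payload)``; a raised exception at
    a point records score 0 and the search continues.  The first ``n_init``
    evaluations are uniform random in the box, the next ``n_iter`` are
    EI-guided.  Returns the full evaluation trace.
    """
    if n_init <= 0 or n_iter < 0:
        raise ValueError("n_init must be positive and n_iter nonnegative")
    rng = rng or np.random.default_rng(0)
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]

    def safe_eval(z):
        try:
            out = objective(z)
        except Exception:
            return 0.0, None
        if isinstance(out, tuple):
            return float(out[0]), out[1]
        return float(out), None

    points = list(rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_init, d)))
    scores = []
    extras = []
    for z in points:
        s, payload = safe_eval(z)
        scores.append(s)
        extras.append(payload)
    for _ in range(n_iter):
        gp = _fit_gp(np.asarray(points), np.asarray(scores), jitter)
        z_next = _maximize_ei(gp, max(scores), bounds, rng)
        s, payload = safe_eval(z_next)
        points.append(z_next)
        scores.append(s)
        extras.append(payload)
    return BOTrace(
        points=np.asarray(points), scores=np.asarray(scores),
        n_init=n_init, extras=extras,
    )


def random_search(objective, bounds, n_total: int,
                  rng: np.random.Generator | None = None) -> BOTrace:
    """Uniform-random baseline with the same evaluation budget as BO."""
    return bo_search(objective, bounds, n_init=n_total, n_iter=0, rng=rng)


def latent_objective(model, qsar_model, n_samples: int = 500,
                     max_ring: int | None = 8, unique: bool = True,
                     rng: np.random.Generator | None = None):
    """Objective z -> (S(z), consensus SMILES): decode, filter, score."""
    from .qsar import activity_score

    rng = rng or np.random.default_rng(0)

    def objective(z):
        report = generate(model, z, n_samples=n_samples, rng=rng)
        result = activity_score(report, qsar_model, unique=unique,
                                max_ring=max_ring)
        return result.score, report.consensus_smiles

    return objective


def default_bounds(model, gaussian_halfwidth: float = 4.0) -> np.ndarray:
    """Latent search box: the prior's support (uniform) or +/-4 sd (Gaussian)."""
    d = model.latent_dim
    if hasattr(model, "prior_spec") and model.prior_spec().family == "uniform":
        spec = model.prior_spec()
        return np.tile([spec.low, spec.high], (d, 1)).astype(float)
    return np.tile([-gaussian_halfwidth, gaussian_halfwidth], (d, 1)).astype(float)


@dataclass
class ProbeCurve:
    """Distance-binned latent smoothness summary around one query molecule."""

    records: pd.DataFrame  # distance, median_tanimoto, valid_fraction, n_attempts
    raw: pd.DataFrame | None = None  # per-sample log (distance, smiles, valid, tanimoto)


def sphere_point(center: np.ndarray, radius: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Uniform draw on the sphere of given radius around ``center``."""
    g = rng.standard_normal(center.shape)
    nrm = np.linalg.norm(g)
    if nrm == 0:
        return center.copy()
    return center + radius * g / nrm


def similarity_probe(model, query: str, d_max: float = 8.0, step: float = 0.1,
                     points_per_bin: int = 10, samples_per_point: int = 500,
                     rng: np.random.Generator | None = None,
                     keep_raw: bool = False) -> ProbeCurve:
    """Median Tanimoto-to-query and valid fraction vs latent distance.

    For each distance d in 0, step, ..., d_max, ``points_per_bin`` points are
    drawn uniformly on the sphere of radius d around the query's latent
    vector and ``samples_per_point`` sequences are decoded at each, giving
    ``points_per_bin * samples_per_point`` reconstruction attempts per bin.
    """
    if not codec.is_valid_smiles(query):
        raise codec.SmilesParseError(f"query is not a valid SMILES: {query!r}")
    rng = rng or np.random.default_rng(0)
    center = model.latent_of([query])[0]
    query_fp = ecfp_fingerprint(query)
    fp_cache: dict[str, float] = {}

    def sim(s: str) -> float:
        if s not in fp_cache:
            fp_cache[s] = tanimoto(query_fp, ecfp_fingerprint(s))
        return fp_cache[s]

    distances = np.round(np.arange(0.0, d_max + step / 2, step), 10)
    rows = []
    raw_rows = [] if keep_raw else None
    for dist in distances:
        sims: list[float] = []
        n_valid = 0
        for _ in range(points_per_bin):
            z = sphere_point(center, dist, rng)
            rep = generate(model, z, n_samples=samples_per_point, rng=rng)
            for s in rep.samples:
                valid = codec.is_valid_smiles(s)
                t = sim(s) if valid else np.nan
                if valid:
                    n_valid += 1
                    sims.append(t)
                if raw_rows is not None:
                    raw_rows.append(
                        {"distance": dist, "smiles": s, "valid": valid,
                         "tanimoto": t}
                    )
        n_attempts = points_per_bin * samples_per_point
        rows.append(
            {
                "distance": dist,
                "median_tanimoto": float(np.median(sims)) if sims else np.nan,
                "valid_fraction": n_valid / n_attempts,
                "n_attempts": n_attempts,
            }
        )
    records = pd.DataFrame(rows)
    raw = pd.DataFrame(raw_rows) if keep_raw else None
    return ProbeCurve(records=records, raw=raw)
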