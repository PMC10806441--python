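"""Bray-Curtis dissimilarity, NMDS ordination, environmental surfaces.

The community table (presence/absence by default, log-percent as an
alternative) is embedded in two dimensions by nonmetric
multidimensional scaling minimising Kruskal stress-1, and each
environmental covariate is regressed on the ordination plane with a
thin-plate-style penalised radial-basis smooth whose flexibility is
chosen by generalised cross-validation — reporting effective degrees
of freedom, an approximate F and the deviance explained. A Mantel-type
distance-decay diagnostic checks whether nearby samples have more
similar communities (spatial autocorrelation would undermine the
permutation inference upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .envdesign import haversine_km


# ---------------------------------------------------------------------------
# dissimilarities

def bray_curtis(matrix: pd.DataFrame, mode: str = "presence") -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples (rows).

    mode='presence' binarises first (equivalent to Sorensen
    dissimilarity); mode='log' transforms percents with
    log10(1 + x / c), c = half the smallest nonzero value, so zeros
    stay zero and the transform is monotone.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = matrix.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundances must be non-negative")
    if mode == "presence":
        X = (X > 0).astype(float)
    elif mode == "log":
        nz = X[X > 0]
        if nz.size == 0:
            raise ValueError("matrix is all zero")
        c = nz.min() / 2.0
        X = np.log10(1.0 + X / c)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'presence' or 'log'")
    if (X.sum(axis=1) == 0).any():
        empty = matrix.index[X.sum(axis=1) == 0].tolist()
        raise ValueError(f"samples with no taxa: {empty}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# NMDS

def kruskal_stress(coords: np.ndarray, D: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities,
    with disparities from isotonic regression of distances on D."""
    d = pdist(coords)
    delta = squareform(D, checks=False)
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d)
    dhat[order] = iso.fit_transform(np.arange(len(order)), d[order])
    denom = np.sum(d ** 2)
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def classical_mds(D: np.ndarray, k: int = 2) -> np.ndarray:
    """Torgerson metric scaling: eigendecomposition of the doubly
    centred squared dissimilarities; used as a warm start."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)[None, :]


@dataclass
class OrdinationResult:
    coords: pd.DataFrame        # samples x 2
    stress: float               # Kruskal stress-1
    input_mode: str
    converged: bool
    seed: int
    n_restarts: int

    def to_tsv(self, path) -> None:
        out = self.coords.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def nmds(D: pd.DataFrame, seed: int = 0, n_restarts: int = 20,
         max_iter: int = 500, eps: float = 1e-6,
         input_mode: str = "presence") -> OrdinationResult:
    """2-D nonmetric MDS minimising Kruskal stress-1.

    Runs SMACOF with a classical-scaling warm start plus ``n_restarts``
    random starts, keeps the configuration with the lowest stress-1,
    and rotates it to principal axes (centred at the origin).
    """
    Dm = D.to_numpy(dtype=float)
    if not np.allclose(Dm, Dm.T) or np.abs(np.diag(Dm)).max() > 1e-12:
        raise ValueError("D must be a symmetric zero-diagonal dissimilarity matrix")
    candidates = []
    init = classical_mds(Dm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords, _, n_it = smacof(Dm, metric=False, n_components=2, init=init,
                                 n_init=1, max_iter=max_iter, eps=eps,
                                 random_state=seed, normalized_stress=True,
                                 return_n_iter=True)
        candidates.append((coords, n_it))
        for r in range(n_restarts):
            coords, _, n_it = smacof(Dm, metric=False, n_components=2,
                                     n_init=1, max_iter=max_iter, eps=eps,
                                     random_state=seed + 1 + r,
                                     normalized_stress=True, return_n_iter=True)
            candidates.append((coords, n_it))
    scored = [(kruskal_stress(c, Dm), c, n_it) for c, n_it in candidates]
    stress, best, n_it = min(scored, key=lambda t: t[0])
    converged = n_it < max_iter

    # centre and rotate to principal axes (sign fixed for determinism)
    best = best - best.mean(axis=0)
    _, _, Vt = np.linalg.svd(best, full_matrices=False)
    rot = best @ Vt.T
    for j in range(rot.shape[1]):
        if rot[np.argmax(np.abs(rot[:, j])), j] < 0:
            rot[:, j] *= -1
    coords = pd.DataFrame(rot, index=D.index, columns=["NMDS1", "NMDS2"])
    return OrdinationResult(coords=coords, stress=float(stress), input_mode=input_mode,
                            converged=bool(converged), seed=seed, n_restarts=n_restarts)


# ---------------------------------------------------------------------------
# thin-plate surface fits

def _tps_basis(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis phi(r) = r^2 log r (0 at r = 0)."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


def _farthest_point_knots(pts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point subset: start nearest the centroid,
    then repeatedly add the point farthest from the chosen set."""
    n = pts.shape[0]
    if k >= n:
        return np.arange(n)
    centroid = pts.mean(axis=0)
    chosen = [int(np.argmin(((pts - centroid) ** 2).sum(axis=1)))]
    mind = ((pts - pts[chosen[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(mind))
        chosen.append(nxt)
        mind = np.minimum(mind, ((pts - pts[nxt]) ** 2).sum(axis=1))
    return np.array(sorted(chosen))


@dataclass
class SurfaceFit:
    variable: str
    effective_df: float
    f_value: float
    deviance_explained: float
    lambda_gcv: float
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_z: np.ndarray

    def summary_row(self) -> dict:
        return {"variable": self.variable, "est_df": round(self.effective_df, 2),
                "f_value": round(self.f_value, 2),
                "deviance_explained_pct": round(100.0 * self.deviance_explained, 1)}


def fit_surface(coords: pd.DataFrame, z: pd.Series, variable: str = "z",
                n_knots: int = 10, grid_res: int = 30,
                lambdas: np.ndarray | None = None) -> SurfaceFit:
    """Penalised thin-plate-style smooth of ``z`` over the ordination.

    The smooth uses a radial basis phi(r) = r^2 log r at
    min(n - 1, ``n_knots``) farthest-point knots plus an unpenalised
    linear part; the ridge penalty acts on the bending-energy norm of
    the radial coefficients and its weight is chosen by generalised
    cross-validation. Reports effective df (trace of the hat matrix),
    an approximate F statistic and deviance explained = 1 - RSS/TSS.
    """
    pts = coords.to_numpy(dtype=float)
    zv = z.loc[coords.index].to_numpy(dtype=float)
    n = pts.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for a surface fit")
    tss = np.sum((zv - zv.mean()) ** 2)
    scale = pts.std(axis=0).mean()
    if scale == 0:
        raise ValueError("degenerate (constant) ordination coordinates")
    P = pts / scale

    k = min(n - 1, n_knots)
    knot_idx = _farthest_point_knots(P, k)
    knots = P[knot_idx]
    Phi = _tps_basis(np.linalg.norm(P[:, None, :] - knots[None, :, :], axis=2))
    M = np.column_stack([np.ones(n), P, Phi])     # n x (3 + k)
    E = _tps_basis(np.linalg.norm(knots[:, None, :] - knots[None, :, :], axis=2))
    ev, U = np.linalg.eigh(E)
    E_psd = (U * np.clip(ev, 0, None)) @ U.T
    S = np.zeros((3 + k, 3 + k))
    S[3:, 3:] = E_psd

    if tss == 0:
        warnings.warn(f"constant response {variable!r}; deviance explained is 0")
        gx, gy, gz = _prediction_grid(P, knots, np.zeros(3 + k), grid_res, scale)
        return SurfaceFit(variable=variable, effective_df=1.0, f_value=0.0,
                          deviance_explained=0.0, lambda_gcv=np.inf,
                          grid_x=gx, grid_y=gy, grid_z=gz + zv.mean())

    if lambdas is None:
        lambdas = np.logspace(-8, 4, 40)
    MtM = M.T @ M
    Mtz = M.T @ zv
    best = None
    for lam in lambdas:
        A = MtM + lam * S + 1e-10 * np.eye(3 + k)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        coef = Ainv @ Mtz
        fitted = M @ coef
        rss = np.sum((zv - fitted) ** 2)
        edf = float(np.trace(M @ Ainv @ M.T))
        if n - edf <= 0:
            continue
        gcv = n * rss / (n - edf) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, coef, rss, edf)
    _, lam, coef, rss, edf = best
    dev = float(max(0.0, 1.0 - rss / tss))
    num_df = max(edf - 1.0, 1e-6)
    den_df = max(n - edf, 1e-6)
    f_value = float(((tss - rss) / num_df) / (rss / den_df)) if rss > 0 else np.inf
    gx, gy, gz = _prediction_grid(P, knots, coef, grid_res, scale)
    return SurfaceFit(variable=variable, effective_df=edf, f_value=f_value,
                      deviance_explained=dev, lambda_gcv=float(lam),
                      grid_x=gx, grid_y=gy, grid_z=gz)


def _prediction_grid(P: np.ndarray, knots: np.ndarray, coef: np.ndarray,
                     grid_res: int, scale: float):
    gx = np.linspace(P[:, 0].min(), P[:, 0].max(), grid_res)
    gy = np.linspace(P[:, 1].min(), P[:, 1].max(), grid_res)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    Phi = _tps_basis(np.linalg.norm(pts[:, None, :] - knots[None, :, :], axis=2))
    M = np.column_stack([np.ones(len(pts)), pts, Phi])
    Z = (M @ coef).reshape(GX.shape)
    return gx * scale, gy * scale, Z


def surface_table(fits: list[SurfaceFit]) -> pd.DataFrame:
    """Summary table of surface fits (variable, Est. DF, F, deviance %)."""
    return pd.DataFrame([f.summary_row() for f in fits]).set_index("variable")


# ---------------------------------------------------------------------------
# distance decay diagnostic

def distance_decay(matrix: pd.DataFrame, lat: pd.Series, lon: pd.Series,
                   n_permutations: int = 999, seed: int = 0,
                   mode: str = "presence") -> dict:
    """Mantel-style test of community similarity against geographic
    distance.

    Pearson correlation between pairwise similarity (1 - Bray-Curtis)
    and great-circle distance, with significance from ``n_permutations``
    joint row/column permutations of the distance matrix (two-sided).
    A clearly negative correlation means nearby samples share more of
    their community — spatial structure the downstream permutation
    tests would need to respect.
    """
    if matrix.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    D = bray_curtis(matrix, mode=mode).to_numpy()
    sim = 1.0 - D
    la = lat.loc[matrix.index].to_numpy(dtype=float)
    lo = lon.loc[matrix.index].to_numpy(dtype=float)
    gdist = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])

    iu = np.triu_indices(len(la), k=1)
    r_obs = float(np.corrcoef(sim[iu], gdist[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(la))
        gp = gdist[np.ix_(perm, perm)]
        r = np.corrcoef(sim[iu], gp[iu])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return {"correlation": r_obs, "p_value": p, "n_samples": int(len(la)),
            "n_permutations": int(n_permutations)}
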