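"""Multiple regression quadratic assignment procedure (MRQAP).

Regresses one dyadic matrix on others by ordinary least squares over the
strictly-lower-triangle dyads, with significance from node permutations under
the double-semi-partialling (DSP) scheme: each predictor is residualized on
the remaining predictors at the matrix level, the residual matrix has its
rows and columns jointly permuted by a random node relabeling, and the full
regression is refit with the permuted residual in that predictor's place.
The pivotal statistic is the OLS t-statistic, which is robust to
collinearity among predictors.  Dyad-level permutation of rows alone would
break the row/column dependence structure of network data; permuting nodes
preserves it, which is the point of the procedure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .events import AssociationMatrix

__all__ = ["MRQAPResult", "mrqap_dsp"]

#: stand-in for an infinite t-statistic when residual variance vanishes
T_CAP = 1e12
#: relative tolerance for |t| ties between a permuted and the observed fit;
#: exact-arithmetic ties (e.g. the identity permutation of the residualized
#: predictor) must count as exceedances despite floating-point noise
TIE_RTOL = 1e-9


@dataclass
class MRQAPResult:
    coefficients: np.ndarray            # intercept first, then predictors
    r2: float
    adjusted_r2: float
    t_values: np.ndarray                # per predictor (no intercept)
    p_values: np.ndarray                # per predictor (no intercept)
    n_permutations: int
    n_dyads: int
    seed: int | None = None
    statistic_kind: str = "t"

    def to_dict(self) -> dict:
        return {
            "coefficients": [float(c) for c in self.coefficients],
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "t_values": [float(t) for t in self.t_values],
            "p_values": [float(p) for p in self.p_values],
            "n_permutations": self.n_permutations,
            "n_dyads": self.n_dyads,
            "seed": self.seed,
            "statistic_kind": self.statistic_kind,
        }


def _dyads(w: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(w.shape[0], k=-1)
    return w[i, j]


def _symmetric_from_dyads(vec: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    m[i, j] = vec
    m[j, i] = vec
    return m


def _ols_t(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Coefficients, t-statistics and R² for y on a full-rank design."""
    n, k = design.shape
    xtx = design.T @ design
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - k
    sigma2 = rss / dof if dof > 0 else 0.0
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.sign(beta) * T_CAP)
    return beta, t, r2


def mrqap_dsp(
    y: AssociationMatrix,
    xs: list[AssociationMatrix],
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MRQAPResult:
    """MRQAP with double semi-partialling over node permutations.

    ``exhaustive=True`` enumerates all n! node permutations (identity
    included) instead of sampling, and reports the exact permutation p-value
    #{pi : |t_pi| >= |t_obs|} / n!; sampling uses the add-one convention
    p = (1 + #exceeding) / (1 + n_permutations) so p is never zero.
    """
    if not xs:
        raise ValueError("at least one predictor matrix is required")
    rosters = {y.roster} | {x.roster for x in xs}
    if len(rosters) != 1:
        raise ValueError("all matrices must share one roster")
    n = len(y.roster)
    if n < 4:
        raise ValueError("need at least 4 nodes")

    p = len(xs)
    yv = _dyads(y.weights)
    xcols = np.column_stack([_dyads(x.weights) for x in xs])
    n_dyads = len(yv)
    design = np.column_stack([np.ones(n_dyads), xcols])

    if np.linalg.matrix_rank(design) < p + 1:
        bad = []
        for i in range(p):
            others = np.column_stack(
                [np.ones(n_dyads)] + [xcols[:, j] for j in range(p) if j != i]
            )
            proj, *_ = np.linalg.lstsq(others, xcols[:, i], rcond=None)
            if np.allclose(others @ proj, xcols[:, i]):
                bad.append(i)
        raise ValueError(
            f"singular design: predictors {bad or 'unknown'} are collinear"
        )

    beta, t_obs, r2 = _ols_t(design, yv)
    dof_denom = n_dyads - p - 1
    adjusted_r2 = 1.0 - (1.0 - r2) * (n_dyads - 1) / dof_denom

    # matrix-level residualization of each predictor on the others
    resid_mats = []
    for i in range(p):
        others = np.column_stack(
            [np.ones(n_dyads)] + [xcols[:, j] for j in range(p) if j != i]
        )
        proj, *_ = np.linalg.lstsq(others, xcols[:, i], rcond=None)
        resid = xcols[:, i] - others @ proj
        resid_mats.append(_symmetric_from_dyads(resid, n))

    if exhaustive:
        perms = [np.array(pi) for pi in itertools.permutations(range(n))]
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        perms = None
        n_perm = n_permutations

    p_values = np.empty(p)
    for i in range(p):
        exceed = 0
        perm_design = design.copy()
        threshold = abs(t_obs[i + 1]) * (1.0 - TIE_RTOL)
        for k in range(n_perm):
            pi = perms[k] if exhaustive else rng.permutation(n)
            permuted = resid_mats[i][np.ix_(pi, pi)]
            perm_design[:, i + 1] = _dyads(permuted)
            _, t_perm, _ = _ols_t(perm_design, yv)
            if abs(t_perm[i + 1]) >= threshold:
                exceed += 1
        if exhaustive:
            p_values[i] = exceed / n_perm
        else:
            p_values[i] = (1 + exceed) / (1 + n_perm)

    return MRQAPResult(
        coefficients=beta,
        r2=r2,
        adjusted_r2=adjusted_r2,
        t_values=t_obs[1:],
        p_values=p_values,
        n_permutations=n_perm,
        n_dyads=n_dyads,
        seed=seed,
    )
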