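"""Fleece-rot phenotypes, pedigree relationships and the animal model.

Fleece rot is scored 0-5 at four sites along the backline; an animal's
score is the *maximum* over sites.  Before SNP association the scores are
residualized with a mixed animal model

    y = X b + Z u + e,   u ~ N(0, sigma2_a * A),   e ~ N(0, sigma2_e * I)

with fixed effects of flock, sex, birth type, rear type and a date-of-birth
covariate, and a polygenic animal effect whose covariance is proportional
to the numerator relationship matrix A derived from the pedigree.  The
*residual fleece-rot score* of an animal is its observed score minus the
model's correction (fixed-effect fit plus predicted breeding value); it can
be negative and is scattered around zero.

A is built by the tabular method; its inverse comes directly from
Henderson's rules (with Quaas's inbreeding-aware Mendelian-sampling
variances, so A * A_inverse = I holds exactly even for inbred pedigrees;
the classic simplified rules are available as an option).  Variance
components are estimated by EM-REML: the fixed effects are absorbed and a
one-off generalized eigendecomposition of (Z'SZ, A^-1) makes every EM
iteration O(n), so the fit is exact REML yet takes milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

TRAITS = ("prewet", "postwet", "diff")


class PedigreeError(ValueError):
    pass


# --------------------------------------------------------------------------
# score handling
# --------------------------------------------------------------------------

def aggregate_scores(site_scores) -> int:
    """Final fleece-rot score = maximum score over the (1-4) body sites."""
    arr = np.asarray(site_scores)
    if arr.ndim != 1 or not 1 <= arr.size <= 4:
        raise ValueError("expected 1-4 site scores")
    if np.any((arr < 0) | (arr > 5)) or not np.all(arr == arr.astype(int)):
        raise ValueError(f"site scores must be integers in 0..5, got {site_scores}")
    return int(arr.max())


def residual_score(observed: float, correction: float) -> float:
    """Observed score minus the model correction (may fall outside 0-5)."""
    if not (np.isfinite(observed) and np.isfinite(correction)):
        raise ValueError("scores must be finite")
    return float(observed) - float(correction)


def derive_trait_scores(phenotypes: pd.DataFrame, diff_sign: str = "post_minus_pre",
                        ) -> pd.DataFrame:
    """Attach fr_prewet / fr_postwet (max over sites) and fr_diff columns.

    The change trait defaults to post-wetting minus pre-wetting; pass
    ``diff_sign='pre_minus_post'`` for the opposite convention.
    """
    out = phenotypes.copy()
    for trait in ("prewet", "postwet"):
        cols = [c for c in out.columns if c.startswith(f"{trait}_site")]
        if not cols:
            raise ValueError(f"no {trait}_site* columns found")
        sites = out[cols].to_numpy()
        if np.any((sites < 0) | (sites > 5)):
            raise ValueError("site scores must lie in 0..5")
        out[f"fr_{trait}"] = sites.max(axis=1)
    sign = 1.0 if diff_sign == "post_minus_pre" else -1.0
    out["fr_diff"] = sign * (out["fr_postwet"] - out["fr_prewet"])
    return out


# --------------------------------------------------------------------------
# pedigree relationships
# --------------------------------------------------------------------------

@dataclass
class PedigreeRelationship:
    animals: list[str]          # topologically ordered, parents first
    A: np.ndarray
    A_inv: np.ndarray
    inbreeding: np.ndarray      # F_i = A_ii - 1

    def index_of(self, animal_ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.animals)}
        try:
            return np.array([pos[a] for a in animal_ids], dtype=np.int64)
        except KeyError as exc:
            raise PedigreeError(f"animal {exc.args[0]!r} not in pedigree") from None


def build_relationship(pedigree: pd.DataFrame,
                       inbreeding: bool = True) -> PedigreeRelationship:
    """Numerator relationship matrix A (tabular method) and its inverse.

    ``pedigree`` has columns animal_id, sire_id, dam_id with 0/NA for
    unknown parents; rows may come in any order (a topological sort is
    applied; a cycle raises naming an animal on it).  Parents referenced but
    never listed are added as founders.  ``inbreeding=False`` switches the
    inverse to Henderson's simplified rules, exact only when no parent is
    inbred.
    """
    ped = pedigree.copy()
    for c in ("animal_id", "sire_id", "dam_id"):
        ped[c] = ped[c].astype(str).replace({"nan": "0", "NA": "0", "": "0"})
    if ped["animal_id"].duplicated().any():
        dup = ped.loc[ped["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise PedigreeError(f"duplicate pedigree entry for {dup!r}")

    parents = dict(zip(ped["animal_id"],
                       zip(ped["sire_id"], ped["dam_id"])))
    listed = set(parents)
    for s, d in list(parents.values()):
        for p in (s, d):
            if p != "0" and p not in listed:
                parents[p] = ("0", "0")     # referenced parent -> founder
                listed.add(p)

    order = _toposort(parents)
    n = len(order)
    idx = {a: i for i, a in enumerate(order)}
    sire = np.array([idx.get(parents[a][0], -1) if parents[a][0] != "0" else -1
                     for a in order])
    dam = np.array([idx.get(parents[a][1], -1) if parents[a][1] != "0" else -1
                    for a in order])

    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    F = np.diag(A) - 1.0

    Ainv = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if inbreeding:
            m = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0) + (F[d] if d >= 0 else -1.0))
        else:
            m = 1.0 - 0.25 * (s >= 0) - 0.25 * (d >= 0)
        alpha = 1.0 / m
        Ainv[i, i] += alpha
        for p in (s, d):
            if p >= 0:
                Ainv[i, p] -= alpha / 2
                Ainv[p, i] -= alpha / 2
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    Ainv[p, q] += alpha / 4
    return PedigreeRelationship(animals=order, A=A, A_inv=Ainv, inbreeding=F)


def _toposort(parents: dict[str, tuple[str, str]]) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}   # 0 visiting, 1 done

    for root in parents:
        if root in state:
            continue
        stack = [(root, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 1
                order.append(node)
                continue
            if state.get(node) == 1:
                continue
            if state.get(node) == 0:
                raise PedigreeError(f"pedigree cycle involving {node!r}")
            state[node] = 0
            stack.append((node, True))
            for p in parents[node]:
                if p != "0" and state.get(p) != 1:
                    if state.get(p) == 0:
                        raise PedigreeError(f"pedigree cycle involving {p!r}")
                    stack.append((p, False))
    return order


# --------------------------------------------------------------------------
# animal model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnimalModelOptions:
    max_iter: int = 500
    tol: float = 1e-8
    fallback_h2: float = 0.3      # used if REML fails to converge
    drop_nonsignificant: bool = False
    wald_alpha: float = 0.05
    fixed_factors: tuple[str, ...] = ("flock", "sex", "birth_type", "rear_type")
    dob_covariate: str = "dob"


@dataclass
class AnimalModelFit:
    trait: str
    sigma2_a: float
    sigma2_e: float
    h2: float
    fixed_effects: pd.Series
    breeding_values: pd.Series     # all pedigree animals
    residuals: pd.Series           # phenotyped animals: y - Xb - Zu
    corrections: pd.Series         # Xb + Zu per phenotyped animal
    wald_tests: pd.DataFrame
    loglik: float
    n_iter: int
    converged: bool
    dropped_factors: list[str] = field(default_factory=list)


def fit_animal_model(
    phenotypes: pd.DataFrame,
    relationship: PedigreeRelationship,
    trait: str = "prewet",
    opts: AnimalModelOptions | None = None,
) -> AnimalModelFit:
    """EM-REML fit of the animal model for one fleece-rot trait.

    ``phenotypes`` must carry the derived ``fr_<trait>`` column (see
    :func:`derive_trait_scores`) plus the fixed-effect columns.  Scores are
    treated as numeric, matching the additive interpretation of the
    downstream allelic-substitution effects.
    """
    opts = opts or AnimalModelOptions()
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}")
    col = f"fr_{trait}"
    if col not in phenotypes.columns:
        raise ValueError(f"phenotypes lack {col}; run derive_trait_scores first")

    phen = phenotypes.dropna(subset=[col]).reset_index(drop=True)
    y = phen[col].to_numpy(dtype=float)
    n = len(y)

    factors = [f for f in opts.fixed_factors if phen[f].nunique() >= 2]
    X, names = _design_fixed(phen, factors, opts.dob_covariate)
    fit = _reml_and_solve(y, X, phen, relationship, opts)

    if opts.drop_nonsignificant:
        wald = _wald_tests(fit, X, names, factors, opts)
        weak = [f for f in factors
                if wald.loc[wald["factor"] == f, "p_value"].iloc[0] >= opts.wald_alpha]
        if weak:
            kept = [f for f in factors if f not in weak]
            X, names = _design_fixed(phen, kept, opts.dob_covariate)
            fit = _reml_and_solve(y, X, phen, relationship, opts)
            fit["dropped"] = weak
            factors = kept
    wald = _wald_tests(fit, X, names, factors, opts)

    b, u = fit["b"], fit["u"]
    Zidx = fit["Zidx"]
    correction = X @ b + u[Zidx]
    resid = y - correction
    return AnimalModelFit(
        trait=trait,
        sigma2_a=fit["s2a"], sigma2_e=fit["s2e"],
        h2=fit["s2a"] / (fit["s2a"] + fit["s2e"]),
        fixed_effects=pd.Series(b, index=names),
        breeding_values=pd.Series(u, index=pd.Index(relationship.animals,
                                                    name="animal_id")),
        residuals=pd.Series(resid, index=phen["animal_id"].to_numpy()),
        corrections=pd.Series(correction, index=phen["animal_id"].to_numpy()),
        wald_tests=wald,
        loglik=fit["loglik"], n_iter=fit["n_iter"], converged=fit["converged"],
        dropped_factors=fit.get("dropped", []),
    )


def _design_fixed(phen: pd.DataFrame, factors: list[str], dob_col: str):
    cols = [np.ones(len(phen))]
    names = ["intercept"]
    for f in factors:
        dummies = pd.get_dummies(phen[f].astype(str), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    if dob_col in phen.columns:
        dob = phen[dob_col].to_numpy(dtype=float)
        cols.append(dob - dob.mean())
        names.append(dob_col)
    return np.column_stack(cols), names


def _reml_and_solve(y, X, phen, relationship, opts: AnimalModelOptions) -> dict:
    n, p = X.shape
    q = len(relationship.animals)
    if n <= p:
        raise ValueError("more fixed-effect parameters than records")
    Zidx = relationship.index_of(phen["animal_id"])
    Ainv = relationship.A_inv

    XtX = X.T @ X
    sign, logdetXtX = np.linalg.slogdet(XtX)
    if sign <= 0:
        raise np.linalg.LinAlgError("fixed-effect design is singular")
    XtX_inv = np.linalg.inv(XtX)
    H = X @ XtX_inv                      # n x p
    Sy = y - H @ (X.T @ y)

    # Z'SZ and Z'Sy with Z a selection matrix onto pedigree positions
    ZtX = np.zeros((q, p))
    np.add.at(ZtX, Zidx, X)
    ZtZ = np.zeros((q, q))
    np.add.at(ZtZ, (Zidx, Zidx), 1.0)
    ZtSZ = ZtZ - ZtX @ XtX_inv @ ZtX.T
    r_u = np.zeros(q)
    np.add.at(r_u, Zidx, Sy)

    # one-off generalized eigendecomposition: ZtSZ w = delta Ainv w
    delta, Phi = scipy.linalg.eigh(ZtSZ, Ainv)
    delta = np.maximum(delta, 0.0)
    phr = Phi.T @ r_u
    yty = float(y @ y)
    Xty = X.T @ y

    var_y = float(np.var(y))
    if var_y <= 0:
        # degenerate: constant phenotype
        return dict(b=XtX_inv @ Xty, u=np.zeros(q), s2a=1e-12, s2e=1e-12,
                    loglik=0.0, n_iter=0, converged=True, Zidx=Zidx,
                    XtX_inv=XtX_inv, ZtX=ZtX, ZtZ=ZtZ, lam=1.0, Ainv=Ainv)

    floor = 1e-8 * var_y

    def solve_at(lam):
        c = phr / (delta + lam)
        u = Phi @ c
        b = XtX_inv @ (Xty - ZtX.T @ u)
        quad = yty - float(b @ Xty) - float(u @ (r_u + ZtX @ (XtX_inv @ Xty)))
        # u'Z'y: Z'y = r_u + Z'X (XtX)^-1 X'y  (undo absorption)
        return c, u, b, max(quad, 0.0)

    def minus2l(s2a, s2e, quad, lam):
        return ((n - p - q) * np.log(s2e) + q * np.log(s2a) + logdetXtX
                + float(np.sum(np.log(delta + lam))) + quad / s2e
                + (n - p) * np.log(2 * np.pi))

    def gather(v_ped):
        return v_ped[Zidx]

    def scatter(v_obs):
        out = np.zeros(q)
        np.add.at(out, Zidx, v_obs)
        return out

    def grad_and_ai(s2a, s2e, lam, c, u, b, quad):
        ehat = y - X @ b - gather(u)
        tr = float(np.sum(1.0 / (delta + lam)))
        uAu = float(c @ c)
        g_a = -0.5 * ((q - lam * tr) / s2a - uAu / s2a ** 2)
        g_e = -0.5 * ((n - p - q + lam * tr) / s2e - float(ehat @ ehat) / s2e ** 2)
        F = np.column_stack([gather(u) / s2a, ehat / s2e])
        PF = np.empty_like(F)
        for j in range(2):
            f = F[:, j]
            Sf = f - H @ (X.T @ f)
            cf = (Phi.T @ scatter(Sf)) / (delta + lam)
            uf = Phi @ cf
            bf = XtX_inv @ (X.T @ f - ZtX.T @ uf)
            PF[:, j] = (f - X @ bf - gather(uf)) / s2e
        AI = 0.5 * (F.T @ PF)
        return np.array([g_a, g_e]), AI

    def em_step(s2a, s2e, lam, c, quad):
        tr = float(np.sum(1.0 / (delta + lam)))
        return (max((float(c @ c) + s2e * tr) / q, floor),
                max(quad / (n - p), floor))

    s2a = max(0.3 * var_y, floor)
    s2e = max(0.7 * var_y, floor)
    converged = False
    it = 0
    n_flat = 0
    n_unpins = 0
    lam = s2e / s2a
    c, u, b, quad = solve_at(lam)
    m2l = minus2l(s2a, s2e, quad, lam)
    for it in range(1, opts.max_iter + 1):
        accepted = False
        # at the sigma2_a boundary the AI step only jitters sigma2_e; the EM
        # update is stationary there and closes convergence cleanly
        if it > 3 and s2a > 2 * floor:
            grad, AI = grad_and_ai(s2a, s2e, lam, c, u, b, quad)
            try:
                step = np.linalg.solve(AI + 1e-12 * np.trace(AI) * np.eye(2), grad)
            except np.linalg.LinAlgError:
                step = None
            if step is not None and np.all(np.isfinite(step)):
                scale = 1.0
                for _ in range(12):
                    # cap downward movement: one AI step may not slam a
                    # component onto the floor (EM cannot pull it back out)
                    s2a_c = max(s2a + scale * step[0], 0.1 * s2a, floor)
                    s2e_c = max(s2e + scale * step[1], 0.1 * s2e, floor)
                    lam_c = s2e_c / s2a_c
                    c_c, u_c, b_c, quad_c = solve_at(lam_c)
                    m2l_c = minus2l(s2a_c, s2e_c, quad_c, lam_c)
                    if m2l_c <= m2l + 1e-10 * max(abs(m2l), 1.0):
                        accepted = True
                        break
                    scale *= 0.5
        if not accepted:
            s2a_c, s2e_c = em_step(s2a, s2e, lam, c, quad)
            lam_c = s2e_c / s2a_c
            c_c, u_c, b_c, quad_c = solve_at(lam_c)
            m2l_c = minus2l(s2a_c, s2e_c, quad_c, lam_c)
        # a component pinned at its floor counts as unchanged
        rel_a = 0.0 if (s2a <= 2 * floor and s2a_c <= 2 * floor) \
            else abs(s2a_c - s2a) / s2a
        rel = max(rel_a, abs(s2e_c - s2e) / s2e)
        flat = abs(m2l_c - m2l) < 1e-10 * max(abs(m2l), 1.0)
        n_flat = n_flat + 1 if flat else 0
        s2a, s2e, lam = s2a_c, s2e_c, lam_c
        c, u, b, quad, m2l = c_c, u_c, b_c, quad_c, m2l_c
        # a variance heading for its boundary changes by a constant factor per
        # EM step forever; a flat restricted likelihood is the honest signal
        if rel < opts.tol or n_flat >= 3:
            if s2a <= 2 * floor and n_unpins < 3:
                # check the gradient at the boundary before accepting it
                ehat = y - X @ b - gather(u)
                tr_b = float(np.sum(1.0 / (delta + lam)))
                g_a = -0.5 * ((q - lam * tr_b) / s2a - float(c @ c) / s2a ** 2)
                if g_a > 1e-6:
                    s2a = 1e-3 * var_y
                    lam = s2e / s2a
                    c, u, b, quad = solve_at(lam)
                    m2l = minus2l(s2a, s2e, quad, lam)
                    n_unpins += 1
                    n_flat = 0
                    continue
            converged = True
            break
    if not converged:
        warnings.warn(
            f"animal-model REML did not converge in {opts.max_iter} iterations; "
            f"falling back to h2 = {opts.fallback_h2}", RuntimeWarning, stacklevel=3)
        s2a = opts.fallback_h2 * var_y
        s2e = (1 - opts.fallback_h2) * var_y

    lam = s2e / s2a
    c, u, b, quad = solve_at(lam)
    ll = -0.5 * minus2l(s2a, s2e, quad, lam)
    return dict(b=b, u=u, s2a=s2a, s2e=s2e, loglik=ll, n_iter=it,
                converged=converged, Zidx=Zidx, XtX_inv=XtX_inv, ZtX=ZtX,
                ZtZ=ZtZ, lam=lam, Ainv=Ainv)


def _wald_tests(fit: dict, X, names: list[str], factors: list[str],
                opts: AnimalModelOptions) -> pd.DataFrame:
    """Chi-square Wald test per fixed factor at the converged components."""
    from scipy import stats

    lam, s2e = fit["lam"], fit["s2e"]
    ZtX, ZtZ, Ainv = fit["ZtX"], fit["ZtZ"], fit["Ainv"]
    XtX = np.linalg.inv(fit["XtX_inv"])
    # X'V^-1 X = (X'X - X'Z (Z'Z + lam A^-1)^-1 Z'X) / s2e
    M_u = ZtZ + lam * Ainv
    XtVX = (XtX - ZtX.T @ np.linalg.solve(M_u, ZtX)) / s2e
    cov_b = np.linalg.inv(XtVX)
    b = fit["b"]
    rows = []
    for f in factors:
        cols = [i for i, nm in enumerate(names) if nm.startswith(f"{f}_")]
        if not cols:
            continue
        bf = b[cols]
        W = float(bf @ np.linalg.solve(cov_b[np.ix_(cols, cols)], bf))
        df = len(cols)
        rows.append((f, W, df, float(stats.chi2.sf(W, df))))
    if opts.dob_covariate in names:
        i = names.index(opts.dob_covariate)
        W = float(b[i] ** 2 / cov_b[i, i])
        rows.append((opts.dob_covariate, W, 1, float(stats.chi2.sf(W, 1))))
    return pd.DataFrame(rows, columns=["factor", "wald", "df", "p_value"])
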