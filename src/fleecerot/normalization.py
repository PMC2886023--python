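"""ANOVA mixed-model normalization of two-colour loop-design microarrays.

Each background-corrected, log2-scale intensity reading is modelled as

    y = mu + C + G + AG + DG + FG + TG + e

where C is a *comparison group* fixed effect (one level per array slide x
printing block x dye channel), G is a random gene effect and AG, DG, FG, TG
are the random interactions of gene with array, dye, flock and treatment
(breed line x time point).  All random effects are independent zero-mean
Gaussians with their own variance component; e is the within-gene residual.

Variance components are estimated by REML — expectation-maximisation steps
with average-information (AI) acceleration and step-halving — and effect
solutions are BLUPs from Henderson's mixed-model equations at the converged
components.  The BLUPs of the treatment x gene interaction are the
*normalized expression* of each gene in each condition: the fixed comparison
group soaks up array/block/channel artefacts, the gene main effect soaks up
overall abundance, and what remains in TG is the condition-specific signal.

Computationally the comparison-group effect (many nuisance levels) is
absorbed exactly, and because every random term is gene-crossed the absorbed
coefficient matrix is block-diagonal by gene up to a low-rank correction,
which Woodbury's identity turns into batched small dense solves — exact, and
fast enough to refit thousands of genes per second per REML iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANDOM_TERMS = ("G", "AG", "DG", "FG", "TG")

#: the ten treatment labels of the default sub-line x time coding:
#: R/S = resistant/susceptible line, H/L = high/low sub-line, digit = time.
SUBLINE_TREATMENTS = ("RH0", "RL0", "SH0", "SL0", "RH1", "RL1", "SH1", "SL1", "RH2", "SH2")


@dataclass(frozen=True)
class VarianceComponents:
    """The six variance parameters of the normalization model (log2 scale)."""

    sigma2_G: float
    sigma2_AG: float
    sigma2_DG: float
    sigma2_FG: float
    sigma2_TG: float
    sigma2_e: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError("variance components must be finite")
        if np.any(arr < 0):
            raise ValueError("variance components must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.sigma2_G, self.sigma2_AG, self.sigma2_DG, self.sigma2_FG,
             self.sigma2_TG, self.sigma2_e]
        )

    @classmethod
    def from_array(cls, arr) -> "VarianceComponents":
        return cls(*(float(v) for v in arr))

    def random_array(self) -> np.ndarray:
        """The five random-term components, without the residual."""
        return self.as_array()[:5]


@dataclass(frozen=True)
class ModelSpec:
    """Structural description of the normalization model.

    The term list is fixed by the design (C fixed; G, AG, DG, FG, TG
    random); what varies is the treatment coding.  ``treatment_coding``
    is 'subline' (10 levels, RH/RL/SH/SL by time — the default used by the
    differential-expression contrasts) or 'linetime' (6 levels, line x
    time); the fit itself accepts whatever labels the observation table
    carries, so the coding is applied upstream when samples are labelled.
    """

    treatment_coding: str = "subline"

    def __post_init__(self):
        if self.treatment_coding not in ("subline", "linetime"):
            raise ValueError("treatment_coding must be 'subline' or 'linetime'")


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 500
    tol_components: float = 1e-8
    tol_logl: float = 1e-10
    floor_frac: float = 1e-8   # component floor as a fraction of var(y)
    n_em_warmup: int = 3       # plain EM steps before trying AI steps
    max_halvings: int = 12


@dataclass
class MixedModelFit:
    components: VarianceComponents
    normalized: pd.DataFrame          # gene x treatment TG BLUPs
    solutions: dict[str, pd.DataFrame | pd.Series]
    mu: float
    fixed_C: pd.Series                # comparison-group effects (contain mu)
    loglik: float
    n_iter: int
    converged: bool
    gradient_norm: float
    loglik_trace: list[float] = field(default_factory=list)


class DesignError(ValueError):
    pass


# --------------------------------------------------------------------------
# internal: absorbed, gene-blocked representation of the model
# --------------------------------------------------------------------------

class _GeneBlocked:
    """Precomputed sufficient statistics for the absorbed MME.

    Unknowns are ordered gene-major with the per-gene layout
    [G | AG(all arrays) | DG(2) | FG(all flocks) | TG(all treatments)];
    levels a gene never meets are padded (their BLUPs are exactly zero and
    they contribute nothing to the REML criterion), which keeps every gene
    block the same shape and lets numpy batch the factorizations.
    """

    def __init__(self, obs: pd.DataFrame):
        req = {"array_id", "block_id", "dye", "gene_id", "flock_id", "treatment_id",
               "log2_intensity"}
        missing = req - set(obs.columns)
        if missing:
            raise DesignError(f"observation table lacks columns: {sorted(missing)}")
        y = obs["log2_intensity"].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise DesignError("log2_intensity contains non-finite values")

        self.genes, g = _codes(obs["gene_id"])
        self.arrays, a = _codes(obs["array_id"])
        self.dyes, d = _codes(obs["dye"])
        self.flocks, f = _codes(obs["flock_id"])
        self.treatments, t = _codes(obs["treatment_id"])
        c_series = (obs["array_id"].astype(str) + "|" + obs["block_id"].astype(str)
                    + "|" + obs["dye"].astype(str))
        self.c_levels, c = _codes(c_series)

        for nm, levels in (("gene", self.genes), ("array", self.arrays),
                           ("dye", self.dyes), ("flock", self.flocks),
                           ("treatment", self.treatments)):
            if len(levels) < 2 and nm != "gene":
                raise DesignError(f"random factor {nm!r} needs >= 2 levels, got {len(levels)}")
        if len(self.genes) < 2:
            raise DesignError("need >= 2 genes")

        G = len(self.genes)
        nA, nD, nF, nT = (len(self.arrays), len(self.dyes),
                          len(self.flocks), len(self.treatments))
        self.offsets = np.cumsum([0, 1, nA, nD, nF])  # starts of G,AG,DG,FG,TG
        self.q = 1 + nA + nD + nF + nT
        self.sizes = np.array([1, nA, nD, nF, nT])
        self.n = len(y)
        self.nc = np.bincount(c, minlength=len(self.c_levels)).astype(float)
        self.p = len(self.c_levels)

        cols = np.empty((self.n, 5), dtype=np.int64)
        cols[:, 0] = 0
        cols[:, 1] = self.offsets[1] + a
        cols[:, 2] = self.offsets[2] + d
        cols[:, 3] = self.offsets[3] + f
        cols[:, 4] = self.offsets[4] + t
        self.cols = cols
        self.g = g
        self.c = c
        self.y = y

        q, c_n = self.q, self.p
        N = np.zeros((G, q, q))
        for i in range(5):
            for j in range(5):
                np.add.at(N, (g, cols[:, i], cols[:, j]), 1.0)
        r = np.zeros((G, q))
        U0 = np.zeros((G, q, c_n))
        for i in range(5):
            np.add.at(r, (g, cols[:, i]), y)
            np.add.at(U0, (g, cols[:, i], c), 1.0)
        self.N = N
        self.r = r
        self.wty = np.zeros(c_n)
        np.add.at(self.wty, c, y)
        self.U = U0 / np.sqrt(self.nc)[None, None, :]
        self.yty = float(y @ y)
        self.var_y = float(np.var(y))
        self.G = G

        # map a layout column to its variance-component index (0..4)
        self.col_term = np.repeat(np.arange(5), self.sizes)
        # total padded level counts per term
        self.q_k = self.sizes * G

    def evaluate(self, comps: VarianceComponents) -> dict:
        """All REML quantities at the given components: BLUPs, -2logL, EM
        updates, gradient, AI matrix."""
        sig = comps.random_array()
        s2e = comps.sigma2_e
        lam = s2e / sig                       # per term
        lam_layout = lam[self.col_term]       # per layout column

        A = self.N.copy()
        idx = np.arange(self.q)
        A[:, idx, idx] += lam_layout[None, :]
        A_inv = np.linalg.inv(A)

        wtilde = self.wty / np.sqrt(self.nc)
        rvec = self.r - self.U @ wtilde                    # absorbed RHS
        V = np.einsum("gij,gjc->gic", A_inv, self.U)
        s0 = np.einsum("gij,gj->gi", A_inv, rvec)
        K = np.eye(self.p) - np.einsum("gqc,gqd->cd", self.U, V)
        signK, logdetK = np.linalg.slogdet(K)
        if signK <= 0:
            raise DesignError("absorbed system not positive definite (model not estimable)")
        K_inv = np.linalg.inv(K)
        Us0 = np.einsum("gqc,gq->c", self.U, s0)
        u = s0 + np.einsum("gqc,c->gq", V @ K_inv, Us0)

        Uu = np.einsum("gqc,gq->c", self.U, u)
        bhat = (self.wty - np.sqrt(self.nc) * Uu) / self.nc
        quad = self.yty - float(bhat @ self.wty) - float(np.einsum("gq,gq->", u, self.r))
        quad = max(quad, 0.0)

        VK = np.einsum("gqc,cd->gqd", V, K_inv)
        diagM = np.einsum("gii->gi", A_inv) + np.einsum("gqc,gqc->gq", VK, V)
        tr_k = np.array([diagM[:, self.offsets[k]:self.offsets[k] + self.sizes[k]].sum()
                         if k < 4 else diagM[:, self.offsets[4]:].sum()
                         for k in range(5)])
        usq_k = np.array([
            (u[:, self.offsets[k]:self.offsets[k] + self.sizes[k]] ** 2).sum()
            if k < 4 else (u[:, self.offsets[4]:] ** 2).sum()
            for k in range(5)])

        sign, logdetA = np.linalg.slogdet(A)
        if np.any(sign <= 0):
            raise DesignError("gene block not positive definite")
        q_tot = self.q_k.sum()
        n, p = self.n, self.p
        minus2l = ((n - p - q_tot) * np.log(s2e)
                   + float(self.q_k @ np.log(sig))
                   + float(logdetA.sum()) + logdetK + float(np.log(self.nc).sum())
                   + quad / s2e + (n - p) * np.log(2 * np.pi))

        # residuals e = y - W b - Z u (needed for gradient wrt sigma2_e and AI)
        fit_rows = bhat[self.c] + u[self.g, self.cols[:, 0]]
        for i in range(1, 5):
            fit_rows = fit_rows + u[self.g, self.cols[:, i]]
        ehat = self.y - fit_rows

        # gradient of logL
        tr_PZZ = (self.q_k - lam * tr_k) / sig
        yPZZPy = usq_k / sig ** 2
        g_rand = -0.5 * (tr_PZZ - yPZZPy)
        tr_P = (n - p - q_tot + float(lam @ tr_k)) / s2e
        g_e = -0.5 * (tr_P - float(ehat @ ehat) / s2e ** 2)
        grad = np.append(g_rand, g_e)

        return dict(u=u, bhat=bhat, quad=quad, minus2l=minus2l, loglik=-0.5 * minus2l,
                    tr_k=tr_k, usq_k=usq_k, grad=grad, ehat=ehat, A_inv=A_inv,
                    K_inv=K_inv, lam=lam)

    def em_update(self, comps: VarianceComponents, ev: dict,
                  floor: float) -> VarianceComponents:
        sig_new = (ev["usq_k"] + comps.sigma2_e * ev["tr_k"]) / self.q_k
        s2e_new = ev["quad"] / (self.n - self.p)
        arr = np.append(sig_new, s2e_new)
        return VarianceComponents.from_array(np.maximum(arr, floor))

    def ai_matrix(self, comps: VarianceComponents, ev: dict) -> np.ndarray:
        """Average-information matrix for (sigma2_G..TG, sigma2_e)."""
        sig = comps.random_array()
        s2e = comps.sigma2_e
        u, A_inv, K_inv = ev["u"], ev["A_inv"], ev["K_inv"]
        n = self.n
        F = np.empty((n, 6))
        for k in range(5):
            F[:, k] = u[self.g, self.cols[:, k]] / sig[k]
        F[:, 5] = ev["ehat"] / s2e

        # P f for each column via an MME solve with f as pseudo-data
        PF = np.empty_like(F)
        for j in range(6):
            f = F[:, j]
            r_f = np.zeros((self.G, self.q))
            for i in range(5):
                np.add.at(r_f, (self.g, self.cols[:, i]), f)
            wtf = np.zeros(self.p)
            np.add.at(wtf, self.c, f)
            rvec = r_f - self.U @ (wtf / np.sqrt(self.nc))
            s0 = np.einsum("gij,gj->gi", A_inv, rvec)
            Us0 = np.einsum("gqc,gq->c", self.U, s0)
            u_f = s0 + np.einsum("gqc,c->gq",
                                 np.einsum("gij,gjc->gic", A_inv, self.U) @ K_inv, Us0)
            Uu = np.einsum("gqc,gq->c", self.U, u_f)
            b_f = (wtf - np.sqrt(self.nc) * Uu) / self.nc
            pred = b_f[self.c] + sum(u_f[self.g, self.cols[:, i]] for i in range(5))
            PF[:, j] = (f - pred) / s2e
        return 0.5 * (F.T @ PF)


def _codes(series: pd.Series):
    cat = pd.Categorical(series)
    return list(cat.categories), np.asarray(cat.codes, dtype=np.int64)


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def fit_mixed_model(
    obs: pd.DataFrame,
    spec: ModelSpec | None = None,
    opts: FitOptions | None = None,
    init: VarianceComponents | None = None,
) -> MixedModelFit:
    """REML fit of the normalization model; TG BLUPs are the normalized
    expression.

    Components are estimated by EM with AI acceleration (AI steps are taken
    when they improve the restricted likelihood, with step-halving, and EM
    otherwise, so the reported likelihood trace is non-decreasing).  Each
    component is floored at ``floor_frac * var(y)``.
    """
    spec = spec or ModelSpec()
    opts = opts or FitOptions()
    gb = _GeneBlocked(obs)
    floor = opts.floor_frac * max(gb.var_y, opts.floor_frac)

    if init is None:
        v0 = max(gb.var_y, floor * 10) / 6.0
        comps = VarianceComponents.from_array(np.full(6, max(v0, floor)))
    else:
        comps = VarianceComponents.from_array(np.maximum(init.as_array(), floor))

    trace: list[float] = []
    ev = gb.evaluate(comps)
    trace.append(ev["loglik"])
    converged = False
    it = 0
    n_unpins = np.zeros(6, dtype=int)
    for it in range(1, opts.max_iter + 1):
        if it <= opts.n_em_warmup:
            cand = gb.em_update(comps, ev, floor)
            ev_cand = gb.evaluate(cand)
        else:
            cand, ev_cand = _ai_or_em(gb, comps, ev, floor, opts)
        old_arr, new_arr = comps.as_array(), cand.as_array()
        at_floor = (old_arr <= 2 * floor) & (new_arr <= 2 * floor)
        rel_c = np.max(np.where(at_floor, 0.0,
                                np.abs(new_arr - old_arr) / np.maximum(old_arr, floor)))
        rel_l = abs(ev_cand["loglik"] - ev["loglik"]) / max(abs(ev["loglik"]), 1.0)
        comps, ev = cand, ev_cand
        trace.append(ev["loglik"])
        if rel_c < opts.tol_components and rel_l < opts.tol_logl:
            # a floored component with positive gradient wants back into the
            # interior: unpin it (a few times at most) instead of stopping
            arr = comps.as_array()
            pinned = arr <= 2 * floor
            wants_up = pinned & (ev["grad"] > 1e-6) & (n_unpins < 3)
            if wants_up.any():
                arr[wants_up] = max(1e-3 * gb.var_y, 100 * floor)
                n_unpins += wants_up
                comps = VarianceComponents.from_array(arr)
                ev = gb.evaluate(comps)
                trace.append(ev["loglik"])
                continue
            converged = True
            break
    if not converged:
        warnings.warn(
            f"REML did not converge in {opts.max_iter} iterations; returning last iterate",
            RuntimeWarning, stacklevel=2)

    return _package_fit(gb, comps, ev, it, converged, trace)


def _ai_or_em(gb: _GeneBlocked, comps: VarianceComponents, ev: dict,
              floor: float, opts: FitOptions):
    """One accelerated step: AI with step-halving, EM as the safe fallback."""
    theta = comps.as_array()
    # components pinned at the floor stay on EM updates; AI accelerates the rest
    free = theta > 2 * floor
    delta = None
    if free.any():
        try:
            AI = gb.ai_matrix(comps, ev)
            AI_f = AI[np.ix_(free, free)]
            d_f = np.linalg.solve(AI_f + 1e-12 * np.eye(free.sum()) * np.trace(AI_f),
                                  ev["grad"][free])
            delta = np.zeros(6)
            delta[free] = d_f
        except np.linalg.LinAlgError:
            delta = None
    if delta is not None and np.all(np.isfinite(delta)):
        em_arr = gb.em_update(comps, ev, floor).as_array()
        # an AI step may shrink a component by at most a factor 10, so a
        # single overshoot cannot slam it onto the floor (where the EM map
        # has a spurious fixed point)
        lower = np.maximum(0.1 * theta, floor)
        step = 1.0
        for _ in range(opts.max_halvings):
            cand_arr = np.maximum(theta + step * delta, lower)
            # pinned components follow their EM update so they can leave the
            # floor when the likelihood pulls them back into the interior
            cand_arr[~free] = em_arr[~free]
            try:
                cand = VarianceComponents.from_array(cand_arr)
                ev_cand = gb.evaluate(cand)
            except (ValueError, DesignError):
                step *= 0.5
                continue
            if ev_cand["loglik"] >= ev["loglik"] - 1e-10 * max(abs(ev["loglik"]), 1.0):
                return cand, ev_cand
            step *= 0.5
    cand = gb.em_update(comps, ev, floor)
    return cand, gb.evaluate(cand)


def _package_fit(gb: _GeneBlocked, comps, ev, n_iter, converged, trace) -> MixedModelFit:
    u = ev["u"]
    genes = pd.Index(gb.genes, name="gene_id")
    sols: dict[str, pd.DataFrame | pd.Series] = {
        "G": pd.Series(u[:, 0], index=genes, name="G")}
    for k, (name, levels) in enumerate(
            [("AG", gb.arrays), ("DG", gb.dyes), ("FG", gb.flocks),
             ("TG", gb.treatments)], start=1):
        lo = gb.offsets[k]
        hi = lo + gb.sizes[k]
        sols[name] = pd.DataFrame(u[:, lo:hi], index=genes, columns=levels)
    fixed_C = pd.Series(ev["bhat"], index=pd.Index(gb.c_levels, name="comparison_group"))
    mu = float(np.average(ev["bhat"], weights=gb.nc))
    return MixedModelFit(
        components=comps,
        normalized=sols["TG"].copy(),
        solutions=sols,
        mu=mu,
        fixed_C=fixed_C,
        loglik=ev["loglik"],
        n_iter=n_iter,
        converged=converged,
        gradient_norm=float(np.linalg.norm(ev["grad"])),
        loglik_trace=trace,
    )


def reml_loglik(obs: pd.DataFrame, comps: VarianceComponents) -> float:
    """Restricted log-likelihood of the normalization model at given
    components (same constant convention as the dense textbook criterion)."""
    gb = _GeneBlocked(obs)
    return gb.evaluate(comps)["loglik"]
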