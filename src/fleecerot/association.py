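"""Per-SNP quality control and additive association to residual FR scores.

For each SNP and population: minor-allele frequency, an exact
Hardy-Weinberg test, and an additive allele-dosage regression of the
animal-model residual fleece-rot score on the number of copies (0/1/2) of
the minor allele.  The slope is the allelic substitution effect beta (score
units per allele copy), its two-sided p-value uses the t distribution with
n-2 degrees of freedom, and the percentage of phenotypic variance explained
is R^2 = 100 * model SS / total SS.  Missing genotypes are deleted pairwise
per SNP; monomorphic SNPs are flagged and reported without estimates.

The HWE test is the exact conditional test: given the observed allele
counts, enumerate every compatible heterozygote count, compute each
configuration's probability under random union of gametes, and sum the
probabilities of configurations no more probable than the one observed
(the mid-p variant, subtracting half the observed configuration's
probability, is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class SnpSummary:
    snp_id: str
    n: int
    n_AA: int
    n_Aa: int
    n_aa: int
    maf: float
    monomorphic: bool


@dataclass
class SnpAssociationResult:
    snp_id: str
    population: str
    trait: str
    n: int
    maf: float
    hwe_p: float
    beta: float          # NaN when monomorphic
    se: float
    r2_percent: float
    p_value: float
    significant: bool
    monomorphic: bool


def genotype_counts(dosages) -> tuple[int, int, int]:
    """(n_hom_major, n_het, n_hom_minor) from 0/1/2 dosage calls (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size and not np.all(np.isin(d, (0.0, 1.0, 2.0))):
        raise ValueError("dosages must be 0, 1 or 2")
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def minor_allele_frequency(dosages) -> SnpSummary:
    """MAF = count of the rarer allele / 2n; monomorphic SNPs get MAF 0."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all genotypes missing")
    n0, n1, n2 = genotype_counts(d)
    n = n0 + n1 + n2
    freq = (n1 + 2 * n2) / (2.0 * n)
    maf = min(freq, 1.0 - freq)
    mono = n1 == 0 and (n0 == 0 or n2 == 0)
    return SnpSummary(snp_id="", n=n, n_AA=n0, n_Aa=n1, n_aa=n2,
                      maf=0.0 if mono else maf, monomorphic=mono)


def hwe_exact_test(counts: tuple[int, int, int], mid_p: bool = False) -> float:
    """Exact conditional Hardy-Weinberg test on (n_AA, n_Aa, n_aa).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations at most as probable as the observed one.
    """
    n_AA, n_Aa, n_aa = (int(c) for c in counts)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0

    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_rare = (n_minor - hets) // 2
    homs_common = n - hets - homs_rare
    valid = homs_common >= 0
    hets, homs_rare, homs_common = hets[valid], homs_rare[valid], homs_common[valid]
    # P(het = h | n, n_minor)  ∝  n! 2^h / (h! n_rr! n_cc!)
    logp = (hets * np.log(2.0) - special.gammaln(hets + 1)
            - special.gammaln(homs_rare + 1) - special.gammaln(homs_common + 1))
    logp -= special.logsumexp(logp)
    probs = np.exp(logp)
    p_obs = probs[hets == n_Aa][0]
    p = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    if mid_p:
        p -= 0.5 * float(p_obs)
    return min(p, 1.0)


def additive_regression(residuals, dosages, alpha: float = 0.05,
                        ) -> SnpAssociationResult:
    """OLS of residual score on minor-allele dosage (with intercept).

    Animals missing either value are excluded pairwise.  Returns a result
    flagged monomorphic (all estimates NaN) when the dosage does not vary.
    """
    r = np.asarray(residuals, dtype=float)
    d = np.asarray(dosages, dtype=float)
    keep = ~(np.isnan(r) | np.isnan(d))
    r, d = r[keep], d[keep]
    if r.size < 3:
        raise ValueError("need >= 3 animals with both genotype and residual")
    summ = minor_allele_frequency(d)
    hwe = hwe_exact_test((summ.n_AA, summ.n_Aa, summ.n_aa))
    if summ.monomorphic or np.var(d) == 0:
        return SnpAssociationResult(
            snp_id="", population="", trait="", n=int(r.size), maf=summ.maf,
            hwe_p=hwe, beta=np.nan, se=np.nan, r2_percent=np.nan,
            p_value=np.nan, significant=False, monomorphic=True)
    if np.var(r) == 0:
        beta, se, pval, r2 = 0.0, 0.0, 1.0, 0.0
    else:
        fit = stats.linregress(d, r)
        beta, se, pval = float(fit.slope), float(fit.stderr), float(fit.pvalue)
        r2 = 100.0 * float(fit.rvalue) ** 2
    return SnpAssociationResult(
        snp_id="", population="", trait="", n=int(r.size), maf=summ.maf,
        hwe_p=hwe, beta=beta, se=se, r2_percent=r2, p_value=pval,
        significant=bool(pval < alpha), monomorphic=False)


def run_association(
    populations: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    traits: tuple[str, ...] = ("prewet", "postwet", "diff"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One result per SNP x population x trait.

    ``populations`` maps a population name to ``(residuals, genotypes)``:
    residuals indexed by animal_id with one column per trait; genotypes with
    an animal_id column and one 0/1/2 dosage column per SNP.  A SNP
    monomorphic in one population is reported n/a there and estimated in the
    others.  A Benjamini-Hochberg adjusted column is appended.
    """
    rows = []
    for pop, (residuals, genotypes) in populations.items():
        geno = genotypes.set_index("animal_id")
        common = residuals.index.intersection(geno.index)
        if len(common) == 0:
            raise ValueError(f"no animals with both residuals and genotypes "
                             f"in population {pop!r}")
        res_p = residuals.loc[common]
        geno_p = geno.loc[common]
        for snp in geno_p.columns:
            for trait in traits:
                if trait not in res_p.columns:
                    raise ValueError(f"residual table for {pop!r} lacks trait {trait!r}")
                out = additive_regression(
                    res_p[trait].to_numpy(dtype=float),
                    geno_p[snp].to_numpy(dtype=float), alpha=alpha)
                out.snp_id, out.population, out.trait = snp, pop, trait
                rows.append(out)
    df = pd.DataFrame([vars(r) for r in rows])
    mask = ~df["p_value"].isna()
    df["p_bh"] = np.nan
    if mask.any():
        p = df.loc[mask, "p_value"].to_numpy()
        m = p.size
        order = np.argsort(p, kind="mergesort")
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        vals = np.empty(m)
        vals[order] = np.clip(adj, 0, 1)
        df.loc[mask, "p_bh"] = vals
    return df
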