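"""Per-variant logistic association engine for the two-consortium contrasts.

The case-only contrast regresses consortium membership (carrier cohort = 1,
population cohort = 0) among breast-cancer cases on allelic dosage, adjusted
for age at diagnosis, country and the leading ancestry principal components;
a 1-df likelihood-ratio test gives the p-value.  Under genotype/mutation
independence in the source population the fitted per-allele odds ratio
estimates the carrier-by-SNP interaction.  The control-only contrast runs the
same machinery on unaffected women to detect violations of that independence.

Fitting is maximum-likelihood IRLS (relative deviance tolerance 1e-8, at most
50 iterations) with the null model shared across a scan for speed; tests
cross-check every fit against an independent GLM implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeMatrix

__all__ = [
    "Contrast",
    "AssocResult",
    "InflationStats",
    "CASE_ONLY", "CASE_ONLY_ER_NEG", "CONTROL_ONLY",
    "contrast_mask",
    "fit_variant",
    "fit_case_only",
    "fit_control_only",
    "scan",
    "compute_pcs",
    "ld_prune",
    "genomic_inflation",
    "heterogeneity_by_country",
    "leave_one_country_out",
]

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass(frozen=True)
class Contrast:
    """A two-consortium comparison definition.

    ``name`` selects the sample filter: ``case_only`` (all cases),
    ``case_only_er_neg`` (carrier cases vs ER-negative population cases;
    the ER restriction never applies to the carrier side) or
    ``control_only`` (unaffected carriers vs population controls).
    """

    name: str
    carrier_gene: str = "BRCA1"

    def __post_init__(self):
        if self.name not in {"case_only", "case_only_er_neg", "control_only"}:
            raise ValueError(f"unknown contrast {self.name!r}")
        if self.carrier_gene not in {"BRCA1", "BRCA2"}:
            raise ValueError(f"carrier gene must be BRCA1 or BRCA2, got {self.carrier_gene!r}")


def CASE_ONLY(gene="BRCA1"):
    return Contrast("case_only", gene)


def CASE_ONLY_ER_NEG(gene="BRCA1"):
    return Contrast("case_only_er_neg", gene)


def CONTROL_ONLY(gene="BRCA1"):
    return Contrast("control_only", gene)


@dataclass
class AssocResult:
    variant_id: str
    beta: float
    se: float
    p: float
    n_used: int
    analysis: str
    converged: bool = True

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    def ci(self, level: float = 0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        return (np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se))


@dataclass
class InflationStats:
    lam: float
    lambda_1000: float
    n: int
    m: int


# ---------------------------------------------------------------------------
# sample selection
# ---------------------------------------------------------------------------

def contrast_mask(samples: pd.DataFrame, contrast: Contrast,
                  min_cimba_per_country: int = 10) -> np.ndarray:
    """Boolean sample filter for a contrast.

    Country strata contributing fewer carrier-cohort subjects than
    ``min_cimba_per_country`` are dropped entirely (both cohorts), mirroring
    the study's country-minimum exclusion rule.
    """
    cimba_side = (samples["cohort"] == "CIMBA") & (samples["carrier_gene"] == contrast.carrier_gene)
    bcac_side = samples["cohort"] == "BCAC"
    if contrast.name == "control_only":
        status_ok = samples["status"] == "control"
    else:
        status_ok = samples["status"] == "case"
    if contrast.name == "case_only_er_neg":
        bcac_side = bcac_side & (samples["er_status"] == "negative")
    mask = (cimba_side | bcac_side) & status_ok
    if min_cimba_per_country:
        cimba_counts = samples.loc[mask & cimba_side, "country"].value_counts()
        ok_countries = set(cimba_counts.index[cimba_counts >= min_cimba_per_country])
        mask = mask & samples["country"].isin(ok_countries)
    return mask.to_numpy()


def outcome_vector(samples: pd.DataFrame) -> np.ndarray:
    """CIMBA membership indicator (the regression outcome)."""
    return (samples["cohort"] == "CIMBA").to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# IRLS logistic core
# ---------------------------------------------------------------------------

def _logit_fit(X: np.ndarray, y: np.ndarray, beta0=None,
               max_iter: int = 50, tol: float = 1e-8):
    """Newton/IRLS maximum-likelihood logistic fit.

    Returns (beta, loglik, cov, converged).  Convergence is a relative
    deviance change below ``tol``; ridge jitter guards singular information
    matrices (near-separation, collinearity).
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    dev = -2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
    converged = False
    XtWX = None
    for _ in range(max_iter):
        w = mu * (1 - mu)
        w = np.maximum(w, 1e-10)
        Xw = X * w[:, None]
        XtWX = X.T @ Xw
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(XtWX + 1e-8 * np.eye(p), grad)
        # step-halving on deviance increase
        for k in range(12):
            cand = beta + step
            eta = X @ cand
            mu_c = 1.0 / (1.0 + np.exp(-eta))
            dev_c = -2.0 * np.sum(y * np.log(mu_c + eps) + (1 - y) * np.log(1 - mu_c + eps))
            if dev_c <= dev + 1e-10:
                break
            step = step / 2.0
        beta, mu = cand, mu_c
        if abs(dev - dev_c) < tol * (abs(dev) + 0.1):
            dev = dev_c
            converged = True
            break
        dev = dev_c
    loglik = -dev / 2.0
    try:
        cov = np.linalg.inv(XtWX) if XtWX is not None else np.full((p, p), np.nan)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(XtWX)
    return beta, loglik, cov, converged


def _design(samples: pd.DataFrame, adjust, pcs=None, countries=None):
    """Covariate design matrix (intercept first) for the selected samples."""
    cols = [np.ones(len(samples))]
    names = ["const"]
    if "age" in adjust:
        cols.append(samples["age"].to_numpy(dtype=float))
        names.append("age")
    if "country" in adjust:
        if countries is None:
            countries = sorted(samples["country"].unique())
        if len(countries) < 2:
            raise ValueError("country adjustment requires >= 2 countries after filtering")
        for c in countries[1:]:  # first country is the reference
            cols.append((samples["country"] == c).to_numpy(dtype=float))
            names.append(f"country_{c}")
    if "pcs" in adjust:
        if pcs is None:
            raise ValueError("pcs requested but not supplied")
        for k in range(pcs.shape[1]):
            cols.append(pcs[:, k])
            names.append(f"pc{k + 1}")
    return np.column_stack(cols), names


def fit_variant(dosage: np.ndarray, samples: pd.DataFrame, contrast: Contrast,
                adjust=("age", "country"), pcs=None, condition_on=None,
                min_cimba_per_country: int = 10) -> AssocResult:
    """Logistic LRT of consortium membership on one variant's dosage.

    ``condition_on`` optionally supplies dosage columns of previously selected
    signal SNPs; they join the covariate (null) side of the likelihood-ratio
    test.  Samples with missing dosage are dropped from this variant only.
    """
    mask = contrast_mask(samples, contrast, min_cimba_per_country)
    dosage = np.asarray(dosage, dtype=float)
    ok = mask & np.isfinite(dosage)
    if condition_on is not None:
        condition_on = np.atleast_2d(np.asarray(condition_on, dtype=float))
        if condition_on.shape[0] != len(dosage):
            condition_on = condition_on.T
        ok = ok & np.all(np.isfinite(condition_on), axis=1)
    sub = samples.loc[ok]
    y = outcome_vector(sub)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"contrast {contrast.name!r} has a single outcome class")
    X0, _ = _design(sub, adjust, pcs=None if pcs is None else pcs[ok])
    if condition_on is not None:
        X0 = np.column_stack([X0, condition_on[ok]])
    d = dosage[ok]
    X1 = np.column_stack([X0, d])
    b0, ll0, _, conv0 = _logit_fit(X0, y)
    if np.all(d == d[0]):
        # constant dosage: no information, LRT statistic 0
        return AssocResult("", 0.0, np.inf, 1.0, len(y), contrast.name, conv0)
    start = np.append(b0, 0.0)
    b1, ll1, cov1, conv1 = _logit_fit(X1, y, beta0=start)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, 1))
    se = float(np.sqrt(max(cov1[-1, -1], 0.0)))
    if not (conv0 and conv1):
        warnings.warn("logistic fit did not converge; result flagged", stacklevel=2)
    return AssocResult("", float(b1[-1]), se, p, len(y), contrast.name, conv0 and conv1)


def fit_case_only(dosage, samples, carrier_gene="BRCA1", er_negative=False,
                  adjust=("age", "country"), pcs=None, condition_on=None,
                  min_cimba_per_country: int = 10) -> AssocResult:
    name = "case_only_er_neg" if er_negative else "case_only"
    return fit_variant(dosage, samples, Contrast(name, carrier_gene), adjust=adjust,
                       pcs=pcs, condition_on=condition_on,
                       min_cimba_per_country=min_cimba_per_country)


def fit_control_only(dosage, samples, carrier_gene="BRCA1",
                     adjust=("age", "country"), pcs=None, condition_on=None,
                     min_cimba_per_country: int = 10) -> AssocResult:
    return fit_variant(dosage, samples, Contrast("control_only", carrier_gene),
                       adjust=adjust, pcs=pcs, condition_on=condition_on,
                       min_cimba_per_country=min_cimba_per_country)


def scan(matrix: GenotypeMatrix, samples: pd.DataFrame, contrast: Contrast,
         adjust=("age", "country"), pcs=None,
         min_cimba_per_country: int = 10) -> pd.DataFrame:
    """Per-variant LRT scan; the null fit is shared across complete variants."""
    mask = contrast_mask(samples, contrast, min_cimba_per_country)
    sub = samples.loc[mask]
    y = outcome_vector(sub)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"contrast {contrast.name!r} has a single outcome class")
    X0, _ = _design(sub, adjust, pcs=None if pcs is None else pcs[mask])
    b0, ll0, _, _ = _logit_fit(X0, y)
    start = np.append(b0, 0.0)
    rows = []
    for j in range(matrix.n_variants):
        d = matrix.dosages[mask, j]
        vid = matrix.variants["variant_id"].iloc[j]
        finite = np.isfinite(d)
        if not finite.all():
            res = fit_variant(matrix.dosages[:, j], samples, contrast, adjust=adjust,
                              pcs=pcs, min_cimba_per_country=min_cimba_per_country)
        elif np.all(d == d[0]):
            res = AssocResult(vid, 0.0, np.inf, 1.0, len(y), contrast.name, True)
        else:
            X1 = np.column_stack([X0, d])
            b1, ll1, cov1, conv = _logit_fit(X1, y, beta0=start)
            lrt = max(2.0 * (ll1 - ll0), 0.0)
            res = AssocResult(vid, float(b1[-1]), float(np.sqrt(max(cov1[-1, -1], 0.0))),
                              float(stats.chi2.sf(lrt, 1)), len(y), contrast.name, conv)
        res.variant_id = vid
        rows.append({
            "variant_id": vid,
            "chrom": matrix.variants["chrom"].iloc[j],
            "pos": matrix.variants["pos"].iloc[j],
            "beta": res.beta, "se": res.se, "or": res.or_, "p": res.p,
            "n": res.n_used, "analysis": res.analysis, "converged": res.converged,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def ld_prune(matrix: GenotypeMatrix, r2_threshold: float = 0.1,
             window: int = 500, step: int = 250) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns a boolean keep mask."""
    n_var = matrix.n_variants
    keep = np.ones(n_var, dtype=bool)
    dos = matrix.dosages
    start = 0
    while start < n_var:
        end = min(start + window, n_var)
        idx = [j for j in range(start, end) if keep[j]]
        for a_pos, j in enumerate(idx):
            if not keep[j]:
                continue
            dj = dos[:, j]
            for k in idx[a_pos + 1:]:
                if not keep[k]:
                    continue
                dk = dos[:, k]
                ok = np.isfinite(dj) & np.isfinite(dk)
                if ok.sum() < 3 or np.std(dj[ok]) == 0 or np.std(dk[ok]) == 0:
                    continue
                r = np.corrcoef(dj[ok], dk[ok])[0, 1]
                if r * r > r2_threshold:
                    keep[k] = False
        if end == n_var:
            break
        start += step
    return keep


def compute_pcs(matrix: GenotypeMatrix, n_pcs: int = 4, pruned_mask=None,
                r2_threshold: float = 0.1) -> np.ndarray:
    """Ancestry principal components from standardized genotyped dosages.

    The variant set is restricted to genotyped variants and LD-pruned
    (pairwise r^2 < ``r2_threshold``) unless a precomputed mask is supplied.
    Signs are fixed so the largest-magnitude loading of each component is
    positive, making repeated runs identical.
    """
    geno = matrix.variants["genotyped"].to_numpy(dtype=bool)
    if pruned_mask is None:
        sub = matrix.subset_variants(geno)
        pruned = ld_prune(sub, r2_threshold=r2_threshold)
        use = sub.dosages[:, pruned]
    else:
        use = matrix.dosages[:, np.asarray(pruned_mask)]
    if use.shape[1] < n_pcs:
        raise ValueError(f"need >= {n_pcs} variants for {n_pcs} PCs, have {use.shape[1]}")
    col_mean = np.nanmean(use, axis=0)
    filled = np.where(np.isfinite(use), use, col_mean)
    sd = filled.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (filled - col_mean) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :n_pcs] * S[:n_pcs]
    for k in range(pcs.shape[1]):
        load = Vt[k]
        if load[np.argmax(np.abs(load))] < 0:
            pcs[:, k] = -pcs[:, k]
    return pcs


# ---------------------------------------------------------------------------
# inflation accounting
# ---------------------------------------------------------------------------

def genomic_inflation(p_values=None, n: int = None, m: int = None,
                      chi2s=None, lam: float = None) -> InflationStats:
    """Genomic-control lambda and its effective-size rescaling lambda_1000.

    lambda is the median observed 1-df chi-square over its null median;
    lambda_1000 = (lambda - 1) * (1/n + 1/m) * 500 + 1 where n and m are the
    population- and carrier-cohort sizes.
    """
    if lam is None:
        if chi2s is None:
            if p_values is None:
                raise ValueError("supply p_values, chi2s or lam")
            p_values = np.asarray(p_values, dtype=float)
            if p_values.size < 100:
                raise ValueError("need >= 100 test statistics for a stable lambda")
            chi2s = stats.chi2.isf(np.clip(p_values, 1e-300, 1.0), 1)
        chi2s = np.asarray(chi2s, dtype=float)
        lam = float(np.median(chi2s) / CHI2_MEDIAN_1DF)
    if n is None or m is None or n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    lambda_1000 = (lam - 1.0) * (1.0 / n + 1.0 / m) * 500.0 + 1.0
    return InflationStats(lam=lam, lambda_1000=float(lambda_1000), n=n, m=m)


# ---------------------------------------------------------------------------
# heterogeneity and sensitivity
# ---------------------------------------------------------------------------

def heterogeneity_by_country(dosage, samples, contrast: Contrast,
                             adjust=("age", "country"), pcs=None,
                             min_cimba_per_country: int = 10):
    """LRT comparing models with and without SNP-by-country interaction terms.

    df = (number of countries with both outcome classes) - 1; countries with
    a single class are dropped from the interaction and the df reduced.
    """
    mask = contrast_mask(samples, contrast, min_cimba_per_country)
    dosage = np.asarray(dosage, dtype=float)
    ok = mask & np.isfinite(dosage)
    sub = samples.loc[ok]
    y = outcome_vector(sub)
    countries = sorted(sub["country"].unique())
    if len(countries) < 2:
        raise ValueError("heterogeneity test requires >= 2 countries")
    informative = [c for c in countries
                   if sub.loc[sub["country"] == c].pipe(outcome_vector).std() > 0]
    if len(informative) < 2:
        raise ValueError("heterogeneity test requires >= 2 countries with both classes")
    X0, _ = _design(sub, adjust, pcs=None if pcs is None else pcs[ok], countries=countries)
    d = dosage[ok]
    Xm = np.column_stack([X0, d])
    b_m, ll_m, _, _ = _logit_fit(Xm, y)
    inter = [d * (sub["country"] == c).to_numpy(dtype=float) for c in informative[1:]]
    Xh = np.column_stack([Xm] + inter)
    b_h, ll_h, _, _ = _logit_fit(Xh, y, beta0=np.append(b_m, np.zeros(len(inter))))
    df = len(informative) - 1
    lrt = max(2.0 * (ll_h - ll_m), 0.0)
    return float(stats.chi2.sf(lrt, df)), df


def leave_one_country_out(dosage, samples, contrast: Contrast,
                          adjust=("age", "country"), pcs=None,
                          min_cimba_per_country: int = 10) -> pd.DataFrame:
    """Refit excluding each country in turn; flag influential countries.

    A country is flagged when its exclusion moves the odds-ratio estimate
    outside the full-data 95% confidence interval.
    """
    mask = contrast_mask(samples, contrast, min_cimba_per_country)
    countries = sorted(samples.loc[mask, "country"].unique())
    if len(countries) < 3:
        raise ValueError("leave-one-out requires >= 3 countries")
    full = fit_variant(dosage, samples, contrast, adjust=adjust, pcs=pcs,
                       min_cimba_per_country=min_cimba_per_country)
    lo, hi = full.ci()
    rows = []
    for c in countries:
        keep = samples["country"] != c
        try:
            res = fit_variant(np.asarray(dosage)[keep.to_numpy()], samples.loc[keep],
                              contrast, adjust=adjust,
                              pcs=None if pcs is None else pcs[keep.to_numpy()],
                              min_cimba_per_country=min_cimba_per_country)
            rows.append({"excluded_country": c, "or": res.or_, "p": res.p,
                         "estimable": True, "outside_full_ci": not (lo <= res.or_ <= hi)})
        except ValueError:
            rows.append({"excluded_country": c, "or": np.nan, "p": np.nan,
                         "estimable": False, "outside_full_ci": False})
    return pd.DataFrame(rows)
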