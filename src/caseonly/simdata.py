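"""Two-consortium synthetic genotype/phenotype generator.

Emulates the statistical structure the case-only analysis assumes: a
population cohort ("BCAC-like" cases and controls, non-carriers) and a
carrier cohort ("CIMBA-like" affected and unaffected mutation carriers),
with LD blocks, two-way ancestral structure, country strata, cohort-specific
age distributions, an ER-status mixture that differs by carrier status,
variants in linkage with carrier status (to exercise the independence
screen) and planted carrier-by-SNP interaction effects.

Haplotypes come from a Gaussian copula: within a block, latent normals form
an autoregressive chain whose lag correlation is calibrated (via the
bivariate-normal orthant probability) so that the realized allelic
correlation between adjacent SNPs equals ``ld_rho``; blocks are independent.
Disease status follows a prospective logistic model

    logit P(case) = b0 + sum b_pop * g + sum b_int * g * carrier
                    + country effect + ancestry effect,

sampled by rejection until the requested case/control counts are met.  Under
this model the case-only log-OR estimates the interaction coefficient up to
a small attenuation that shrinks with the baseline disease probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .geno_io import GenotypeMatrix, validate_samples

__all__ = [
    "SimConfig",
    "HaplotypePool",
    "simulate_haplotype_pool",
    "simulate_cohorts",
    "write_truth_table",
    "read_truth_table",
]

_SQRT2 = np.sqrt(2.0)


def _phi(x):
    return 0.5 * (1.0 + special.erf(x / _SQRT2))


def _bvn_cdf(h, k, rho):
    """P(Z1 < h, Z2 < k) for standard bivariate normal, via Owen's T."""
    if abs(rho) >= 1.0 - 1e-12:
        rho = np.sign(rho) * (1.0 - 1e-12)
    if h == 0.0:
        h = 1e-12
    if k == 0.0:
        k = 1e-12
    denom = np.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = 0.0 if h * k > 0 else 0.5
    val = 0.5 * (_phi(h) + _phi(k)) - special.owens_t(h, a_h) - special.owens_t(k, a_k) - beta
    return float(np.clip(val, 0.0, 1.0))


def _binary_corr(f1, f2, rho_latent):
    """Allelic correlation of two thresholded latent normals."""
    t1, t2 = stats.norm.ppf(f1), stats.norm.ppf(f2)
    p11 = _bvn_cdf(t1, t2, rho_latent)
    denom = np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    return (p11 - f1 * f2) / denom


def _calibrate_latent_rho(f1, f2, target):
    """Latent correlation giving adjacent allelic correlation = target."""
    if target == 0.0:
        return 0.0
    hi = 0.99999
    r_max = _binary_corr(f1, f2, hi)
    if r_max <= target:
        return hi
    return float(optimize.brentq(lambda r: _binary_corr(f1, f2, r) - target,
                                 0.0, hi, xtol=1e-8))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic two-consortium dataset.

    Defaults mirror the study conditions the analysis was built for, at a
    scale a workstation can simulate: four countries, carrier cases about
    sixteen years younger than population cases, a predominantly ER-negative
    tumour mixture in carriers and roughly one fifth ER-negative in the
    population cohort.  Effect lists refer to generated variant ids
    (``var00000``, ``var00001``, ... in panel order).
    """

    n_bcac_cases: int = 5000
    n_bcac_controls: int = 5000
    n_cimba_cases: int = 5000
    n_cimba_unaffected: int = 5000
    n_blocks: int = 10
    snps_per_block: int = 10
    allele_freq_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.6
    n_countries: int = 4
    country_effect_sd: float = 0.2
    fst_like_shift: float = 0.0
    interaction_effects: list = field(default_factory=list)   # [(variant_id, log-OR)]
    population_effects: list = field(default_factory=list)    # [(variant_id, log-OR)]
    linked_to_carrier: list = field(default_factory=list)     # [(variant_id, freq offset)]
    er_neg_prob_carrier: float = 0.7
    er_neg_prob_population: float = 0.2
    age_mean_by_cohort: dict = field(default_factory=lambda: {"BCAC": 58.4, "CIMBA": 42.5})
    age_sd: float = 8.0
    er_missing_prob: float = 0.28
    prevalent_prob_by_cohort: dict = field(default_factory=lambda: {"BCAC": 0.423, "CIMBA": 0.681})
    carrier_gene: str = "BRCA1"
    baseline_logit: float = -4.0
    ancestry_effect: float = 0.0
    subpop_b_prob: dict = field(default_factory=lambda: {"BCAC": 0.5, "CIMBA": 0.5})
    genotyped_fraction: float = 0.3
    imputed_r2_range: tuple = (0.3, 1.0)
    seed: int = 0

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.snps_per_block

    def variant_ids(self) -> list:
        return [f"var{i:05d}" for i in range(self.n_variants)]

    def validate(self) -> None:
        for name in ["n_bcac_cases", "n_bcac_controls", "n_cimba_cases",
                     "n_cimba_unaffected", "n_blocks", "snps_per_block", "n_countries"]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        for name in ["er_neg_prob_carrier", "er_neg_prob_population", "er_missing_prob",
                     "genotyped_fraction"]:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie strictly inside (0, 1)")
        ids = set(self.variant_ids())
        for lst, name in [(self.interaction_effects, "interaction_effects"),
                          (self.population_effects, "population_effects"),
                          (self.linked_to_carrier, "linked_to_carrier")]:
            for vid, _ in lst:
                if vid not in ids:
                    raise ValueError(f"{name} references unknown variant {vid!r}")

    def _child_rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class HaplotypePool:
    """Binary haplotypes (haplotype x variant) with panel metadata."""

    haplotypes: np.ndarray
    positions: np.ndarray
    chroms: np.ndarray
    frequencies: np.ndarray
    block_bounds: list  # [(start, end)] half-open variant index ranges

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


def _build_panel(config: SimConfig):
    """Variant panel layout: ids, chromosomes, positions, base frequencies."""
    rng = config._child_rng(0)
    lo, hi = config.allele_freq_range
    freqs = rng.uniform(lo, hi, size=config.n_variants)
    chroms, positions, bounds = [], [], []
    for b in range(config.n_blocks):
        chrom = str(1 + b % 22)
        base = 1_000_000 + (b // 22) * 2_000_000
        start = b * config.snps_per_block
        bounds.append((start, start + config.snps_per_block))
        for i in range(config.snps_per_block):
            chroms.append(chrom)
            positions.append(base + i * 2_000)
    return (np.asarray(config.variant_ids()), np.asarray(chroms),
            np.asarray(positions, dtype=int), freqs, bounds)


def _subpop_freqs(config: SimConfig, base_freqs: np.ndarray, subpopulation: str) -> np.ndarray:
    shift = config.fst_like_shift if subpopulation == "A" else -config.fst_like_shift
    freqs = base_freqs + shift
    if np.any((freqs < 0.01) | (freqs > 0.99)):
        warnings.warn("allele frequency clamped to [0.01, 0.99] after subpopulation shift",
                      stacklevel=2)
        freqs = np.clip(freqs, 0.01, 0.99)
    return freqs


class _CopulaSampler:
    """Per-subpopulation calibrated thresholded-AR haplotype sampler."""

    def __init__(self, config: SimConfig, freqs: np.ndarray, block_bounds):
        self.thresholds = stats.norm.ppf(freqs)
        self.block_bounds = block_bounds
        n_var = len(freqs)
        self.lag = np.zeros(n_var)
        if config.ld_rho > 0:
            for start, end in block_bounds:
                for j in range(start + 1, end):
                    self.lag[j] = _calibrate_latent_rho(freqs[j - 1], freqs[j], config.ld_rho)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        out = np.empty((n, len(self.thresholds)), dtype=np.uint8)
        for start, end in self.block_bounds:
            z = rng.standard_normal(n)
            out[:, start] = z < self.thresholds[start]
            for j in range(start + 1, end):
                a = self.lag[j]
                z = a * z + np.sqrt(1.0 - a * a) * rng.standard_normal(n)
                out[:, j] = z < self.thresholds[j]
        return out


def simulate_haplotype_pool(config: SimConfig, subpopulation: str = "A",
                            n_haplotypes: int = 10_000) -> HaplotypePool:
    """Draw a pool of binary haplotypes for one ancestral subpopulation."""
    config.validate()
    if subpopulation not in {"A", "B"}:
        raise ValueError("subpopulation must be 'A' or 'B'")
    ids, chroms, positions, base_freqs, bounds = _build_panel(config)
    freqs = _subpop_freqs(config, base_freqs, subpopulation)
    sampler = _CopulaSampler(config, freqs, bounds)
    rng = config._child_rng(1 if subpopulation == "A" else 2)
    haps = sampler.draw(n_haplotypes, rng)
    return HaplotypePool(haps, positions, chroms, freqs, bounds)


def _effect_vector(config: SimConfig, pairs) -> np.ndarray:
    vec = np.zeros(config.n_variants)
    index = {vid: i for i, vid in enumerate(config.variant_ids())}
    for vid, val in pairs:
        vec[index[vid]] += val
    return vec


def simulate_cohorts(config: SimConfig, max_rounds: int = 200):
    """Generate the full two-consortium dataset.

    Returns ``(GenotypeMatrix, sample table, truth table)``.  Identical
    configs (including seed) give byte-identical outputs.
    """
    config.validate()
    ids, chroms, positions, base_freqs, bounds = _build_panel(config)
    samplers = {s: _CopulaSampler(config, _subpop_freqs(config, base_freqs, s), bounds)
                for s in ("A", "B")}

    rng_struct = config._child_rng(3)
    country_effects = rng_struct.normal(0.0, config.country_effect_sd, size=config.n_countries)
    countries = [f"C{i + 1}" for i in range(config.n_countries)]

    beta_pop = _effect_vector(config, config.population_effects)
    beta_int = _effect_vector(config, config.interaction_effects)
    link_offset = _effect_vector(config, config.linked_to_carrier)
    index = {vid: i for i, vid in enumerate(ids)}
    linked_idx = [index[vid] for vid, _ in config.linked_to_carrier]

    cohort_specs = [
        ("BCAC", False, config.n_bcac_cases, config.n_bcac_controls, 4),
        ("CIMBA", True, config.n_cimba_cases, config.n_cimba_unaffected, 5),
    ]

    dosage_parts, sample_rows = [], []
    sid = 0
    for cohort, is_carrier, need_cases, need_controls, key in cohort_specs:
        rng = config._child_rng(key)
        got_cases, got_controls = 0, 0
        kept_dos, kept_meta = [], []
        batch = max(2048, need_cases + need_controls)
        p_b = config.subpop_b_prob[cohort]
        for _ in range(max_rounds):
            if got_cases >= need_cases and got_controls >= need_controls:
                break
            subpop = np.where(rng.random(batch) < p_b, "B", "A")
            dos = np.empty((batch, config.n_variants), dtype=np.int8)
            for s in ("A", "B"):
                m = subpop == s
                n_s = int(m.sum())
                if n_s == 0:
                    continue
                haps = samplers[s].draw(2 * n_s, rng)
                dos[m] = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))
            if is_carrier and linked_idx:
                for j in linked_idx:
                    f = base_freqs[j]
                    delta = link_offset[j]
                    d = dos[:, j].astype(np.int8)
                    if delta > 0:
                        p_up = min(delta / (1 - f), 1.0)
                        add = rng.random((batch, 2)) < p_up
                        room = np.clip(2 - d, 0, 2)
                        inc = np.minimum(add.sum(axis=1), room)
                        dos[:, j] = d + inc.astype(np.int8)
                    elif delta < 0:
                        p_dn = min(-delta / f, 1.0)
                        rem = rng.random((batch, 2)) < p_dn
                        dec = np.minimum(rem.sum(axis=1), d)
                        dos[:, j] = d - dec.astype(np.int8)
            country_ix = rng.integers(0, config.n_countries, size=batch)
            eta = (config.baseline_logit
                   + dos @ beta_pop
                   + (dos @ beta_int if is_carrier else 0.0)
                   + country_effects[country_ix]
                   + config.ancestry_effect * (subpop == "B"))
            p_case = 1.0 / (1.0 + np.exp(-eta))
            is_case = rng.random(batch) < p_case
            for take_case in (True, False):
                want = (need_cases - got_cases) if take_case else (need_controls - got_controls)
                if want <= 0:
                    continue
                rows = np.flatnonzero(is_case == take_case)[:want]
                if rows.size == 0:
                    continue
                kept_dos.append(dos[rows])
                for r in rows:
                    kept_meta.append((take_case, country_ix[r], subpop[r]))
                if take_case:
                    got_cases += rows.size
                else:
                    got_controls += rows.size
        if got_cases < need_cases or got_controls < need_controls:
            stratum = "cases" if got_cases < need_cases else "controls"
            raise RuntimeError(
                f"could not reach requested {stratum} count for cohort {cohort} "
                f"after {max_rounds} sampling rounds")
        dos_cohort = np.concatenate(kept_dos, axis=0)
        dosage_parts.append(dos_cohort.astype(np.float32))
        rng_ph = config._child_rng(key + 10)
        for (case, c_ix, subpop_lab) in kept_meta:
            status = "case" if case else "control"
            age = float(np.clip(rng_ph.normal(config.age_mean_by_cohort[cohort],
                                              config.age_sd), 18.0, None))
            if case:
                p_neg = (config.er_neg_prob_carrier if is_carrier
                         else config.er_neg_prob_population)
                er = "negative" if rng_ph.random() < p_neg else "positive"
                if rng_ph.random() < config.er_missing_prob:
                    er = "unknown"
                prevalent = bool(rng_ph.random() < config.prevalent_prob_by_cohort[cohort])
            else:
                er = "unknown"
                prevalent = False
            sample_rows.append({
                "sample_id": f"S{sid:06d}",
                "cohort": cohort,
                "status": status,
                "carrier_gene": config.carrier_gene if is_carrier else "none",
                "age": age,
                "country": countries[c_ix],
                "er_status": er,
                "subpop": subpop_lab,
                "is_prevalent": prevalent,
            })
            sid += 1

    dosages = np.concatenate(dosage_parts, axis=0).astype(float)
    samples = validate_samples(pd.DataFrame(sample_rows))

    rng_meta = config._child_rng(8)
    genotyped = rng_meta.random(config.n_variants) < config.genotyped_fraction
    r2_lo, r2_hi = config.imputed_r2_range
    r2_bcac = np.where(genotyped, 1.0, rng_meta.uniform(r2_lo, r2_hi, config.n_variants))
    r2_cimba = np.where(genotyped, 1.0, rng_meta.uniform(r2_lo, r2_hi, config.n_variants))
    call_rate = np.where(genotyped, rng_meta.uniform(0.96, 1.0, config.n_variants), 1.0)
    bcac_cases = ((samples["cohort"] == "BCAC") & (samples["status"] == "case")).to_numpy()
    maf = dosages[bcac_cases].mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)

    variants = pd.DataFrame({
        "variant_id": ids, "chrom": chroms, "pos": positions,
        "ref": "A", "alt": "G",
        "genotyped": genotyped, "r2_bcac": r2_bcac, "r2_cimba": r2_cimba,
        "maf_bcac_cases": maf, "call_rate": call_rate,
    })
    matrix = GenotypeMatrix(dosages, variants, samples["sample_id"].to_numpy())

    truth = pd.DataFrame({
        "variant_id": ids,
        "beta_interaction": beta_int,
        "beta_population": beta_pop,
        "carrier_linked": link_offset != 0.0,
        "link_offset": link_offset,
    })
    return matrix, samples, truth


def write_truth_table(truth: pd.DataFrame, path) -> None:
    if len(truth) == 0:
        raise ValueError("truth table is empty")
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
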