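"""Synthetic cohort generator with Mendelian trio genotypes and an SES pathway.

The generator produces families of siblings (MZ twins, DZ twins, full
siblings, singletons) with phased parental haplotypes, per-child
transmitted/non-transmitted allele bookkeeping, a parental-SES latent built
from the summed parental genome scores plus environmental noise, observable
SES indicators derived from that latent, and a two-wave verbal-ability
phenotype with family / person / wave random intercepts.

Causal structure
----------------
* each child receives, at every SNP, one of the two alleles of each parent
  with probability 1/2, independently across SNPs (no linkage);
* parental SES latent:  S* = gamma * (U_mother + U_father) + eps_S,
  eps_S ~ N(0, var_ses_env), where U is a parent's true genome score;
* phenotype (per person-wave row):

      Y = beta0 + b_child * Z(U_o) + c_env * Z(S*) + gxe * Z(U_o) Z(S*)
          + demographic terms + mu_family + nu_person + e_wave

Because parental SES is driven by *all* parental alleles while the child
receives only half of them, the offspring score and the SES latent are
correlated; downstream model fits can therefore be validated against the
closed-form population slopes in :func:`model_implied_slopes` and against
the stored ground truth (``TruthRecord``).

Everything is drawn from a single ``numpy`` Generator seeded by
``SimulationConfig.seed``: identical configs give identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "TrioGenotypes",
    "TruthRecord",
    "SimulatedCohort",
    "transmit_alleles",
    "build_parental_ses",
    "simulate_cohort",
    "inject_missingness",
    "write_cohort",
    "read_cohort",
    "model_implied_slopes",
    "parent_offspring_correlation",
    "mean_ibd_proportion",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


SIBSHIP_TYPES = ("mz", "dz", "fullsib", "singleton")

#: columns of the cohort table that count as SES indicators for missingness
SES_INDICATOR_COLUMNS = (
    "mother_edu",
    "father_edu",
    "mother_occ_code",
    "father_occ_code",
    "income_quintile",
    "sibship_size",
)

TRACT_MEASURES = (
    "tract_poverty",
    "tract_unemployment",
    "tract_female_headed",
    "tract_no_hs_diploma",
    "tract_college_degree",
    "tract_managerial_jobs",
)

EDUCATION_LEVELS = ("lt_hs", "hs_some_college", "college")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the generative model.

    Defaults define the package's reference study conditions: a cohort of
    roughly 5,000 persons in sibling-clustered families on a PVT-like
    phenotype scale, with the SES latent carrying a genomic share of about
    18% of its variance and analyst weight files that are noisy versions of
    the true per-SNP weights.
    """

    n_families: int = 3000
    #: siblings per non-singleton family: an int, or a {size: prob} mapping
    sibs_per_family: int | dict = 2
    #: proportions of family types, keys from SIBSHIP_TYPES
    sibship_mix: dict = field(
        default_factory=lambda: {
            "mz": 0.05,
            "dz": 0.05,
            "fullsib": 0.60,
            "singleton": 0.30,
        }
    )
    n_snps: int = 200
    allele_freq_range: tuple = (0.2, 0.8)
    n_strata: int = 2
    strata_weights: tuple = (0.8, 0.2)
    fst: float = 0.01
    #: sd of true weights is tau/sqrt(K) so the score variance is K-invariant
    tau: float = 1.0
    #: effect of summed parental genome score on the parental-SES latent
    gamma: float = 0.5
    #: effect of one SD of the offspring true score on the phenotype
    b_child: float = 2.5
    #: effect of one SD of the SES latent on the phenotype
    c_env: float = 4.2
    #: interaction between standardized offspring score and SES latent
    gxe_coef: float = 0.0
    var_ses_env: float = 1.0
    var_family: float = 38.0
    var_person: float = 28.0
    var_wave: float = 25.0
    #: per-SNP sd of noise added to true weights (education-like weight file)
    gwas_noise_sd: float = 0.065
    #: same for the weaker, cognition-like weight file
    gwas_noise_sd_cog: float = 0.12
    missing_rate: float = 0.05
    beta0: float = 85.0
    age_effect: float = 0.4
    sex_effect: float = -1.1
    stratum_effect: float = -4.4
    in_school_effect: float = 1.5
    us_born_effect: float = 2.0
    english_home_effect: float = 4.6
    seed: int = 2022

    def __post_init__(self):
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("allele_freq_range must satisfy 0 < lo < hi < 1")
        for name in ("var_ses_env", "var_family", "var_person", "var_wave", "fst"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must be in [0, 1]")
        mix = self.sibship_mix
        unknown = set(mix) - set(SIBSHIP_TYPES)
        if unknown:
            raise ConfigError(f"unknown sibship types in mix: {sorted(unknown)}")
        total = sum(mix.values())
        if any(v < 0 for v in mix.values()) or abs(total - 1.0) > 1e-8:
            raise ConfigError("sibship_mix proportions must be >= 0 and sum to 1")
        if self.n_strata < 1:
            raise ConfigError("n_strata must be >= 1")
        if len(self.strata_weights) != self.n_strata:
            raise ConfigError("strata_weights length must equal n_strata")
        if abs(sum(self.strata_weights) - 1.0) > 1e-8:
            raise ConfigError("strata_weights must sum to 1")
        sizes = self._sib_sizes()
        if min(sizes) < 1:
            raise ConfigError("sibs_per_family sizes must be >= 1")
        twins = mix.get("mz", 0) + mix.get("dz", 0)
        if twins > 0 and max(sizes) < 2:
            raise ConfigError(
                "infeasible sibship mix: twin families requested with sibs_per_family=1"
            )

    def _sib_sizes(self):
        if isinstance(self.sibs_per_family, int):
            return [self.sibs_per_family]
        return sorted(self.sibs_per_family)

    def draw_sib_count(self, rng) -> int:
        if isinstance(self.sibs_per_family, int):
            return self.sibs_per_family
        sizes = sorted(self.sibs_per_family)
        probs = np.array([self.sibs_per_family[s] for s in sizes], dtype=float)
        probs = probs / probs.sum()
        return int(rng.choice(sizes, p=probs))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["allele_freq_range"] = list(self.allele_freq_range)
        d["strata_weights"] = list(self.strata_weights)
        return d


@dataclass
class TrioGenotypes:
    """Phased parental haplotypes plus per-child transmission bookkeeping.

    Arrays are indexed by family (``F``), parent (0=mother, 1=father),
    haplotype (0/1) and SNP (``K``); children are rows of the person-level
    arrays in the same order as ``TruthRecord.persons``.
    """

    snp_ids: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    allele_freqs: np.ndarray          # (n_strata, K) per-stratum frequencies
    true_weights: np.ndarray          # (K,)
    parent_haplotypes: np.ndarray     # (F, 2, 2, K) uint8
    family_ids: np.ndarray            # (F,)
    family_stratum: np.ndarray        # (F,)
    person_ids: np.ndarray            # (N,)
    person_family_index: np.ndarray   # (N,) index into family arrays
    transmitted: np.ndarray           # (N, 2, K) allele transmitted per parent
    non_transmitted: np.ndarray       # (N, 2, K)
    transmission_choice: np.ndarray   # (N, 2, K) which haplotype was passed

    @property
    def child_dosages(self) -> np.ndarray:
        """0/1/2 effect-allele counts per child (N, K)."""
        return self.transmitted.sum(axis=1)

    @property
    def parent_dosages(self) -> np.ndarray:
        """(F, 2, K) dosage of each parent."""
        return self.parent_haplotypes.sum(axis=2)

    def scores(self):
        """(t_score, nt_score) per child: weighted transmitted / non-transmitted sums."""
        w = self.true_weights
        t = self.transmitted.sum(axis=1) @ w
        nt = self.non_transmitted.sum(axis=1) @ w
        return t, nt

    def parent_scores(self) -> np.ndarray:
        """(F, 2) true score of each parent."""
        return self.parent_dosages @ self.true_weights


@dataclass
class TruthRecord:
    """Ground truth: per-person latent quantities and the parameters used."""

    persons: pd.DataFrame
    params: dict

    def verify_mendelian(self, trios: TrioGenotypes) -> None:
        """Assert the built-in Mendelian identities; raises AssertionError."""
        dos = trios.child_dosages
        assert dos.min() >= 0 and dos.max() <= 2
        t, nt = trios.scores()
        np.testing.assert_allclose(t, self.persons["t_score"].to_numpy())
        np.testing.assert_allclose(nt, self.persons["nt_score"].to_numpy())


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: pd.DataFrame
    trios: TrioGenotypes
    truth: TruthRecord
    weights: dict            # {"edu": DataFrame, "cog": DataFrame} analyst files
    config: SimulationConfig


# ---------------------------------------------------------------------------
# transmission


def transmit_alleles(parent_haplotypes, rng):
    """Transmit one allele per SNP from a phased parent.

    Parameters
    ----------
    parent_haplotypes : array-like
        Two 0/1 haplotype arrays of equal length (shape ``(2, K)`` or a pair).
    rng : numpy.random.Generator

    Returns
    -------
    (transmitted, non_transmitted) : pair of (K,) uint8 arrays
    """
    hap = np.asarray(parent_haplotypes)
    if hap.ndim != 2 or hap.shape[0] != 2:
        a, b = parent_haplotypes
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("parent haplotypes must be two equal-length 1-D arrays")
        hap = np.stack([a, b])
    if hap.shape[0] != 2:
        raise ValueError("a parent has exactly two haplotypes")
    k = hap.shape[1]
    pick = rng.integers(0, 2, size=k)
    cols = np.arange(k)
    transmitted = hap[pick, cols]
    non_transmitted = hap[1 - pick, cols]
    return transmitted.astype(np.uint8), non_transmitted.astype(np.uint8)


def _transmission_bits(rng, n, k):
    return rng.integers(0, 2, size=(n, 2, k), dtype=np.uint8)


# ---------------------------------------------------------------------------
# SES indicators


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _quantile_cut(latent, qs, labels, rng=None):
    """Cut a latent variable at sample quantiles into ordered labels."""
    if len(latent) == 0:
        return np.array([], dtype=object)
    edges = np.quantile(latent, qs)
    idx = np.searchsorted(edges, latent, side="right")
    return np.asarray(labels, dtype=object)[idx]


def build_parental_ses(parent_scores, config: SimulationConfig, rng):
    """Build the family SES latent and its observable indicators.

    ``parent_scores`` is an ``(F, 2)`` array of parental true genome scores.
    Returns ``(ses_latent, indicators)`` where ``indicators`` is a family-level
    DataFrame holding ordinal education, occupation codes, income quintile,
    sibship size, the two-biological-parent flag and six tract proportions
    per wave. All indicators are noisy monotone functions of the latent, so
    the multi-indicator SES block and the neighborhood index of the design
    builder are exercised without modelling each indicator causally.
    """
    from .sesbuild import load_occupation_lookup

    parent_scores = np.asarray(parent_scores, dtype=float)
    n_fam = parent_scores.shape[0]
    eps = rng.normal(0.0, math.sqrt(config.var_ses_env), size=n_fam)
    ses = config.gamma * parent_scores.sum(axis=1) + eps

    if n_fam == 0:
        z = np.array([])
    else:
        sd = ses.std(ddof=1) if n_fam > 1 else 1.0
        z = (ses - ses.mean()) / (sd if sd > 0 else 1.0)

    lookup = load_occupation_lookup()
    by_prestige = {
        p: lookup.loc[lookup["prestige11"] == p, "occ_code"].tolist()
        for p in sorted(lookup["prestige11"].unique())
    }

    def occ_codes(noise_sd=1.0):
        latent = z + rng.normal(0, noise_sd, n_fam)
        if n_fam == 0:
            return np.array([], dtype=float)
        ranks = latent.argsort().argsort() / max(n_fam - 1, 1)
        prestige = np.clip(np.ceil(ranks * 11), 1, 11).astype(int)
        out = np.empty(n_fam, dtype=float)
        for i, p in enumerate(prestige):
            codes = by_prestige.get(p) or by_prestige[min(by_prestige, key=lambda q: abs(q - p))]
            out[i] = codes[int(rng.integers(0, len(codes)))]
        return out

    ind = pd.DataFrame(index=pd.RangeIndex(n_fam))
    # tercile-like cuts matched loosely to the observed education distribution
    ind["mother_edu"] = _quantile_cut(z + rng.normal(0, 0.8, n_fam), [0.16, 0.75], EDUCATION_LEVELS)
    ind["father_edu"] = _quantile_cut(z + rng.normal(0, 0.8, n_fam), [0.16, 0.75], EDUCATION_LEVELS)
    ind["mother_occ_code"] = occ_codes()
    ind["father_occ_code"] = occ_codes()
    inc_latent = z + rng.normal(0, 0.7, n_fam)
    ind["income_quintile"] = (
        _quantile_cut(inc_latent, [0.2, 0.4, 0.6, 0.8], [1, 2, 3, 4, 5]).astype(float)
        if n_fam
        else np.array([])
    )
    ind["two_bio_parents"] = (rng.random(n_fam) < _sigmoid(0.1 + 0.5 * z)).astype(int)
    ind["sibship_size"] = np.clip(
        np.round(2.2 - 0.9 * z + rng.normal(0, 1.2, n_fam)), 0, 15
    ).astype(float)

    shared = -z + rng.normal(0, 0.5, n_fam)
    for wave in (1, 3):
        d = shared + rng.normal(0, 0.4, n_fam)
        ind[f"tract_poverty_w{wave}"] = _sigmoid(-1.5 + 0.8 * d)
        ind[f"tract_unemployment_w{wave}"] = _sigmoid(-2.0 + 0.6 * d)
        ind[f"tract_female_headed_w{wave}"] = _sigmoid(-1.6 + 0.5 * d)
        ind[f"tract_no_hs_diploma_w{wave}"] = _sigmoid(-1.2 + 0.7 * d)
        ind[f"tract_college_degree_w{wave}"] = _sigmoid(-0.8 - 0.7 * d)
        ind[f"tract_managerial_jobs_w{wave}"] = _sigmoid(-1.0 - 0.6 * d)
    return ses, ind


# ---------------------------------------------------------------------------
# main generator


def _draw_snps(config: SimulationConfig, rng):
    k = config.n_snps
    snp_ids = np.array([f"rs{i + 1:06d}" for i in range(k)])
    bases = np.array(list("ACGT"))
    eff_idx = rng.integers(0, 4, size=k)
    shift = rng.integers(1, 4, size=k)
    effect = bases[eff_idx]
    other = bases[(eff_idx + shift) % 4]
    lo, hi = config.allele_freq_range
    base_p = rng.uniform(lo, hi, size=k)
    if config.n_strata > 1 and config.fst > 0:
        f = config.fst
        a = base_p * (1 - f) / f
        b = (1 - base_p) * (1 - f) / f
        freqs = np.clip(rng.beta(a, b, size=(config.n_strata, k)), 0.01, 0.99)
    else:
        freqs = np.tile(base_p, (config.n_strata, 1))
    weights = rng.normal(0.0, config.tau / math.sqrt(k), size=k)
    return snp_ids, effect, other, freqs, weights


def _standardize(x):
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    Returns the long-format cohort table (two wave rows per person), the trio
    genotypes, the ground-truth record and the two analyst weight tables.
    MCAR missingness at ``config.missing_rate`` is already injected into the
    SES indicator columns of the returned cohort.
    """
    rng = np.random.default_rng(config.seed)
    n_fam = config.n_families
    k = config.n_snps

    snp_ids, effect, other, freqs, weights = _draw_snps(config, rng)

    fam_types = (
        rng.choice(
            SIBSHIP_TYPES,
            size=n_fam,
            p=[config.sibship_mix.get(t, 0.0) for t in SIBSHIP_TYPES],
        )
        if n_fam
        else np.array([], dtype=object)
    )
    fam_stratum = (
        rng.choice(config.n_strata, size=n_fam, p=list(config.strata_weights))
        if n_fam
        else np.array([], dtype=int)
    )
    fam_ids = np.array([f"F{i + 1:05d}" for i in range(n_fam)])

    p_fam = freqs[fam_stratum]  # (F, K)
    parent_haps = (
        rng.random((n_fam, 2, 2, k)) < p_fam[:, None, None, :]
    ).astype(np.uint8)

    # family sizes
    sizes = np.ones(n_fam, dtype=int)
    for i, t in enumerate(fam_types):
        if t == "singleton":
            sizes[i] = 1
        elif t in ("mz", "dz"):
            sizes[i] = 2
        else:
            sizes[i] = config.draw_sib_count(rng)

    n_persons = int(sizes.sum())
    person_fam = np.repeat(np.arange(n_fam), sizes)
    child_rank = np.concatenate([np.arange(s) for s in sizes]) if n_fam else np.array([], dtype=int)
    person_ids = np.array(
        [f"{fam_ids[f]}_{r + 1}" for f, r in zip(person_fam, child_rank)]
    )

    # transmission: per child, per parent, a 0/1 haplotype choice per SNP.
    # MZ co-twins copy the first twin's choices.
    pick = _transmission_bits(rng, n_persons, k)
    if n_persons:
        is_mz = fam_types[person_fam] == "mz"
        first_row_of_family = np.searchsorted(person_fam, person_fam)
        copy_mask = is_mz & (child_rank > 0)
        pick[copy_mask] = pick[first_row_of_family[copy_mask]]

    haps = parent_haps[person_fam]  # (N, 2, 2, K)
    cols = np.arange(k)
    transmitted = np.empty((n_persons, 2, k), dtype=np.uint8)
    non_transmitted = np.empty((n_persons, 2, k), dtype=np.uint8)
    for parent in (0, 1):
        sel = pick[:, parent, :]
        transmitted[:, parent, :] = np.take_along_axis(
            haps[:, parent], sel[:, None, :], axis=1
        )[:, 0, :]
        non_transmitted[:, parent, :] = np.take_along_axis(
            haps[:, parent], (1 - sel)[:, None, :], axis=1
        )[:, 0, :]

    trios = TrioGenotypes(
        snp_ids=snp_ids,
        effect_alleles=effect,
        other_alleles=other,
        allele_freqs=freqs,
        true_weights=weights,
        parent_haplotypes=parent_haps,
        family_ids=fam_ids,
        family_stratum=fam_stratum,
        person_ids=person_ids,
        person_family_index=person_fam,
        transmitted=transmitted,
        non_transmitted=non_transmitted,
        transmission_choice=pick,
    )

    t_score, nt_score = trios.scores()
    u_o = t_score
    parent_scores = trios.parent_scores()
    ses_latent, fam_ind = build_parental_ses(parent_scores, config, rng)

    z_u = _standardize(u_o)
    z_s = _standardize(ses_latent[person_fam]) if n_persons else np.array([])

    # demographics
    female = rng.integers(0, 2, n_persons)
    hispanic = (fam_stratum[person_fam] >= 1).astype(int) if n_persons else np.array([], dtype=int)
    us_born = (rng.random(n_persons) < np.where(hispanic == 1, 0.53, 0.71)).astype(int)
    english_home = (rng.random(n_persons) < np.where(hispanic == 1, 0.55, 1.0)).astype(int)
    age_base_fam = rng.uniform(12, 18, n_fam) if n_fam else np.array([])
    age_w1 = np.empty(n_persons)
    for f, r, i in zip(person_fam, child_rank, range(n_persons)):
        if fam_types[f] in ("mz", "dz") or r == 0:
            age_w1[i] = age_base_fam[f]
        else:
            age_w1[i] = np.clip(age_base_fam[f] + rng.uniform(-3, 3), 12, 18)

    mu_family = rng.normal(0, math.sqrt(config.var_family), n_fam)
    nu_person = rng.normal(0, math.sqrt(config.var_person), n_persons)
    e_wave = rng.normal(0, math.sqrt(config.var_wave), (n_persons, 2))
    in_school = rng.random((n_persons, 2)) < np.array([0.58, 0.45])

    rows = []
    for widx, wave in enumerate((1, 3)):
        age = age_w1 + (7.0 if wave == 3 else 0.0)
        fixed = (
            config.beta0
            + config.b_child * z_u
            + config.c_env * z_s
            + config.gxe_coef * z_u * z_s
            + config.age_effect * age
            + config.sex_effect * female
            + config.stratum_effect * hispanic
            + config.in_school_effect * in_school[:, widx]
            + config.us_born_effect * us_born
            + config.english_home_effect * english_home
        )
        y = fixed + mu_family[person_fam] + nu_person + e_wave[:, widx]
        df = pd.DataFrame(
            {
                "person_id": person_ids,
                "family_id": fam_ids[person_fam],
                "sibship_type": fam_types[person_fam],
                "wave": wave,
                "pvt_score": y,
                "age": age,
                "female": female,
                "us_born": us_born,
                "english_home": english_home,
                "in_school": in_school[:, widx].astype(int),
                "stratum": fam_stratum[person_fam],
                "hispanic": hispanic,
                "tract_id": fam_ids[person_fam],
            }
        )
        fi = fam_ind.iloc[person_fam].reset_index(drop=True)
        for col in (
            "mother_edu",
            "father_edu",
            "mother_occ_code",
            "father_occ_code",
            "income_quintile",
            "two_bio_parents",
            "sibship_size",
        ):
            df[col] = fi[col].to_numpy()
        for m in TRACT_MEASURES:
            df[m] = fi[f"{m}_w{wave}"].to_numpy()
        rows.append(df)

    cohort = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["person_id", "wave"], kind="stable")
        .reset_index(drop=True)
    )

    truth_persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "family_id": fam_ids[person_fam],
            "sibship_type": fam_types[person_fam],
            "stratum": fam_stratum[person_fam],
            "u_true": u_o,
            "t_score": t_score,
            "nt_score": nt_score,
            "ses_latent": ses_latent[person_fam] if n_persons else np.array([]),
            "z_u": z_u,
            "z_ses": z_s,
            "mu_family": mu_family[person_fam] if n_persons else np.array([]),
            "nu_person": nu_person,
            "e_wave1": e_wave[:, 0] if n_persons else np.array([]),
            "e_wave3": e_wave[:, 1] if n_persons else np.array([]),
        }
    )
    var_u_theoretical = _theoretical_score_variance(config, freqs, weights)
    params = dict(config.to_dict())
    params["var_u_theoretical"] = var_u_theoretical
    truth = TruthRecord(persons=truth_persons, params=params)

    def noisy_weights(sd):
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "effect_allele": effect,
                "beta": weights + rng.normal(0, sd, k),
            }
        )

    analyst_weights = {
        "edu": noisy_weights(config.gwas_noise_sd),
        "cog": noisy_weights(config.gwas_noise_sd_cog),
    }

    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, rng)

    return SimulatedCohort(
        cohort=cohort, trios=trios, truth=truth, weights=analyst_weights, config=config
    )


def _theoretical_score_variance(config, freqs, weights):
    """Var(U) = sum_k w_k^2 * 2 p_k q_k for a single stratum (mixture-averaged
    within-stratum term otherwise; only the single-stratum value feeds the
    slope oracle)."""
    p = freqs[0] if config.n_strata == 1 else (np.asarray(config.strata_weights) @ freqs)
    return float(np.sum(weights**2 * 2 * p * (1 - p)))


def parent_offspring_correlation(trios: TrioGenotypes) -> float:
    """Pooled parent-offspring dosage correlation, centered per SNP and stratum.

    Without centering, shared SNP means (and stratum frequency differences)
    inflate the correlation; after centering the expected value under
    Mendelian transmission with random mating is 0.5.
    """
    child = trios.child_dosages.astype(float)
    parents = trios.parent_dosages[trios.person_family_index].astype(float)
    strat = trios.family_stratum[trios.person_family_index]
    xs, ys = [], []
    for s in np.unique(strat):
        m = strat == s
        if m.sum() < 2:
            continue
        c = child[m] - child[m].mean(axis=0)
        for parent in (0, 1):
            p = parents[m, parent, :] - parents[m, parent, :].mean(axis=0)
            xs.append(c.ravel())
            ys.append(p.ravel())
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return float(np.corrcoef(x, y)[0, 1])


def mean_ibd_proportion(trios: TrioGenotypes, fam_types=None,
                        sibship_types=("dz", "fullsib")) -> float:
    """Mean proportion of SNPs at which sibling pairs received the same
    parental haplotype (expected 0.5 for DZ twins and full siblings, 1.0 for
    MZ co-twins). ``fam_types`` is the per-family sibship-type array; omit it
    to pool all sibling pairs."""
    fam_of = trios.person_family_index
    shares = []
    for fam in np.unique(fam_of):
        if fam_types is not None and fam_types[fam] not in sibship_types:
            continue
        idx = np.where(fam_of == fam)[0]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                same = (
                    trios.transmission_choice[idx[a]]
                    == trios.transmission_choice[idx[b]]
                )
                shares.append(same.mean())
    return float(np.mean(shares)) if shares else float("nan")


# ---------------------------------------------------------------------------
# missingness


def inject_missingness(cohort: pd.DataFrame, rate: float, rng) -> pd.DataFrame:
    """Set SES indicator cells to missing completely at random.

    A "cell" is a person x indicator pair: wave rows of the same person stay
    consistent. Phenotype, ids and demographics are never touched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missing rate must be in [0, 1]")
    out = cohort.copy()
    if rate == 0 or out.empty:
        return out
    persons = out["person_id"].unique()
    pos = {p: i for i, p in enumerate(persons)}
    row_person = out["person_id"].map(pos).to_numpy()
    for col in SES_INDICATOR_COLUMNS:
        if col not in out.columns:
            continue
        miss = rng.random(len(persons)) < rate
        mask = miss[row_person]
        if out[col].dtype == object:
            out.loc[mask, col] = np.nan
        else:
            out[col] = out[col].astype(float)
            out.loc[mask, col] = np.nan
    return out


# ---------------------------------------------------------------------------
# analytic oracle


def model_implied_slopes(truth: TruthRecord) -> dict:
    """Closed-form population regression slopes implied by the generative model.

    Derivation (single stratum, standardized scales). Write ``U`` for the
    offspring true score, ``NT`` for the weighted non-transmitted score, and
    ``S* = gamma (U + NT) + eps``.  With ``V = Var(U) = Var(NT) = sum w^2 2pq``
    and transmission independent across parents and SNPs:

        Cov(U, S*)  = gamma V
        Var(S*)     = 2 gamma^2 V + var_ses_env
        rho         = Corr(U, S*) = gamma V / (sqrt(V) sigma_S)

    and for ``Y = b Z(U) + c Z(S*) + independent noise`` the single-predictor
    population slopes on standardized regressors are

        SES-only slope = c + b rho
        PGS-only slope = b + c rho

    Requires ``n_strata == 1``: with substructure plus a stratum phenotype
    effect the single-predictor slopes acquire extra confounding terms.
    """
    p = truth.params
    if p["n_strata"] != 1:
        raise ValueError("slope oracle is defined for single-stratum cohorts")
    v = p["var_u_theoretical"]
    gamma, c, b = p["gamma"], p["c_env"], p["b_child"]
    var_s = 2 * gamma**2 * v + p["var_ses_env"]
    rho = gamma * v / math.sqrt(v * var_s)
    return {
        "var_u": v,
        "var_ses": var_s,
        "rho": rho,
        "ses_only_slope": c + b * rho,
        "pgs_only_slope": b + c * rho,
    }


# ---------------------------------------------------------------------------
# I/O


RAW_HEADER = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _raw_frame(sim: SimulatedCohort) -> pd.DataFrame:
    trios = sim.trios
    dos = trios.child_dosages
    female = (
        sim.cohort.drop_duplicates("person_id").set_index("person_id")["female"]
        if not sim.cohort.empty
        else pd.Series(dtype=int)
    )
    cols = {
        "FID": trios.family_ids[trios.person_family_index],
        "IID": trios.person_ids,
        "PAT": np.zeros(len(trios.person_ids), dtype=int),
        "MAT": np.zeros(len(trios.person_ids), dtype=int),
        "SEX": np.array(
            [2 if female.get(p, 0) == 1 else 1 for p in trios.person_ids], dtype=int
        ),
        "PHENOTYPE": np.full(len(trios.person_ids), -9, dtype=int),
    }
    snp_cols = {
        f"{sid}_{al}": (dos[:, j] if len(trios.person_ids) else np.array([], dtype=int))
        for j, (sid, al) in enumerate(zip(trios.snp_ids, trios.effect_alleles))
    }
    return pd.DataFrame({**cols, **snp_cols})


def write_cohort(sim: SimulatedCohort, outdir) -> dict:
    """Write the cohort bundle to ``outdir``; returns the path map.

    Formats: cohort and truth as CSV, dosages in the PLINK ``.raw`` text
    dialect, analyst weights as 3-column TSVs, true parameters as JSON.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out / "cohort.csv",
        "dosages": out / "dosages.raw",
        "weights_edu": out / "weights_edu.tsv",
        "weights_cog": out / "weights_cog.tsv",
        "truth": out / "truth.csv",
        "truth_params": out / "truth_params.json",
    }
    sim.cohort.to_csv(paths["cohort"], index=False)
    _raw_frame(sim).to_csv(paths["dosages"], sep=" ", index=False)
    sim.weights["edu"].to_csv(paths["weights_edu"], sep="\t", index=False)
    sim.weights["cog"].to_csv(paths["weights_cog"], sep="\t", index=False)
    sim.truth.persons.to_csv(paths["truth"], index=False)
    with open(paths["truth_params"], "w") as fh:
        json.dump(sim.truth.params, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(outdir) -> dict:
    """Read back a bundle written by :func:`write_cohort`."""
    out = Path(outdir)
    cohort = pd.read_csv(out / "cohort.csv")
    weights = {
        "edu": pd.read_csv(out / "weights_edu.tsv", sep="\t"),
        "cog": pd.read_csv(out / "weights_cog.tsv", sep="\t"),
    }
    truth = pd.read_csv(out / "truth.csv")
    with open(out / "truth_params.json") as fh:
        params = json.load(fh)
    return {"cohort": cohort, "weights": weights, "truth": truth, "params": params}
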