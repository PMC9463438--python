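"""Polygenic scoring and ancestry principal components.

Reads a GWAS weight table (snp_id, effect_allele, beta), a dosage matrix in
the PLINK ``.raw`` text dialect (or a plain person x SNP table), computes the
weighted-sum polygenic score

    PGS_i = sum_j beta_j * X_ij,      X_ij in [0, 2] effect-allele dosages,

standardizes it into a Z score within user-chosen strata, and computes the
top principal components of the standardized dosage matrix for use as
population-stratification controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GwasWeights",
    "DosageMatrix",
    "read_weights",
    "read_dosages",
    "compute_pgs",
    "standardize",
    "genotype_pcs",
]

VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
RAW_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GwasWeights:
    """Per-SNP effect alleles and weights."""

    table: pd.DataFrame  # columns: snp_id, effect_allele, beta

    def __post_init__(self):
        t = self.table
        dup = t["snp_id"][t["snp_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate snp_id(s) in weights: {sorted(set(dup))[:5]}")
        bad = set(t["effect_allele"].astype(str)) - VALID_ALLELES
        if bad:
            raise ValueError(f"non-ACGT effect allele(s): {sorted(bad)}")
        if not np.all(np.isfinite(t["beta"].to_numpy(dtype=float))):
            raise ValueError("non-finite beta in weights")

    def __len__(self):
        return len(self.table)

    @property
    def snp_ids(self):
        return self.table["snp_id"].to_numpy()

    @property
    def betas(self):
        return self.table["beta"].to_numpy(dtype=float)


@dataclass
class DosageMatrix:
    """Effect-allele dosages aligned to a weight table.

    ``values`` is persons x SNPs with entries in [0, 2]; fractional entries
    appear where missing genotypes were imputed to twice the observed allele
    frequency.
    """

    person_ids: np.ndarray
    snp_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.person_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix dimensions inconsistent with ids")
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 2):
            raise ValueError("dosage outside [0, 2]")


def read_weights(path) -> GwasWeights:
    """Read a 3-column tab-delimited weight file with header.

    Raises on duplicate SNP ids, non-ACGT alleles, or an unparseable beta
    (the error names the offending line).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    required = ["snp_id", "effect_allele", "beta"]
    if list(raw.columns[:3]) != required:
        raise ValueError(f"weight file must have header columns {required}")
    betas = pd.to_numeric(raw["beta"], errors="coerce")
    bad = betas.isna() & raw["beta"].notna()
    if bad.any() or raw["beta"].isna().any():
        line = int(np.argmax((bad | raw["beta"].isna()).to_numpy())) + 2  # 1-based + header
        raise ValueError(f"unparseable beta at line {line} of {path}")
    table = pd.DataFrame(
        {
            "snp_id": raw["snp_id"].astype(str),
            "effect_allele": raw["effect_allele"].astype(str).str.upper(),
            "beta": betas.astype(float),
        }
    )
    return GwasWeights(table)


def _counted_alleles(columns):
    """Map column name -> (snp_id, counted_allele or None).

    ``.raw`` columns are ``SNP_allele``; a plain table may name columns by
    bare SNP id, in which case the counted allele is unknown and assumed to
    be the effect allele.
    """
    out = {}
    for col in columns:
        snp, sep, allele = col.rpartition("_")
        if sep and len(allele) == 1 and allele.upper() in VALID_ALLELES:
            out[col] = (snp, allele.upper())
        else:
            out[col] = (col, None)
    return out


def read_dosages(path, weights: GwasWeights) -> DosageMatrix:
    """Read dosages and align them to ``weights``.

    Accepts the PLINK ``.raw`` dialect (header ``FID IID PAT MAT SEX
    PHENOTYPE`` then one ``SNP_allele`` column per SNP, whitespace-delimited)
    or a plain table with a ``person_id`` column and ``SNP`` or ``SNP_allele``
    columns. Where the counted allele differs from the weight file's effect
    allele the dosage is reflected (d -> 2 - d); missing entries are imputed
    to twice the observed effect-allele frequency at that SNP. A/T and C/G
    SNP flips are strand-ambiguous and trigger a warning.
    """
    head = pd.read_csv(path, sep=None, engine="python", nrows=0)
    if list(head.columns[:6]) == RAW_META_COLUMNS:
        df = pd.read_csv(path, sep=r"\s+")
        person_ids = df["IID"].astype(str).to_numpy()
        snp_cols = [c for c in df.columns if c not in RAW_META_COLUMNS]
    else:
        df = pd.read_csv(path, sep=None, engine="python")
        if "person_id" not in df.columns:
            raise ValueError("plain dosage table needs a 'person_id' column")
        person_ids = df["person_id"].astype(str).to_numpy()
        snp_cols = [c for c in df.columns if c != "person_id"]

    col_info = _counted_alleles(snp_cols)
    by_snp = {snp: (col, allele) for col, (snp, allele) in col_info.items()}

    missing = [s for s in weights.snp_ids if s not in by_snp]
    if missing:
        raise ValueError(f"SNP(s) in weights absent from dosage file: {missing[:10]}")

    n = len(person_ids)
    k = len(weights)
    values = np.empty((n, k), dtype=float)
    ambiguous = []
    for j, (snp, eff) in enumerate(
        zip(weights.snp_ids, weights.table["effect_allele"])
    ):
        col, counted = by_snp[snp]
        d = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        obs0 = d[~np.isnan(d)]
        if len(obs0) and (obs0.min() < 0 or obs0.max() > 2):
            raise ValueError(f"dosage outside [0, 2] in column {col!r}")
        if counted and counted != eff:
            d = 2.0 - d
            if _COMPLEMENT.get(counted) == eff:
                ambiguous.append(snp)
        obs = d[~np.isnan(d)]
        if np.isnan(d).any():
            freq = obs.mean() / 2.0 if len(obs) else 0.0
            d = np.where(np.isnan(d), 2.0 * freq, d)
        values[:, j] = d
    if ambiguous:
        warnings.warn(
            f"strand-ambiguous allele flip (A/T or C/G) at {len(ambiguous)} SNP(s), "
            f"e.g. {ambiguous[:3]}; complement strand cannot be resolved",
            UserWarning,
            stacklevel=2,
        )
    return DosageMatrix(person_ids=person_ids, snp_ids=weights.snp_ids.copy(), values=values)


def dosages_from_arrays(person_ids, snp_ids, values) -> DosageMatrix:
    """Build a DosageMatrix directly from in-memory arrays (already aligned)."""
    return DosageMatrix(
        person_ids=np.asarray(person_ids),
        snp_ids=np.asarray(snp_ids),
        values=np.asarray(values, dtype=float),
    )


def compute_pgs(weights: GwasWeights, dosages: DosageMatrix) -> pd.DataFrame:
    """Raw polygenic score per person: the weighted dosage sum."""
    if len(weights) == 0:
        raise ValueError("empty weight set")
    if not np.array_equal(weights.snp_ids, dosages.snp_ids):
        raise ValueError("dosage matrix is not aligned to the weight table")
    raw = dosages.values @ weights.betas
    return pd.DataFrame({"person_id": dosages.person_ids, "pgs_raw": raw})


def standardize(scores: pd.DataFrame, strata=None, score_col: str = "pgs_raw") -> pd.DataFrame:
    """Z-standardize raw scores within strata (sample sd, n-1 denominator).

    ``strata`` maps person_id -> stratum label (Series, dict or array aligned
    with ``scores``); omit it to standardize within the combined sample. The
    output carries the stratum used plus the per-stratum mean and sd.
    """
    out = scores.copy()
    if strata is None:
        lab = pd.Series("all", index=out.index)
    elif isinstance(strata, pd.Series) and not strata.index.equals(out.index):
        lab = out["person_id"].map(strata)
        if lab.isna().any():
            raise ValueError("strata mapping misses some person_ids")
    else:
        lab = pd.Series(np.asarray(strata), index=out.index)
    out["stratum"] = lab.to_numpy()
    z = np.empty(len(out))
    for s, idx in out.groupby("stratum").groups.items():
        vals = out.loc[idx, score_col].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"stratum {s!r} has fewer than 2 persons")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero within-stratum score variance in stratum {s!r}")
        z[out.index.get_indexer(idx)] = (vals - vals.mean()) / sd
    out["pgs_z"] = z
    return out


def genotype_pcs(dosages: DosageMatrix, k: int = 10) -> pd.DataFrame:
    """Top-k principal components of the column-standardized dosage matrix.

    Monomorphic SNPs are dropped before standardization. Components are
    mutually orthogonal; each component's sign is fixed so its largest-
    magnitude SNP loading is positive.
    """
    x = dosages.values
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    poly = sd > 0
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    if k > min(x.shape[0], int(poly.sum())):
        raise ValueError("k exceeds the number of persons or polymorphic SNPs")
    xs = (x[:, poly] - x[:, poly].mean(axis=0)) / sd[poly]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    pcs = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    cols = {f"pc{j + 1}": pcs[:, j] for j in range(k)}
    return pd.DataFrame({"person_id": dosages.person_ids, **cols})
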