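"""SES design construction.

Builds the regression design used by the multilevel models: reference-coded
categorical SES blocks with explicit "missing" levels, the tract-level
neighborhood-disadvantage index (first principal component of six tract
measures, computed separately per wave), and the single SES summary score
(first principal component of ordinal SES inputs) used by the G×E analysis.

Category coding follows the convention that every categorical block carries
an indicator column per non-reference level plus one "missing" column that is
always emitted (all zero when nothing is missing) so the design schema is
stable across cohorts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "load_occupation_lookup",
    "encode_categoricals",
    "neighborhood_index",
    "ses_summary_pc",
    "build_design",
    "SesDesign",
]

MISSING = "missing"

EDUCATION_LEVELS = ("lt_hs", "hs_some_college", "college")        # ref: lt_hs
OCCUPATION_CLASSES = (
    "manual_blue_collar",                                          # reference
    "none_other",
    "sales_service_admin",
    "professional_managerial",
)
INCOME_LEVELS = (1, 2, 3, 4, 5)                                    # ref: 1 (0-20 pct)
SIBSHIP_LEVELS = ("no_sibling", "sib_1_2", "sib_3_5", "sib_6plus") # ref: no_sibling

TRACT_MEASURES = (
    "tract_poverty",
    "tract_unemployment",
    "tract_female_headed",
    "tract_no_hs_diploma",
    "tract_college_degree",
    "tract_managerial_jobs",
)

_EDU_ORDINAL = {"lt_hs": 1, "hs_some_college": 2, "college": 3}


def load_occupation_lookup() -> pd.DataFrame:
    """Packaged occupation table: raw 16 codes -> 5-class collapse and the
    11-level prestige scale. Shipped as an editable CSV."""
    ref = importlib.resources.files("gnurture.data") / "occupation_codes.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    df["occ_code"] = df["occ_code"].astype(int)
    return df


@dataclass
class SesDesign:
    """Design matrix plus bookkeeping of which columns form which block."""

    data: pd.DataFrame
    blocks: dict = field(default_factory=dict)

    @property
    def ses_columns(self):
        cols = []
        for block_cols in self.blocks.values():
            cols.extend(block_cols)
        return cols


def _encode_block(values: pd.Series, levels, reference, prefix) -> pd.DataFrame:
    """Reference-code one categorical block with an explicit missing level.

    ``values`` may contain NaN (coded as missing). Unknown labels raise.
    """
    out = pd.DataFrame(index=values.index)
    is_na = values.isna()
    known = set(map(str, levels)) | {MISSING}
    bad = set(values[~is_na].astype(str).unique()) - known
    if bad:
        raise ValueError(
            f"unknown category label(s) in {values.name!r}: {sorted(bad)}"
        )
    coded = values.astype("string").where(~is_na, MISSING)
    for lev in levels:
        if str(lev) == str(reference):
            continue
        out[f"{prefix}_{lev}"] = (coded == str(lev)).astype(int)
    out[f"{prefix}_{MISSING}"] = (coded == MISSING).astype(int)
    return out


def encode_categoricals(cohort: pd.DataFrame) -> SesDesign:
    """Encode the SES categorical blocks of a cohort table.

    Expects the documented cohort schema (education levels, 16-code parental
    occupations, income quintiles 1-5, sibship size counts, two-biological-
    parent flag). Occupation codes are collapsed through the packaged lookup
    before coding. Returns a :class:`SesDesign` whose ``data`` aligns with
    the input rows and whose ``blocks`` map block names to column lists.
    """
    lookup = load_occupation_lookup().set_index("occ_code")["class5"]
    design = pd.DataFrame(index=cohort.index)
    blocks = {}

    for parent in ("mother", "father"):
        col = f"{parent}_edu"
        enc = _encode_block(cohort[col], EDUCATION_LEVELS, "lt_hs", col)
        design = pd.concat([design, enc], axis=1)
        blocks[col] = list(enc.columns)

    for parent in ("mother", "father"):
        col = f"{parent}_occ_code"
        codes = cohort[col]
        is_na = codes.isna()
        numeric = pd.to_numeric(codes, errors="coerce")
        bad = codes[~is_na & numeric.isna()]
        if len(bad):
            raise ValueError(
                f"unknown category label(s) in {col!r}: {sorted(set(bad.astype(str)))[:5]}"
            )
        unknown_codes = set(numeric.dropna().astype(int)) - set(lookup.index)
        if unknown_codes:
            raise ValueError(
                f"unknown occupation code(s) in {col!r}: {sorted(unknown_codes)}"
            )
        classes = numeric.map(lambda c: lookup.get(int(c)) if pd.notna(c) else np.nan)
        classes.name = col
        enc = _encode_block(
            classes, OCCUPATION_CLASSES, "manual_blue_collar", f"{parent}_occ"
        )
        design = pd.concat([design, enc], axis=1)
        blocks[f"{parent}_occ"] = list(enc.columns)

    inc = pd.to_numeric(cohort["income_quintile"], errors="coerce")
    bad_inc = set(inc.dropna().astype(int)) - set(INCOME_LEVELS)
    if bad_inc:
        raise ValueError(f"unknown category label(s) in 'income_quintile': {sorted(bad_inc)}")
    inc_lab = inc.map(lambda q: f"q{int(q)}" if pd.notna(q) else np.nan)
    inc_lab.name = "income_quintile"
    enc = _encode_block(inc_lab, [f"q{q}" for q in INCOME_LEVELS], "q1", "income")
    design = pd.concat([design, enc], axis=1)
    blocks["income"] = list(enc.columns)

    size = pd.to_numeric(cohort["sibship_size"], errors="coerce")
    cat = pd.Series(
        np.select(
            [size == 0, size <= 2, size <= 5, size > 5],
            list(SIBSHIP_LEVELS),
            default=None,
        ),
        index=cohort.index,
        name="sibship",
    ).where(size.notna(), np.nan)
    enc = _encode_block(cat, SIBSHIP_LEVELS, "no_sibling", "sibship")
    design = pd.concat([design, enc], axis=1)
    blocks["sibship"] = list(enc.columns)

    design["two_bio_parents"] = (
        pd.to_numeric(cohort["two_bio_parents"], errors="coerce").fillna(0).astype(int)
    )
    blocks["family_structure"] = ["two_bio_parents"]

    return SesDesign(data=design, blocks=blocks)


def _first_pc(x: np.ndarray):
    """First principal component of a column-standardized matrix via SVD.

    Returns (scores, loadings). Columns with zero variance raise.
    """
    sd = x.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("all input measures have zero variance")
    keep = sd > 0
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    scores = u[:, 0] * s[0]
    loadings = np.zeros(x.shape[1])
    loadings[keep] = vt[0]
    return scores, loadings


def neighborhood_index(panel: pd.DataFrame, wave_col: str = "wave") -> pd.DataFrame:
    """Per-tract standardized neighborhood-disadvantage score, per wave.

    ``panel`` holds one row per tract (and wave, if ``wave_col`` present) with
    the six tract proportion columns. A separate principal component analysis
    is run for each wave; the component is oriented so the below-poverty
    proportion loads positively (higher score = more disadvantaged) and is
    standardized to mean 0, sd 1 within wave.
    """
    missing_cols = [c for c in TRACT_MEASURES if c not in panel.columns]
    if missing_cols:
        raise ValueError(f"panel lacks tract measures: {missing_cols}")
    waves = panel[wave_col].unique() if wave_col in panel.columns else [None]
    out = []
    for w in waves:
        sub = panel if w is None else panel[panel[wave_col] == w]
        if len(sub) < 2:
            raise ValueError("need at least two tracts per wave")
        x = sub[list(TRACT_MEASURES)].to_numpy(dtype=float)
        scores, loadings = _first_pc(x)
        pov = loadings[TRACT_MEASURES.index("tract_poverty")]
        orient = pov if pov != 0 else loadings[np.argmax(np.abs(loadings))]
        if orient < 0:
            scores = -scores
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        res = pd.DataFrame(
            {"tract_id": sub["tract_id"].to_numpy(), "nbhd_disadvantage": scores}
        )
        if w is not None:
            res[wave_col] = w
        out.append(res)
    return pd.concat(out, ignore_index=True)


def ses_summary_pc(cohort: pd.DataFrame, nbhd: pd.Series | None = None,
                   stratum_col: str = "stratum") -> pd.Series:
    """Single standardized SES summary score (first principal component).

    Inputs are ordinal/continuous versions of the SES block: parental
    education (1-3), income quintile (1-5), parental occupation on the
    11-level prestige scale, sibship size, the two-biological-parent flag and
    (when supplied) the neighborhood-disadvantage index with its sign flipped
    so that *higher = more advantaged* on every input. Missing values are
    mean-substituted within stratum before the PCA. The component is oriented
    so parental education loads positively and standardized to mean 0, sd 1.

    Returns a Series aligned with ``cohort``'s rows.
    """
    lookup = load_occupation_lookup().set_index("occ_code")["prestige11"]

    inputs = pd.DataFrame(index=cohort.index)
    for parent in ("mother", "father"):
        inputs[f"{parent}_edu_ord"] = cohort[f"{parent}_edu"].map(_EDU_ORDINAL)
        occ = pd.to_numeric(cohort[f"{parent}_occ_code"], errors="coerce")
        inputs[f"{parent}_occ_prestige"] = occ.map(
            lambda c: lookup.get(int(c)) if pd.notna(c) else np.nan
        )
    inputs["income_quintile"] = pd.to_numeric(cohort["income_quintile"], errors="coerce")
    inputs["sibship_size_neg"] = -pd.to_numeric(cohort["sibship_size"], errors="coerce")
    inputs["two_bio_parents"] = pd.to_numeric(cohort["two_bio_parents"], errors="coerce")
    if nbhd is not None:
        inputs["nbhd_advantage"] = -pd.to_numeric(nbhd, errors="coerce").to_numpy()

    complete = inputs.notna().sum(axis=0) > 0
    if complete.sum() < 2:
        raise ValueError("need at least two SES indicators with data")
    inputs = inputs.loc[:, complete]

    if stratum_col in cohort.columns:
        grp = cohort[stratum_col]
        filled = inputs.groupby(grp, group_keys=False).apply(
            lambda d: d.fillna(d.mean())
        )
        filled = filled.fillna(inputs.mean())
    else:
        filled = inputs.fillna(inputs.mean())

    scores, loadings = _first_pc(filled.to_numpy(dtype=float))
    edu_cols = [i for i, c in enumerate(inputs.columns) if c.endswith("_edu_ord")]
    orient = loadings[edu_cols].sum() if edu_cols else loadings[np.argmax(np.abs(loadings))]
    if orient < 0:
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return pd.Series(scores, index=cohort.index, name="ses_pc")


DEMOGRAPHIC_COLUMNS = ("age", "female", "us_born", "english_home", "in_school", "hispanic")


def build_design(cohort: pd.DataFrame) -> SesDesign:
    """Full analysis design: SES blocks + neighborhood index + demographics.

    Convenience wrapper used by the pipeline: encodes the categorical blocks,
    computes the per-wave neighborhood index from the tract columns, merges
    demographics, and attaches the SES summary score as ``ses_pc``.
    """
    enc = encode_categoricals(cohort)
    data = enc.data
    blocks = dict(enc.blocks)

    panel = cohort[["tract_id", "wave", *TRACT_MEASURES]].drop_duplicates(
        ["tract_id", "wave"]
    )
    idx = neighborhood_index(panel)
    merged = cohort[["tract_id", "wave"]].merge(idx, on=["tract_id", "wave"], how="left")
    data = data.copy()
    data["nbhd_disadvantage"] = merged["nbhd_disadvantage"].to_numpy()
    blocks["neighborhood"] = ["nbhd_disadvantage"]

    for col in DEMOGRAPHIC_COLUMNS:
        if col in cohort.columns:
            data[col] = cohort[col].to_numpy()
    for col in ("person_id", "family_id", "sibship_type", "wave", "pvt_score", "stratum"):
        if col in cohort.columns:
            data[col] = cohort[col].to_numpy()

    data["ses_pc"] = ses_summary_pc(cohort, nbhd=data["nbhd_disadvantage"]).to_numpy()
    return SesDesign(data=data, blocks=blocks)
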